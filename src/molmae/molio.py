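"""Molecular I/O: SMILES parsing, graph featurization, datasets and splits.

Molecules are heavy-atom graphs (implicit hydrogens), the standard
MoleculeNet convention. Node and edge features are small categorical
vocabularies — the minimal set used throughout GNN pretraining work:

* node: atomic number (Z = 1..119, plus an out-of-vocabulary bucket) and
  the RDKit chirality tag (4 categories);
* edge: bond type (single / double / triple / aromatic, plus OOV) and
  bond direction (none / end-up-right / end-down-right).

Every chemical bond is stored in both directions so message passing can
treat ``edge_index`` as a directed edge list.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from .exceptions import (
    ConfigurationError,
    DatasetError,
    GraphIntegrityError,
    SmilesLengthError,
    SmilesParseError,
)

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

MAX_SMILES_LEN = 125

# Node feature vocabularies.
N_ATOM_TYPES = 120          # Z in 1..119 -> index Z-1; index 119 is OOV
ATOM_OOV_INDEX = 119
CHIRALITY_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
)
N_CHIRALITY_TAGS = len(CHIRALITY_TAGS)

# Edge feature vocabularies.
BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
BOND_OOV_INDEX = len(BOND_TYPES)   # 4
N_BOND_TYPES = len(BOND_TYPES) + 1  # incl. OOV
BOND_DIRS = (
    Chem.BondDir.NONE,
    Chem.BondDir.ENDUPRIGHT,
    Chem.BondDir.ENDDOWNRIGHT,
)
N_BOND_DIRS = len(BOND_DIRS)


@dataclass
class MolecularGraph:
    """A featurized heavy-atom molecular graph.

    ``edge_index`` has shape ``(2, E)`` with each chemical bond present in
    both directions; ``edge_attrs`` rows align with ``edge_index`` columns.
    """

    smiles: str
    node_attrs: np.ndarray          # (n_nodes, 2) int
    edge_index: np.ndarray          # (2, E) int
    edge_attrs: np.ndarray          # (E, 2) int

    @property
    def n_nodes(self) -> int:
        return int(self.node_attrs.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edge_index.shape[1])

    def validate(self) -> None:
        n = self.n_nodes
        if self.node_attrs.ndim != 2 or self.node_attrs.shape[1] != 2:
            raise GraphIntegrityError("node_attrs must be (n_nodes, 2)")
        if self.edge_index.shape[0] != 2:
            raise GraphIntegrityError("edge_index must be (2, E)")
        if self.edge_attrs.shape[0] != self.edge_index.shape[1]:
            raise GraphIntegrityError("edge_attrs rows must align with edge_index")
        if self.n_edges:
            if self.edge_index.min() < 0 or self.edge_index.max() >= n:
                raise GraphIntegrityError("edge endpoint out of range")
            if np.any(self.edge_index[0] == self.edge_index[1]):
                raise GraphIntegrityError("self-loop edge from a bond")
            fwd = {(int(u), int(v)): tuple(a)
                   for (u, v), a in zip(self.edge_index.T, self.edge_attrs)}
            for (u, v), attrs in fwd.items():
                if fwd.get((v, u)) != attrs:
                    raise GraphIntegrityError("edge_index is not symmetric")


def featurize(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(node_attrs, edge_index, edge_attrs)`` for a parsed molecule.

    Out-of-vocabulary atoms or bond types map to the OOV bucket with a
    logged warning.
    """
    node_attrs = np.zeros((mol.GetNumAtoms(), 2), dtype=np.int64)
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if 1 <= z <= 119:
            z_idx = z - 1
        else:
            z_idx = ATOM_OOV_INDEX
            logger.warning("atom Z=%d outside vocabulary; using OOV bucket", z)
        try:
            chir_idx = CHIRALITY_TAGS.index(atom.GetChiralTag())
        except ValueError:
            chir_idx = CHIRALITY_TAGS.index(Chem.ChiralType.CHI_OTHER)
        node_attrs[atom.GetIdx()] = (z_idx, chir_idx)

    src, dst, attrs = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        try:
            bt = BOND_TYPES.index(bond.GetBondType())
        except ValueError:
            bt = BOND_OOV_INDEX
            logger.warning("bond type %s outside vocabulary; using OOV bucket",
                           bond.GetBondType())
        try:
            bd = BOND_DIRS.index(bond.GetBondDir())
        except ValueError:
            bd = 0
        src.extend((u, v))
        dst.extend((v, u))
        attrs.extend(((bt, bd), (bt, bd)))
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    edge_attrs = np.array(attrs, dtype=np.int64).reshape(-1, 2)
    return node_attrs, edge_index, edge_attrs


def parse_smiles(smiles: str, max_len: int = MAX_SMILES_LEN) -> MolecularGraph:
    """Parse one SMILES string into a featurized :class:`MolecularGraph`."""
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    if max_len < 1:
        raise ConfigurationError(f"max_len must be >= 1, got {max_len}")
    if len(smiles) > max_len:
        raise SmilesLengthError(
            f"SMILES longer than {max_len} characters: {smiles[:40]}...")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    node_attrs, edge_index, edge_attrs = featurize(mol)
    graph = MolecularGraph(canonical, node_attrs, edge_index, edge_attrs)
    graph.validate()
    return graph


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES (empty string for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)


@dataclass
class TaskDataset:
    """Molecules with labels, a task type, and (optionally) a split.

    ``labels`` is ``(n_molecules, n_tasks)`` float; missing entries are NaN
    (multi-task masking). ``split`` maps partition name to row indices.
    """

    graphs: list[MolecularGraph]
    labels: np.ndarray
    task_type: str                  # "classification" | "regression"
    split: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.task_type not in ("classification", "regression"):
            raise ConfigurationError(f"unknown task_type: {self.task_type!r}")
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=np.float64))
        if self.labels.shape[0] != len(self.graphs):
            raise DatasetError("labels rows must match number of graphs")

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def n_tasks(self) -> int:
        return int(self.labels.shape[1])

    def subset(self, indices: list[int]) -> "TaskDataset":
        return TaskDataset([self.graphs[i] for i in indices],
                           self.labels[np.asarray(indices, dtype=int)],
                           self.task_type)

    def validate_split(self) -> None:
        if not self.split:
            raise DatasetError("dataset has no split assigned")
        seen: set[int] = set()
        total = 0
        for part, idx in self.split.items():
            s = set(idx)
            if len(s) != len(idx):
                raise DatasetError(f"duplicate indices in partition {part!r}")
            if s & seen:
                raise DatasetError("split partitions are not disjoint")
            seen |= s
            total += len(idx)
        if total != len(self.graphs):
            raise DatasetError("split does not cover all graphs")


def scaffold_split(dataset: TaskDataset,
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
                   ) -> TaskDataset:
    """Deterministic Bemis-Murcko scaffold split.

    Whole scaffold groups are assigned greedily — largest group first,
    ties broken by lexicographic scaffold string — filling train, then
    valid, then test. A group larger than the entire train allocation is
    still placed in train (with a warning) so the scaffold invariant is
    never broken.

    Acyclic molecules have no ring system, hence no Bemis-Murcko
    framework; each forms its own singleton group (keyed by canonical
    SMILES for determinism) rather than one giant pseudo-group, so they
    distribute across partitions like any other structural outlier.
    """
    if len(dataset) == 0:
        raise DatasetError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ConfigurationError(f"fractions must sum to 1, got {fractions}")
    n = len(dataset)
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(dataset.graphs):
        scaffold = murcko_scaffold(g.smiles)
        key = scaffold if scaffold else f"\x00acyclic:{g.smiles}:{i}"
        groups.setdefault(key, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    cap_train = int(round(fractions[0] * n))
    cap_valid = int(round(fractions[1] * n))
    parts: dict[str, list[int]] = {"train": [], "valid": [], "test": []}
    for scaffold, idx in ordered:
        if len(idx) > cap_train:
            logger.warning(
                "scaffold group %r (%d molecules) exceeds the train allocation "
                "(%d); placing it in train", scaffold, len(idx), cap_train)
            parts["train"].extend(idx)
        elif len(parts["train"]) + len(idx) <= cap_train:
            parts["train"].extend(idx)
        elif len(parts["valid"]) + len(idx) <= cap_valid:
            parts["valid"].extend(idx)
        else:
            parts["test"].extend(idx)
    out = TaskDataset(dataset.graphs, dataset.labels, dataset.task_type,
                      {k: sorted(v) for k, v in parts.items()})
    out.validate_split()
    return out


def random_split(dataset: TaskDataset,
                 fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> TaskDataset:
    """Uniform random split (used for regression tasks)."""
    if len(dataset) == 0:
        raise DatasetError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ConfigurationError(f"fractions must sum to 1, got {fractions}")
    n = len(dataset)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    split = {"train": sorted(map(int, perm[:n_train])),
             "valid": sorted(map(int, perm[n_train:n_train + n_valid])),
             "test": sorted(map(int, perm[n_train + n_valid:]))}
    out = TaskDataset(dataset.graphs, dataset.labels, dataset.task_type, split)
    out.validate_split()
    return out


def read_dataset(path: str | Path, smiles_col: str = "smiles",
                 label_cols: list[str] | None = None,
                 task_type: str = "classification",
                 max_len: int = MAX_SMILES_LEN) -> TaskDataset:
    """Read a MoleculeNet-layout CSV (``smiles`` column + label columns).

    Rows whose SMILES do not parse (or exceed ``max_len``) are dropped with
    a logged count; missing labels are preserved as NaN.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise DatasetError(f"empty dataset file: {path}")
    if smiles_col not in df.columns:
        raise ConfigurationError(f"missing SMILES column {smiles_col!r} in {path}")
    if label_cols is None:
        label_cols = [c for c in df.columns if c != smiles_col]
    for col in label_cols:
        if col not in df.columns:
            raise ConfigurationError(f"missing label column {col!r} in {path}")

    graphs: list[MolecularGraph] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    label_values = df[label_cols].to_numpy(dtype=np.float64) if label_cols \
        else np.zeros((len(df), 0))
    for i, smi in enumerate(df[smiles_col].astype(str)):
        try:
            graphs.append(parse_smiles(smi, max_len=max_len))
        except (SmilesParseError, SmilesLengthError):
            n_dropped += 1
            continue
        rows.append(label_values[i])
    if n_dropped:
        logger.info("dropped %d unparseable/over-length SMILES rows from %s",
                    n_dropped, path)
    if not graphs:
        raise DatasetError(f"no parseable molecules in {path}")
    labels = np.vstack(rows) if rows and rows[0].size else np.zeros((len(graphs), 0))
    return TaskDataset(graphs, labels, task_type)


def write_split_manifest(dataset: TaskDataset, path: str | Path) -> None:
    """Write the split as JSON lists of row indices per partition."""
    dataset.validate_split()
    Path(path).write_text(json.dumps(
        {k: list(map(int, v)) for k, v in dataset.split.items()}, indent=2))
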