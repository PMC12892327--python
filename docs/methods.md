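# Methods

This note documents the models implemented in `molmae`, the choices made
where the design was genuinely open, the synthetic data used to exercise
them, and the limits of what the tests show.

## Numerical core

No deep-learning framework is used. `molmae._autodiff` is a tape-based
reverse-mode automatic-differentiation engine over float64 NumPy arrays
(broadcast arithmetic, batched matmul, reductions, softmax, gather /
scatter-add, sparse-dense products). Constants never enter the tape, so
`Tensor.detach()` *is* the stop-gradient operator: quantities built from
detached data receive exactly zero gradient, which the tests assert
analytically rather than approximately. Double precision makes the
equivariance and oracle checks meaningful at 1e−6–1e−5 tolerances.

## Graph representation

Molecules are heavy-atom graphs (implicit hydrogens, the MoleculeNet
convention). Node features: atomic number (1–119 plus an OOV bucket) and
the RDKit chirality tag (4 values). Edge features: bond type (single /
double / triple / aromatic + OOV) and bond direction (3 values). Each
bond is stored in both directions. SMILES longer than 125 characters are
rejected — the cap matching the drug-like chemical space the method
targets. The feature set is deliberately the minimal one used across the
GNN-pretraining literature; nothing in the method depends on richer
descriptors.

## Parameter-free tokenizer

Reconstruction targets are per-node concatenations of K = 3 linear
propagation steps, H^l = ω(A) H^(l−1), starting from the encoder's own
embedding of the *unmasked* node attributes. ω(A) defaults to the
symmetric-normalized adjacency with self-loops (the simplified-GCN
operator); row-normalized and raw-sum variants are available via
`tokenizer.norm`. Two ambiguities were settled as follows:

* the concatenation covers hops 1..K — hop 0 carries no structural
  information; a config flag (`tokenizer.include_h0`) re-includes it;
* the tokenizer owns no weights (`n_trainable_parameters() == 0`); the
  shared embedding is counted with the encoder, and targets are always
  detached, so no loss can train the tokenizer through its output.

## Encoder and masking

Masking draws ⌊ρn + 0.5⌋ nodes (half-up rounding, minimum 1) and swaps
their embeddings for a learnable `[MASK]` row; edges are never masked.
The default ratio 0.45 is the value at which the architecture study
found the mask/reconstruct trade-off best. The encoder is a GIN stack of
depth 3 (sum aggregation with bond-feature messages, 2-layer MLP update,
layer norm + ReLU between layers); GCN and GAT variants exist behind
`encoder.arch` because the source description is inconsistent about the
pretraining encoder (a single-layer GCN in the text, GIN-3 in the
ablation optimum) — depth and architecture are therefore configuration,
with GIN-3 the default.

## Graph-Transformer decoder

One decoder layer runs `dmpn_hops` dynamic-message-passing steps —
m_v = Σ_{u∈N(v)} W[h_v ; h_u ; H_uv], h_v ← σ(W^l m_v + b^l) with W^l
shared across hops of a layer — followed by multi-head attention over
the nodes of each molecule (2 heads; attention is masked to be strictly
intra-molecule in batched mode). Agg2Node sums neighbor states per node;
Agg2Edge sums the two endpoint states per edge. A single long-range
residual carries the decoder's projected *input* node and edge features
to the output stage (there are no short-range residuals around the
message-passing or attention blocks), then layer norm, then a
feed-forward block. The concrete combiner inside the DMPN aggregation
(concatenate–project–sum) is the minimal choice consistent with the
triple (h_v, h_u, H_uv); the FFN keeps its internal residual so the
"zero the projections → output equals the projected residual" identity
holds exactly, which the tests use. Node and edge states are mean-pooled
per molecule and fused by a 2-layer MLP into the graph-level vector.

## Multi-view remasking and loss

Each view independently redraws ⌊ρn + 0.5⌋ nodes per molecule and
replaces their latent rows with a learnable decoder-side remask token.
`objective.views` = 0 / 1 / K ≥ 2 reproduces the no-remask, single-remask
and multi-view arms of the ablation. The Scaled Cosine Error
(1 − cos)^γ with γ = 2 (any γ > 1 is accepted) is evaluated, by default,
only on the originally masked nodes — the printed loss definition sums
over all nodes but normalizes by the masked count, an inconsistency
resolved in favor of the masked support (`objective.support = all`
restores the other reading). The default reconstruction target is the
tokenizer output (`objective.target = raw` switches to one-hot input
features); with raw targets the tokenizer would be purposeless, so
tokens are the default. Averaging SCE across views acts as a variance
regularizer; the test suite verifies the gradient-dispersion reduction
K = 4 vs K = 1 with a one-sided Mann-Whitney test.

## Fusion strategies

The sequence side tokenizes SMILES with the standard chemistry regex
(bracket atoms and two-letter elements are single tokens), adds learned
positional embeddings and pools a prepended `[CLS]` token from a 2-layer
post-norm Transformer.

* **Dual-tower**: symmetric InfoNCE on projected pooled vectors. As
  printed, the denominator of the contrastive ratio contains only
  matched pairs, which makes the loss identically zero; the implementation
  uses standard in-batch negatives cos(x_i, y_j), which is what the
  surrounding description of "maximizing the distance to other molecules'
  features" requires. Default τ = 0.5 (the dual tower needs a larger
  temperature than Q-Former).
* **Q-Former**: 16 learnable queries; per block, self-attention among
  queries, cross-attention to the molecule's node latents (this is where
  dimensions are aligned), FFN. Pair similarity is max_k cos(m_ik, t_j);
  the same max is applied on both InfoNCE directions for symmetry.
  Default τ = 0.1.
* **Dual-view consistency**: 3-layer projection and 2-layer prediction
  MLPs per modality; L = −cos(q_s, SG(p_g)) − cos(q_g, SG(p_s)) ∈ [−2, 2]
  with no negatives. The masked views feeding the loss reuse the
  pretraining node mask on the graph side and replace the same fraction
  of SMILES tokens with `[OOV]` on the sequence side (the masking ratio
  for these views is not otherwise specified). The projection grid
  (2–5 layers × 64–512 dims) is exposed because the prose (3 layers) and
  the ablation optimum (four 256-d layers) disagree.

Graph-side input to every strategy is the encoder's mean-pooled node
latents.

## Synthetic data

`molmae.synthdata` composes molecules from six ring cores (benzene,
pyridine, furan, thiophene, pyrrole, cyclohexane) and alkyl-chain cores,
attaching 0–3 acyclic substituents (alkyl, halide, amine, hydroxyl,
carbonyl…) by valence-respecting single bonds, so every emitted SMILES is
chemically valid by construction and well under the 125-character cap.
Ring cores are cycled round-robin, so scaffold-group sizes are exactly
balanced and scaffold splits behave deterministically; the ring fraction
is controlled exactly (default 0.5). Labels are computable from
structure: ring presence (binary), heteroatom count (regression), and an
additive per-element logP surrogate with an explicitly tabulated
contribution map. The corpus emulates the *structural* variety a
scaffold split needs (several ring systems, acyclic outliers) but none
of the property noise, activity cliffs, assay artifacts or size range of
real assay data — passing tests demonstrate that the machinery learns
and generalizes across scaffolds on clean signals, not that any
particular accuracy transfers to real benchmarks.

## Splits and evaluation

Scaffold splits group molecules by Bemis–Murcko scaffold string and
assign whole groups greedily (largest first, lexicographic tie-break,
filling train, then valid, then test). Acyclic molecules have no ring
system and hence no Murcko framework; each forms its own singleton group
rather than one giant pseudo-group keyed by the empty string — otherwise
every acyclic molecule lands in a single partition and a
structure-determined binary task becomes degenerate. An oversized group
is placed in train with a warning. Classification fine-tuning uses the
scaffold split, regression the random split. Evaluation defaults to the
full held-out set (valid ∪ test): the valid partition is never used for
model selection anywhere in the harness, so scoring it loses nothing and
keeps both classes present in small corpora; `finetune.eval_split`
restores test-only scoring.

Classification reports per-task ROC-AUC with missing labels excluded and
single-class tasks dropped (logged); regression reports RMSE. Reports
average over the configured seed list (five by default).

## Problem sizes and training settings

All study sizes were chosen as the smallest at which each effect is
clearly measurable on one CPU: overfit sanity uses 32 molecules × 200
epochs (batch 8); downstream recovery pretrains on 128 molecules and
fine-tunes on 400 (ring-presence corpus at ring fraction 0.9, under
which the greedy scaffold split deterministically holds out one unseen
ring system plus acyclic molecules, so held-out AUC is well-defined);
the remask ablation uses 96 pretraining molecules, a 240-molecule task,
five seeds, and a *linear probe* (frozen encoder) — with full fine-tuning
at this scale every arm saturates at AUC 1.0 and the comparison becomes
vacuous, whereas the probe isolates the quality of the pretrained
representation, which is the quantity the ablation is about. Optimizer
is Adam at lr 1e−3 throughout (the source defers its schedule to
supplementary material not available here; these are package defaults,
not reported settings). Hidden dimensions of 32 are used in the test
battery; defaults are 64.

## Determinism and numerical choices

Every loop is CPU-deterministic given the config seed (parameter init,
batch order, mask and remask draws all derive from it); repeated runs
reproduce loss trajectories bit for bit. Cosine similarities use an
ε-guarded denominator (ε = 1e−8) so zero-norm rows contribute finite
values and gradients. Mask counts round half-up (NumPy's banker's
rounding would make 0.45 × 20 ambiguous). Attention masks use additive
−1e9. Checkpoints serialize every parameter plus the config hash
(SHA-256 of the canonical JSON) into a single `.npz`.

## Known limitations

* No 3D information: conformers, stereochemistry beyond the RDKit tag,
  and geometry-aware pretraining are out of scope.
* The decoder attends over nodes only; edge states are carried through
  Agg2Edge but not attended over.
* Contrastive pretraining at desk scale uses small in-batch negative
  sets; temperatures were not re-tuned for them.
* Pure-NumPy training is practical up to thousands of molecules; the
  implementation is for study and verification, not large-corpus
  pretraining.
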