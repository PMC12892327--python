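"""Exception hierarchy used across the package."""


class MolmaeError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(MolmaeError, ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class SmilesLengthError(MolmaeError, ValueError):
    """Raised when a SMILES string exceeds the configured length cap."""


class ConfigurationError(MolmaeError, ValueError):
    """Raised for invalid configuration values (ratios, depths, head counts...)."""


class ContractError(MolmaeError, RuntimeError):
    """Raised when an operation is called with state violating its contract."""


class GraphIntegrityError(MolmaeError, ValueError):
    """Raised when a molecular graph violates its structural invariants."""


class DatasetError(MolmaeError, ValueError):
    """Raised for malformed or empty dataset inputs."""
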