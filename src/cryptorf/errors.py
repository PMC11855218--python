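"""Exception hierarchy shared across the package."""


class CryptOrfError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(CryptOrfError, ValueError):
    """A coordinate (offset, span) falls outside its sequence."""


class PhaseError(CryptOrfError, ValueError):
    """A nucleotide span that must be codon-phased is not a multiple of 3."""


class DataError(CryptOrfError, ValueError):
    """Inconsistent input data (alignment/member mismatch, bad group file)."""


class ConfigurationError(CryptOrfError, ValueError):
    """Invalid run parameters (empty groups, out-of-range options)."""


class GenerationError(CryptOrfError, RuntimeError):
    """Constrained sequence generation could not satisfy its constraints."""
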