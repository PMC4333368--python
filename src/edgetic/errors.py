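"""Exception hierarchy shared across the package."""


class EdgeticError(Exception):
    """Base class for all package errors."""


class StructureFormatError(EdgeticError):
    """Input text is not parseable PDB or mmCIF."""


class EmptyModelError(EdgeticError):
    """Structure contained no polymer chain."""


class ConfigError(EdgeticError):
    """Inconsistent or unknown configuration value."""


class InputError(EdgeticError):
    """Invalid user-supplied value (symbol, score range, table margin...)."""


class DerivationError(EdgeticError):
    """Pair-potential derivation is impossible on the given interfaces."""


class CalibrationError(EdgeticError):
    """Gold standard is degenerate or the corpus cannot support calibration."""


class GenerationError(EdgeticError):
    """A synthetic fixture spec could not be satisfied."""
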