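"""Exception hierarchy for kisbreed."""


class KisBreedError(Exception):
    """Base class for all kisbreed errors."""


class ConfigurationError(KisBreedError):
    """Invalid configuration: bad counts, rates, or cross-field constraints."""


class CalibrationError(KisBreedError):
    """Trait variance calibration impossible (e.g. all QTLs monomorphic)."""


class GenerationError(KisBreedError):
    """A requested object cannot be generated (e.g. too few eligible markers)."""


class DataShapeError(KisBreedError):
    """Inputs do not cover the required markers/loci or have mismatched shapes."""


class DegenerateDataError(KisBreedError):
    """Degenerate input data (e.g. all markers monomorphic for a GRM)."""


class NumericalError(KisBreedError):
    """A numerical routine failed (singular system, divergent chain)."""
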