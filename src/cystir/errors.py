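"""Exception hierarchy for cystir.

All package-specific failures derive from :class:`CystirError` so callers can
catch one base class; most also derive from the closest builtin (ValueError,
KeyError) so generic handling keeps working.
"""


class CystirError(Exception):
    """Base class for all cystir errors."""


class SpectrumFormatError(CystirError, ValueError):
    """A spectrum file could not be parsed."""


class SpectrumValidationError(CystirError, ValueError):
    """Spectrum arrays violate an invariant (non-monotonic grid, NaN, ...)."""


class GridRangeError(CystirError, ValueError):
    """A requested wavenumber or window lies outside a spectrum's coverage."""


class DegenerateReferenceError(CystirError, ValueError):
    """Reference spectrum is (numerically) zero on the requested fit window."""


class ConditioningError(CystirError, ValueError):
    """Deconvolution design matrix is rank-deficient / badly conditioned."""


class CalibrationError(CystirError, ValueError):
    """Calibration series is degenerate or a model is unusable for prediction."""


class ParameterError(CystirError, ValueError):
    """Invalid algorithm parameter (even SG window, bad polyorder, ...)."""


class PairingError(CystirError, ValueError):
    """Paired-method comparison received unmatched sample ids."""


class InsufficientDataError(CystirError, ValueError):
    """Too few observations for the requested statistic."""
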