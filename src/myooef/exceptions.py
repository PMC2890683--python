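"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`MyooefError`,
so callers can catch one type at a pipeline boundary.  Ordinary argument-domain
violations (negative tau, OEF outside [0, 1], unknown compartment) raise plain
``ValueError`` subclasses of it.
"""


class MyooefError(Exception):
    """Base class for all errors raised by myooef."""


class DataError(MyooefError, ValueError):
    """Malformed input data (CSV parsing, invalid series, mismatched grids)."""


class FitError(MyooefError, RuntimeError):
    """A regression failed to converge or produced a non-physical solution."""


class CalibrationError(FitError):
    """Rest calibration could not invert the two-compartment signal equation."""


class NoSolutionError(FitError):
    """The measured apparent T2 lies outside the range attainable on OEF in [0, 1].

    Attributes
    ----------
    attainable : tuple (t2_at_oef1_ms, t2_at_oef0_ms)
        The closed interval of apparent-T2 values the forward model can produce.
    """

    def __init__(self, message, attainable=None):
        super().__init__(message)
        self.attainable = attainable


class ModelViolationError(FitError):
    """The forward model violated an assumption (e.g. non-monotone T2(OEF))."""
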