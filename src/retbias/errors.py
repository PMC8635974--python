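"""Exception hierarchy for the retbias package."""


class RetbiasError(Exception):
    """Base class for all package errors."""


class ProtocolError(RetbiasError):
    """Invalid agonist-application protocol (overlap, bad times, bad concentrations)."""


class CorrectionError(RetbiasError):
    """Channel correction produced unusable data (e.g. widespread negative donor)."""


class TraceError(RetbiasError):
    """A ratio trace cannot be computed or processed."""


class WindowError(RetbiasError):
    """An amplitude-extraction window is empty or outside the recording."""


class FitError(RetbiasError):
    """A model fit could not be performed on the given data."""


class ConfigError(RetbiasError):
    """Pipeline configuration is invalid."""


class ScenarioError(RetbiasError):
    """Unknown synthetic scenario name."""
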