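"""Exception and warning types shared across the package."""


class SersmixError(Exception):
    """Base class for all package errors."""


class FormatError(SersmixError):
    """A spectra file could not be parsed; message names the offending row/column."""


class DuplicateRecordError(SersmixError):
    """Duplicate (sample, spot, shift) record, or duplicate shift within one spectrum."""


class GridMismatchError(SersmixError):
    """Spectra are not on the shift grid the operation requires."""


class ExtrapolationError(SersmixError):
    """Requested resampling grid extends outside the measured shift range."""


class DegenerateSpectrumError(SersmixError):
    """Spectrum has no usable intensity (e.g. all-zero under closure)."""


class RankError(SersmixError):
    """Too many principal components requested for the training set size."""


class DegenerateComponentsError(SersmixError):
    """The composition system is singular or ill-conditioned (near-collinear components)."""


class ParameterError(SersmixError):
    """Invalid parameter value (e.g. non-positive kinetics factor)."""


class DesignError(SersmixError):
    """Simulation design inconsistency (e.g. sample references unknown component)."""


class SampleLookupError(SersmixError):
    """Requested sample id is absent from a score table."""


class OutOfSimplexWarning(UserWarning):
    """A solved composition has fractions outside [0, 1] (noise or extrapolation)."""


class LowVarianceWarning(UserWarning):
    """Retained principal components explain less than 99% of training variance."""


class IntensityBudgetWarning(UserWarning):
    """Pure-component spectra have unequal total intensity, so intensity shares
    differ from mole-fraction weights."""
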