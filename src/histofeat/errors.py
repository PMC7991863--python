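"""Exception hierarchy for the histofeat pipeline.

Every error class maps to a distinct process exit code in the CLI (see
:mod:`histofeat.cli`), so scripted callers can distinguish bad parameters
from bad files from degenerate data.
"""


class HistofeatError(Exception):
    """Base class for all histofeat errors."""


class ParameterError(HistofeatError):
    """A parameter value is invalid or infeasible (e.g. an ROI area larger
    than the image grid, or a kurtosis target below the skewness^2 + 1
    moment bound)."""


class ConfigError(HistofeatError):
    """A run configuration is internally inconsistent (e.g. the extract
    stage is disabled but no feature table is supplied)."""


class UnsupportedInputError(HistofeatError):
    """The input file parses but is not a supported image class
    (multi-frame DICOM, RGB raster, ...)."""


class MetadataError(HistofeatError):
    """Required physical metadata is missing; in particular a raster image
    without a pixel-spacing sidecar is never given a silent default."""


class SchemaError(HistofeatError):
    """A tabular input does not match the documented column schema."""


class CongruenceError(HistofeatError):
    """An image and an ROI mask have different grid dimensions."""


class EmptyROIError(HistofeatError):
    """The ROI selects too few pixels for feature extraction (< 3)."""


class DegenerateInputError(HistofeatError):
    """A statistic is undefined for the given data (constant intensities
    have no standardized moments; a pooled t-test needs nonzero variance)."""
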