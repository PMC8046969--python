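"""Exception hierarchy.

All errors derive from :class:`SomasegError` so callers can catch the
package's failures with one clause; each subclass also derives from the
closest builtin so untyped ``except ValueError`` style code keeps working.
"""


class SomasegError(Exception):
    """Base class for all package errors."""


class FormatError(SomasegError, ValueError):
    """A file is not in the expected on-disk format."""


class EmptyInputError(SomasegError, ValueError):
    """An input carried no usable data (zero pages, empty list...)."""


class BoundsError(SomasegError, ValueError):
    """A geometric object does not fit inside its raster frame."""


class CoordinateOverflowError(SomasegError, OverflowError):
    """A vertex cannot be represented in the ImageJ 16-bit offset scheme."""


class SamplingError(SomasegError, RuntimeError):
    """Rejection sampling exhausted its retry budget."""


class PlacementError(SamplingError):
    """No collision-free placement could be found for a patch."""


class EstimationError(SomasegError, RuntimeError):
    """A statistic could not be estimated from the given data."""


class ConfigurationError(SomasegError, ValueError):
    """An invalid model or pipeline configuration."""


class ResourceError(SomasegError, FileNotFoundError):
    """A required external resource (e.g. a weights file) is missing."""


class DivergenceError(SomasegError, RuntimeError):
    """Training produced a non-finite loss."""


class ContractError(SomasegError, ValueError):
    """Two arguments that must agree (shapes, frames, counts) do not."""


class UndefinedMetricError(SomasegError, ValueError):
    """A metric is undefined for the given input (e.g. two empty masks)."""


class DependencyError(SomasegError, RuntimeError):
    """A pipeline stage is missing an artifact a previous stage produces."""
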