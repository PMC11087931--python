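"""Exception hierarchy shared across the toolkit."""


class CaasegError(Exception):
    """Base class for all caaseg errors."""


class FormatError(CaasegError):
    """File is not a recognised/valid volume or structure-set format."""


class UnsupportedGeometryError(CaasegError):
    """Non-axis-aligned orientation (direction cosines != identity), gantry tilt, etc."""


class GridMismatchError(CaasegError):
    """Two objects that must share one voxel grid do not."""


class ValidationError(CaasegError):
    """Domain invariant violated (non-binary mask, bad Likert score, ...)."""


class ParameterError(CaasegError, ValueError):
    """Parameter outside its admissible range."""


class LocalizationError(CaasegError):
    """Automatic heart localisation failed (e.g. fewer than two lungs found)."""


class MissingStructureError(CaasegError, KeyError):
    """A required structure is absent from a structure set."""


class DegenerateInputError(CaasegError):
    """Input is formally valid but carries no usable information (e.g. all-empty rater masks)."""


class UndefinedMetricError(CaasegError):
    """Requested metric is undefined for this input (e.g. 1-cc dose on a 0.8 cm^3 structure)."""


class CapabilityError(CaasegError):
    """Optional feature whose runtime support is not available in this installation."""
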