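"""Exception hierarchy for occlustress.

CLI maps InputError subclasses to exit code 2 and NumericalError to 3.
"""


class OcclustressError(Exception):
    """Base class for all package errors."""


class InputError(OcclustressError):
    """Invalid user input (files, parameters, schemas). CLI exit code 2."""


class MeshFormatError(InputError):
    """Unparseable mesh file; message names the offending line/byte offset."""


class EmptyMeshError(InputError):
    """Mesh with no vertices or faces where content is required."""


class DimensionError(InputError):
    """Array shape mismatch (e.g. scalar field length != face count)."""


class SchemaError(InputError):
    """CSV/config file does not match the documented schema."""


class SamplingError(InputError):
    """Non-uniform or otherwise invalid time sampling."""


class CoverageError(InputError):
    """Recording streams do not cover a common task interval."""


class ResolutionError(InputError):
    """Requested segmentation finer than the available samples."""


class DegenerateVectorError(InputError):
    """Coincident fixed/movable landmarks; message names the frame."""


class ParameterError(InputError):
    """Out-of-range scalar parameter."""


class GenerationError(InputError):
    """Synthetic dentition parameters produce invalid geometry."""


class LabelError(InputError):
    """Invalid or unknown tooth label."""


class ComparisonError(InputError):
    """Reports are not comparable (mismatched tooth sets or framing)."""


class StaleIndexError(OcclustressError):
    """A SpatialIndex was queried after its source mesh changed."""


class NumericalError(OcclustressError):
    """Numerical failure during solving. CLI exit code 3."""
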