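"""Exception hierarchy.

Every failure mode the pipeline distinguishes gets its own class so callers
can react (skip-and-log vs abort) without string matching.
"""


class ConcordError(Exception):
    """Base class for all package errors."""


class UnsupportedFormatError(ConcordError):
    """File extension or content is not a supported mask format."""


class MissingSpacingError(ConcordError):
    """Volumetric file carries no usable voxel-spacing metadata."""


class GridMismatchError(ConcordError):
    """Two masks (or a mask and an expected grid) live on different lattices."""


class EmptyMaskError(ConcordError):
    """An operation requiring at least one occupied voxel got an empty mask."""


class NoLongitudinalOverlapError(ConcordError):
    """Raters' contours share no common slice along the superior axis."""


class PolygonError(ConcordError):
    """Slice polygon is self-intersecting or not aligned with any slice."""


class ManifestError(ConcordError):
    """Cohort manifest is incomplete or inconsistent."""


class PhantomError(ConcordError):
    """Phantom specification produces structures that overlap or exceed the grid."""


class NoiseTooSevereError(ConcordError):
    """Simulated rater noise erased the structure entirely."""
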