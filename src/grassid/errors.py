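"""Exception hierarchy for the seedling discrimination pipeline."""


class GrassIdError(Exception):
    """Base class for all package-specific errors."""


class EmptySegmentation(GrassIdError):
    """No plant pixels survived segmentation (or a region operation got an empty mask)."""


class OutOfBounds(GrassIdError):
    """Requested crop rectangle exceeds the image extent."""


class InvalidGeometry(GrassIdError):
    """Nonpositive field-of-view or image dimensions in a resolution computation."""


class ZeroIntensity(GrassIdError):
    """Colour indices are undefined for a pure-black (0, 0, 0) pixel."""


class DegenerateColumn(GrassIdError):
    """A feature column has zero variance; correlations/standardization undefined."""


class SingularInput(GrassIdError):
    """Correlation matrix not invertible / eigendecomposition impossible."""


class NoComponents(GrassIdError):
    """No eigenvalue meets the retention criterion."""


class InsufficientGroups(GrassIdError):
    """Fewer than two groups, or a group with fewer than two observations."""


class ZeroWithinVariance(GrassIdError):
    """All within-group variation is zero; the F statistic is undefined."""


class OverlappingIntervals(GrassIdError):
    """Group confidence intervals intersect; a gap-midpoint threshold is undefined."""


class MissingFeature(GrassIdError):
    """A feature table lacks a column the model requires."""


class MissingComponent(GrassIdError):
    """A score table lacks a component a threshold refers to."""


class CanvasTooSmall(GrassIdError):
    """Synthetic leaves would not fit on the requested canvas."""
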