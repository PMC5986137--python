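"""Exception hierarchy for landmark-data validation and analysis errors."""


class LandmarkDataError(ValueError):
    """Base class for all landmark-data errors raised by this package."""


class FormatError(LandmarkDataError):
    """A file or matrix does not conform to the expected layout."""


class CompletenessError(LandmarkDataError):
    """Missing or non-numeric coordinate values (complete data are required)."""


class DimensionalityError(LandmarkDataError):
    """Invalid landmark count or physical dimensionality (must be 2-D or 3-D)."""


class SpecimenMismatchError(LandmarkDataError):
    """Two datasets that should describe the same specimens do not correspond."""


class DegenerateSpecimenError(LandmarkDataError):
    """A specimen configuration has zero centroid size (all landmarks coincide)."""


class DegenerateDataError(LandmarkDataError):
    """A specimen constellation carries no variance, so congruence is undefined."""
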