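"""Exception hierarchy for the codcast pipeline."""


class CodcastError(Exception):
    """Base class for all pipeline errors."""


class SeriesFormatError(CodcastError):
    """Malformed annual-series file (bad row, duplicate year, missing header)."""


class BaselineError(CodcastError):
    """Baseline window does not overlap the series sufficiently."""


class AlignmentError(CodcastError):
    """Lag-aware alignment produced an empty (or invalid) design."""


class ConfigurationError(CodcastError):
    """Inconsistent scenario or run configuration."""


class StationarityError(CodcastError):
    """AR(1) coefficient outside the stationary region."""


class SeriesLengthError(CodcastError):
    """Series too short for the requested operation."""


class RankDeficiencyError(CodcastError):
    """Design matrix is rank deficient; orthogonalize or drop predictors."""
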