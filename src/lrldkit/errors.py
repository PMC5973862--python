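"""Exception hierarchy shared across lrldkit modules."""


class LrldkitError(Exception):
    """Base class for all lrldkit errors."""


class FormatError(LrldkitError):
    """A file does not conform to its declared on-disk format."""


class ConsistencyError(LrldkitError):
    """Companion files disagree on dimensions or identifiers."""


class UndefinedStatsError(LrldkitError):
    """A summary statistic is undefined for the given data (e.g. all missing)."""


class MonomorphicLocusError(LrldkitError):
    """LD is undefined because a locus carries a single allele."""


class EmptyTableError(LrldkitError):
    """No jointly non-missing samples for a two-locus table."""


class ConfigurationError(LrldkitError):
    """An analysis was configured with impossible or empty inputs."""


class FitError(LrldkitError):
    """A model fit failed to converge or showed separation."""


class SimulationError(LrldkitError):
    """A simulation could not satisfy its sampling targets."""
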