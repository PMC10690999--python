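"""Exception hierarchy shared across the pipeline stages."""


class ProfilerError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ProfilerError):
    """A config file (thresholds, lexicon, exclusions, run config) is invalid."""


class InputError(ProfilerError):
    """An input table cannot be read or fails structural validation."""


class ClassificationError(ProfilerError):
    """A product cannot be routed to a threshold rule."""


class AllocationError(ProfilerError):
    """Brand sales cannot be split across product variants."""


class IntegrityError(ProfilerError):
    """Cross-stage consistency is broken (e.g. allocation without classification)."""


class GenerationError(ProfilerError):
    """The synthetic-market generator was given an infeasible target."""


class AggregationError(ProfilerError):
    """Aggregation cannot proceed (e.g. no matched, classifiable sales)."""
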