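"""Exception hierarchy for tbgenes."""


class TBGenesError(Exception):
    """Base class for all tbgenes errors."""


class ConfigError(TBGenesError, ValueError):
    """A simulation or pipeline configuration field is invalid."""


class ValidationError(TBGenesError, ValueError):
    """Input data violates a documented precondition."""


class DesignError(ValidationError):
    """The tissue/sample design table is inconsistent with the matrix."""


class GeneSetError(ValidationError):
    """A gene set is empty or has no overlap with the scored matrix."""


class ScreenError(ValidationError):
    """The candidate screen received non-alignable inputs."""


class DegenerateSplitError(ValidationError):
    """A median split is impossible because all scores are identical."""
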