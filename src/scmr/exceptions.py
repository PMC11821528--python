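"""Package-wide exception types."""


class ScmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScmrError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(ScmrError, ValueError):
    """Malformed or unresolvable input table/file."""


class RankDeficiencyError(ScmrError, ValueError):
    """Design matrix is rank deficient; message names the collinear columns."""


class EmptyCohortError(ScmrError, ValueError):
    """A filter removed every donor."""
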