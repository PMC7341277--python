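"""Exception hierarchy.

All errors raised on purpose by this package derive from
:class:`CounselnetError`, so callers (and the CLI) can distinguish
user-input problems (:class:`ValidationError` and subclasses, exit
code 2) from genuine runtime failures (exit code 1).
"""


class CounselnetError(Exception):
    """Base class for all counselnet errors."""


class ValidationError(CounselnetError, ValueError):
    """Invalid user input: out-of-range parameter, unknown state, bad count."""


class InfeasibleMomentsError(ValidationError):
    """Requested (mean, sd) pair lies outside what any Beta can achieve."""


class StructureError(CounselnetError):
    """Invalid network structure: cycle, missing parent, duplicate id."""


class InconsistentEvidenceError(CounselnetError):
    """Evidence assignment has zero probability under the model."""


class ConfigError(ValidationError):
    """Malformed structured-text configuration.

    ``path`` locates the offending key, e.g. ``individuals[2].sire``.
    """

    def __init__(self, message: str, path: str = ""):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)
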