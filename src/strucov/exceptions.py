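"""Exception hierarchy shared by all strucov modules."""


class StrucovError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StrucovError):
    """A table is missing a required column or contains unknown ROI names."""


class ValidationError(StrucovError):
    """A table cell violates an invariant (non-positive volume, negative score, ...)."""


class DegenerateInputError(StrucovError):
    """An input is statistically degenerate (constant column, too few subjects)."""


class ConfigError(StrucovError):
    """A generator or run configuration is infeasible."""


class FormatError(StrucovError):
    """An external file does not follow its declared dialect."""
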