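"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value is missing, unresolvable, or inconsistent."""


class InputError(ValueError):
    """User-supplied data (CSV rows, paired samples) failed validation."""


class MethodNotApplicableError(RuntimeError):
    """A prediction method's required loads are absent from the profile.

    Raised rather than silently skipping so callers can report the gap.
    """

    def __init__(self, method: str, missing_loads):
        self.method = method
        self.missing_loads = tuple(sorted(missing_loads))
        super().__init__(
            f"method {method!r} requires loads {self.missing_loads} %1RM "
            "that are absent from the profile"
        )


class InsufficientDataError(InputError):
    """Fewer paired observations than the statistic requires."""
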