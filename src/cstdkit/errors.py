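"""Exception types shared across the package."""


class CstdkitError(Exception):
    """Base class for all package-specific errors."""


class CoverageError(CstdkitError):
    """A lineage does not contain an individual for a requested sampling year/age."""


class FitError(CstdkitError):
    """A log-linear trend fit cannot be performed (too few usable records)."""


class PeriodError(CstdkitError):
    """An operation was requested for a calendar period in which it is undefined."""


class IntegrationError(CstdkitError):
    """The body-burden integrator produced a non-finite or invalid state."""


class FixtureNotFoundError(CstdkitError, FileNotFoundError):
    """A packaged data fixture is not present in the installation."""
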