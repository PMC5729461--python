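"""Exception hierarchy."""


class AmplifilterError(Exception):
    """Base class for all package errors."""


class DesignParseError(AmplifilterError):
    """Malformed or inconsistent amplicon-design BED file."""


class ConfigError(AmplifilterError):
    """Invalid threshold configuration."""


class VcfParseError(AmplifilterError):
    """Unreadable or structurally invalid VCF input."""


class FixtureSpecError(AmplifilterError):
    """A synthetic-fixture scenario is infeasible or does not force its intended category."""
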