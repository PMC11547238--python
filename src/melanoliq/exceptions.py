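"""Exception hierarchy shared across the pipeline."""


class MelanoliqError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MelanoliqError, ValueError):
    """Invalid simulation or pipeline configuration."""


class DomainError(MelanoliqError, ValueError):
    """An argument outside its mathematical domain (e.g. tumor fraction >= 1)."""


class EmptyProfileError(MelanoliqError, ValueError):
    """A count profile with no reads where reads are required."""


class InsufficientPanelError(MelanoliqError, ValueError):
    """Reference panel has too few members to define null statistics."""


class UnreliableScoreError(MelanoliqError, ValueError):
    """Too few usable features remain to report a score."""


class SaturationError(MelanoliqError, ValueError):
    """All droplets positive: concentration not estimable, dilute the sample."""


class SchemaError(MelanoliqError, ValueError):
    """Tabular input does not match the documented schema."""


class PipelineError(MelanoliqError, RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""
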