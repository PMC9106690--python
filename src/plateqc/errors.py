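"""Exception types shared across the pipeline."""


class PlateQCError(Exception):
    """Base class for all pipeline errors."""


class PanelFormatError(PlateQCError):
    """A panel definition file is malformed (unknown class, duplicates, empty)."""


class PlateFormatError(PlateQCError):
    """A plate export table violates the expected layout or value contracts."""


class ConfigError(PlateQCError):
    """A run or scenario configuration is inconsistent."""
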