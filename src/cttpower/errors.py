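"""Error taxonomy shared across modules.

Both derive from ValueError so library callers can catch broadly; the CLI
maps them to distinct exit codes (config error -> 2, degenerate data -> 3).
"""


class ConfigError(ValueError):
    """Invalid parameters, grids or configuration."""


class DegenerateDataError(ValueError):
    """Data lack the variation an operation requires (e.g. zero variance)."""
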