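"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class FormatError(ValueError):
    """A data file violates the tabular column/ordering contract."""


class DegenerateDataError(ValueError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot proceed (e.g. every participant rejected by QC)."""
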