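"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent parameters (e.g. min_features > max_features)."""


class EmptyGroupError(ValueError):
    """A (cell type, condition) group contains no cells."""


class EmptySignatureError(ValueError):
    """Both the activated and inhibited pathway lists are empty; the query
    would be vacuous."""


class GmtParseError(ValueError):
    """Malformed GMT input; carries the offending line number in the message."""


class AxisMismatchError(ValueError):
    """Two profiles or matrices do not share the same gene axis."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
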