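"""Exception hierarchy for metroaccess."""


class MetroAccessError(Exception):
    """Base class for all metroaccess errors."""


class ConfigError(MetroAccessError):
    """Invalid configuration (non-increasing radii, negative counts, ...)."""


class GenerationError(MetroAccessError):
    """Synthetic-city generation failed (e.g. an empty typology ring)."""


class SpeedModelError(MetroAccessError):
    """Road speed model problem: unknown class label or non-positive speed."""


class FeedError(MetroAccessError):
    """Invalid transit feed: missing file, dangling id, non-monotone times."""


class ParseError(MetroAccessError):
    """Malformed input file; message carries file and row/feature context."""


class PipelineError(MetroAccessError):
    """A pipeline stage failed; message names the stage."""
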