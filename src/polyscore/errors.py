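"""Exception hierarchy for the scoring pipeline."""


class PolyscoreError(Exception):
    """Base class for all polyscore errors."""


class ConfigError(PolyscoreError):
    """Invalid user configuration (missing columns, bad thresholds, ...)."""


class FormatError(PolyscoreError):
    """Malformed input file; message names the file and, where known, line."""


class EvaluationError(PolyscoreError):
    """Model fitting impossible (too few complete sample pairs)."""
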