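"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Invalid configuration or input contract violation; names the field."""


class SchemaError(ValueError):
    """Malformed on-disk artifact (clock file, coefficient table, config)."""


class LeakageError(RuntimeError):
    """Train/test partitions overlap where strict separation is required."""


class StaleInputError(RuntimeError):
    """An upstream artifact changed since the manifest that consumed it."""
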