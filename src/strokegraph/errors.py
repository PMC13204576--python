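"""Exception hierarchy used across the pipeline."""


class StrokeGraphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StrokeGraphError, ValueError):
    """A configuration value is invalid (bad range ordering, non-positive scale, ...)."""


class InputError(StrokeGraphError, ValueError):
    """An input array or file violates a precondition (shape mismatch, non-finite, ...)."""


class ContractError(StrokeGraphError, RuntimeError):
    """An operation was invoked in a state its contract forbids."""
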