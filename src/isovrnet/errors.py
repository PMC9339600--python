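"""Exception types shared across the package."""


class IsovrnetError(Exception):
    """Base class for package errors."""


class ParameterError(IsovrnetError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigError(IsovrnetError, ValueError):
    """A configuration document is malformed or out of range."""


class StateError(IsovrnetError, ValueError):
    """An operation was applied to a node in an incompatible state."""
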