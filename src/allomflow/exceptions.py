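"""Exception hierarchy shared across modules."""


class AllomflowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AllomflowError, ValueError):
    """Invalid input data or configuration."""


class TopologyError(ValidationError):
    """Internode table violates tree-topology constraints."""


class SimulationError(AllomflowError, RuntimeError):
    """Network simulation produced an invalid or runaway state."""
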