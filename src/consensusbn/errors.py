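"""Exception hierarchy shared across the package."""


class ConsensusBNError(Exception):
    """Base class for all package errors."""


class ContractError(ConsensusBNError, ValueError):
    """A caller violated an operation's precondition."""


class ModelError(ConsensusBNError, ValueError):
    """A network, CPT or dataset is internally inconsistent."""


class StructuralError(ModelError):
    """A graph-structure violation (cycles, duplicate edges, ...)."""


class ZeroEvidenceError(ModelError):
    """Conditioning on an event of probability zero."""


class AlignmentError(ConsensusBNError):
    """No equivalence-preserving edge-reversal sequence exists."""

    def __init__(self, message: str, conflicting_edges=()):
        super().__init__(message)
        self.conflicting_edges = tuple(conflicting_edges)
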