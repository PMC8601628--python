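"""Exception hierarchy shared across the pipeline stages."""


class NetPotentialError(Exception):
    """Base class for all package errors."""


class FormatError(NetPotentialError):
    """An input file does not conform to its declared format."""


class EmptyNetworkError(NetPotentialError):
    """Parsing or filtering produced a network with no edges/nodes."""


class UnknownSampleError(NetPotentialError, KeyError):
    """A sample identifier is not present in the expression matrix."""


class UnknownGeneError(NetPotentialError, KeyError):
    """A gene symbol is not a node of the network / not scored."""


class RewireExhaustedError(NetPotentialError):
    """Degree-preserving rewiring ran out of its retry budget."""


class ConfigError(NetPotentialError):
    """Pipeline configuration failed validation."""


class StageError(NetPotentialError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
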