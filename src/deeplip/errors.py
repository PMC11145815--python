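"""Exception hierarchy for the package."""


class DeepLIPError(Exception):
    """Base class for all package errors."""


class ParseError(DeepLIPError):
    """A structure file could not be parsed."""


class EmptyMoleculeError(DeepLIPError):
    """A ligand record contains no atoms."""


class EmptyPocketError(DeepLIPError):
    """A pocket record contains no usable residues/atoms."""


class AlphabetError(DeepLIPError):
    """A sequence letter is outside the 20-letter amino-acid alphabet."""


class SequenceLengthError(DeepLIPError):
    """A sequence is too short for the requested descriptor."""


class ShapeError(DeepLIPError):
    """Array/feature dimensions do not match the model contract."""


class ConfigError(DeepLIPError):
    """Inconsistent model or training configuration."""


class GraphConstructionError(DeepLIPError):
    """A spatial complex graph could not be built."""


class DivergenceError(DeepLIPError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class SearchFailure(DeepLIPError):
    """Every hyperparameter-search trial failed."""
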