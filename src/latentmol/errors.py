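"""Exception and warning types shared across the package."""


class LatentmolError(Exception):
    """Base class for all package-specific errors."""


class InvalidSmiles(LatentmolError):
    """A SMILES string could not be parsed into a molecule."""


class InvalidSmarts(LatentmolError):
    """A SMARTS pattern could not be parsed."""


class UnknownSymbol(LatentmolError):
    """A character or token is not representable in the tokenization scheme
    or model vocabulary."""


class FileFormatError(LatentmolError):
    """An input file does not match its declared format."""


class DimensionError(LatentmolError):
    """A latent vector does not have the expected number of components."""


class RangeWarning(UserWarning):
    """A latent-vector component lies outside the tanh range [-1, 1]."""


class CorpusTooSmall(LatentmolError):
    """Fewer valid molecules than the training loop requires."""


class NonFiniteLoss(LatentmolError):
    """Training diverged: the loss became NaN or infinite."""


class TooFewRecords(LatentmolError):
    """Not enough records to perform the requested split."""


class DegenerateLabels(LatentmolError):
    """A classification label set contains a single class."""


class EmptyObjectives(LatentmolError):
    """A score was requested with no objectives."""


class NegativeWeight(LatentmolError):
    """An objective weight is not strictly positive."""


class NonFiniteScore(LatentmolError):
    """An objective function returned NaN or infinity during optimization."""


class GrammarExhausted(LatentmolError):
    """The fragment grammar could not produce the requested number of
    unique molecules within the attempt budget."""
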