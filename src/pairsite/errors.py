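"""Named exception types raised across the package."""


class PairsiteError(Exception):
    """Base class for all package errors."""


class MissingChainError(PairsiteError):
    """Requested chain identifier is absent from the structure file."""


class EmptyChainError(PairsiteError):
    """A selected chain contains no protein residues."""


class UnsupportedModeError(PairsiteError):
    """Operation requires structural data but got a sequence-only pair."""


class UnknownSymbolError(PairsiteError):
    """Residue letter outside the 22-symbol alphabet."""


class ProfileMismatchError(PairsiteError):
    """Profile file row count (or residue letters) disagree with the chain."""


class ShapeMismatchError(PairsiteError):
    """Matrix/vector dimensions disagree."""


class SingleClassError(PairsiteError):
    """Training or calibration data contain only one label class."""


class EmptyInputError(PairsiteError):
    """Empty matrix/list where at least one element is required."""


class ModeMismatchError(PairsiteError):
    """Feature blocks or models built under different modes were combined."""


class InfeasibleGeometryError(PairsiteError):
    """Synthetic complex generator could not realise the requested interface."""


class DatasetError(PairsiteError):
    """Dataset directory is missing, empty or malformed."""
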