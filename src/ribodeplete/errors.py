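"""Exception hierarchy shared across the package."""


class RibodepleteError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(RibodepleteError):
    """Alignment records violate the aligned-FASTA contract (e.g. ragged rows)."""


class AlphabetError(RibodepleteError):
    """A sequence contains characters outside {A, C, G, U/T, -}."""


class InputError(RibodepleteError):
    """Malformed or empty input data."""


class ParameterError(RibodepleteError):
    """A numeric parameter violates its documented constraints."""


class PlacementError(RibodepleteError):
    """An oligo window touches a gap-masked alignment column."""


class InfeasibleDesignError(RibodepleteError):
    """No admissible alignment window can host an oligo of the requested length."""


class RecipeError(RibodepleteError):
    """A synthetic-data recipe is internally inconsistent."""
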