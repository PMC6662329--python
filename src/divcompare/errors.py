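"""Exception hierarchy shared across the package.

Every reader/estimator raises a subclass of :class:`DivcompareError` so that
pipeline code can distinguish domain failures from programming errors.
"""


class DivcompareError(Exception):
    """Base class for all domain errors raised by divcompare."""


class FormatError(DivcompareError):
    """Malformed input file (ragged alignment, non-integer allele, ...)."""


class PairingError(FormatError):
    """An individual does not have exactly two haplotype sequences."""


class AlphabetError(FormatError):
    """Sequence contains a character outside {A, C, G, T, N, -}."""


class VocabularyError(FormatError):
    """A categorical metadata value is outside the closed vocabulary."""


class BoundsError(FormatError):
    """A codon index lies outside the declared reading frame."""


class DegenerateInputError(DivcompareError):
    """No usable data remain after filtering (e.g. zero usable columns)."""


class InsufficientSampleError(DivcompareError):
    """Too few sequences/individuals for the requested estimator."""


class EmptyLocusError(DivcompareError):
    """A locus has no typed individuals in the requested population."""


class CapacityError(DivcompareError):
    """A demographic matching request exceeds the available individuals."""


class StopCodonError(DivcompareError):
    """A stop codon was supplied where a sense codon is required."""


class AmbiguityError(DivcompareError):
    """A codon contains an ambiguous or missing base."""


class GenerationError(DivcompareError):
    """The synthetic generator could not satisfy its constraints."""
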