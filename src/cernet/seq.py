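"""RNA sequence primitives.

All sequences are handled internally as uppercase RNA over {A, C, G, U};
DNA input (T) is accepted and mapped to U on load. Only Watson-Crick pairs
are complementary here — G:U wobble is deliberately not treated as a pair
in the seed (canonical-site convention).
"""

from __future__ import annotations

from .errors import AlphabetError

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def clean_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase, map T->U, and validate the alphabet."""
    s = sequence.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{context} contains non-RNA characters: {sorted(bad)!r}"
        )
    if not s:
        raise AlphabetError(f"{context} is empty")
    return s


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of an RNA string."""
    return sequence.translate(_COMPLEMENT)[::-1]
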