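"""Shared sequence helpers.

All sequences are handled internally in the DNA alphabet (T, not U), stored
5'->3'. U is accepted on input and normalised to T.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")


def normalize(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET
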