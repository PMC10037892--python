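"""Small sequence helpers used throughout the pipeline.

Coordinates are 0-based half-open everywhere. Masking follows the softmask
convention: lowercase bases and N count as masked.
"""

from __future__ import annotations

from .errors import InvalidSequenceError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = set("ACGTNacgtn")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C among all bases (case-insensitive)."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def is_masked(seq: str) -> bool:
    """True if any base is soft-masked (lowercase) or N."""
    return any(c == "N" or c == "n" or c.islower() for c in seq)


def check_acgt(seq: str, context: str = "sequence") -> str:
    """Validate that ``seq`` is non-empty uppercase-equivalent ACGT; return upper."""
    s = seq.upper()
    if not s or any(c not in "ACGT" for c in s):
        raise InvalidSequenceError(
            f"{context} must be non-empty and contain only A/C/G/T: {seq!r}"
        )
    return s


def gc_clamp_5prime(seq: str, window: int = 3, min_gc: int = 2) -> bool:
    """GC clamp at the 5' end: >= ``min_gc`` of the first ``window`` bases are G/C."""
    head = seq[:window].upper()
    return sum(c in "GC" for c in head) >= min_gc


def gc_clamp_3prime(seq: str, window: int = 3, min_gc: int = 2) -> bool:
    """GC clamp at the 3' end: >= ``min_gc`` of the last ``window`` bases are G/C."""
    tail = seq[-window:].upper()
    return sum(c in "GC" for c in tail) >= min_gc
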