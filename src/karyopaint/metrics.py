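"""Assembly contiguity and karyotype length statistics.

N50: smallest length L such that sequences of length >= L sum to at least
half the assembly. L90 (``l_fraction`` with fraction 0.9): minimal number of
largest sequences covering 90% of the assembly.

Chromosome lengths measured on spreads are confounded by per-spread
chromatin compaction; :func:`relative_lengths` removes it by normalizing
every spread to its own X-chromosome measurement before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

logger = logging.getLogger(__name__)


def n50(lengths) -> int:
    """Smallest length whose descending cumulative sum reaches half the total."""
    arr = _validate(lengths)
    arr = np.sort(arr)[::-1]
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(arr[idx])


def l_fraction(lengths, fraction: float = 0.9) -> int:
    """Minimal number of largest sequences summing to >= fraction * total."""
    if not (0 < fraction <= 1):
        raise InvalidParameterError("fraction must be in (0, 1]")
    arr = _validate(lengths)
    arr = np.sort(arr)[::-1]
    csum = np.cumsum(arr)
    return int(np.searchsorted(csum, fraction * csum[-1])) + 1


def _validate(lengths) -> np.ndarray:
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("empty length list")
    if (arr <= 0).any():
        raise InvalidParameterError("lengths must be positive")
    return arr


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    l90: int
    largest: int

    @classmethod
    def from_lengths(cls, lengths) -> "AssemblyStats":
        arr = _validate(lengths)
        return cls(
            n_sequences=int(arr.size),
            total_length=int(arr.sum()),
            n50=n50(arr),
            l90=l_fraction(arr, 0.9),
            largest=int(arr.max()),
        )

    @classmethod
    def from_fasta(cls, path, split_at_gaps: bool = False) -> "AssemblyStats":
        """Stats from a FASTA; with ``split_at_gaps`` records are split at
        runs of N (contig rather than scaffold statistics)."""
        from .io import read_fasta

        seqs = read_fasta(path)
        if split_at_gaps:
            import re

            lengths = [
                len(piece)
                for s in seqs.values()
                for piece in re.split("[Nn]+", s)
                if piece
            ]
        else:
            lengths = [len(s) for s in seqs.values()]
        return cls.from_lengths(lengths)

    def fraction_covered_by(self, subset_lengths) -> float:
        sub = float(np.asarray(list(subset_lengths), dtype=float).sum())
        return sub / self.total_length

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "total_length": self.total_length,
            "n50": self.n50,
            "l90": self.l90,
            "largest": self.largest,
        }


def relative_lengths(
    measurements: pd.DataFrame,
    x_chromosome: str,
) -> pd.DataFrame:
    """Per-chromosome relative-length summary from per-spread measurements.

    ``measurements`` columns: spread_id, chromosome, length_um. Each spread's
    lengths are divided by that spread's X measurement and rescaled by the
    grand-mean X length, so the X entry equals the grand-mean X length by
    construction; spreads missing an X measurement are dropped with a
    warning. Returns chromosome / relative_length (mean) / sd / n_spreads.
    """
    req = {"spread_id", "chromosome", "length_um"}
    if not req.issubset(measurements.columns):
        raise InvalidParameterError(f"measurements need columns {sorted(req)}")
    x_rows = measurements[measurements["chromosome"] == x_chromosome]
    x_of = x_rows.set_index("spread_id")["length_um"]
    good = measurements["spread_id"].isin(x_of.index)
    dropped = set(measurements.loc[~good, "spread_id"])
    if dropped:
        logger.warning("spreads without an X measurement dropped: %s", sorted(dropped))
    m = measurements[good].copy()
    if m.empty:
        raise InvalidParameterError("no spread contains an X measurement")
    grand_x = float(x_of.mean())
    m["rel"] = m.apply(
        lambda r: r["length_um"] / x_of[r["spread_id"]] * grand_x, axis=1
    )
    out = (
        m.groupby("chromosome")["rel"]
        .agg(relative_length="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
             n_spreads="count")
        .reset_index()
    )
    return out
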