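"""DNA hybridization thermodynamics.

Nearest-neighbor (NN) model with the unified DNA/DNA parameter set
(SantaLucia 1998): per-stack enthalpies (kcal/mol) and entropies
(cal/mol/K), duplex-initiation terms split by terminal base pair.

Three quantities are derived from these tables:

* :func:`melting_temperature` — duplex Tm with monovalent-salt entropy
  correction and a linear formamide depression (default 0.72 degC per
  percent formamide, configurable).
* :func:`duplex_dg` — free energy of the most stable ungapped duplex
  between two oligos, used for self-/hetero-dimer screening of barcode
  sequences. Bulges and internal loops are neglected: for 20-mer primer
  screening the dominant failure mode is a contiguous complementary
  stretch.
* :func:`hairpin_dg` — minimum free energy over all stem-loop
  configurations of a single oligo (exhaustive stem enumeration, loop
  penalty from a hairpin-loop table treated as purely entropic so it can
  be evaluated at any temperature).

Free energies are reported in kcal/mol; more negative = more stable.
"""

from __future__ import annotations

import math

from .errors import InvalidSequenceError
from .seqs import check_acgt

R_GAS = 1.987  # cal / (mol K)

# stack -> (dH kcal/mol, dS cal/mol/K); key is the 5'->3' top-strand dinucleotide
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}

# duplex initiation per terminal base pair
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

# hairpin loop dG at 37 degC (kcal/mol) by loop length (SantaLucia-style table)
HAIRPIN_LOOP_DG37: dict[int, float] = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.4,
    12: 4.7, 14: 5.0, 16: 5.2, 18: 5.4, 20: 5.5, 25: 5.9, 30: 6.3,
}

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}

T37 = 310.15  # 37 degC in kelvin


def _stack_sum(seq: str) -> tuple[float, float]:
    """Sum NN stack (dH, dS) over a perfectly paired duplex of ``seq``."""
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = NN_PARAMS[seq[i : i + 2]]
        dh += h
        ds += s
    return dh, ds


def _init_terms(seq: str) -> tuple[float, float]:
    dh = 0.0
    ds = 0.0
    for base in (seq[0], seq[-1]):
        h, s = INIT_GC if base in "GC" else INIT_AT
        dh += h
        ds += s
    return dh, ds


def nn_enthalpy_entropy(seq: str) -> tuple[float, float]:
    """Total (dH kcal/mol, dS cal/mol/K) for ``seq`` paired with its perfect
    complement, including initiation terms."""
    s = check_acgt(seq, "oligo")
    dh, ds = _stack_sum(s)
    ih, is_ = _init_terms(s)
    return dh + ih, ds + is_


def melting_temperature(
    sequence: str,
    salt_molarity: float = 0.39,
    formamide_fraction: float = 0.5,
    total_strand_conc: float = 5e-8,
    formamide_coeff: float = 0.72,
) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Parameters
    ----------
    sequence : str
        Oligo sequence, length >= 8, A/C/G/T only.
    salt_molarity : float
        Monovalent cation concentration (mol/L); the entropic correction
        ``dS + 0.368 (N-1) ln[Na+]`` is applied. Default 0.39 M matches a
        2x SSC hybridization buffer.
    formamide_fraction : float
        Volume fraction of formamide; Tm is depressed linearly by
        ``formamide_coeff`` degC per percent.
    total_strand_conc : float
        Total oligo strand concentration (mol/L); probe excess is assumed,
        so the concentration term is CT/4.
    """
    s = check_acgt(sequence, "oligo")
    if len(s) < 8:
        raise InvalidSequenceError("Tm model requires length >= 8")
    if salt_molarity <= 0 or total_strand_conc <= 0:
        raise InvalidSequenceError("salt and strand concentrations must be positive")
    dh, ds = nn_enthalpy_entropy(s)
    ds_salt = ds + 0.368 * (len(s) - 1) * math.log(salt_molarity)
    tm_k = dh * 1000.0 / (ds_salt + R_GAS * math.log(total_strand_conc / 4.0))
    tm_c = tm_k - 273.15
    return tm_c - formamide_coeff * (100.0 * formamide_fraction)


def _dg_at(dh: float, ds: float, temp_c: float) -> float:
    t_k = temp_c + 273.15
    return dh - t_k * ds / 1000.0


def duplex_dg(seq1: str, seq2: str, temp_c: float = 37.0) -> float:
    """Free energy (kcal/mol) of the most stable ungapped duplex between two
    oligos (antiparallel, contiguous complementary stretch).

    Scans every relative offset of ``seq1`` against ``seq2``; each maximal
    complementary run of >= 2 bp is scored as stacked NN pairs plus the two
    terminal initiation penalties. Returns 0.0 (no stable structure) if no
    run of length >= 2 exists.
    """
    a = check_acgt(seq1, "seq1")
    b = check_acgt(seq2, "seq2")
    # seq1[i] pairs with seq2[j]; antiparallel => as i increases j decreases.
    # Walk anti-diagonals i + j = d.
    best = 0.0
    n, m = len(a), len(b)
    for d in range(n + m - 1):
        i_lo = max(0, d - m + 1)
        i_hi = min(n - 1, d)
        run_start: int | None = None
        for i in range(i_lo, i_hi + 2):
            paired = i <= i_hi and _PAIR[a[i]] == b[d - i]
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                seg = a[run_start:i]
                if len(seg) >= 2:
                    dh, ds = _stack_sum(seg)
                    ih, is_ = _init_terms(seg)
                    best = min(best, _dg_at(dh + ih, ds + is_, temp_c))
                run_start = None
    return best


def hairpin_dg(sequence: str, temp_c: float = 42.0, min_stem: int = 2, min_loop: int = 3) -> float:
    """Minimum hairpin free energy (kcal/mol) at ``temp_c`` by exhaustive
    stem-loop enumeration.

    A hairpin with stem ``[i, i+s)`` paired to ``[j-s+1, j]`` and loop
    ``j - i + 1 - 2 s >= min_loop`` is scored as the NN stack sum of the stem
    (with one terminal initiation at the open end) plus a loop penalty.
    The loop penalty table (dG at 37 degC) is treated as purely entropic and
    rescaled linearly with absolute temperature; lengths beyond the table are
    extrapolated with the Jacobson-Stockmayer ``1.75 R T ln(n/30)`` term.
    Returns 0.0 if no hairpin is possible.
    """
    s = check_acgt(sequence, "oligo")
    n = len(s)
    best = 0.0
    for i in range(n):
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            max_stem = (j - i + 1 - min_loop) // 2
            # extend stem pair by pair from the outside in
            dh = 0.0
            ds = 0.0
            length = 0
            for k in range(max_stem):
                if _PAIR[s[i + k]] != s[j - k]:
                    break
                length = k + 1
                if k > 0:
                    h, st = NN_PARAMS[s[i + k - 1 : i + k + 1]]
                    dh += h
                    ds += st
                if length >= min_stem:
                    loop_len = j - i + 1 - 2 * length
                    # one initiation at the open (duplex) end of the stem
                    ih, is_ = INIT_GC if s[i] in "GC" else INIT_AT
                    dg = _dg_at(dh + ih, ds + is_, temp_c) + _loop_dg(loop_len, temp_c)
                    best = min(best, dg)
    return best


def _loop_dg(loop_len: int, temp_c: float) -> float:
    t_k = temp_c + 273.15
    if loop_len in HAIRPIN_LOOP_DG37:
        g37 = HAIRPIN_LOOP_DG37[loop_len]
    elif loop_len < 30:
        below = max(k for k in HAIRPIN_LOOP_DG37 if k <= loop_len)
        above = min(k for k in HAIRPIN_LOOP_DG37 if k >= loop_len)
        if below == above:
            g37 = HAIRPIN_LOOP_DG37[below]
        else:
            w = (loop_len - below) / (above - below)
            g37 = HAIRPIN_LOOP_DG37[below] * (1 - w) + HAIRPIN_LOOP_DG37[above] * w
    else:
        g37 = HAIRPIN_LOOP_DG37[30] + 1.75 * R_GAS / 1000.0 * T37 * math.log(loop_len / 30.0)
    # purely entropic: scale linearly with absolute temperature
    return g37 * (t_k / T37)
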