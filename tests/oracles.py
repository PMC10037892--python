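"""Independent reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way (full
enumeration, O(n^2) scans, plain dictionaries) and shares no code with the
package beyond published physical constants.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

# SantaLucia unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K),
# re-keyed here independently of the package tables.
NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
R = 1.987
PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def nn_tm(seq: str, na: float, ct: float) -> float:
    """Hand-summed nearest-neighbor Tm (degC), no formamide."""
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = NN[seq[i : i + 2]]
        dh += h
        ds += s
    for b in (seq[0], seq[-1]):
        h, s = INIT_GC if b in "GC" else INIT_AT
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    return dh * 1000.0 / (ds + R * math.log(ct / 4.0)) - 273.15


def duplex_dg_oracle(a: str, b: str, temp_c: float = 37.0) -> float:
    """Most stable ungapped antiparallel duplex: enumerate every contiguous
    complementary run (i in a against j in b, antiparallel) of length >= 2."""
    t_k = temp_c + 273.15
    best = 0.0
    for i0 in range(len(a)):
        for j0 in range(len(b) - 1, -1, -1):
            # extend a run starting at (i0, j0): a[i0+k] pairs b[j0-k]
            k = 0
            while i0 + k < len(a) and j0 - k >= 0 and PAIR[a[i0 + k]] == b[j0 - k]:
                k += 1
                if k >= 2:
                    seg = a[i0 : i0 + k]
                    dh, ds = 0.0, 0.0
                    for x in range(k - 1):
                        h, s = NN[seg[x : x + 2]]
                        dh += h
                        ds += s
                    for bb in (seg[0], seg[-1]):
                        h, s = INIT_GC if bb in "GC" else INIT_AT
                        dh += h
                        ds += s
                    best = min(best, dh - t_k * ds / 1000.0)
    return best


def sw_ungapped_score(query: str, genome: dict[str, str],
                      match: int = 1, mismatch: int = -2) -> int:
    """Full ungapped Smith-Waterman (per-diagonal Kadane over every diagonal,
    no seeding) against both strands."""
    comp = str.maketrans("ACGT", "TGCA")
    best = 0
    for q in (query, query.translate(comp)[::-1]):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for s in genome.values():
            sa = np.frombuffer(s.upper().encode(), dtype=np.uint8)
            n, m = len(qa), len(sa)
            for off in range(-n + 1, m):
                run = 0
                for qi in range(n):
                    gi = off + qi
                    if 0 <= gi < m:
                        run = max(0, run + (match if qa[qi] == sa[gi] else mismatch))
                        best = max(best, run)
                    else:
                        run = 0
    return best


def n50_oracle(lengths) -> int:
    """Quadratic N50: largest L in the set with sum(x >= L) >= total/2."""
    total = sum(lengths)
    candidates = [L for L in lengths if sum(x for x in lengths if x >= L) >= total / 2.0]
    return max(candidates)


def l_fraction_oracle(lengths, fraction: float) -> int:
    xs = sorted(lengths, reverse=True)
    total = sum(xs)
    acc = 0
    for i, x in enumerate(xs, start=1):
        acc += x
        if acc >= fraction * total:
            return i
    return len(xs)


def tiers_oracle(m: int, budget: int) -> tuple[int, int, int]:
    """Exhaustive (n3, n2, n1) maximizing 3n3+2n2+n1 within budget,
    lexicographic tie-break on (n3, n2)."""
    best = None
    for n3 in range(m + 1):
        for n2 in range(m - n3 + 1):
            n1 = m - n3 - n2
            tot = 3 * n3 + 2 * n2 + n1
            if tot <= budget:
                key = (tot, n3, n2)
                if best is None or key > best[0]:
                    best = (key, (n3, n2, n1))
    return best[1]


def place_windows_oracle(geom, ideal, min_gap, min_term, scaffold_length):
    """Brute-force lexicographic-minimum placement over all window subsets."""
    n = len(ideal)
    best_cost, best_choice = None, None
    for combo in itertools.combinations(range(len(geom)), n):
        ok = True
        for j in combo:
            start, end, _ = geom[j]
            if start < min_term or end > scaffold_length - min_term:
                ok = False
                break
        if ok:
            for a, b in zip(combo, combo[1:]):
                if geom[b][0] - geom[a][1] < min_gap:
                    ok = False
                    break
        if not ok:
            continue
        cost = [0.0, 0.0, 0.0]
        for k, j in enumerate(combo):
            start, end, hom = geom[j]
            cost[0] += abs((start + end) / 2 - ideal[k])
            cost[1] += hom
            cost[2] += end - start
        cost = tuple(cost)
        if best_cost is None or cost < best_cost:
            best_cost, best_choice = cost, list(combo)
    return best_choice


# ---------------------------------------------------------------------------
# rearrangement parsimony oracle

def _canon_chrom(c):
    rc = tuple((b, -s) for b, s in reversed(c))
    return min(tuple(c), rc)


def _canon(state):
    return tuple(sorted(_canon_chrom(c) for c in state))


def _neighbors(state):
    chroms = [list(c) for c in state]
    out = set()
    # inversions
    for ci, c in enumerate(chroms):
        for i in range(len(c)):
            for j in range(i + 1, len(c) + 1):
                seg = [(b, -s) for b, s in reversed(c[i:j])]
                nc = tuple(c[:i] + seg + c[j:])
                out.add(_canon([tuple(x) for k, x in enumerate(chroms) if k != ci] + [nc]))
    # fissions
    for ci, c in enumerate(chroms):
        for i in range(1, len(c)):
            rest = [tuple(x) for k, x in enumerate(chroms) if k != ci]
            out.add(_canon(rest + [tuple(c[:i]), tuple(c[i:])]))
    # fusions
    for ci in range(len(chroms)):
        for cj in range(len(chroms)):
            if ci == cj:
                continue
            a, b = chroms[ci], chroms[cj]
            rest = [tuple(x) for k, x in enumerate(chroms) if k not in (ci, cj)]
            for bb in (b, [(x, -s) for x, s in reversed(b)]):
                out.add(_canon(rest + [tuple(a + bb)]))
    # translocations (excise, reinsert unflipped)
    for ci, c in enumerate(chroms):
        L = len(c)
        for i in range(L):
            for j in range(i + 1, L + 1):
                if i == 0 and j == L:
                    continue
                seg = c[i:j]
                remainder = c[:i] + c[j:]
                others = [(k, x) for k, x in enumerate(chroms) if k != ci]
                for pos in range(len(remainder) + 1):
                    nc = tuple(remainder[:pos] + seg + remainder[pos:])
                    out.add(_canon([tuple(x) for _, x in others] + [nc]))
                for k, x in others:
                    for pos in range(len(x) + 1):
                        nx = tuple(list(x[:pos]) + seg + list(x[pos:]))
                        rest = [tuple(y) for m, y in others if m != k]
                        if remainder:
                            rest.append(tuple(remainder))
                        out.add(_canon(rest + [nx]))
    return out


def min_events_oracle(reference, query, max_events=4):
    """Plain BFS distance between block arrangements; None if unreachable."""
    start = _canon([tuple((b, 1) for b in v) for v in reference.values()])
    goal = _canon([tuple(v) for v in query.values()])
    if start == goal:
        return 0
    seen = {start}
    frontier = deque([(start, 0)])
    while frontier:
        state, d = frontier.popleft()
        if d >= max_events:
            continue
        for ns in _neighbors(state):
            if ns == goal:
                return d + 1
            if ns not in seen:
                seen.add(ns)
                frontier.append((ns, d + 1))
    return None
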