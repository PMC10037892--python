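"""Probe-set design: allocation, window selection, barcodes, colours, assembly.

A probe is a pool of oligos (default 1500) whose genome-homolog segments tile
a window of one scaffold. Each final oligo is a 79-mer::

    5' - reverse primer (20) - genome homolog (39) - forward primer (20) - 3'

The 20-mer primers/adapters/detectors are *orthogonal* sequences — no
significant homology to the target genome — screened for genome homology and
for self-/hetero-dimer stability. Reverse primers are scaffold-specific
(amplify one scaffold's probes out of a library); forward primers and
adapters are fluorophore-specific so fluorophores stay interchangeable.

Colour schemes: three fluorophores give six colours (three singles plus
three two-fluorophore mixes); each scaffold's ordered per-probe colour
pattern must be unique within its hybridization pool.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import (
    CapacityError,
    InfeasibleDesignError,
    InvalidParameterError,
    InvalidSequenceError,
)
from .mining import OligoCandidate
from .seqs import gc_clamp_3prime, gc_clamp_5prime, revcomp
from .thermo import duplex_dg

logger = logging.getLogger(__name__)

FLUOROPHORES = ("FAM", "ATTO550", "ATTO647")

# colour <-> fluorophore-set mapping (singles then mixes)
COLOUR_OF_SET = {
    frozenset({"FAM"}): "blue",
    frozenset({"ATTO550"}): "yellow",
    frozenset({"ATTO647"}): "red",
    frozenset({"FAM", "ATTO550"}): "green",
    frozenset({"ATTO550", "ATTO647"}): "orange",
    frozenset({"FAM", "ATTO647"}): "violet",
}
SET_OF_COLOUR = {v: k for k, v in COLOUR_OF_SET.items()}
COLOUR_ORDER = ("blue", "yellow", "red", "green", "orange", "violet")

T7_PROMOTER = "CGATTGAGGCCGGTAATACGACTCACTATAGGG"  # 33-mer prepended to reverse primers


# ---------------------------------------------------------------------------
# allocation


@dataclass
class AllocationScheme:
    """Per-scaffold probe counts plus the library (pool) partition."""

    counts: dict[str, int]
    libraries: list[list[str]]
    capacity: int
    n_oligo: int

    @property
    def total_probes(self) -> int:
        return sum(self.counts.values())

    @property
    def total_oligos(self) -> int:
        return self.total_probes * self.n_oligo

    def library_of(self, scaffold_id: str) -> int:
        for i, lib in enumerate(self.libraries):
            if scaffold_id in lib:
                return i
        raise InvalidParameterError(f"{scaffold_id} not in any library")


def allocate_probe_counts(
    scaffold_lengths: dict[str, int],
    suspected_misassembly: set[str] | None = None,
    n_libraries: int = 3,
    capacity: int = 92_000,
    n_oligo: int = 1500,
    max_count: int = 5,
    tier_sizes: tuple[int, int, int] | None = None,
) -> AllocationScheme:
    """Tier scaffolds by length into probe counts.

    The longest scaffold receives ``max_count`` probes; scaffolds under
    suspicion of mis-assembly receive at least 4 (extra probes refine
    breakpoint localization); the rest are tiered into 3/2/1 probes in
    decreasing length order. With ``tier_sizes`` = (n3, n2, n1) the tier
    boundaries are given explicitly; otherwise they are chosen to maximize
    the total probe count under the oligo budget ``n_libraries * capacity``
    (ties broken by preferring larger tiers for longer scaffolds).
    """
    suspected = set(suspected_misassembly or ())
    if capacity < n_oligo:
        raise InfeasibleDesignError("library capacity smaller than one probe")
    order = sorted(scaffold_lengths, key=lambda s: (-scaffold_lengths[s], s))
    if not order:
        raise InvalidParameterError("no scaffolds")
    budget = (n_libraries * capacity) // n_oligo
    counts: dict[str, int] = {}
    n_susp_rest = len(suspected - {order[0]})
    n_plain_rest = len(order) - 1 - n_susp_rest
    top_count = min(max_count, budget - 4 * n_susp_rest - n_plain_rest)
    if top_count < 1:
        raise InfeasibleDesignError(
            f"budget {budget} probes cannot give every scaffold at least one probe"
        )
    counts[order[0]] = max(top_count, 4) if order[0] in suspected and top_count < 4 else top_count
    for s in order[1:]:
        if s in suspected:
            counts[s] = 4
    fixed = sum(counts.values())
    rest = [s for s in order[1:] if s not in suspected]
    m = len(rest)
    if fixed + m > budget:
        raise InfeasibleDesignError(
            f"budget {budget} probes cannot give every scaffold at least one probe"
        )
    if tier_sizes is not None:
        n3, n2, n1 = tier_sizes
        if n3 + n2 + n1 != m:
            raise InvalidParameterError(
                f"tier_sizes sum {n3 + n2 + n1} != {m} unsuspected non-top scaffolds"
            )
    else:
        n3, n2, n1 = _max_fill_tiers(m, budget - fixed)
    for i, s in enumerate(rest):
        counts[s] = 3 if i < n3 else (2 if i < n3 + n2 else 1)
    total_oligos = sum(counts.values()) * n_oligo
    if total_oligos > n_libraries * capacity:
        raise InfeasibleDesignError("allocation exceeds total library capacity")
    libraries = _partition_into_libraries(order, counts, n_libraries, capacity, n_oligo)
    return AllocationScheme(counts, libraries, capacity, n_oligo)


def _max_fill_tiers(m: int, budget: int) -> tuple[int, int, int]:
    """Maximize 3*n3 + 2*n2 + n1 with n3+n2+n1 = m under the probe budget,
    ties broken lexicographically (larger n3, then larger n2)."""
    best = None
    for n3 in range(m, -1, -1):
        for n2 in range(m - n3, -1, -1):
            n1 = m - n3 - n2
            total = 3 * n3 + 2 * n2 + n1
            if total <= budget:
                key = (total, n3, n2)
                if best is None or key > best[0]:
                    best = (key, (n3, n2, n1))
                break  # decreasing n2 only lowers the total
    assert best is not None
    return best[1]


def _partition_into_libraries(order, counts, n_libraries, capacity, n_oligo):
    """Greedy least-loaded assignment of scaffolds (in length order) to pools."""
    loads = [0] * n_libraries
    libs: list[list[str]] = [[] for _ in range(n_libraries)]
    for s in order:
        need = counts[s] * n_oligo
        i = min(range(n_libraries), key=lambda j: (loads[j], j))
        if loads[i] + need > capacity:
            raise InfeasibleDesignError("library capacity exceeded during partitioning")
        loads[i] += need
        libs[i].append(s)
    return libs


# ---------------------------------------------------------------------------
# probe windows


@dataclass
class ProbeWindow:
    probe_id: str
    scaffold_id: str
    start: int
    end: int
    oligos: list[OligoCandidate]
    design_index: int = 0
    fluorophores: frozenset | None = None
    reverse_primer_id: str | None = None
    forward_primer_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class ProbePlan:
    windows: list[ProbeWindow]
    scaffold_lengths: dict[str, int]
    n_oligo: int

    def by_scaffold(self) -> dict[str, list[ProbeWindow]]:
        out: dict[str, list[ProbeWindow]] = {}
        for w in self.windows:
            out.setdefault(w.scaffold_id, []).append(w)
        for ws in out.values():
            ws.sort(key=lambda w: w.design_index)
        return out

    def window(self, probe_id: str) -> ProbeWindow:
        for w in self.windows:
            if w.probe_id == probe_id:
                return w
        raise InvalidParameterError(f"unknown probe {probe_id}")


def probe_label(scaffold_id: str, index: int) -> str:
    """Probe name: scaffold's numeric rank + 'p' + 0-based probe index
    (e.g. probe 1 of scaffold_12 -> '12p1')."""
    short = scaffold_id.split("_")[-1] if "_" in scaffold_id else scaffold_id
    return f"{short}p{index}"


def _window_geometry(cands: list[OligoCandidate], j: int, n_oligo: int):
    start = cands[j].start
    end = cands[j + n_oligo - 1].end
    if n_oligo > 1:
        gaps = [cands[j + i + 1].start - cands[j + i].end for i in range(n_oligo - 1)]
        hom = float(np.var(gaps))
    else:
        hom = 0.0
    return start, end, hom


def select_probe_windows(
    candidates: list[OligoCandidate],
    n_probes: int,
    scaffold_length: int,
    n_oligo: int = 1500,
    min_gap: int = 7_000_000,
    min_terminus_distance: int = 250_000,
) -> list[ProbeWindow]:
    """Choose ``n_probes`` disjoint windows of ``n_oligo`` consecutive
    candidates each, separated by >= ``min_gap`` and >= ``min_terminus_distance``
    from both scaffold ends when feasible (the terminus constraint is relaxed
    with a warning otherwise).

    Among feasible placements the lexicographic objective is minimized:
    centrality (summed distance of window centres from their ideal
    equally-spaced positions), then homogeneity (summed variance of
    inter-oligo spacing), then size (summed span).
    """
    if n_probes < 1:
        raise InvalidParameterError("n_probes must be >= 1")
    cands = sorted(candidates, key=lambda c: c.start)
    sid = cands[0].scaffold_id if cands else "?"
    n_windows = len(cands) - n_oligo + 1
    if n_windows < n_probes:
        raise InfeasibleDesignError(
            f"scaffold {sid}: {len(cands)} candidates cannot host "
            f"{n_probes} probes of {n_oligo} oligos"
        )
    geom = [_window_geometry(cands, j, n_oligo) for j in range(n_windows)]
    ideal = [scaffold_length * (2 * k + 1) / (2 * n_probes) for k in range(n_probes)]

    choice = _place_windows(geom, ideal, min_gap, min_terminus_distance, scaffold_length)
    if choice is None:
        logger.warning(
            "scaffold %s: relaxing min_terminus_distance=%d (no feasible placement)",
            sid, min_terminus_distance,
        )
        choice = _place_windows(geom, ideal, min_gap, 0, scaffold_length)
    if choice is None:
        raise InfeasibleDesignError(
            f"scaffold {sid}: no placement of {n_probes} windows with min_gap={min_gap}"
        )
    windows = []
    for k, j in enumerate(choice):
        start, end, _ = geom[j]
        windows.append(
            ProbeWindow(
                probe_id=probe_label(sid, k),
                scaffold_id=sid,
                start=start,
                end=end,
                oligos=cands[j : j + n_oligo],
                design_index=k,
            )
        )
    return windows


def _place_windows(geom, ideal, min_gap, min_term, scaffold_length):
    """Lexicographic-cost DP over window positions; returns chosen window
    indices or None if infeasible."""
    n_probes = len(ideal)
    W = len(geom)
    INF = (math.inf, math.inf, math.inf)

    def cost(k, j):
        start, end, hom = geom[j]
        if start < min_term or end > scaffold_length - min_term:
            return None
        centre = (start + end) / 2
        return (abs(centre - ideal[k]), hom, end - start)

    # f[j] = best cumulative tuple with slot k at window j; parent pointers
    prev_f: list[tuple | None] = []
    parents: list[list[int | None]] = []
    for k in range(n_probes):
        cur: list[tuple | None] = [None] * W
        par: list[int | None] = [None] * W
        if k == 0:
            for j in range(W):
                c = cost(0, j)
                if c is not None:
                    cur[j] = c
        else:
            # windows sorted by start; ends are monotone, so feasible
            # predecessors of j form a prefix — track its running best
            best_prefix: tuple | None = None
            best_idx: int | None = None
            p = 0
            for j in range(W):
                start_j = geom[j][0]
                while p < W and geom[p][1] + min_gap <= start_j:
                    if prev_f[p] is not None and (
                        best_prefix is None or prev_f[p] < best_prefix
                    ):
                        best_prefix = prev_f[p]
                        best_idx = p
                    p += 1
                c = cost(k, j)
                if c is not None and best_prefix is not None:
                    cur[j] = tuple(a + b for a, b in zip(best_prefix, c))
                    par[j] = best_idx
        prev_f = cur
        parents.append(par)
    finals = [(v, j) for j, v in enumerate(prev_f) if v is not None]
    if not finals:
        return None
    _, j = min(finals)
    choice = [j]
    for k in range(n_probes - 1, 0, -1):
        j = parents[k][j]
        choice.append(j)
    return list(reversed(choice))


def probe_plan_stats(plan: ProbePlan) -> dict:
    """Summary geometry of a probe plan.

    Gaps are edge-to-edge between consecutive windows of the same scaffold;
    terminus distances are from each scaffold's first/last window to its
    ends; oligo density is mean oligo count divided by mean span in kb.
    """
    spans = [w.span for w in plan.windows]
    if not spans:
        raise InvalidParameterError("empty plan")
    gaps: list[int] = []
    termini: list[int] = []
    for sid, ws in plan.by_scaffold().items():
        ws = sorted(ws, key=lambda w: w.start)
        L = plan.scaffold_lengths[sid]
        termini.append(ws[0].start)
        termini.append(L - ws[-1].end)
        for a, b in zip(ws, ws[1:]):
            gaps.append(b.start - a.end)

    def summary(xs):
        if not xs:
            return None
        arr = np.asarray(xs, dtype=float)
        return {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    mean_span_kb = float(np.mean(spans)) / 1000.0
    mean_oligos = float(np.mean([len(w.oligos) for w in plan.windows]))
    return {
        "span": summary(spans),
        "gap": summary(gaps),
        "gap_stats_empty": not gaps,
        "terminus": summary(termini),
        "oligo_density_per_kb": oligo_density(mean_oligos, mean_span_kb),
    }


def oligo_density(n_oligo: float, mean_span_kb: float) -> float:
    """Oligos per kb of targeted sequence: n_oligo / mean probe span (kb)."""
    if mean_span_kb <= 0:
        raise InvalidParameterError("mean span must be positive")
    return n_oligo / mean_span_kb


# ---------------------------------------------------------------------------
# orthogonal barcode processing


@dataclass
class OrthoSeq:
    seq: str
    role: str = "unassigned"
    gc_clamp_5prime: bool = False
    gc_clamp_3prime: bool = False
    min_self_dg: float | None = None
    min_hetero_dg: float | None = None
    genome_evalue: float | None = None

    def __post_init__(self) -> None:
        if len(self.seq) != 20:
            raise InvalidSequenceError(f"orthogonal sequences are 20-mers, got {self.seq!r}")
        self.gc_clamp_5prime = gc_clamp_5prime(self.seq)
        self.gc_clamp_3prime = gc_clamp_3prime(self.seq)


def slice_orthologs(pool: list[str]) -> list[str]:
    """All six 20-nt substrings of each 25-mer, in offset order; duplicates
    are retained (deduplication is a separate step)."""
    out: list[str] = []
    for s in pool:
        if len(s) != 25:
            raise InvalidSequenceError(f"expected a 25-mer, got length {len(s)}")
        for i in range(6):
            out.append(s[i : i + 20])
    return out


def karlin_altschul_params(match: int = 1, mismatch: int = -2,
                           k_const: float = 0.621) -> tuple[float, float]:
    """(lambda, K) for an ungapped match/mismatch scoring scheme over uniform
    base composition. lambda solves sum p_i p_j exp(lambda s_ij) = 1; K is
    taken as the standard ungapped value for the scheme (0.621 for +1/-2)."""

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lam = brentq(f, 1e-6, 10.0)
    return lam, k_const


class SeedIndex:
    """Exact ``word_size``-mer position index over a genome, built once and
    reused across queries."""

    def __init__(self, genome: dict[str, str], word_size: int = 6):
        self.word_size = word_size
        self.seqs = [s.upper() for s in genome.values()]
        self.words: dict[str, list[tuple[int, int]]] = {}
        for si, su in enumerate(self.seqs):
            for i in range(len(su) - word_size + 1):
                self.words.setdefault(su[i : i + word_size], []).append((si, i))


def best_ungapped_score(query: str, genome: dict[str, str] | SeedIndex,
                        match: int = 1, mismatch: int = -2,
                        word_size: int = 6) -> int:
    """Best ungapped local-alignment score of ``query`` against either strand
    of the genome, seeded on exact ``word_size``-mer matches (no seed -> 0).

    ``genome`` may be a prebuilt :class:`SeedIndex` to amortize index
    construction over many queries."""
    index = genome if isinstance(genome, SeedIndex) else SeedIndex(genome, word_size)
    best = 0
    for q in (query.upper(), revcomp(query.upper())):
        m = len(q)
        seen: set[tuple[int, int]] = set()
        for wi in range(m - index.word_size + 1):
            for si, gi in index.words.get(q[wi : wi + index.word_size], ()):
                diag = (si, gi - wi)
                if diag in seen:
                    continue
                seen.add(diag)
                s = index.seqs[si]
                off = gi - wi
                run = 0
                for qi in range(m):
                    pj = off + qi
                    if 0 <= pj < len(s):
                        run = max(0, run + (match if q[qi] == s[pj] else mismatch))
                        best = max(best, run)
                    else:
                        run = 0
    return best


def screen_ortho_homology(
    seqs: list[str] | list[OrthoSeq],
    genome: dict[str, str],
    evalue_cutoff: float = 25.0,
    match: int = 1,
    mismatch: int = -2,
    word_size: int = 6,
) -> list[OrthoSeq]:
    """Remove sequences with significant genome homology.

    The best seeded ungapped local-alignment score is converted to an
    e-value with Karlin-Altschul statistics (E = K m n exp(-lambda S), n =
    total genome length); sequences with e-value < ``evalue_cutoff`` are
    removed so only genome-orthogonal candidates remain. Every sequence is
    annotated with its e-value.
    """
    if not genome:
        raise InvalidParameterError("genome must be non-empty")
    orthos = [s if isinstance(s, OrthoSeq) else OrthoSeq(s) for s in seqs]
    lam, kconst = karlin_altschul_params(match, mismatch)
    n_total = sum(len(s) for s in genome.values())
    index = SeedIndex(genome, word_size)
    kept = []
    for o in orthos:
        score = best_ungapped_score(o.seq, index, match, mismatch, word_size)
        o.genome_evalue = kconst * len(o.seq) * n_total * math.exp(-lam * score)
        if o.genome_evalue >= evalue_cutoff:
            kept.append(o)
    return kept


def dimer_filter(
    seqs: list[str] | list[OrthoSeq],
    dg_min: float = -9.0,
    temp_c: float = 37.0,
) -> list[OrthoSeq]:
    """Greedy prefix subset free of stable self- and hetero-dimers.

    A sequence is kept iff its most stable self-dimer and its most stable
    hetero-dimer against every previously kept sequence have free energy
    >= ``dg_min`` kcal/mol. Greedy in input order: a maximum-subset search
    is NP-hard and the greedy rule is deterministic. Annotations record the
    minimum self and hetero dimer free energies at decision time.
    """
    orthos = [s if isinstance(s, OrthoSeq) else OrthoSeq(s) for s in seqs]
    kept: list[OrthoSeq] = []
    for o in orthos:
        o.min_self_dg = duplex_dg(o.seq, o.seq, temp_c)
        if o.min_self_dg < dg_min:
            continue
        hetero = [duplex_dg(o.seq, k.seq, temp_c) for k in kept]
        o.min_hetero_dg = min(hetero) if hetero else None
        if o.min_hetero_dg is not None and o.min_hetero_dg < dg_min:
            continue
        kept.append(o)
    return kept


# ---------------------------------------------------------------------------
# roles, colours, assembly


@dataclass
class RoleAssignment:
    reverse_of: dict[tuple[int, str], OrthoSeq]  # (library index, scaffold) -> seq
    forward_of: dict[str, OrthoSeq]  # fluorophore -> seq
    adapter_of: dict[str, OrthoSeq]  # fluorophore -> seq
    ids: dict[str, str]  # sequence -> stable id

    def detector_of(self, fluor: str) -> str:
        """Detection oligo: complement of the fluorophore's adapter (the
        fluorophore itself is conjugated to this oligo)."""
        return revcomp(self.adapter_of[fluor].seq)

    def id_of(self, seq: str) -> str:
        return self.ids[seq]


def assign_roles(
    pool: list[OrthoSeq],
    libraries: list[list[str]],
    fluorophores: tuple[str, ...] = FLUOROPHORES,
    max_scaffolds_per_reverse: int = 4,
    seed: int = 0,
) -> RoleAssignment:
    """Attribute barcode roles from a filtered orthogonal pool.

    5'-GC-clamped sequences are preferred for reverse primers and
    3'-clamped ones for forward primers (a terminal clamp strengthens
    binding where extension starts); remaining choices are drawn in a
    seed-shuffled order. Forward and adapter sequences are
    fluorophore-specific and shared by all libraries; a reverse sequence
    serves at most one scaffold per library and at most
    ``max_scaffolds_per_reverse`` scaffolds overall.
    """
    rng = np.random.default_rng(seed)
    shuffled = list(pool)
    rng.shuffle(shuffled)  # type: ignore[arg-type]
    available = list(shuffled)

    def take(key) -> OrthoSeq:
        if not available:
            raise CapacityError("orthogonal pool exhausted while assigning roles")
        ranked = sorted(range(len(available)), key=lambda i: (key(available[i]), i))
        return available.pop(ranked[0])

    forward_of: dict[str, OrthoSeq] = {}
    adapter_of: dict[str, OrthoSeq] = {}
    # forwards want a 3' clamp and should not consume 5'-clamped (reverse-
    # preferred) sequences; adapters prefer unclamped ones
    for fl in fluorophores:
        fwd = take(lambda o: (not o.gc_clamp_3prime, o.gc_clamp_5prime))
        fwd.role = "forward"
        forward_of[fl] = fwd
    for fl in fluorophores:
        ad = take(lambda o: (o.gc_clamp_5prime, o.gc_clamp_3prime))
        ad.role = "adapter"
        adapter_of[fl] = ad

    reverse_of: dict[tuple[int, str], OrthoSeq] = {}
    reverse_pool: list[OrthoSeq] = []  # already promoted to reverse role
    usage: dict[str, int] = {}
    for li, lib in enumerate(libraries):
        used_here: set[str] = set()
        for scaffold in lib:
            pick = None
            for r in reverse_pool:  # reuse across libraries first
                if r.seq not in used_here and usage[r.seq] < max_scaffolds_per_reverse:
                    pick = r
                    break
            if pick is None:
                pick = take(lambda o: (not o.gc_clamp_5prime,))
                pick.role = "reverse"
                reverse_pool.append(pick)
                usage[pick.seq] = 0
            usage[pick.seq] += 1
            used_here.add(pick.seq)
            reverse_of[(li, scaffold)] = pick

    ids: dict[str, str] = {}
    for i, o in enumerate(reverse_pool):
        ids[o.seq] = f"R{i + 1:02d}"
    for i, fl in enumerate(fluorophores):
        ids[forward_of[fl].seq] = f"F{i + 1:02d}"
        ids[adapter_of[fl].seq] = f"A{i + 1:02d}"
    return RoleAssignment(reverse_of, forward_of, adapter_of, ids)


@dataclass
class ColourScheme:
    """Ordered per-probe colour pattern per scaffold, plus the cross-pool
    repeats report."""

    pattern: dict[str, tuple[str, ...]]
    cross_pool_repeats: list[tuple[str, str]]

    def fluorophores_for(self, scaffold_id: str, probe_index: int) -> frozenset:
        return SET_OF_COLOUR[self.pattern[scaffold_id][probe_index]]


def assign_colour_schemes(
    allocation: AllocationScheme,
    palette: tuple[str, ...] = FLUOROPHORES,
) -> ColourScheme:
    """Assign each scaffold an ordered colour pattern, unique within its pool.

    The colour alphabet is the three single fluorophores plus the three
    unordered pairs (six colours). Within one library no two scaffolds may
    share an identical ordered pattern; repeats across pools are allowed and
    reported. Raises if a pool holds more same-probe-count scaffolds than
    distinct patterns exist (6^n)."""
    if len(palette) != 3:
        raise InvalidParameterError("the colour model assumes a 3-fluorophore palette")
    pattern: dict[str, tuple[str, ...]] = {}
    seen_by_pool: list[set[tuple[str, ...]]] = []
    for li, lib in enumerate(allocation.libraries):
        used: set[tuple[str, ...]] = set()
        by_count: dict[int, int] = {}
        for s in lib:
            by_count[allocation.counts[s]] = by_count.get(allocation.counts[s], 0) + 1
        for n, cnt in by_count.items():
            if cnt > 6 ** n:
                raise InfeasibleDesignError(
                    f"pool {li}: {cnt} scaffolds with {n} probes exceed {6 ** n} "
                    "distinct colour patterns; split the pool"
                )
        for s in lib:
            n = allocation.counts[s]
            for cand in itertools.product(COLOUR_ORDER, repeat=n):
                if cand not in used:
                    used.add(cand)
                    pattern[s] = cand
                    break
        seen_by_pool.append(used)
    repeats = []
    for i in range(len(seen_by_pool)):
        for j in range(i + 1, len(seen_by_pool)):
            for pat in seen_by_pool[i] & seen_by_pool[j]:
                a = [s for s in allocation.libraries[i] if pattern[s] == pat]
                b = [s for s in allocation.libraries[j] if pattern[s] == pat]
                for x in a:
                    for y in b:
                        repeats.append((x, y))
    return ColourScheme(pattern, repeats)


def apply_colours(plan: ProbePlan, scheme: ColourScheme) -> None:
    for w in plan.windows:
        w.fluorophores = scheme.fluorophores_for(w.scaffold_id, w.design_index)


@dataclass
class AssembledOligo:
    oligo_id: str
    probe_id: str
    scaffold_id: str
    homolog: str
    start: int
    end: int
    reverse_id: str
    forward_id: str
    fluorophore: str
    sequence: str  # the 79-mer


@dataclass
class PrimerRecord:
    primer_id: str
    kind: str  # reverse_amplification | forward_amplification | detector
    sequence: str
    fluorophore: str | None = None


def assemble_oligos(
    plan: ProbePlan,
    allocation: AllocationScheme,
    roles: RoleAssignment,
    t7: str = T7_PROMOTER,
) -> tuple[list[AssembledOligo], list[PrimerRecord]]:
    """Assemble final 79-mers and the amplification/detection oligo set.

    Each oligo is reverse(20) + homolog(39) + forward(20). A probe carrying
    two fluorophores alternates its oligos between the two fluorophores'
    forward primers. The reverse amplification primer for PCR/IVT is the T7
    promoter (33 nt) followed by the reverse complement of the oligo's
    5' reverse segment (53 nt total); the forward amplification primer is
    adapter(20) + forward(20) (40 nt); the detector is the adapter's
    complement, conjugated to its fluorophore.
    """
    oligos: list[AssembledOligo] = []
    for w in plan.windows:
        if w.fluorophores is None:
            raise InvalidParameterError(f"probe {w.probe_id} has no colour assigned")
        li = allocation.library_of(w.scaffold_id)
        rev = roles.reverse_of.get((li, w.scaffold_id))
        if rev is None:
            raise CapacityError(f"no reverse primer for {w.scaffold_id} in library {li}")
        w.reverse_primer_id = roles.id_of(rev.seq)
        fls = sorted(w.fluorophores)
        w.forward_primer_ids = [roles.id_of(roles.forward_of[f].seq) for f in fls]
        for i, cand in enumerate(w.oligos):
            fl = fls[i % len(fls)]
            fwd = roles.forward_of[fl]
            seq = rev.seq + cand.sequence + fwd.seq
            oligos.append(
                AssembledOligo(
                    oligo_id=f"{w.probe_id}_{i:05d}",
                    probe_id=w.probe_id,
                    scaffold_id=w.scaffold_id,
                    homolog=cand.sequence,
                    start=cand.start,
                    end=cand.end,
                    reverse_id=roles.id_of(rev.seq),
                    forward_id=roles.id_of(fwd.seq),
                    fluorophore=fl,
                    sequence=seq,
                )
            )
    primers: list[PrimerRecord] = []
    emitted: set[str] = set()
    for (li, scaffold), rev in roles.reverse_of.items():
        rid = roles.id_of(rev.seq)
        if rid not in emitted:
            emitted.add(rid)
            primers.append(
                PrimerRecord(f"T7_{rid}", "reverse_amplification", t7 + revcomp(rev.seq))
            )
    for fl in roles.forward_of:
        fid = roles.id_of(roles.forward_of[fl].seq)
        aid = roles.id_of(roles.adapter_of[fl].seq)
        primers.append(
            PrimerRecord(
                f"{aid}_{fid}", "forward_amplification",
                roles.adapter_of[fl].seq + roles.forward_of[fl].seq, fl,
            )
        )
        primers.append(PrimerRecord(f"DET_{aid}", "detector", roles.detector_of(fl), fl))
    return oligos, primers


def split_oligo(sequence: str) -> tuple[str, str, str]:
    """Recover (reverse, homolog, forward) from an assembled 79-mer."""
    if len(sequence) != 79:
        raise InvalidSequenceError("assembled oligos are 79-mers")
    return sequence[0:20], sequence[20:59], sequence[59:79]
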