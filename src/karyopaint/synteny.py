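"""Synteny blocks and block-level rearrangement classification.

Whole-genome alignments (PAF) are chained into co-linear synteny blocks,
summed into a chromosome-association table (the input of a Sankey or
Jupiter-style figure), and — at the level of a handful of blocks per
ancestral chromosome — explained by a minimum number of rearrangement
events among {fission, fusion, translocation, inversion}, found by
exhaustive breadth-first search over signed block arrangements. When
several event orders are equally parsimonious they are all reported and
the chronology marked undetermined; the search never picks one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidParameterError

MAX_BLOCKS_FOR_SEARCH = 10

# a chromosome is a tuple of (block_id, sign) with sign in {+1, -1};
# a genome state is a sorted tuple of canonical chromosomes


@dataclass
class SyntenyBlock:
    query_chromosome: str
    query_start: int
    query_end: int
    reference_chromosome: str
    reference_start: int
    reference_end: int
    strand: str
    aligned_bases: int

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start or self.reference_end <= self.reference_start:
            raise InvalidParameterError("block intervals must have positive length")
        span = min(
            self.query_end - self.query_start,
            self.reference_end - self.reference_start,
        )
        self.aligned_bases = min(self.aligned_bases, span)


def chain_blocks(paf: pd.DataFrame, min_block: int = 100_000, max_gap: int = 500_000) -> list[SyntenyBlock]:
    """Merge co-linear same-strand alignments within ``max_gap`` (on both
    genomes) into blocks; drop blocks whose query span is below
    ``min_block``; return blocks sorted by query position."""
    blocks: list[SyntenyBlock] = []
    if len(paf) == 0:
        return blocks
    for (q, t, strand), grp in paf.groupby(["query", "target", "strand"], sort=True):
        grp = grp.sort_values("qstart")
        cur = None
        for _, r in grp.iterrows():
            rec = (int(r["qstart"]), int(r["qend"]), int(r["tstart"]), int(r["tend"]),
                   int(r.get("matches", r["qend"] - r["qstart"])))
            if cur is None:
                cur = list(rec)
                continue
            q_gap = rec[0] - cur[1]
            if strand == "+":
                t_gap = rec[2] - cur[3]
                colinear = rec[2] >= cur[2]
            else:
                t_gap = cur[2] - rec[3]
                colinear = rec[3] <= cur[3]
            if 0 <= q_gap <= max_gap or (q_gap < 0 and -q_gap <= max_gap):
                pass
            else:
                colinear = False
            if colinear and abs(t_gap) <= max_gap and q_gap <= max_gap:
                cur[1] = max(cur[1], rec[1])
                cur[2] = min(cur[2], rec[2])
                cur[3] = max(cur[3], rec[3])
                cur[4] += rec[4]
            else:
                blocks.append(SyntenyBlock(q, cur[0], cur[1], t, cur[2], cur[3], strand, cur[4]))
                cur = list(rec)
        blocks.append(SyntenyBlock(q, cur[0], cur[1], t, cur[2], cur[3], strand, cur[4]))
    blocks = [b for b in blocks if b.query_end - b.query_start >= min_block]
    blocks.sort(key=lambda b: (b.query_chromosome, b.query_start))
    return blocks


def chromosome_associations(blocks: list[SyntenyBlock], min_weight: int = 0) -> pd.DataFrame:
    """Weighted bipartite table (query chromosome, reference chromosome,
    aligned bases) — the direct input of a Sankey diagram."""
    if not blocks:
        raise InvalidParameterError("no blocks")
    rows: dict[tuple[str, str], int] = {}
    for b in blocks:
        key = (b.query_chromosome, b.reference_chromosome)
        rows[key] = rows.get(key, 0) + b.aligned_bases
    table = pd.DataFrame(
        [{"source": q, "target": t, "value": v} for (q, t), v in sorted(rows.items())]
    )
    return table[table["value"] >= min_weight].reset_index(drop=True)


# ---------------------------------------------------------------------------
# rearrangement parsimony


@dataclass
class RearrangementEvent:
    kind: str  # fission | fusion | translocation | inversion
    participants: tuple
    pericentric: bool = False
    ordering_note: str = ""


@dataclass
class RearrangementAnalysis:
    n_events: int
    events: list[RearrangementEvent]
    scenarios: list[tuple[str, ...]] = field(default_factory=list)
    chronology_determined: bool = True

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(e.kind for e in self.events)


def _canon_chrom(c: tuple) -> tuple:
    rc = tuple((bid, -s) for bid, s in reversed(c))
    return min(c, rc)


def _canon(state) -> tuple:
    return tuple(sorted(_canon_chrom(tuple(c)) for c in state))


def _moves(state):
    """All single-event successors: (new_state, kind, participants)."""
    chroms = [list(c) for c in state]
    n = len(chroms)
    # inversion: reverse + sign-flip a contiguous segment
    for ci, c in enumerate(chroms):
        L = len(c)
        for i in range(L):
            for j in range(i + 1, L + 1):
                seg = [(b, -s) for b, s in reversed(c[i:j])]
                if seg == c[i:j]:
                    continue
                new_c = c[:i] + seg + c[j:]
                rest = [tuple(x) for k, x in enumerate(chroms) if k != ci]
                yield (
                    _canon(rest + [tuple(new_c)]),
                    "inversion",
                    tuple(b for b, _ in c[i:j]),
                )
    # fission: split one chromosome in two
    for ci, c in enumerate(chroms):
        for i in range(1, len(c)):
            rest = [tuple(x) for k, x in enumerate(chroms) if k != ci]
            yield (
                _canon(rest + [tuple(c[:i]), tuple(c[i:])]),
                "fission",
                (tuple(b for b, _ in c),),
            )
    # fusion: concatenate two chromosomes in any relative orientation
    for ci in range(n):
        for cj in range(n):
            if ci == cj:
                continue
            a, b = chroms[ci], chroms[cj]
            rest = [tuple(x) for k, x in enumerate(chroms) if k not in (ci, cj)]
            for bb in (b, [(x, -s) for x, s in reversed(b)]):
                yield (
                    _canon(rest + [tuple(a + bb)]),
                    "fusion",
                    (tuple(x for x, _ in a), tuple(x for x, _ in b)),
                )
    # translocation: excise a contiguous segment, reinsert elsewhere unflipped
    for ci, c in enumerate(chroms):
        L = len(c)
        for i in range(L):
            for j in range(i + 1, L + 1):
                if i == 0 and j == L:
                    continue
                seg = c[i:j]
                remainder = c[:i] + c[j:]
                others = [(k, x) for k, x in enumerate(chroms) if k != ci]
                # reinsert into the remainder of the same chromosome
                for pos in range(len(remainder) + 1):
                    if pos == i:
                        continue
                    new_c = remainder[:pos] + seg + remainder[pos:]
                    rest = [tuple(x) for k, x in others]
                    yield (
                        _canon(rest + [tuple(new_c)]),
                        "translocation",
                        tuple(b for b, _ in seg),
                    )
                # or into another chromosome
                for k, x in others:
                    for pos in range(len(x) + 1):
                        new_x = list(x[:pos]) + seg + list(x[pos:])
                        rest = [tuple(y) for m, y in others if m != k]
                        if remainder:
                            rest.append(tuple(remainder))
                        yield (
                            _canon(rest + [tuple(new_x)]),
                            "translocation",
                            tuple(b for b, _ in seg),
                        )


def classify_rearrangements(
    reference: dict[str, list[str]],
    query: dict[str, list[tuple[str, int]]],
    centromere_blocks: set[str] | None = None,
    max_events: int = 4,
    max_scenarios: int = 64,
) -> RearrangementAnalysis:
    """Minimum-event explanation turning the reference block arrangement into
    the query arrangement.

    ``reference``: per ancestral chromosome, block ids in order (forward).
    ``query``: per query chromosome, (block id, sign) with sign +-1.
    Exhaustive breadth-first search over signed block arrangements up to
    ``max_events`` events; every minimal event-kind order is collected and
    the chronology is marked undetermined when more than one order exists.
    Inversions whose segment contains a block in ``centromere_blocks`` are
    flagged pericentric.
    """
    n_blocks = sum(len(v) for v in reference.values())
    if n_blocks > MAX_BLOCKS_FOR_SEARCH:
        raise InvalidParameterError(
            f"{n_blocks} blocks exceed the exhaustive-search limit "
            f"({MAX_BLOCKS_FOR_SEARCH}); raise min_block to coarsen the blocks"
        )
    ref_ids = sorted(b for v in reference.values() for b in v)
    qry_ids = sorted(b for v in query.values() for b, _ in v)
    if ref_ids != qry_ids:
        raise InvalidParameterError("reference and query must contain the same blocks")
    start = _canon([tuple((b, 1) for b in v) for v in reference.values()])
    goal = _canon([tuple(v) for v in query.values()])
    if start == goal:
        return RearrangementAnalysis(0, [], [()])

    # BFS layers, recording minimal predecessors for path enumeration
    dist = {start: 0}
    preds: dict[tuple, list[tuple]] = {}
    frontier = [start]
    depth = 0
    while frontier and depth < max_events:
        depth += 1
        nxt = []
        for s in frontier:
            for ns, kind, part in _moves(s):
                d = dist.get(ns)
                if d is None:
                    dist[ns] = depth
                    preds[ns] = [(s, kind, part)]
                    nxt.append(ns)
                elif d == depth:
                    preds[ns].append((s, kind, part))
        if goal in dist:
            break
        frontier = nxt
    if goal not in dist:
        raise InvalidParameterError(
            f"no explanation within {max_events} events; raise max_events"
        )

    paths: list[list[tuple[str, tuple]]] = []

    def back(state, acc):
        if len(paths) >= max_scenarios:
            return
        if state == start and len(acc) == dist[goal]:
            paths.append(list(reversed(acc)))
            return
        for prev, kind, part in preds.get(state, []):
            if dist.get(prev) == dist[state] - 1:
                back(prev, acc + [(kind, part)])

    back(goal, [])
    cen = centromere_blocks or set()
    scenarios = sorted({tuple(k for k, _ in p) for p in paths})
    chrono = len(scenarios) == 1
    best = min(paths, key=lambda p: tuple(k for k, _ in p))
    events = []
    for i, (kind, part) in enumerate(best):
        note = "" if chrono else "chronology undetermined"
        peri = kind == "inversion" and any(b in cen for b in part)
        events.append(RearrangementEvent(kind, part, pericentric=peri, ordering_note=note))
    return RearrangementAnalysis(dist[goal], events, scenarios, chrono)


def arrangements_from_blocks(blocks: list[SyntenyBlock]):
    """Derive (reference, query) arrangements for the parsimony search from
    chained blocks: block ids are assigned per reference chromosome in
    reference order; query chromosomes list them in query order with the
    alignment strand as sign."""
    ref: dict[str, list[str]] = {}
    named = []
    for b in sorted(blocks, key=lambda b: (b.reference_chromosome, b.reference_start)):
        bid = f"{b.reference_chromosome}.{len(ref.get(b.reference_chromosome, []))}"
        ref.setdefault(b.reference_chromosome, []).append(bid)
        named.append((b, bid))
    qry: dict[str, list[tuple[str, int]]] = {}
    for b, bid in sorted(named, key=lambda x: (x[0].query_chromosome, x[0].query_start)):
        qry.setdefault(b.query_chromosome, []).append((bid, 1 if b.strand == "+" else -1))
    return ref, qry
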