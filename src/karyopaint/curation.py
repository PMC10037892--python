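"""Interpreting hybridization observations to curate a scaffold assembly.

The FISH readout for one probe is the chromosome it lights up, its rank
along the chromatid counted from the centromere, and (on late metaphase
spreads) which side of the centromere it sits on. From repeated spreads this
module:

1. assigns each scaffold to the chromosome(s) its probes vote for;
2. flags mis-assemblies — *chimeric* scaffolds whose probes land on two or
   more chromosomes, and *reordered* scaffolds whose single-chromosome probe
   order is neither the designed order nor its full reversal (a full
   reversal is just the opposite orientation, not an error);
3. localizes each chimera's breakpoint inside the gap between the two
   flanking probes, narrowed by whole-genome alignments to a reference
   genome when available (midpoint fallback otherwise);
4. splits chimeric scaffolds, orients every part centromere -> telomere from
   the late-metaphase colour-pattern order, and emits an ordered,
   oriented chromosome build (AGP).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from .design import ProbePlan, ProbeWindow
from .errors import ConsistencyError, InvalidParameterError
from .synthetic import HybObservation

logger = logging.getLogger(__name__)

MORPHOLOGY_RANK = {"acrocentric": 0, "submetacentric": 1, "metacentric": 2}


# ---------------------------------------------------------------------------
# scaffold -> chromosome assignment


@dataclass
class Assignment:
    probe_chromosome: dict[str, str]
    probe_votes: dict[str, Counter]
    probe_order: dict[str, float]  # median rank from the centromere
    probe_side: dict[str, str]  # majority centromere side ('p'/'q')
    ambiguous_probes: set[str]
    unplaced_probes: set[str]
    scaffold_chromosomes: dict[str, set[str]]

    def chromosome_of(self, scaffold_id: str) -> set[str]:
        return self.scaffold_chromosomes.get(scaffold_id, set())


def assign_scaffolds(
    observations: list[HybObservation],
    plan: ProbePlan,
    min_spreads: int = 2,
) -> Assignment:
    """Majority-vote placement of probes, then scaffolds, onto chromosomes.

    A probe's placement needs at least ``min_spreads`` concordant spreads;
    probes with a majority below that support are flagged ambiguous, probes
    never observed are listed unplaced (neither is an error). An observation
    whose colour contradicts the plan's fluorophore assignment is discarded.
    """
    known = {w.probe_id: w for w in plan.windows}
    for o in observations:
        if o.probe_id not in known:
            raise InvalidParameterError(f"observed unknown probe {o.probe_id}")
    votes: dict[str, Counter] = {}
    orders: dict[str, list[int]] = {}
    sides: dict[str, list[str]] = {}
    for o in observations:
        w = known[o.probe_id]
        if w.fluorophores is not None and frozenset(o.colour) != frozenset(w.fluorophores):
            logger.warning("probe %s: colour mismatch, observation discarded", o.probe_id)
            continue
        votes.setdefault(o.probe_id, Counter())[o.chromosome_label] += 1
        orders.setdefault(o.probe_id, [])
        sides.setdefault(o.probe_id, [])
        orders[o.probe_id].append(o.order_index)
        if o.centromere_side:
            sides[o.probe_id].append(o.centromere_side)

    probe_chromosome: dict[str, str] = {}
    probe_order: dict[str, float] = {}
    probe_side: dict[str, str] = {}
    ambiguous: set[str] = set()
    unplaced = {p for p in known if p not in votes}
    for pid, tally in votes.items():
        label, support = tally.most_common(1)[0]
        if support < min_spreads:
            ambiguous.add(pid)
            continue
        probe_chromosome[pid] = label
        probe_order[pid] = float(median(orders[pid]))
        if sides[pid]:
            probe_side[pid] = Counter(sides[pid]).most_common(1)[0][0]

    scaffold_chromosomes: dict[str, set[str]] = {}
    for pid, label in probe_chromosome.items():
        scaffold_chromosomes.setdefault(known[pid].scaffold_id, set()).add(label)
    return Assignment(
        probe_chromosome, votes, probe_order, probe_side,
        ambiguous, unplaced, scaffold_chromosomes,
    )


# ---------------------------------------------------------------------------
# anomaly detection


def detect_anomalies(assignment: Assignment, plan: ProbePlan) -> dict[str, str]:
    """Per-scaffold status: chimeric, reordered or clean.

    Chimeric (probes on >= 2 chromosomes) takes precedence over reordered
    (single chromosome, but the observed probe order along the chromatid is
    neither the design order nor its full reversal).

    Ranks are counted from the centromere separately on each arm, so they
    are linearized before comparison: p-arm probes in descending rank order,
    then q-arm probes in ascending order (probes without side information
    sort with the q arm). A clean scaffold spanning the centromere therefore
    stays clean."""
    statuses: dict[str, str] = {}
    for sid, windows in plan.by_scaffold().items():
        chroms = assignment.chromosome_of(sid)
        if len(chroms) >= 2:
            statuses[sid] = "chimeric"
            continue
        placed = [w for w in windows if w.probe_id in assignment.probe_order]
        if len(placed) < 2:
            statuses[sid] = "clean"
            continue
        keys = []
        for w in placed:
            r = assignment.probe_order[w.probe_id]
            side = assignment.probe_side.get(w.probe_id)
            keys.append((0, -r) if side == "p" else (1, r))
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        pos = {idx: p for p, idx in enumerate(order)}
        perm = [pos[i] for i in range(len(keys))]
        identity = list(range(len(placed)))
        statuses[sid] = "clean" if perm in (identity, identity[::-1]) else "reordered"
    return statuses


# ---------------------------------------------------------------------------
# breakpoints


@dataclass
class Breakpoint:
    scaffold_id: str
    left_bound: int
    right_bound: int
    flanking_probe_ids: tuple[str, str]
    evidence: str  # synteny | midpoint_fallback
    reference_chromosomes: tuple[str | None, str | None] = (None, None)

    @property
    def midpoint(self) -> int:
        return (self.left_bound + self.right_bound) // 2


def locate_breakpoints(
    scaffold_id: str,
    plan: ProbePlan,
    assignment: Assignment,
    alignments: pd.DataFrame | None = None,
    statuses: dict[str, str] | None = None,
) -> Breakpoint:
    """Breakpoint interval of a chimeric scaffold.

    The interval starts as the gap between the flanking probes (the last
    probe voting for the first chromosome and the first voting for the
    second; they must be adjacent in design order). Reference-genome
    alignments (PAF columns: query, qstart, qend, strand, target, tstart,
    tend) narrow it to the gap between the last block consistent with the
    left reference chromosome and the first consistent with the right; with
    no informative alignment the full inter-probe gap is returned with
    ``evidence='midpoint_fallback'``.
    """
    if statuses is not None and statuses.get(scaffold_id) != "chimeric":
        raise ConsistencyError(f"{scaffold_id} is not flagged chimeric")
    windows = sorted(
        (w for w in plan.windows if w.scaffold_id == scaffold_id),
        key=lambda w: w.design_index,
    )
    labels = [assignment.probe_chromosome.get(w.probe_id) for w in windows]
    placed = [(w, l) for w, l in zip(windows, labels) if l is not None]
    chroms = []
    for _, l in placed:
        if l not in chroms:
            chroms.append(l)
    if len(chroms) < 2:
        raise ConsistencyError(f"{scaffold_id}: fewer than two chromosomes observed")
    left_chrom, right_chrom = chroms[0], chroms[1]
    left_ws = [w for w, l in placed if l == left_chrom]
    right_ws = [w for w, l in placed if l == right_chrom]
    left_flank, right_flank = left_ws[-1], right_ws[0]
    if right_flank.design_index != left_flank.design_index + 1:
        raise ConsistencyError(
            f"{scaffold_id}: flanking probes {left_flank.probe_id}/{right_flank.probe_id} "
            "are not adjacent in design order"
        )
    gap_start, gap_end = left_flank.end, right_flank.start

    ref_left = ref_right = None
    lo, hi = gap_start, gap_end
    evidence = "midpoint_fallback"
    if alignments is not None and len(alignments):
        aln = alignments[alignments["query"] == scaffold_id]
        ref_left = _majority_reference(aln, left_ws)
        ref_right = _majority_reference(aln, right_ws)
        if ref_left and ref_right and ref_left != ref_right:
            in_gap = aln[(aln["qend"] > gap_start) & (aln["qstart"] < gap_end)]
            left_blocks = in_gap[in_gap["target"] == ref_left]
            right_blocks = in_gap[in_gap["target"] == ref_right]
            cand_lo = int(min(left_blocks["qend"].max(), gap_end)) if len(left_blocks) else gap_start
            cand_hi = int(max(right_blocks["qstart"].min(), gap_start)) if len(right_blocks) else gap_end
            # cand_lo == cand_hi is a point estimate (blocks abut exactly)
            if cand_lo <= cand_hi and (cand_lo > gap_start or cand_hi < gap_end):
                lo, hi = cand_lo, cand_hi
                evidence = "synteny"
    return Breakpoint(
        scaffold_id, lo, hi, (left_flank.probe_id, right_flank.probe_id),
        evidence, (ref_left, ref_right),
    )


def _majority_reference(aln: pd.DataFrame, windows: list[ProbeWindow]) -> str | None:
    weights: Counter = Counter()
    for w in windows:
        hit = aln[(aln["qend"] > w.start) & (aln["qstart"] < w.end)]
        for _, row in hit.iterrows():
            ov = min(row["qend"], w.end) - max(row["qstart"], w.start)
            weights[row["target"]] += ov
    return weights.most_common(1)[0][0] if weights else None


# ---------------------------------------------------------------------------
# splitting, orientation, chromosome building


@dataclass
class ScaffoldPart:
    part_id: str
    scaffold_id: str
    start: int
    end: int
    orientation: str | None  # '+' | '-' | None (undetermined)
    assigned_chromosome: str | None
    order_on_chromosome: int = 0
    arm: str = "q"
    probe_ids: list[str] = field(default_factory=list)
    low_confidence: bool = False
    breakpoint: Breakpoint | None = None

    @property
    def label(self) -> str:
        """Composition label: part id plus 'rev' for reversed parts."""
        return self.part_id + ("rev" if self.orientation == "-" else "")

    def __len__(self) -> int:
        return self.end - self.start


def _part_name(scaffold_id: str, probe_indices: list[int], whole: bool) -> str:
    short = scaffold_id.split("_")[-1] if "_" in scaffold_id else scaffold_id
    if whole:
        return short
    a, b = probe_indices[0], probe_indices[-1]
    return f"{short}p{a}" if a == b else f"{short}p{a}-{b}"


def split_and_orient(
    plan: ProbePlan,
    assignment: Assignment,
    statuses: dict[str, str],
    breakpoints: dict[str, Breakpoint],
    scaffold_lengths: dict[str, int],
) -> list[ScaffoldPart]:
    """Split chimeric scaffolds at breakpoint midpoints and orient all parts.

    Orientation is '+' when the designed probe order runs centromere ->
    telomere (observed rank increases with design index), '-' ('rev') when
    it runs the other way. Single-probe parts default to '+' with a
    low-confidence flag; spreads that contradict each other on centromere
    side leave the orientation unset with a warning.
    """
    parts: list[ScaffoldPart] = []
    for sid, windows in plan.by_scaffold().items():
        L = scaffold_lengths[sid]
        if statuses.get(sid) == "chimeric":
            bp = breakpoints.get(sid)
            if bp is None:
                raise InvalidParameterError(f"chimeric scaffold {sid} has no breakpoint")
            mid = bp.midpoint
            left = [w for w in windows if w.end <= mid]
            right = [w for w in windows if w.start >= mid]
            pieces = [((0, mid), left), ((mid, L), right)]
        else:
            pieces = [((0, L), windows)]
        for (a, b), ws in pieces:
            idxs = [w.design_index for w in ws]
            part = ScaffoldPart(
                part_id=_part_name(sid, idxs, whole=len(ws) == len(windows)),
                scaffold_id=sid,
                start=a,
                end=b,
                orientation=None,
                assigned_chromosome=_part_chromosome(ws, assignment),
                probe_ids=[w.probe_id for w in ws],
                breakpoint=breakpoints.get(sid) if statuses.get(sid) == "chimeric" else None,
            )
            _orient_part(part, ws, assignment)
            parts.append(part)
    _order_parts(parts, assignment, plan)
    return parts


def _part_chromosome(ws, assignment) -> str | None:
    tally = Counter(
        assignment.probe_chromosome[w.probe_id]
        for w in ws
        if w.probe_id in assignment.probe_chromosome
    )
    return tally.most_common(1)[0][0] if tally else None


def _orient_part(part: ScaffoldPart, ws, assignment: Assignment) -> None:
    ranked = [(w.design_index, assignment.probe_order[w.probe_id])
              for w in ws if w.probe_id in assignment.probe_order]
    sides = [assignment.probe_side.get(w.probe_id) for w in ws]
    sides = [s for s in sides if s]
    if sides:
        part.arm = Counter(sides).most_common(1)[0][0]
        if len(set(sides)) > 1 and len(ranked) < 2:
            logger.warning("part %s: contradictory centromere sides; orientation unset",
                           part.part_id)
            part.orientation = None
            return
    if len(ranked) < 2:
        part.orientation = "+"
        part.low_confidence = True
        return
    ranked.sort()
    diffs = [b[1] - a[1] for a, b in zip(ranked, ranked[1:])]
    if all(d > 0 for d in diffs):
        part.orientation = "+"
    elif all(d < 0 for d in diffs):
        part.orientation = "-"
    else:
        logger.warning("part %s: inconsistent probe order; orientation unset", part.part_id)
        part.orientation = None


def _order_parts(parts: list[ScaffoldPart], assignment: Assignment, plan: ProbePlan) -> None:
    """Rank parts along each chromosome from the centromere outward
    (p-arm parts first, descending rank; then q-arm ascending)."""
    by_chrom: dict[str, list[ScaffoldPart]] = {}
    for p in parts:
        if p.assigned_chromosome:
            by_chrom.setdefault(p.assigned_chromosome, []).append(p)
    for chrom, ps in by_chrom.items():
        def key(part: ScaffoldPart):
            ranks = [assignment.probe_order[pid] for pid in part.probe_ids
                     if pid in assignment.probe_order]
            r = min(ranks) if ranks else float("inf")
            return (0, -r) if part.arm == "p" else (1, r)

        for i, p in enumerate(sorted(ps, key=key)):
            p.order_on_chromosome = i


@dataclass
class ChromosomeBuild:
    chromosome_id: str
    parts: list[ScaffoldPart]
    morphology: str | None = None
    centromere_end: str = "left"
    gap_policy: tuple[str, int, str] = ("U", 100, "map")

    @property
    def composition(self) -> str:
        return "".join(p.label for p in self.parts)

    def total_component_bases(self) -> int:
        return sum(len(p) for p in self.parts)


def build_chromosomes(
    parts: list[ScaffoldPart],
    gap_size: int = 100,
    morphology: dict[str, str] | None = None,
) -> list[ChromosomeBuild]:
    """Group ordered parts into per-chromosome builds (AGP-ready).

    Component order follows ``order_on_chromosome`` from the centromere; two
    parts claiming one order index is a collision error."""
    by_chrom: dict[str, list[ScaffoldPart]] = {}
    for p in parts:
        if p.assigned_chromosome is None:
            continue
        by_chrom.setdefault(p.assigned_chromosome, []).append(p)
    builds = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: p.order_on_chromosome)
        orders = [p.order_on_chromosome for p in ps]
        if len(set(orders)) != len(orders):
            raise ConsistencyError(f"{chrom}: duplicate order index among parts")
        builds.append(
            ChromosomeBuild(
                chrom, ps,
                morphology=(morphology or {}).get(chrom),
                gap_policy=("U", gap_size, "map"),
            )
        )
    return builds


# ---------------------------------------------------------------------------
# karyotype numbering / idiogram


def order_and_number(
    builds: list[ChromosomeBuild],
    relative_lengths: pd.DataFrame,
    sex_chromosome: str | None = None,
) -> pd.DataFrame:
    """Number chromosomes by cytogenetic convention and emit the idiogram table.

    Autosomes are numbered acrocentric first, then submetacentric, then
    metacentric, by decreasing relative length within each morphology class;
    the sex chromosome is labelled X and excluded from autosome numbering.
    Length ties break by composition string (logged). ``relative_lengths``
    needs columns chromosome / relative_length / sd. Output columns:
    chromosome, label, relative_length, sd, morphology, composition.
    """
    if not builds:
        raise InvalidParameterError("no chromosome builds")
    for b in builds:
        if b.morphology is None:
            raise InvalidParameterError(f"{b.chromosome_id}: morphology required")
    rl = relative_lengths.set_index("chromosome")

    def sort_key(b: ChromosomeBuild):
        length = float(rl.loc[b.chromosome_id, "relative_length"])
        return (MORPHOLOGY_RANK[b.morphology], -length, b.composition)

    autosomes = sorted(
        (b for b in builds if b.chromosome_id != sex_chromosome), key=sort_key
    )
    lengths = [float(rl.loc[b.chromosome_id, "relative_length"]) for b in autosomes]
    if len(set(lengths)) != len(lengths):
        logger.warning("length ties broken by composition string")
    rows = []
    for i, b in enumerate(autosomes, start=1):
        rows.append(_idiogram_row(b, str(i), rl))
    for b in builds:
        if b.chromosome_id == sex_chromosome:
            rows.append(_idiogram_row(b, "X", rl))
    return pd.DataFrame(rows)


def _idiogram_row(build: ChromosomeBuild, label: str, rl: pd.DataFrame) -> dict:
    return {
        "chromosome": build.chromosome_id,
        "label": label,
        "relative_length": float(rl.loc[build.chromosome_id, "relative_length"]),
        "sd": float(rl.loc[build.chromosome_id, "sd"]),
        "morphology": build.morphology,
        "composition": build.composition,
    }


# ---------------------------------------------------------------------------
# one-call curation


@dataclass
class CurationResult:
    assignment: Assignment
    statuses: dict[str, str]
    breakpoints: dict[str, Breakpoint]
    parts: list[ScaffoldPart]
    builds: list[ChromosomeBuild]


def curate(
    observations: list[HybObservation],
    plan: ProbePlan,
    scaffold_lengths: dict[str, int],
    alignments: pd.DataFrame | None = None,
    min_spreads: int = 2,
    gap_size: int = 100,
    morphology: dict[str, str] | None = None,
) -> CurationResult:
    """Run the whole curation chain: assign, detect, break, split, build."""
    assignment = assign_scaffolds(observations, plan, min_spreads=min_spreads)
    statuses = detect_anomalies(assignment, plan)
    breakpoints = {
        sid: locate_breakpoints(sid, plan, assignment, alignments, statuses)
        for sid, st in statuses.items()
        if st == "chimeric"
    }
    parts = split_and_orient(plan, assignment, statuses, breakpoints, scaffold_lengths)
    builds = build_chromosomes(parts, gap_size=gap_size, morphology=morphology)
    return CurationResult(assignment, statuses, breakpoints, parts, builds)
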