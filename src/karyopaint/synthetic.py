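"""Toy genomes, fragmented scaffold sets and simulated hybridization data.

This module manufactures the inputs the rest of the pipeline consumes, with
complete ground truth, so every downstream stage can be exercised without any
external download:

* a multi-chromosome genome with a chosen karyotype (acrocentric /
  submetacentric / metacentric morphologies and centromere placements) and
  planted exact-duplication repeat tracts;
* scaffolds cut from that genome, optionally with planted chimeric joins
  (two chromosomes glued into one scaffold) and internal inversions — the two
  mis-assembly classes a FISH screen can reveal;
* an orthogonal 25-mer pool standing in for a published barcode library;
* per-spread hybridization observations: which chromosome each probe lights
  up, its rank along the chromatid from the centromere, its colour, and a
  per-spread chromatin-compaction factor (multiplicative log-normal — real
  spreads differ in compaction with the mitotic stage of the cell).

All generators take an explicit integer seed and are bit-reproducible; a
single :class:`numpy.random.Generator` is created per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CapacityError,
    ConsistencyError,
    InvalidParameterError,
    LookupError_,
)
from .seqs import revcomp

MORPHOLOGIES = ("acrocentric", "submetacentric", "metacentric")

# centromere placement as a fraction of chromosome length per morphology
_CENTROMERE_FRAC = {"acrocentric": 0.02, "submetacentric": 0.30, "metacentric": 0.50}

BASES = np.array(list("ACGT"))


@dataclass
class Chromosome:
    id: str
    sequence: str
    morphology: str
    centromere_position: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 <= self.centromere_position < n):
            raise InvalidParameterError("centromere_position outside chromosome")
        if self.morphology == "acrocentric" and self.centromere_position > 0.05 * n:
            raise InvalidParameterError("acrocentric centromere must be in the first 5%")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatTract:
    chromosome_id: str
    start: int
    end: int
    family: int


@dataclass
class ToyGenome:
    chromosomes: list[Chromosome]
    repeat_fraction: float
    seed: int
    repeat_tracts: list[RepeatTract] = field(default_factory=list)

    def chromosome(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise LookupError_(chrom_id)

    def sequences(self) -> dict[str, str]:
        return {c.id: c.sequence for c in self.chromosomes}

    def total_length(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(self.sequences(), path)


@dataclass
class ScaffoldPartTruth:
    """One contiguous genome slice inside a scaffold (0-based half-open)."""

    chromosome_id: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    parts: list[ScaffoldPartTruth]
    junctions: list[int] = field(default_factory=list)
    inverted_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_chimeric(self) -> bool:
        return len({p.chromosome_id for p in self.parts}) >= 2

    @property
    def length(self) -> int:
        return sum(len(p) for p in self.parts)

    def part_offsets(self) -> list[int]:
        """Scaffold-local start offset of each part."""
        offs = [0]
        for p in self.parts[:-1]:
            offs.append(offs[-1] + len(p))
        return offs

    def map_to_genome(self, pos: int) -> tuple[str, int]:
        """Map a scaffold-local position to (chromosome, genome position)."""
        if not (0 <= pos < self.length):
            raise ConsistencyError(
                f"position {pos} outside scaffold {self.scaffold_id} (len {self.length})"
            )
        off = 0
        for p in self.parts:
            if pos < off + len(p):
                local = pos - off
                if p.strand == "+":
                    return p.chromosome_id, p.start + local
                return p.chromosome_id, p.end - 1 - local
            off += len(p)
        raise AssertionError("unreachable")


@dataclass
class ScaffoldSet:
    sequences: dict[str, str]
    truths: list[ScaffoldTruth]

    def truth(self, scaffold_id: str) -> ScaffoldTruth:
        for t in self.truths:
            if t.scaffold_id == scaffold_id:
                return t
        raise LookupError_(scaffold_id)

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(self.sequences, path)


@dataclass
class HybObservation:
    spread_id: int
    probe_id: str
    chromosome_label: str
    order_index: int
    colour: frozenset
    stage: str = "late_metaphase"
    length_scale: float = 1.0
    centromere_side: str | None = None


def observations_to_frame(observations: list[HybObservation]) -> pd.DataFrame:
    rows = [
        {
            "spread_id": o.spread_id,
            "probe_id": o.probe_id,
            "chromosome_label": o.chromosome_label,
            "order_index": o.order_index,
            "colour": "+".join(sorted(o.colour)),
            "stage": o.stage,
            "length_scale": o.length_scale,
            "centromere_side": o.centromere_side if o.centromere_side else ".",
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


def observations_from_frame(df: pd.DataFrame) -> list[HybObservation]:
    out = []
    for _, r in df.iterrows():
        side = r.get("centromere_side")
        out.append(
            HybObservation(
                spread_id=int(r["spread_id"]),
                probe_id=str(r["probe_id"]),
                chromosome_label=str(r["chromosome_label"]),
                order_index=int(r["order_index"]),
                colour=frozenset(str(r["colour"]).split("+")),
                stage=str(r.get("stage", "late_metaphase")),
                length_scale=float(r.get("length_scale", 1.0)),
                centromere_side=None if side in (".", None) or pd.isna(side) else str(side),
            )
        )
    return out


def generate_toy_genome(
    n_chromosomes: int,
    length_range: tuple[int, int] = (100_000, 300_000),
    repeat_fraction: float = 0.0,
    morphology_plan: list[str] | None = None,
    seed: int = 0,
    repeat_unit_length: int = 200,
    repeat_copies: int = 5,
) -> ToyGenome:
    """Generate a random multi-chromosome genome with planted repeats.

    Repeat tracts are exact internal duplications: a source tract is copied
    verbatim to ``repeat_copies - 1`` other non-overlapping loci and every
    copy (source included) is recorded in the truth table, until the recorded
    fraction of bases reaches ``repeat_fraction``.
    """
    if n_chromosomes < 1:
        raise InvalidParameterError("n_chromosomes must be >= 1")
    if not (0 <= repeat_fraction < 1):
        raise InvalidParameterError("repeat_fraction must be in [0, 1)")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise InvalidParameterError("invalid length_range")
    if lo < 10_000:
        raise InvalidParameterError("chromosome lengths must be >= 10 kb")
    if morphology_plan is None:
        morphology_plan = ["acrocentric"] * n_chromosomes
    if len(morphology_plan) != n_chromosomes:
        raise InvalidParameterError("morphology_plan length != n_chromosomes")
    for m in morphology_plan:
        if m not in MORPHOLOGIES:
            raise InvalidParameterError(f"unknown morphology {m!r}")

    rng = np.random.default_rng(seed)
    arrays: list[np.ndarray] = []
    for i in range(n_chromosomes):
        length = int(rng.integers(lo, hi + 1))
        arrays.append(rng.choice(BASES, size=length))

    chrom_ids = [f"chr{i + 1}" for i in range(n_chromosomes)]
    tracts: list[RepeatTract] = []
    if repeat_fraction > 0:
        tracts = _plant_repeats(
            arrays, chrom_ids, repeat_fraction, repeat_unit_length, repeat_copies, rng
        )
    chroms = []
    for cid, morph, arr in zip(chrom_ids, morphology_plan, arrays):
        cen = int(_CENTROMERE_FRAC[morph] * arr.size)
        chroms.append(Chromosome(cid, "".join(arr), morph, cen))
    return ToyGenome(chroms, repeat_fraction, seed, tracts)


def _plant_repeats(arrays, chrom_ids, target_fraction, unit_len, copies, rng):
    total = sum(a.size for a in arrays)
    target_bases = target_fraction * total
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(arrays))}
    tracts: list[RepeatTract] = []
    planted = 0
    family = 0
    guard = 0
    while planted < target_bases:
        guard += 1
        if guard > 100_000:
            raise InvalidParameterError("cannot reach repeat_fraction; genome too small")
        unit = rng.choice(BASES, size=unit_len)
        placed = 0
        for _ in range(copies):
            ci = int(rng.integers(0, len(arrays)))
            arr = arrays[ci]
            if arr.size <= unit_len:
                continue
            pos = int(rng.integers(0, arr.size - unit_len))
            if any(pos < e and pos + unit_len > s for s, e in occupied[ci]):
                continue
            arr[pos : pos + unit_len] = unit
            occupied[ci].append((pos, pos + unit_len))
            tracts.append(RepeatTract(chrom_ids[ci], pos, pos + unit_len, family))
            placed += 1
        planted += placed * unit_len
        family += 1
    return tracts


def fragment_into_scaffolds(
    genome: ToyGenome,
    n_scaffolds: int,
    chimera_spec: list[tuple[str, str]] | None = None,
    inversion_spec: list[tuple[object, int, int]] | None = None,
    seed: int = 0,
    min_piece_length: int = 20_000,
) -> ScaffoldSet:
    """Cut the genome into scaffolds, planting chimeras and inversions.

    ``chimera_spec`` is a list of (chromA, chromB) ids; each entry yields one
    scaffold joining a slice of each, its junction offset recorded.
    ``inversion_spec`` entries are (scaffold, start, end): the scaffold-local
    interval [start, end) is reverse-complemented in the emitted sequence and
    the truth parts are split accordingly. ``scaffold`` may be the final
    scaffold name or an integer k meaning the k-th longest ("scaffold_k",
    1-based; scaffolds are named in decreasing length order).
    """
    chimera_spec = list(chimera_spec or [])
    inversion_spec = list(inversion_spec or [])
    known = {c.id for c in genome.chromosomes}
    for a, b in chimera_spec:
        for cid in (a, b):
            if cid not in known:
                raise LookupError_(cid)

    n_parts = n_scaffolds + len(chimera_spec)
    if n_parts < len(genome.chromosomes):
        raise InvalidParameterError(
            "n_scaffolds too small: every chromosome must contribute at least one piece"
        )
    rng = np.random.default_rng(seed)

    # how many pieces each chromosome is cut into: start at 1, add cuts to
    # the chromosomes with the largest bases-per-piece ratio
    pieces_per = {c.id: 1 for c in genome.chromosomes}
    while sum(pieces_per.values()) < n_parts:
        ratios = {c.id: len(c) / pieces_per[c.id] for c in genome.chromosomes}
        cid = max(ratios, key=lambda k: (ratios[k], k))
        if ratios[cid] < 2 * min_piece_length:
            raise InvalidParameterError(
                "not enough chromosome material for the requested scaffold count"
            )
        pieces_per[cid] += 1

    pieces: dict[str, list[tuple[str, int, int]]] = {}
    for c in genome.chromosomes:
        k = pieces_per[c.id]
        cuts = _random_cuts(len(c), k, min_piece_length, rng)
        pieces[c.id] = [
            (c.id, cuts[i], cuts[i + 1]) for i in range(k)
        ]

    seq_of = genome.sequences()
    raw: list[tuple[list[ScaffoldPartTruth], str]] = []
    # chimeric scaffolds first: take the distal-most remaining piece of each partner
    for a, b in chimera_spec:
        if not pieces[a] or not pieces[b]:
            raise InvalidParameterError(f"chromosome {a} or {b} has no piece left for a chimera")
        pa = pieces[a].pop()
        pb = pieces[b].pop()
        parts = [ScaffoldPartTruth(pa[0], pa[1], pa[2]), ScaffoldPartTruth(pb[0], pb[1], pb[2])]
        seq = seq_of[pa[0]][pa[1] : pa[2]] + seq_of[pb[0]][pb[1] : pb[2]]
        raw.append((parts, seq))
    for cid in sorted(pieces):
        for p in pieces[cid]:
            raw.append(([ScaffoldPartTruth(p[0], p[1], p[2])], seq_of[p[0]][p[1] : p[2]]))

    # name by decreasing length (rank 1 = longest), ties by construction order
    order = sorted(range(len(raw)), key=lambda i: (-len(raw[i][1]), i))
    truths: list[ScaffoldTruth] = []
    sequences: dict[str, str] = {}
    for rank, idx in enumerate(order, start=1):
        parts, seq = raw[idx]
        name = f"scaffold_{rank}"
        junctions = []
        off = 0
        for p in parts[:-1]:
            off += len(p)
            junctions.append(off)
        truths.append(ScaffoldTruth(name, parts, junctions))
        sequences[name] = seq
    truths.sort(key=lambda t: int(t.scaffold_id.split("_")[1]))

    for spec in inversion_spec:
        sid, a, b = spec
        name = f"scaffold_{sid}" if isinstance(sid, int) else str(sid)
        if name not in sequences:
            raise LookupError_(name)
        truth = next(t for t in truths if t.scaffold_id == name)
        _apply_inversion(truth, sequences, a, b)
    return ScaffoldSet(sequences, truths)


def _random_cuts(length: int, k: int, min_piece: int, rng) -> list[int]:
    """k+1 cut positions 0=c0<...<ck=length with pieces >= min_piece."""
    if k == 1:
        return [0, length]
    if k * min_piece > length:
        raise InvalidParameterError("chromosome too short for requested pieces")
    slack = length - k * min_piece
    interior = np.sort(rng.integers(0, slack + 1, size=k - 1))
    cuts = [0]
    for i, s in enumerate(interior, start=1):
        cuts.append(int(s) + i * min_piece)
    cuts.append(length)
    return cuts


def _apply_inversion(truth: ScaffoldTruth, sequences: dict[str, str], a: int, b: int) -> None:
    seq = sequences[truth.scaffold_id]
    if not (0 <= a < b <= len(seq)):
        raise InvalidParameterError(f"inversion [{a},{b}) outside scaffold {truth.scaffold_id}")
    # locate the single truth part containing [a, b)
    off = 0
    new_parts: list[ScaffoldPartTruth] = []
    done = False
    for p in truth.parts:
        if not done and off <= a and b <= off + len(p):
            if p.strand != "+":
                raise InvalidParameterError("nested inversions are not supported")
            ga, gb = p.start + (a - off), p.start + (b - off)
            for piece in (
                ScaffoldPartTruth(p.chromosome_id, p.start, ga, "+"),
                ScaffoldPartTruth(p.chromosome_id, ga, gb, "-"),
                ScaffoldPartTruth(p.chromosome_id, gb, p.end, "+"),
            ):
                if len(piece) > 0:
                    new_parts.append(piece)
            done = True
        else:
            new_parts.append(p)
        off += len(p)
    if not done:
        raise InvalidParameterError(
            f"inversion [{a},{b}) must lie within a single part of {truth.scaffold_id}"
        )
    truth.parts = new_parts
    truth.inverted_intervals.append((a, b))
    sequences[truth.scaffold_id] = seq[:a] + revcomp(seq[a:b]) + seq[b:]


def reconstruct_scaffold(truth: ScaffoldTruth, genome: ToyGenome) -> str:
    """Rebuild a scaffold's sequence from its truth parts (round-trip check)."""
    out = []
    seqs = genome.sequences()
    for p in truth.parts:
        s = seqs[p.chromosome_id][p.start : p.end]
        out.append(s if p.strand == "+" else revcomp(s))
    return "".join(out)


def generate_ortho_pool(n: int, length: int = 25, seed: int = 0,
                        gc_range: tuple[float, float] = (0.2, 0.8)) -> list[str]:
    """``n`` distinct uppercase ``length``-mers with GC inside ``gc_range``."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if n > 4 ** length:
        raise CapacityError(f"cannot draw {n} distinct {length}-mers")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    pool: list[str] = []
    lo, hi = gc_range
    guard = 0
    while len(pool) < n:
        guard += 1
        if guard > 200 * n + 10_000:
            raise CapacityError("GC constraint leaves too few distinct sequences")
        s = "".join(rng.choice(BASES, size=length))
        gc = (s.count("G") + s.count("C")) / length
        if lo <= gc <= hi and s not in seen:
            seen.add(s)
            pool.append(s)
    return pool


def simulate_hybridization(
    plan,
    truths: list[ScaffoldTruth],
    genome: ToyGenome,
    n_spreads: int = 3,
    dropout_rate: float = 0.0,
    length_noise_sd: float = 0.0,
    seed: int = 0,
    stage: str = "late_metaphase",
) -> list[HybObservation]:
    """Simulate per-spread probe sightings from a probe plan and truth tables.

    With ``dropout_rate`` 0 every probe is seen once per spread on the
    chromosome its truth part belongs to, ranked along the chromatid by
    genomic distance from the centromere. The per-spread ``length_scale``
    is log-normal with log-sd ``length_noise_sd``.
    """
    if not (0 <= dropout_rate < 1):
        raise InvalidParameterError("dropout_rate must be in [0, 1)")
    truth_of = {t.scaffold_id: t for t in truths}
    windows = list(plan.windows) if hasattr(plan, "windows") else list(plan)
    # map each probe midpoint to the genome once
    placed = []
    for w in windows:
        t = truth_of.get(w.scaffold_id)
        if t is None:
            raise LookupError_(w.scaffold_id)
        if not (0 <= w.start < w.end <= t.length):
            raise ConsistencyError(
                f"probe {w.probe_id} [{w.start},{w.end}) outside scaffold {w.scaffold_id}"
            )
        mid = (w.start + w.end) // 2
        chrom, gpos = t.map_to_genome(mid)
        placed.append((w, chrom, gpos))

    rng = np.random.default_rng(seed)
    observations: list[HybObservation] = []
    for spread in range(n_spreads):
        scale = float(math.exp(rng.normal(0.0, length_noise_sd))) if length_noise_sd > 0 else 1.0
        seen = [(w, chrom, gpos) for (w, chrom, gpos) in placed
                if dropout_rate == 0 or rng.random() >= dropout_rate]
        # rank signals per (chromosome, arm) by distance from the centromere
        by_arm: dict[tuple[str, str], list[tuple[int, object]]] = {}
        for w, chrom, gpos in seen:
            cen = genome.chromosome(chrom).centromere_position
            side = "p" if gpos < cen else "q"
            by_arm.setdefault((chrom, side), []).append((abs(gpos - cen), w))
        for (chrom, side), items in by_arm.items():
            items.sort(key=lambda x: x[0])
            for rank, (_, w) in enumerate(items):
                colour = getattr(w, "fluorophores", None) or frozenset({"FAM"})
                observations.append(
                    HybObservation(
                        spread_id=spread,
                        probe_id=w.probe_id,
                        chromosome_label=chrom,
                        order_index=rank,
                        colour=frozenset(colour),
                        stage=stage,
                        length_scale=scale,
                        centromere_side=side if stage == "late_metaphase" else None,
                    )
                )
    return observations


def simulate_reference_alignments(
    truths: list[ScaffoldTruth],
    genome: ToyGenome,
    tile: int = 5_000,
    margin: int = 0,
) -> pd.DataFrame:
    """Synthetic whole-genome alignments of scaffolds to a reference genome
    (here the true toy genome plays the reference), as PAF-like rows.

    Each truth part is tiled into ``tile``-sized alignment records mapping
    scaffold coordinates to reference chromosome coordinates; ``margin``
    trims each part's ends, leaving unaligned sequence around junctions the
    way diverged real references do.
    """
    rows = []
    for t in truths:
        off = 0
        qlen = t.length
        for p in t.parts:
            a, b = off + margin, off + len(p) - margin
            pos = a
            while pos < b:
                end = min(pos + tile, b)
                local = pos - off
                if p.strand == "+":
                    ts, te = p.start + local, p.start + local + (end - pos)
                else:
                    te = p.end - local
                    ts = te - (end - pos)
                rows.append(
                    {
                        "query": t.scaffold_id, "qlen": qlen, "qstart": pos,
                        "qend": end, "strand": p.strand,
                        "target": p.chromosome_id,
                        "tlen": len(genome.chromosome(p.chromosome_id)),
                        "tstart": ts, "tend": te,
                        "matches": end - pos, "alnlen": end - pos, "mapq": 60,
                    }
                )
                pos = end
            off += len(p)
    return pd.DataFrame(rows)


def simulate_spread_measurements(
    genome: ToyGenome,
    n_spreads: int = 5,
    length_noise_sd: float = 0.1,
    measurement_noise_sd: float = 0.0,
    seed: int = 0,
    um_per_mb: float = 3.0,
) -> pd.DataFrame:
    """Per-spread chromosome length measurements (micrometres).

    Each spread carries one multiplicative log-normal compaction factor
    applied to every chromosome, plus optional per-measurement noise.
    Columns: spread_id, chromosome, length_um.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spread in range(n_spreads):
        scale = float(math.exp(rng.normal(0.0, length_noise_sd))) if length_noise_sd > 0 else 1.0
        for c in genome.chromosomes:
            noise = (
                float(math.exp(rng.normal(0.0, measurement_noise_sd)))
                if measurement_noise_sd > 0
                else 1.0
            )
            rows.append(
                {
                    "spread_id": spread,
                    "chromosome": c.id,
                    "length_um": len(c) / 1e6 * um_per_mb * scale * noise,
                }
            )
    return pd.DataFrame(rows)
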