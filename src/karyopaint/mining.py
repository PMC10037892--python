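"""Candidate oligo mining.

Scans scaffolds for 39-mer genome-homolog windows suitable for
hybridization probes, filtering on melting temperature, GC content,
genome-wide k-mer abundance (a uniqueness proxy) and hairpin secondary
structure at the hybridization temperature. Masked bases (N or softmasked
lowercase) are never included in a candidate.

Tiling is greedy left-to-right: the next window starts at the first
position at least ``min_spacing`` bases past the previous accepted
window's end, so accepted candidates never overlap. All filters are
annotate-then-subset, which makes their composition order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidParameterError
from .seqs import gc_fraction, revcomp
from .thermo import hairpin_dg, melting_temperature

OLIGO_LENGTH = 39


@dataclass
class MiningParams:
    """Mining-filter configuration (defaults follow a balanced mining mode:
    a narrow Tm window at the probe formamide condition, wide GC bounds,
    18-mer uniqueness counting and a zero hairpin threshold at 42 degC)."""

    oligo_length: int = OLIGO_LENGTH
    tm_window: tuple[float, float] = (42.0, 47.0)
    gc_window: tuple[float, float] = (0.20, 0.80)
    k: int = 18
    max_kmer_count_allowed: int = 5
    hybridization_temp: float = 42.0
    formamide_fraction: float = 0.5
    salt_molarity: float = 0.39
    hairpin_dg_threshold: float = 0.0
    min_spacing: int = 0

    def __post_init__(self) -> None:
        if self.tm_window[0] >= self.tm_window[1]:
            raise InvalidParameterError("tm_window min must be < max")
        if self.k > self.oligo_length:
            raise InvalidParameterError("k must be <= oligo_length")


@dataclass
class OligoCandidate:
    scaffold_id: str
    start: int
    end: int
    sequence: str
    tm: float
    gc: float
    max_kmer_count: int | None = None
    hairpin_dg: float | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise InvalidParameterError("candidate coordinates do not match sequence")


def mine_candidates(
    scaffold_id: str, scaffold: str, params: MiningParams | None = None
) -> list[OligoCandidate]:
    """Greedy left-to-right scan for unmasked windows passing Tm/GC filters.

    Returns candidates sorted by start; every candidate has length
    ``params.oligo_length`` (39 by default). An empty list is a valid
    result (e.g. a fully masked scaffold).
    """
    params = params or MiningParams()
    L = params.oligo_length
    n = len(scaffold)
    out: list[OligoCandidate] = []
    pos = 0
    while pos + L <= n:
        window = scaffold[pos : pos + L]
        if any(c == "N" or c == "n" or c.islower() for c in window):
            # jump past the last masked base in the window
            last_masked = max(
                i for i, c in enumerate(window) if c == "N" or c == "n" or c.islower()
            )
            pos += last_masked + 1
            continue
        gc = gc_fraction(window)
        tm = melting_temperature(
            window,
            salt_molarity=params.salt_molarity,
            formamide_fraction=params.formamide_fraction,
        )
        if params.gc_window[0] <= gc <= params.gc_window[1] and (
            params.tm_window[0] <= tm <= params.tm_window[1]
        ):
            out.append(OligoCandidate(scaffold_id, pos, pos + L, window, tm, gc))
            pos += L + params.min_spacing
        else:
            pos += 1
    return out


def count_genome_kmers(genome: dict[str, str], k: int) -> dict[str, int]:
    """Genome-wide k-mer counts over both strands, keyed by canonical k-mer
    (lexicographic min of the k-mer and its reverse complement). N bases
    break k-mers; softmasked bases still count (repeat abundance is exactly
    what this filter measures)."""
    counts: dict[str, int] = {}
    for seq in genome.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            canon = min(kmer, revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def max_kmer_count(sequence: str, counts: dict[str, int], k: int) -> int:
    """Highest genome-wide occurrence count among the sequence's k-mers.

    Counts are per canonical k-mer over both strands, so a value of c means
    the k-mer occurs c times in the genome (forward or reverse)."""
    best = 0
    s = sequence.upper()
    for i in range(len(s) - k + 1):
        canon = min(s[i : i + k], revcomp(s[i : i + k]))
        best = max(best, counts.get(canon, 0))
    return best


def kmer_filter(
    candidates: list[OligoCandidate],
    genome: dict[str, str],
    k: int = 18,
    max_kmer_count_allowed: int = 5,
) -> list[OligoCandidate]:
    """Drop candidates containing any k-mer occurring more than
    ``max_kmer_count_allowed`` times genome-wide (both strands); the count is
    annotated on every candidate, retained or not."""
    counts = count_genome_kmers(genome, k)
    kept = []
    for c in candidates:
        c.max_kmer_count = max_kmer_count(c.sequence, counts, k)
        c.flags["kmer_pass"] = c.max_kmer_count <= max_kmer_count_allowed
        if c.flags["kmer_pass"]:
            kept.append(c)
    return kept


def structure_check(
    candidate: OligoCandidate, temperature: float = 42.0, dg_threshold: float = 0.0
) -> bool:
    """Hairpin screen at the hybridization temperature.

    Fails iff the minimum predicted hairpin free energy is below
    ``dg_threshold`` (default 0: any favourable hairpin fails). The free
    energy is annotated on the candidate either way."""
    dg = hairpin_dg(candidate.sequence, temp_c=temperature)
    candidate.hairpin_dg = dg
    ok = dg >= dg_threshold
    candidate.flags["structure_pass"] = ok
    return ok


def structure_filter(
    candidates: list[OligoCandidate], temperature: float = 42.0, dg_threshold: float = 0.0
) -> list[OligoCandidate]:
    return [c for c in candidates if structure_check(c, temperature, dg_threshold)]


def mine_scaffolds(
    scaffolds: dict[str, str],
    params: MiningParams | None = None,
    genome: dict[str, str] | None = None,
) -> dict[str, list[OligoCandidate]]:
    """Full mining pass per scaffold: tile + Tm/GC, then k-mer abundance
    against ``genome`` (the scaffold set itself when omitted), then the
    hairpin screen."""
    params = params or MiningParams()
    genome = genome if genome is not None else scaffolds
    counts = count_genome_kmers(genome, params.k)
    result: dict[str, list[OligoCandidate]] = {}
    for sid, seq in scaffolds.items():
        cands = mine_candidates(sid, seq, params)
        kept = []
        for c in cands:
            c.max_kmer_count = max_kmer_count(c.sequence, counts, params.k)
            c.flags["kmer_pass"] = c.max_kmer_count <= params.max_kmer_count_allowed
            if not c.flags["kmer_pass"]:
                continue
            if structure_check(c, params.hybridization_temp, params.hairpin_dg_threshold):
                kept.append(c)
        result[sid] = kept
    return result
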