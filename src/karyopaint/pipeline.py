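"""End-to-end convenience wrappers tying the stages together.

These are what the command-line interface and most scripted analyses call:
one function to design a complete probe plan from a scaffold set, one to
prepare the orthogonal barcode library, and one re-export of the curation
chain. Geometry defaults (inter-probe gap, terminus distance) are stated at
mammalian genome scale and scaled down automatically for small genomes so
the same code runs on toy data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import (
    AllocationScheme,
    ColourScheme,
    OrthoSeq,
    ProbePlan,
    allocate_probe_counts,
    apply_colours,
    assemble_oligos,
    assign_colour_schemes,
    assign_roles,
    dimer_filter,
    screen_ortho_homology,
    select_probe_windows,
    slice_orthologs,
)
from .mining import MiningParams, mine_scaffolds

# geometry defaults at mammalian scale
DEFAULT_MIN_GAP = 7_000_000
DEFAULT_MIN_TERMINUS = 250_000


def scaled_geometry(scaffold_length: int, n_probes: int,
                    min_gap: int | None = None,
                    min_terminus: int | None = None) -> tuple[int, int]:
    """Per-scaffold geometry constraints, scaled down for short scaffolds.

    The mammalian-scale defaults (7 Mb inter-probe gap, 250 kb terminus
    clearance) are capped at length/(3*n_probes) and length/20 so small toy
    scaffolds keep proportionate spacing instead of becoming infeasible."""
    gap = min(min_gap if min_gap is not None else DEFAULT_MIN_GAP,
              max(1, scaffold_length // (3 * max(n_probes, 1))))
    term = min(min_terminus if min_terminus is not None else DEFAULT_MIN_TERMINUS,
               max(0, scaffold_length // 20))
    return gap, term


@dataclass
class DesignResult:
    plan: ProbePlan
    allocation: AllocationScheme
    colours: ColourScheme
    candidates: dict


def design_probe_plan(
    scaffolds: dict[str, str],
    genome: dict[str, str] | None = None,
    suspected_misassembly: set[str] | None = None,
    n_libraries: int = 3,
    capacity: int = 92_000,
    n_oligo: int = 1500,
    params: MiningParams | None = None,
    min_gap: int | None = None,
    min_terminus_distance: int | None = None,
    tier_sizes: tuple[int, int, int] | None = None,
    max_count: int = 5,
) -> DesignResult:
    """Mine candidates, allocate probe counts, place windows, assign colours."""
    lengths = {k: len(v) for k, v in scaffolds.items()}
    allocation = allocate_probe_counts(
        lengths, suspected_misassembly, n_libraries, capacity, n_oligo,
        max_count=max_count, tier_sizes=tier_sizes,
    )
    candidates = mine_scaffolds(scaffolds, params, genome)
    windows = []
    for sid, n_probes in allocation.counts.items():
        gap, term = scaled_geometry(lengths[sid], n_probes, min_gap, min_terminus_distance)
        windows.extend(
            select_probe_windows(
                candidates[sid], n_probes, lengths[sid],
                n_oligo=n_oligo, min_gap=gap, min_terminus_distance=term,
            )
        )
    plan = ProbePlan(windows, lengths, n_oligo)
    colours = assign_colour_schemes(allocation)
    apply_colours(plan, colours)
    return DesignResult(plan, allocation, colours, candidates)


def prepare_barcodes(
    pool_25mers: list[str],
    genome: dict[str, str],
    evalue_cutoff: float = 25.0,
    dg_min: float = -9.0,
    deduplicate: bool = True,
) -> list[OrthoSeq]:
    """Slice 25-mers into 20-mers and apply the genome-homology and dimer
    screens, returning role-ready orthogonal sequences."""
    sliced = slice_orthologs(pool_25mers)
    if deduplicate:
        sliced = list(dict.fromkeys(sliced))
    screened = screen_ortho_homology(sliced, genome, evalue_cutoff=evalue_cutoff)
    return dimer_filter(screened, dg_min=dg_min)


def finish_design(
    result: DesignResult,
    barcodes: list[OrthoSeq],
    seed: int = 0,
):
    """Assign barcode roles and assemble the final 79-mers and primers."""
    roles = assign_roles(barcodes, result.allocation.libraries, seed=seed)
    oligos, primers = assemble_oligos(result.plan, result.allocation, roles)
    return roles, oligos, primers
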