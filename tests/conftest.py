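"""Shared fixtures: a small end-to-end toy universe plus hand-built
curation fixtures."""

from __future__ import annotations

import pytest

import karyopaint as kp
from karyopaint import pipeline
from karyopaint import synthetic as ksyn
from karyopaint.design import ProbePlan, ProbeWindow, probe_label
from karyopaint.synthetic import HybObservation


@pytest.fixture(scope="session")
def toy_genome():
    return kp.generate_toy_genome(4, (60_000, 120_000), 0.0, seed=7)


@pytest.fixture(scope="session")
def scaffold_set(toy_genome):
    return kp.fragment_into_scaffolds(toy_genome, 6, [("chr1", "chr3")], seed=7)


@pytest.fixture(scope="session")
def design_result(toy_genome, scaffold_set):
    return pipeline.design_probe_plan(
        scaffold_set.sequences, toy_genome.sequences(), capacity=200, n_oligo=8
    )


@pytest.fixture(scope="session")
def observations(design_result, scaffold_set, toy_genome):
    return ksyn.simulate_hybridization(
        design_result.plan, scaffold_set.truths, toy_genome, n_spreads=3, seed=5
    )


@pytest.fixture(scope="session")
def alignments(scaffold_set, toy_genome):
    return ksyn.simulate_reference_alignments(scaffold_set.truths, toy_genome, tile=5000)


def make_geometric_plan(lengths: dict[str, int], n_probes: int = 6,
                        width: int = 40) -> ProbePlan:
    """Probe windows at even fractions of each scaffold (no mined oligos);
    enough for hybridization/curation tests where sequence content is
    irrelevant."""
    windows = []
    for sid, L in lengths.items():
        for k in range(n_probes):
            centre = int(L * (2 * k + 1) / (2 * n_probes))
            windows.append(
                ProbeWindow(probe_label(sid, k), sid, centre - width // 2,
                            centre - width // 2 + width, [], design_index=k)
            )
    return ProbePlan(windows, lengths, 0)


def run_recovery(seed: int):
    """One zero-noise parameter-recovery round: 10 scaffolds, 2 planted
    chimeras, 1 planted inversion. Returns (scaffold_set, target, result)."""
    genome = kp.generate_toy_genome(5, (80_000, 115_000), 0.0, seed=seed)
    chim = [("chr1", "chr3"), ("chr2", "chr5")]
    first = kp.fragment_into_scaffolds(genome, 10, chim, seed=seed)
    target = next(
        t.scaffold_id for t in first.truths if not t.is_chimeric and len(t.parts) == 1
    )
    L_t = next(t.length for t in first.truths if t.scaffold_id == target)
    inv = (target, int(0.25 * L_t), int(0.80 * L_t))
    sset = kp.fragment_into_scaffolds(genome, 10, chim, inversion_spec=[inv], seed=seed)
    lengths = {k: len(v) for k, v in sset.sequences.items()}
    plan = make_geometric_plan(lengths)
    obs = ksyn.simulate_hybridization(plan, sset.truths, genome, n_spreads=3, seed=seed)
    result = kp.curate(obs, plan, lengths)
    return sset, target, result


def _obs(spread, probe, chrom, rank, side="q"):
    return HybObservation(
        spread_id=spread, probe_id=probe, chromosome_label=chrom,
        order_index=rank, colour=frozenset({"FAM"}), centromere_side=side,
    )


def make_published_fixture():
    """Hand-built observations encoding corroborated chromosome compositions:

    * chromosome 34 = 20p0-1 rev + 56 rev + 13 rev
    * chromosome 6 = scaffolds 18, 14, 68
    * splits 1->(7,20), 2->(16,18), 12->(1,4), 20->(2,34), 25->(3,8)

    Returns (plan, observations, lengths).
    """
    lengths = {
        "scaffold_20": 40_000, "scaffold_56": 40_000, "scaffold_13": 40_000,
        "scaffold_18": 40_000, "scaffold_14": 40_000, "scaffold_68": 40_000,
        "scaffold_1": 40_000, "scaffold_2": 40_000, "scaffold_12": 40_000,
        "scaffold_25": 40_000,
    }
    n_probes = {
        "scaffold_20": 4, "scaffold_56": 2, "scaffold_13": 2,
        "scaffold_18": 2, "scaffold_14": 2, "scaffold_68": 2,
        "scaffold_1": 4, "scaffold_2": 4, "scaffold_12": 4, "scaffold_25": 4,
    }
    windows = []
    for sid, n in n_probes.items():
        for k in range(n):
            start = 4_000 + 9_000 * k
            windows.append(
                ProbeWindow(probe_label(sid, k), sid, start, start + 1_000, [],
                            design_index=k)
            )
    plan = ProbePlan(windows, lengths, 0)

    # (probe, chromosome, rank): decreasing rank along design order => 'rev'
    placements = [
        # chromosome 34: 20p0-1 rev, then 56 rev, then 13 rev, outward from
        # the centromere
        ("20p0", "34", 1), ("20p1", "34", 0),
        ("56p0", "34", 3), ("56p1", "34", 2),
        ("13p0", "34", 5), ("13p1", "34", 4),
        # scaffold_20's other half sits on chromosome 2 (split 20 -> (2, 34))
        ("20p2", "2", 0), ("20p3", "2", 1),
        # chromosome 6 = scaffolds 18, 14, 68
        ("18p0", "6", 0), ("18p1", "6", 1),
        ("14p0", "6", 2), ("14p1", "6", 3),
        ("68p0", "6", 4), ("68p1", "6", 5),
        # remaining published splits
        ("1p0", "7", 0), ("1p1", "7", 1), ("1p2", "20", 0), ("1p3", "20", 1),
        ("2p0", "16", 0), ("2p1", "16", 1), ("2p2", "18", 0), ("2p3", "18", 1),
        ("12p0", "1", 0), ("12p1", "1", 1), ("12p2", "4", 0), ("12p3", "4", 1),
        ("25p0", "3", 0), ("25p1", "3", 1), ("25p2", "8", 0), ("25p3", "8", 1),
    ]
    observations = [
        _obs(spread, probe, chrom, rank)
        for spread in range(2)
        for probe, chrom, rank in placements
    ]
    return plan, observations, lengths
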