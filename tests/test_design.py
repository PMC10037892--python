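import collections

import numpy as np
import pytest

from karyopaint.design import (
    FLUOROPHORES,
    OrthoSeq,
    ProbePlan,
    ProbeWindow,
    T7_PROMOTER,
    _max_fill_tiers,
    allocate_probe_counts,
    apply_colours,
    assemble_oligos,
    assign_colour_schemes,
    assign_roles,
    best_ungapped_score,
    dimer_filter,
    karlin_altschul_params,
    oligo_density,
    probe_label,
    probe_plan_stats,
    screen_ortho_homology,
    select_probe_windows,
    slice_orthologs,
    split_oligo,
)
from karyopaint.errors import (
    CapacityError,
    InfeasibleDesignError,
    InvalidParameterError,
    InvalidSequenceError,
)
from karyopaint.mining import OligoCandidate
from karyopaint.seqs import revcomp
from karyopaint.thermo import duplex_dg
from oracles import place_windows_oracle, sw_ungapped_score, tiers_oracle


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _lengths(n, top=100_000, step=1_000):
    return {f"scaffold_{i + 1}": top - i * step for i in range(n)}


# ---------------------------------------------------------------------------
# allocation


def test_allocation_published_configuration():
    lengths = _lengths(68, top=200_000)
    alloc = allocate_probe_counts(
        lengths, suspected_misassembly={"scaffold_2", "scaffold_12"},
        n_libraries=3, capacity=92_000, n_oligo=1_500, tier_sizes=(29, 34, 2),
    )
    hist = collections.Counter(alloc.counts.values())
    assert hist == {5: 1, 4: 2, 3: 29, 2: 34, 1: 2}
    assert alloc.total_probes == 170
    assert alloc.total_oligos == 255_000
    assert alloc.counts["scaffold_1"] == 5  # longest
    assert alloc.counts["scaffold_2"] == 4  # suspected
    assert alloc.counts["scaffold_12"] == 4


def test_allocation_minimal_budget_single_scaffold():
    alloc = allocate_probe_counts({"s": 10_000}, n_libraries=1,
                                  capacity=1_500, n_oligo=1_500)
    assert alloc.counts == {"s": 1}


def test_allocation_tiers_match_exhaustive_oracle():
    for m in range(0, 11):
        for budget in range(m, 3 * m + 4):
            assert _max_fill_tiers(m, budget) == tiers_oracle(m, budget)


def test_allocation_infeasible_budget():
    with pytest.raises(InfeasibleDesignError):
        allocate_probe_counts(_lengths(10), n_libraries=1,
                              capacity=4_500, n_oligo=1_500)  # 3 probes, 10 scaffolds


def test_allocation_library_partition_respects_capacity():
    alloc = allocate_probe_counts(_lengths(68),
                                  suspected_misassembly={"scaffold_2", "scaffold_12"},
                                  n_libraries=3, capacity=92_000, n_oligo=1_500,
                                  tier_sizes=(29, 34, 2))
    seen = [s for lib in alloc.libraries for s in lib]
    assert sorted(seen) == sorted(alloc.counts)
    for lib in alloc.libraries:
        assert sum(alloc.counts[s] for s in lib) * 1_500 <= 92_000


def test_allocation_tier_sizes_validated():
    with pytest.raises(InvalidParameterError):
        allocate_probe_counts(_lengths(10), tier_sizes=(1, 1, 1))


# ---------------------------------------------------------------------------
# window selection


def _mk_candidates(starts, width=39, sid="s"):
    return [OligoCandidate(sid, s, s + width, "A" * width, tm=44.0, gc=0.5)
            for s in starts]


def _geom(cands, n_oligo):
    out = []
    for j in range(len(cands) - n_oligo + 1):
        start = cands[j].start
        end = cands[j + n_oligo - 1].end
        gaps = [cands[j + i + 1].start - cands[j + i].end for i in range(n_oligo - 1)]
        hom = float(np.var(gaps)) if n_oligo > 1 else 0.0
        out.append((start, end, hom))
    return out


def test_window_selection_matches_bruteforce_oracle():
    rng = np.random.default_rng(31)
    for trial in range(25):
        n_cand = int(rng.integers(8, 15))
        starts = np.sort(rng.choice(np.arange(100, 9_500, 60), size=n_cand,
                                    replace=False))
        cands = _mk_candidates([int(s) for s in starts])
        n_oligo = 2
        n_probes = int(rng.integers(2, 4))
        L = 10_000
        min_gap, min_term = 200, 100
        geom = _geom(cands, n_oligo)
        ideal = [L * (2 * k + 1) / (2 * n_probes) for k in range(n_probes)]
        expected = place_windows_oracle(geom, ideal, min_gap, min_term, L)
        if expected is None:
            expected = place_windows_oracle(geom, ideal, min_gap, 0, L)
        if expected is None:
            with pytest.raises(InfeasibleDesignError):
                select_probe_windows(cands, n_probes, L, n_oligo=n_oligo,
                                     min_gap=min_gap, min_terminus_distance=min_term)
            continue
        windows = select_probe_windows(cands, n_probes, L, n_oligo=n_oligo,
                                       min_gap=min_gap, min_terminus_distance=min_term)
        got = [geom.index((w.start, w.end, float(np.var(
            [w.oligos[i + 1].start - w.oligos[i].end for i in range(n_oligo - 1)]
        )))) for w in windows]
        assert got == expected, f"trial {trial}"


def test_window_selection_postconditions():
    cands = _mk_candidates(list(range(0, 4_000, 50)))
    windows = select_probe_windows(cands, 3, 4_039, n_oligo=4,
                                   min_gap=300, min_terminus_distance=200)
    assert len(windows) == 3
    assert [w.design_index for w in windows] == [0, 1, 2]
    assert [w.probe_id for w in windows] == ["sp0", "sp1", "sp2"]
    for w in windows:
        assert len(w.oligos) == 4
        assert w.start >= 200 and w.end <= 4_039 - 200
    for a, b in zip(windows, windows[1:]):
        assert b.start - a.end >= 300


def test_window_selection_relaxes_terminus_with_warning(caplog):
    # every window violates a huge terminus clearance; placement must relax
    cands = _mk_candidates(list(range(0, 2_000, 50)))
    with caplog.at_level("WARNING"):
        windows = select_probe_windows(cands, 1, 2_039, n_oligo=2,
                                       min_gap=100, min_terminus_distance=1_500)
    assert len(windows) == 1
    assert any("relaxing" in r.message for r in caplog.records)


def test_window_selection_infeasible():
    cands = _mk_candidates([0, 50])
    with pytest.raises(InfeasibleDesignError):
        select_probe_windows(cands, 3, 1_000, n_oligo=2, min_gap=10)


def test_probe_plan_stats_and_density():
    lengths = {"s": 4_039}
    cands = _mk_candidates(list(range(0, 4_000, 50)))
    windows = select_probe_windows(cands, 2, 4_039, n_oligo=4,
                                   min_gap=300, min_terminus_distance=0)
    stats = probe_plan_stats(ProbePlan(windows, lengths, 4))
    assert stats["span"]["mean"] > 0
    assert not stats["gap_stats_empty"]
    assert stats["oligo_density_per_kb"] == pytest.approx(
        4 / (stats["span"]["mean"] / 1000.0)
    )
    assert oligo_density(1_500, 401.5) == pytest.approx(3.74, abs=0.005)
    with pytest.raises(InvalidParameterError):
        oligo_density(1_500, 0.0)


def test_probe_label():
    assert probe_label("scaffold_12", 1) == "12p1"
    assert probe_label("s7", 0) == "s7p0"


# ---------------------------------------------------------------------------
# orthogonal barcodes


def test_slice_orthologs():
    rng = np.random.default_rng(32)
    pool = [_random_seq(rng, 25) for _ in range(10)]
    sliced = slice_orthologs(pool)
    assert len(sliced) == 60
    for i, s in enumerate(pool):
        for off in range(6):
            assert sliced[6 * i + off] == s[off : off + 20]
    with pytest.raises(InvalidSequenceError):
        slice_orthologs(["ACGT"])


def test_karlin_altschul_lambda_solves_identity():
    lam, k = karlin_altschul_params(1, -2)
    assert 0.25 * np.exp(lam) + 0.75 * np.exp(-2 * lam) == pytest.approx(1.0, abs=1e-9)
    assert k == pytest.approx(0.621)


def test_best_ungapped_score_vs_full_dp():
    rng = np.random.default_rng(33)
    genome = {"g": _random_seq(rng, 3_000)}
    # planted exact hit: seeded search must find the full score
    planted = genome["g"][1000:1020]
    assert best_ungapped_score(planted, genome) == sw_ungapped_score(planted, genome)
    assert best_ungapped_score(revcomp(planted), genome) == 20
    for _ in range(15):
        q = _random_seq(rng, 20)
        seeded = best_ungapped_score(q, genome)
        full = sw_ungapped_score(q, genome)
        assert seeded <= full
        # any 20-mer alignment scoring >= 12 contains a 6-base exact run,
        # so the word-6 seed cannot miss it
        if full >= 12:
            assert seeded == full


def test_screen_ortho_homology_removes_planted_sequence():
    rng = np.random.default_rng(34)
    genome = {"g": _random_seq(rng, 50_000)}
    planted = genome["g"][100:120]
    randoms = [_random_seq(rng, 20) for _ in range(10)]
    kept = screen_ortho_homology([planted] + randoms, genome, evalue_cutoff=1e-3)
    kept_seqs = {o.seq for o in kept}
    assert planted not in kept_seqs
    for o in kept:
        assert o.genome_evalue >= 1e-3


def test_screen_with_exhaustive_seeding_matches_dp_classification():
    # word_size=4 makes the seeded scan provably exhaustive for 20-mer
    # scores >= 8 (runs of <= 3 matches cannot reach score 8); thresholds
    # here sit well above that
    rng = np.random.default_rng(35)
    genome = {"g": _random_seq(rng, 8_000)}
    pool = [_random_seq(rng, 20) for _ in range(30)]
    pool.append(genome["g"][500:520])
    lam, K = karlin_altschul_params(1, -2)
    n_total = sum(len(s) for s in genome.values())
    cutoff = 1e-2
    expected = [
        q for q in pool
        if K * 20 * n_total * np.exp(-lam * sw_ungapped_score(q, genome)) >= cutoff
    ]
    got = screen_ortho_homology(pool, genome, evalue_cutoff=cutoff, word_size=4)
    assert [o.seq for o in got] == expected
    # default word size can only under-estimate scores => keeps a superset
    got6 = screen_ortho_homology(pool, genome, evalue_cutoff=cutoff, word_size=6)
    assert {o.seq for o in got6} >= set(expected)


def test_dimer_filter_matches_greedy_oracle():
    rng = np.random.default_rng(36)
    pool = [_random_seq(rng, 20) for _ in range(40)]
    dg_min = -9.0
    kept = dimer_filter(pool, dg_min=dg_min)
    # independent greedy reconstruction with the tested duplex model
    expected: list[str] = []
    for s in pool:
        if duplex_dg(s, s) < dg_min:
            continue
        if any(duplex_dg(s, k) < dg_min for k in expected):
            continue
        expected.append(s)
    assert [o.seq for o in kept] == expected
    for o in kept:
        assert o.min_self_dg >= dg_min
        assert o.min_hetero_dg is None or o.min_hetero_dg >= dg_min


def test_dimer_filter_rejects_self_complement():
    palindrome = "ACGTACGTACGTACGTACGT"  # self-complementary 20-mer
    assert revcomp(palindrome) == palindrome
    kept = dimer_filter([palindrome], dg_min=-9.0)
    assert kept == []


# ---------------------------------------------------------------------------
# roles, colours, assembly


def _pool(specs):
    """specs: list of (5'clamp, 3'clamp) booleans -> synthetic OrthoSeqs."""
    out = []
    rng = np.random.default_rng(37)
    for c5, c3 in specs:
        head = "GC" if c5 else "AT"
        tail = "CG" if c3 else "TA"
        mid = _random_seq(rng, 16)
        o = OrthoSeq(head + mid + tail)
        assert o.gc_clamp_5prime == c5 and o.gc_clamp_3prime == c3
        out.append(o)
    return out


def test_assign_roles_preferences_and_reuse():
    # 8 scaffolds over 2 libraries; plenty of clamped sequences
    libraries = [[f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]]
    pool = _pool([(True, False)] * 6 + [(False, True)] * 4 + [(False, False)] * 6)
    roles = assign_roles(pool, libraries, seed=0)
    for fl in FLUOROPHORES:
        assert roles.forward_of[fl].gc_clamp_3prime
        assert not roles.forward_of[fl].gc_clamp_5prime
        assert roles.detector_of(fl) == revcomp(roles.adapter_of[fl].seq)
    reverses = {o.seq for o in roles.reverse_of.values()}
    # reuse across libraries: 4 reverse sequences serve 8 scaffold slots
    assert len(reverses) == 4
    usage = collections.Counter(o.seq for o in roles.reverse_of.values())
    assert max(usage.values()) <= 4
    for li, lib in enumerate(libraries):
        seqs = [roles.reverse_of[(li, s)].seq for s in lib]
        assert len(set(seqs)) == len(seqs), "unique reverse per library"
    for o in roles.reverse_of.values():
        assert o.gc_clamp_5prime, "5'-clamped sequences preferred as reverses"


def test_assign_roles_pool_exhaustion():
    with pytest.raises(CapacityError):
        assign_roles(_pool([(False, False)] * 4), [["s1", "s2", "s3"]])


def test_colour_schemes_unique_within_pool():
    lengths = {f"s{i}": 50_000 - i for i in range(7)}
    alloc = allocate_probe_counts(lengths, n_libraries=1, capacity=92_000,
                                  n_oligo=1_500, max_count=2,
                                  tier_sizes=(0, 6, 0))
    assert all(c == 2 for c in alloc.counts.values())
    scheme = assign_colour_schemes(alloc)
    pats = [scheme.pattern[s] for s in lengths]
    assert len(set(pats)) == len(pats)
    assert all(len(p) == 2 for p in pats)


def test_colour_schemes_capacity_error():
    lengths = {f"s{i}": 99_000 - i for i in range(37)}
    counts = {s: 1 for s in lengths}
    from karyopaint.design import AllocationScheme

    alloc = AllocationScheme(counts, [list(lengths)], capacity=92_000, n_oligo=1)
    # 37 single-probe scaffolds in one pool exceed the 6 distinct colours
    with pytest.raises(InfeasibleDesignError):
        assign_colour_schemes(alloc)


def test_colour_cross_pool_repeats_reported():
    from karyopaint.design import AllocationScheme

    alloc = AllocationScheme({"a": 1, "b": 1}, [["a"], ["b"]],
                             capacity=92_000, n_oligo=1)
    scheme = assign_colour_schemes(alloc)
    assert scheme.pattern["a"] == scheme.pattern["b"]
    assert ("a", "b") in scheme.cross_pool_repeats


def test_assemble_oligos_structure_and_roundtrip():
    rng = np.random.default_rng(38)
    lengths = {"s1": 30_000, "s2": 25_000}
    alloc = allocate_probe_counts(lengths, n_libraries=1, capacity=92_000,
                                  n_oligo=3, max_count=2, tier_sizes=(0, 1, 0))
    windows = []
    for sid in lengths:
        for k in range(alloc.counts[sid]):
            oligos = [
                OligoCandidate(sid, 100 * k + 40 * i, 100 * k + 40 * i + 39,
                               _random_seq(rng, 39), tm=44.0, gc=0.5)
                for i in range(3)
            ]
            windows.append(ProbeWindow(probe_label(sid, k), sid,
                                       oligos[0].start, oligos[-1].end,
                                       oligos, design_index=k))
    plan = ProbePlan(windows, lengths, 3)
    scheme = assign_colour_schemes(alloc)
    apply_colours(plan, scheme)
    # force one two-fluorophore probe to exercise forward-primer alternation
    plan.windows[0].fluorophores = frozenset({"FAM", "ATTO550"})
    pool = _pool([(True, False)] * 4 + [(False, True)] * 4 + [(False, False)] * 4)
    roles = assign_roles(pool, alloc.libraries, seed=1)
    oligos, primers = assemble_oligos(plan, alloc, roles)

    assert len(oligos) == sum(len(w.oligos) for w in windows)
    for o in oligos:
        assert len(o.sequence) == 79
        rev, hom, fwd = split_oligo(o.sequence)
        assert hom == o.homolog
        assert roles.id_of(rev) == o.reverse_id
        assert roles.id_of(fwd) == o.forward_id
    # reverse amplification primers: T7 promoter + reverse complement of the
    # oligo's 5' segment, 53 nt
    t7s = [p for p in primers if p.kind == "reverse_amplification"]
    assert t7s and all(len(p.sequence) == 53 for p in t7s)
    assert all(p.sequence.startswith(T7_PROMOTER) for p in t7s)
    fwd_amp = [p for p in primers if p.kind == "forward_amplification"]
    assert len(fwd_amp) == 3 and all(len(p.sequence) == 40 for p in fwd_amp)
    dets = [p for p in primers if p.kind == "detector"]
    assert len(dets) == 3 and all(len(p.sequence) == 20 for p in dets)
    # a two-fluorophore probe alternates forward primers oligo by oligo
    for w in plan.windows:
        if len(w.fluorophores) == 2:
            fids = [o.forward_id for o in oligos if o.probe_id == w.probe_id]
            assert len(set(fids)) == 2
            assert fids[0] != fids[1]


def test_split_oligo_validates_length():
    with pytest.raises(InvalidSequenceError):
        split_oligo("ACGT")
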