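import pandas as pd
import pytest

import karyopaint as kp
from karyopaint.curation import (
    assign_scaffolds,
    build_chromosomes,
    detect_anomalies,
    locate_breakpoints,
    order_and_number,
    split_and_orient,
)
from karyopaint.design import ProbePlan, ProbeWindow
from karyopaint.errors import ConsistencyError, InvalidParameterError
from karyopaint.synthetic import HybObservation
from conftest import make_published_fixture, run_recovery


def _obs(spread, probe, chrom, rank, side="q", colour=frozenset({"FAM"})):
    return HybObservation(spread_id=spread, probe_id=probe, chromosome_label=chrom,
                          order_index=rank, colour=colour, centromere_side=side)


def _plan(n_probes, sid="scaffold_1", L=50_000):
    windows = [
        ProbeWindow(f"{sid.split('_')[-1]}p{k}", sid, 5_000 + 8_000 * k,
                    6_000 + 8_000 * k, [], design_index=k)
        for k in range(n_probes)
    ]
    return ProbePlan(windows, {sid: L}, 0)


# ---------------------------------------------------------------------------
# assignment


def test_majority_vote_and_ambiguity():
    plan = _plan(2)
    obs = [
        _obs(0, "1p0", "chrA", 0), _obs(1, "1p0", "chrA", 0), _obs(2, "1p0", "chrB", 0),
        _obs(0, "1p1", "chrA", 1),  # single spread: below min_spreads
    ]
    a = assign_scaffolds(obs, plan, min_spreads=2)
    assert a.probe_chromosome == {"1p0": "chrA"}
    assert a.ambiguous_probes == {"1p1"}
    assert a.unplaced_probes == set()
    assert a.chromosome_of("scaffold_1") == {"chrA"}


def test_unplaced_probes_listed():
    plan = _plan(3)
    obs = [_obs(s, "1p0", "chrA", 0) for s in range(2)]
    a = assign_scaffolds(obs, plan)
    assert a.unplaced_probes == {"1p1", "1p2"}


def test_unknown_probe_rejected():
    with pytest.raises(InvalidParameterError):
        assign_scaffolds([_obs(0, "zzz", "chrA", 0)], _plan(1))


def test_colour_mismatch_discarded():
    plan = _plan(1)
    plan.windows[0].fluorophores = frozenset({"ATTO647"})
    wrong = [_obs(s, "1p0", "chrA", 0, colour=frozenset({"FAM"})) for s in range(3)]
    a = assign_scaffolds(wrong, plan)
    assert a.probe_chromosome == {}
    right = [_obs(s, "1p0", "chrA", 0, colour=frozenset({"ATTO647"})) for s in range(3)]
    a2 = assign_scaffolds(right, plan)
    assert a2.probe_chromosome == {"1p0": "chrA"}


def test_median_order_is_robust():
    plan = _plan(1)
    obs = [_obs(0, "1p0", "chrA", 2), _obs(1, "1p0", "chrA", 2),
           _obs(2, "1p0", "chrA", 9)]
    a = assign_scaffolds(obs, plan)
    assert a.probe_order["1p0"] == 2


# ---------------------------------------------------------------------------
# anomaly detection


def _assign(plan, placements):
    """placements: probe -> (chrom, rank, side)"""
    obs = [
        _obs(s, p, c, r, side)
        for s in range(2)
        for p, (c, r, side) in placements.items()
    ]
    return assign_scaffolds(obs, plan)


def test_statuses_clean_reversed_reordered_chimeric():
    plan = _plan(3)
    clean = _assign(plan, {"1p0": ("c", 0, "q"), "1p1": ("c", 1, "q"),
                           "1p2": ("c", 2, "q")})
    assert detect_anomalies(clean, plan)["scaffold_1"] == "clean"
    reversed_ = _assign(plan, {"1p0": ("c", 2, "q"), "1p1": ("c", 1, "q"),
                               "1p2": ("c", 0, "q")})
    assert detect_anomalies(reversed_, plan)["scaffold_1"] == "clean"
    reordered = _assign(plan, {"1p0": ("c", 1, "q"), "1p1": ("c", 0, "q"),
                               "1p2": ("c", 2, "q")})
    assert detect_anomalies(reordered, plan)["scaffold_1"] == "reordered"
    chimeric = _assign(plan, {"1p0": ("c", 0, "q"), "1p1": ("d", 0, "q"),
                              "1p2": ("d", 1, "q")})
    assert detect_anomalies(chimeric, plan)["scaffold_1"] == "chimeric"


def test_clean_scaffold_spanning_centromere_stays_clean():
    plan = _plan(4)
    # design order runs p-arm (decreasing rank towards the centromere) then
    # q-arm: genomically co-linear, so clean
    a = _assign(plan, {"1p0": ("c", 1, "p"), "1p1": ("c", 0, "p"),
                       "1p2": ("c", 0, "q"), "1p3": ("c", 1, "q")})
    assert detect_anomalies(a, plan)["scaffold_1"] == "clean"


# ---------------------------------------------------------------------------
# breakpoints


def test_breakpoint_midpoint_fallback():
    plan = _plan(4)
    a = _assign(plan, {"1p0": ("c", 0, "q"), "1p1": ("c", 1, "q"),
                       "1p2": ("d", 0, "q"), "1p3": ("d", 1, "q")})
    statuses = detect_anomalies(a, plan)
    bp = locate_breakpoints("scaffold_1", plan, a, None, statuses)
    w1, w2 = plan.windows[1], plan.windows[2]
    assert (bp.left_bound, bp.right_bound) == (w1.end, w2.start)
    assert bp.evidence == "midpoint_fallback"
    assert bp.flanking_probe_ids == ("1p1", "1p2")
    assert bp.midpoint == (w1.end + w2.start) // 2


def test_breakpoint_requires_chimeric_status():
    plan = _plan(2)
    a = _assign(plan, {"1p0": ("c", 0, "q"), "1p1": ("c", 1, "q")})
    statuses = detect_anomalies(a, plan)
    with pytest.raises(ConsistencyError):
        locate_breakpoints("scaffold_1", plan, a, None, statuses)


def test_breakpoint_synteny_narrowing():
    plan = _plan(4)
    a = _assign(plan, {"1p0": ("chrA", 0, "q"), "1p1": ("chrA", 1, "q"),
                       "1p2": ("chrB", 0, "q"), "1p3": ("chrB", 1, "q")})
    statuses = detect_anomalies(a, plan)
    junction = 17_000  # between probe 1 (ends 14 000) and probe 2 (starts 21 000)
    rows = []
    for qs in range(0, junction, 1_000):
        rows.append(dict(query="scaffold_1", qlen=50_000, qstart=qs,
                         qend=min(qs + 1_000, junction), strand="+",
                         target="chrA", tlen=10**6, tstart=qs, tend=qs + 1_000,
                         matches=900, alnlen=1_000, mapq=60))
    for qs in range(junction, 50_000, 1_000):
        rows.append(dict(query="scaffold_1", qlen=50_000, qstart=qs,
                         qend=min(qs + 1_000, 50_000), strand="+",
                         target="chrB", tlen=10**6, tstart=qs, tend=qs + 1_000,
                         matches=900, alnlen=1_000, mapq=60))
    bp = locate_breakpoints("scaffold_1", plan, a, pd.DataFrame(rows), statuses)
    assert bp.evidence == "synteny"
    assert bp.left_bound <= junction <= bp.right_bound
    assert (bp.right_bound - bp.left_bound) <= 1_000
    assert bp.reference_chromosomes == ("chrA", "chrB")


# ---------------------------------------------------------------------------
# splitting / orientation / builds


def test_split_and_orient_labels():
    plan = _plan(4)
    a = _assign(plan, {"1p0": ("c", 0, "q"), "1p1": ("c", 1, "q"),
                       "1p2": ("d", 1, "q"), "1p3": ("d", 0, "q")})
    statuses = detect_anomalies(a, plan)
    bps = {"scaffold_1": locate_breakpoints("scaffold_1", plan, a, None, statuses)}
    parts = split_and_orient(plan, a, statuses, bps, {"scaffold_1": 50_000})
    assert [p.part_id for p in parts] == ["1p0-1", "1p2-3"]
    left, right = parts
    assert left.orientation == "+" and right.orientation == "-"
    assert right.label == "1p2-3rev"
    assert left.end == right.start == bps["scaffold_1"].midpoint
    assert left.assigned_chromosome == "c" and right.assigned_chromosome == "d"


def test_single_probe_part_low_confidence():
    plan = _plan(1)
    a = _assign(plan, {"1p0": ("c", 0, "q")})
    parts = split_and_orient(plan, a, {"scaffold_1": "clean"}, {}, {"scaffold_1": 50_000})
    assert parts[0].orientation == "+"
    assert parts[0].low_confidence
    assert parts[0].part_id == "1"  # whole scaffold keeps its short name


def test_build_chromosomes_order_and_collision():
    plan = _plan(2)
    a = _assign(plan, {"1p0": ("c", 0, "q"), "1p1": ("c", 1, "q")})
    parts = split_and_orient(plan, a, {"scaffold_1": "clean"}, {}, {"scaffold_1": 50_000})
    builds = build_chromosomes(parts)
    assert len(builds) == 1 and builds[0].chromosome_id == "c"
    dup = parts + parts
    with pytest.raises(ConsistencyError):
        build_chromosomes(dup)


def test_order_and_number_convention():
    plan = _plan(2)
    a = _assign(plan, {"1p0": ("c", 0, "q"), "1p1": ("c", 1, "q")})
    parts = split_and_orient(plan, a, {"scaffold_1": "clean"}, {}, {"scaffold_1": 50_000})
    # three pseudo-chromosomes sharing the same single part list for ranking
    builds = build_chromosomes(parts, morphology={"c": "metacentric"})
    b = builds[0]
    import copy

    b2 = copy.deepcopy(b)
    b2.chromosome_id = "d"
    b2.morphology = "acrocentric"
    for p in b2.parts:
        p.assigned_chromosome = "d"
    b3 = copy.deepcopy(b)
    b3.chromosome_id = "x"
    b3.morphology = "acrocentric"
    rl = pd.DataFrame(
        {"chromosome": ["c", "d", "x"], "relative_length": [9.0, 5.0, 7.0],
         "sd": [0.1, 0.1, 0.1]}
    )
    table = order_and_number([b, b2, b3], rl, sex_chromosome="x")
    # acrocentrics first by length, then metacentrics; X labelled last
    assert list(table["label"]) == ["1", "2", "X"]
    assert list(table["chromosome"]) == ["d", "c", "x"]
    # numbering is invariant to input order
    table2 = order_and_number([b3, b, b2], rl, sex_chromosome="x")
    assert list(table2["chromosome"]) == list(table["chromosome"])


def test_order_and_number_requires_morphology():
    plan = _plan(1)
    a = _assign(plan, {"1p0": ("c", 0, "q")})
    parts = split_and_orient(plan, a, {"scaffold_1": "clean"}, {}, {"scaffold_1": 50_000})
    builds = build_chromosomes(parts)
    rl = pd.DataFrame({"chromosome": ["c"], "relative_length": [1.0], "sd": [0.0]})
    with pytest.raises(InvalidParameterError):
        order_and_number(builds, rl)


# ---------------------------------------------------------------------------
# end-to-end recovery and published fixtures


def test_end_to_end_chain_on_toy_universe(design_result, observations,
                                          alignments, scaffold_set):
    lengths = {k: len(v) for k, v in scaffold_set.sequences.items()}
    res = kp.curate(observations, design_result.plan, lengths, alignments)
    chimeric_truth = {t.scaffold_id for t in scaffold_set.truths if t.is_chimeric}
    assert {s for s, st in res.statuses.items() if st == "chimeric"} == chimeric_truth
    sid = next(iter(chimeric_truth))
    bp = res.breakpoints[sid]
    truth = next(t for t in scaffold_set.truths if t.scaffold_id == sid)
    assert bp.evidence == "synteny"
    assert bp.left_bound <= truth.junctions[0] <= bp.right_bound


def test_zero_noise_recovery_single_seed():
    sset, target, res = run_recovery(seed=3)
    chimeric_truth = {t.scaffold_id for t in sset.truths if t.is_chimeric}
    assert {s for s, st in res.statuses.items() if st == "chimeric"} == chimeric_truth
    assert {s for s, st in res.statuses.items() if st == "reordered"} == {target}


def test_published_composition_fixture():
    plan, obs, lengths = make_published_fixture()
    res = kp.curate(obs, plan, lengths)
    builds = {b.chromosome_id: b for b in res.builds}
    assert builds["34"].composition == "20p0-1rev56rev13rev"
    assert {p.scaffold_id for p in builds["6"].parts} == {
        "scaffold_18", "scaffold_14", "scaffold_68"
    }
    split_truth = {
        "scaffold_1": {"7", "20"},
        "scaffold_2": {"16", "18"},
        "scaffold_12": {"1", "4"},
        "scaffold_20": {"2", "34"},
        "scaffold_25": {"3", "8"},
    }
    for sid, chroms in split_truth.items():
        assert res.statuses[sid] == "chimeric"
        assert res.assignment.chromosome_of(sid) == chroms
    clean = {"scaffold_56", "scaffold_13", "scaffold_18", "scaffold_14", "scaffold_68"}
    for sid in clean:
        assert res.statuses[sid] == "clean"
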