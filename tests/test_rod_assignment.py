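"""Rod detection and combinatorial assignment search."""

import numpy as np
import pytest

from helixtrace import ec_constraints, rod_assignment as ra, synthetic_data as sd
from helixtrace.helix_geometry import build_ideal_helix, fit_axis, place_helix
from helixtrace.map_ops import DensityMap
from helixtrace.rod_assignment import (
    Assignment,
    AssignmentEntry,
    AssignmentProblem,
    count_assignments,
    enumerate_assignments,
    match_rods,
    rod_angle,
    rod_detect,
    score_assignment,
    search_best,
)
from helixtrace.synthetic_data import MapSpec


class TestRodDetect:
    def test_all_zero_map_empty(self):
        m = DensityMap(np.zeros((16, 16, 16)), 1.64, np.zeros(3))
        assert rod_detect(m, 0.0) == []

    def test_threshold_outside_range_rejected(self, bundle_map):
        with pytest.raises(ValueError):
            rod_detect(bundle_map, 1e6)

    def test_single_helix_axis_and_length(self):
        h = build_ideal_helix(20)
        m = sd.render_map(h, MapSpec())
        (rod,) = rod_detect(m, 0.5)
        true_axis = fit_axis(h)
        assert rod_angle(rod, true_axis) <= 5.0
        expected = 19 * 1.56
        assert abs(rod.length - expected) <= 0.2 * expected

    def test_bundle_recovered_one_to_one(self, small_bundle, bundle_map):
        rods = rod_detect(bundle_map, 0.5)
        assert len(rods) == 4
        matches = match_rods(rods, small_bundle.rods)
        assert sorted(m for m in matches if m is not None) == [0, 1, 2, 3]
        for k, mi in enumerate(matches):
            assert rod_angle(rods[mi], small_bundle.rods[k]) < 5.0

    def test_centerline_mode_on_packed_bundle(self):
        case = sd.make_study_case(0)
        rods = rod_detect(case["map"], 0.35, method="centerline")
        assert len(rods) >= 6
        tg = sd.true_geometry_in(case["truth"], rods)
        assert tg is not None


class TestEnumeration:
    @pytest.mark.parametrize("k,expected", [(1, 2), (2, 8), (3, 48)])
    def test_exhaustive_counts_small(self, k, expected):
        segments = [(i + 1, 1 + 30 * i, 20 + 30 * i) for i in range(k)]
        rods = [fit_axis(place_helix(20, r, "forward"))
                for r in _well_separated_rods(k)]
        problem = AssignmentProblem(segments=segments, rods=rods, pairs=_dummy_pairs())
        assignments = list(enumerate_assignments(problem))
        assert len(assignments) == expected == count_assignments(k, k)
        assert len({a.geometry_key() for a in assignments}) == expected

    def test_closed_form_up_to_six(self):
        expected = [2, 8, 48, 384, 3840, 46080]
        assert [count_assignments(k, k) for k in range(1, 7)] == expected

    def test_cap_enforced(self):
        segments = [(i + 1, 1 + 30 * i, 20 + 30 * i) for i in range(9)]
        rods = _well_separated_rods(9)
        problem = AssignmentProblem(segments=segments, rods=rods, pairs=_dummy_pairs())
        with pytest.raises(ValueError, match="heuristic"):
            list(enumerate_assignments(problem))

    def test_injectivity_enforced(self):
        with pytest.raises(ValueError):
            Assignment(((1, AssignmentEntry(0, "forward")),
                        (2, AssignmentEntry(0, "reverse"))))


def _well_separated_rods(n, spacing=40.0):
    from helixtrace.helix_geometry import RodAxis

    return [RodAxis([i * spacing, 0.0, -15.0], [i * spacing, 0.0, 15.0])
            for i in range(n)]


def _dummy_pairs():
    return [ec_constraints.ContactPair(1, 10, 1.0)]


def _problem_from_truth(truth, pairs, **kwargs):
    return AssignmentProblem(segments=truth.segments, rods=truth.rods,
                             pairs=pairs, **kwargs)


class TestScoring:
    def test_zero_resolvable_pairs_is_error(self):
        truth = sd.make_bundle(2, [15, 15], rng_seed=0)
        pairs = [ec_constraints.ContactPair(500, 600, 1.0)]
        problem = _problem_from_truth(truth, pairs)
        with pytest.raises(ValueError):
            score_assignment(problem, next(enumerate_assignments(problem)))

    def test_true_assignment_fully_satisfied_without_false_positives(self):
        truth = sd.make_bundle(4, [20] * 4, rng_seed=8)
        pairs = sd.make_contacts(truth, 30, 0.0, rng_seed=9)
        problem = _problem_from_truth(truth, pairs)
        geo = Assignment(tuple(
            (hid, AssignmentEntry(e.rod, e.direction))
            for hid, e in truth.true_assignment.entries))
        _, report = score_assignment(problem, geo)
        assert report.fraction_satisfied == 1.0

    def test_direction_flip_scores_worse(self):
        wins = 0
        for seed in range(10):
            truth = sd.make_bundle(4, [24] * 4, rng_seed=seed, layout="row")
            pairs = sd.make_contacts(truth, 30, 0.0, rng_seed=seed + 50)
            problem = _problem_from_truth(truth, pairs)
            geo = {hid: AssignmentEntry(e.rod, e.direction)
                   for hid, e in truth.true_assignment.entries}
            flipped = dict(geo)
            e1 = flipped[1]
            flipped[1] = AssignmentEntry(
                e1.rod, "reverse" if e1.direction == "forward" else "forward")
            _, rep_true = score_assignment(problem, Assignment(tuple(sorted(geo.items()))))
            _, rep_flip = score_assignment(problem, Assignment(tuple(sorted(flipped.items()))))
            wins += rep_true.n_satisfied > rep_flip.n_satisfied
        assert wins >= 8


class TestSearch:
    def test_no_rods_is_error(self):
        with pytest.raises(ValueError):
            AssignmentProblem(segments=[(1, 1, 20)], rods=[], pairs=_dummy_pairs())

    def test_two_candidate_case_prefers_better_direction(self):
        # one helix, one rod, pairs to a fixed partner: forward vs reverse
        truth = sd.make_bundle(1, [20], rng_seed=0)
        helix = truth.helices[1]
        partner = build_ideal_helix(10, first_residue=101).transformed(
            np.eye(3), helix.ca[0] + np.array([6.0, 0, 0]))
        pairs = [ec_constraints.ContactPair(truth.segments[0][1] + k, 101 + k,
                                            1.0 - 0.1 * k, "A", "C")
                 for k in range(5)]
        problem = AssignmentProblem(segments=truth.segments, rods=truth.rods,
                                    pairs=pairs, partner_models={"C": partner})
        sols = search_best(problem, top_k=None)
        (best, rep), (second, rep2) = sols.solutions[:2]
        assert rep.n_satisfied >= rep2.n_satisfied
        assert sols.exhaustive and sols.n_evaluated == 2

    def test_pruned_matches_full_scan(self):
        for seed in (0, 1):
            truth = sd.make_bundle(4, [20, 24, 22, 26], rng_seed=seed)
            pairs = sd.make_contacts(truth, 20, 0.05, rng_seed=seed + 7)
            problem = _problem_from_truth(truth, pairs)
            full = search_best(problem, top_k=None, prune=False)
            pruned = search_best(problem, top_k=5, prune=True)
            full_keys = [a.geometry_key() for a, _ in full.solutions[:5]]
            pruned_keys = [a.geometry_key() for a, _ in pruned.solutions]
            assert full_keys == pruned_keys
            assert pruned.unique_maximizer == full.unique_maximizer

    def test_ranking_deterministic(self):
        truth = sd.make_bundle(4, [20] * 4, rng_seed=4)
        pairs = sd.make_contacts(truth, 15, 0.07, rng_seed=5)
        problem = _problem_from_truth(truth, pairs)
        a = search_best(problem, top_k=5)
        b = search_best(problem, top_k=5)
        assert [x.geometry_key() for x, _ in a.solutions] == \
               [x.geometry_key() for x, _ in b.solutions]

    def test_recovery_degrades_with_false_positive_rate(self):
        # success should not improve as the false-positive rate rises
        rates = {}
        for fp in (0.0, 0.2):
            hits = 0
            for seed in range(8):
                case = sd.make_study_case(seed, fp_rate=fp, with_map=False)
                truth = case["truth"]
                problem = AssignmentProblem(
                    segments=truth.segments, rods=truth.rods,
                    pairs=case["pairs"] + case["inter_pairs"],
                    partner_models={"C": case["ring"]})
                sols = search_best(problem, top_k=1)
                hits += (sols.best[0].geometry_key()
                         == truth.true_assignment.geometry_key())
            rates[fp] = hits
        assert rates[0.0] >= rates[0.2]

    def test_heuristic_mode_runs(self):
        truth = sd.make_bundle(4, [20] * 4, rng_seed=3)
        pairs = sd.make_contacts(truth, 30, 0.0, rng_seed=2)
        problem = _problem_from_truth(truth, pairs)
        sols = search_best(problem, mode="heuristic")
        assert not sols.exhaustive
        assert sols.best[1].n_pairs == 30
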