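"""Synthetic ground truths: bundles, contact lists, rendered maps, state ensembles."""

import numpy as np
import pytest

from helixtrace import synthetic_data as sd
from helixtrace.helix_geometry import build_ideal_helix, fit_axis, segment_distance
from helixtrace.synthetic_data import MapSpec


class TestMakeBundle:
    def test_single_helix(self):
        truth = sd.make_bundle(1, [10], rng_seed=0)
        assert truth.segments == [(1, 1, 10)]
        entry = truth.true_assignment[1]
        assert entry.rod == 0

    def test_seeded_determinism(self):
        a = sd.make_bundle(6, [20] * 6, rng_seed=42)
        b = sd.make_bundle(6, [20] * 6, rng_seed=42)
        assert np.array_equal(a.model.coords, b.model.coords)
        assert a.true_assignment.geometry_key() == b.true_assignment.geometry_key()

    def test_segments_nonoverlapping_ascending(self):
        truth = sd.make_bundle(5, [12, 15, 20, 12, 18], rng_seed=1)
        for (_, f1, l1), (_, f2, _) in zip(truth.segments, truth.segments[1:]):
            assert f1 <= l1 < f2

    def test_axis_spacing_band(self):
        # default packing at 10 Å spacing keeps minimum inter-axis distances
        # within [8, 12] Å across 100 seeded bundles
        for seed in range(100):
            truth = sd.make_bundle(4, [20] * 4, spacing=10.0, rng_seed=seed)
            axes = [fit_axis(m) for m in truth.helices.values()]
            dmin = min(segment_distance(axes[i].endpoint_a, axes[i].endpoint_b,
                                        axes[j].endpoint_a, axes[j].endpoint_b)
                       for i in range(4) for j in range(i + 1, 4))
            assert 8.0 <= dmin <= 12.0

    def test_unphysical_spacing_rejected(self):
        with pytest.raises(ValueError, match="unphysically small"):
            sd.make_bundle(4, [20] * 4, spacing=3.0, rng_seed=0)

    def test_short_helix_rejected(self):
        with pytest.raises(ValueError):
            sd.make_bundle(2, [10, 4], rng_seed=0)

    def test_physical_packing(self):
        from scipy.spatial.distance import cdist

        truth = sd.make_bundle(6, sd.STUDY_LENGTHS, rng_seed=7,
                               **sd.STUDY_CONDITIONS)
        helices = list(truth.helices.values())
        for i in range(len(helices)):
            for j in range(i + 1, len(helices)):
                assert cdist(helices[i].ca, helices[j].ca).min() >= 3.8


class TestMakeContacts:
    def test_composition_is_exact(self):
        truth = sd.make_bundle(6, sd.STUDY_LENGTHS, rng_seed=0, **sd.STUDY_CONDITIONS)
        pairs = sd.make_contacts(truth, 90, 0.06, rng_seed=1)
        assert len(pairs) == 90
        dists = []
        for p in pairs:
            i = truth.model.index_of(p.res_i)
            j = truth.model.index_of(p.res_j)
            dists.append(np.linalg.norm(truth.model.ca[i] - truth.model.ca[j]))
        dists = np.array(dists)
        assert (dists <= 8.0).sum() == 85  # round(90 * 0.94)
        assert (dists > 20.0).sum() == 5

    def test_zero_fp_rate_all_true(self):
        truth = sd.make_bundle(4, [20] * 4, rng_seed=2)
        pairs = sd.make_contacts(truth, 30, 0.0, rng_seed=3)
        from helixtrace.ec_constraints import satisfaction

        assert satisfaction(truth.model, pairs, 15.0).fraction_satisfied == 1.0

    def test_sequence_separation_respected(self):
        truth = sd.make_bundle(4, [20] * 4, rng_seed=4)
        pairs = sd.make_contacts(truth, 30, 0.1, rng_seed=5)
        assert all(p.separation >= 5 for p in pairs)

    def test_scores_strictly_ordered(self):
        truth = sd.make_bundle(4, [20] * 4, rng_seed=4)
        pairs = sd.make_contacts(truth, 30, 0.1, rng_seed=5)
        scores = sorted((p.score for p in pairs), reverse=True)
        assert len(set(scores)) == len(scores)

    def test_shortfall_error_names_counts(self):
        truth = sd.make_bundle(2, [8, 8], spacing=10.0, rng_seed=0)
        with pytest.raises(ValueError, match="shortfall"):
            sd.make_contacts(truth, 500, 0.0, rng_seed=0)

    def test_satisfaction_floor_over_seeds(self):
        # false pairs generated beyond 20 Å always violate the 15 Å check on
        # the generating model, so the fraction is exactly 85/90 per seed
        from helixtrace.ec_constraints import satisfaction

        for seed in range(30):
            truth = sd.make_bundle(6, sd.STUDY_LENGTHS, rng_seed=seed,
                                   **sd.STUDY_CONDITIONS)
            pairs = sd.make_contacts(truth, 90, 0.06, rng_seed=seed + 100)
            frac = satisfaction(truth.model, pairs, 15.0).fraction_satisfied
            assert frac >= 85 / 90


class TestRenderMap:
    def test_single_atom_peak_at_centre(self):
        h = build_ideal_helix(1)
        m = sd.render_map(h, MapSpec(box_edge=21))
        peak = np.unravel_index(np.argmax(m.grid), m.shape)
        world = m.index_to_world(np.array(peak))
        assert np.linalg.norm(world - h.ca[0]) <= m.voxel_size

    def test_seeded_determinism(self, small_bundle):
        spec = MapSpec(noise_sigma=0.3)
        a = sd.render_map(small_bundle.model, spec, rng_seed=9)
        b = sd.render_map(small_bundle.model, spec, rng_seed=9)
        assert np.array_equal(a.grid, b.grid)

    def test_integral_proportional_to_atom_count(self):
        # noise-free integral scales with the number of contributing atoms
        spec = MapSpec(box_edge=48)
        one = sd.render_map(build_ideal_helix(1), spec).grid.sum()
        ten = sd.render_map(build_ideal_helix(10), spec).grid.sum()
        assert ten / one == pytest.approx(10.0, rel=0.01)

    def test_model_outside_box_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            sd.render_map(build_ideal_helix(40), MapSpec(box_edge=10))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MapSpec(voxel_size=2.0, resolution=3.0)  # below Nyquist


class TestStateEnsemble:
    def test_zero_angle_matches_base_render(self, small_bundle):
        centre = small_bundle.model.ca.mean(axis=0)
        maps, models = sd.make_state_ensemble(
            small_bundle, {1, 2, 3, 4}, [0.0], centre, [0, 0, 1], MapSpec())
        assert np.allclose(models[0].ca, small_bundle.model.ca, atol=1e-9)

    def test_empty_mobile_part_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            sd.make_state_ensemble(small_bundle, set(), [5.0],
                                   [0, 0, 0], [0, 0, 1], MapSpec())

    def test_mobile_region_has_higher_variance(self, small_bundle):
        from helixtrace.map_ops import average_maps

        centre = small_bundle.model.ca.mean(axis=0)
        angles = [0, 5, 10, 15, 20, 25, 30]
        maps, models = sd.make_state_ensemble(
            small_bundle, {4}, angles, centre, [0, 0, 1],
            MapSpec(noise_sigma=0.05), rng_seed=3)
        _, var = average_maps(maps)
        mobile_ca = np.concatenate(
            [m.ca[-20:] for m in models])  # helix 4 across states
        static_ca = models[0].ca[:60]
        idx = np.indices(var.shape).reshape(3, -1).T
        world = var.index_to_world(idx)
        from scipy.spatial.distance import cdist

        near_mobile = cdist(world, mobile_ca).min(axis=1) < 3.0
        near_static = (cdist(world, static_ca).min(axis=1) < 3.0) & ~near_mobile
        v = var.grid.reshape(-1)
        assert np.median(v[near_mobile]) > np.median(v[near_static])


class TestStudyCase:
    def test_case_contents_and_determinism(self):
        a = sd.make_study_case(3)
        b = sd.make_study_case(3)
        assert np.array_equal(a["map"].grid, b["map"].grid)
        assert len(a["pairs"]) == 90
        assert len(a["inter_pairs"]) == 6
        assert all(not p.same_chain for p in a["inter_pairs"])

    def test_save_truth_roundtrip(self, tmp_path):
        import json

        case = sd.make_study_case(0, with_map=False)
        sd.save_truth(case["truth"], tmp_path, partner=case["ring"],
                      pairs=case["pairs"])
        from helixtrace.helix_geometry import read_pdb
        from helixtrace.ec_constraints import read_contacts

        chains = read_pdb(tmp_path / "truth.pdb")
        assert set(chains) == {"A", "C"}
        assert read_contacts(tmp_path / "contacts.txt") == case["pairs"]
        meta = json.loads((tmp_path / "truth.json").read_text())
        assert meta["segments"] == [list(s) for s in case["truth"].segments]
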