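"""Generators: distributions, determinism, and ground-truth consistency."""

import numpy as np
import pytest

from nemascore.pillar_tracking import PillarArena
from nemascore.strength_assay import f95
from nemascore.synthetic_data import (
    StrainProfile,
    default_strain_panel,
    expected_endpoint_fraction,
    expected_f95,
    load_profiles_yaml,
    render_arena_frame,
    save_profiles_yaml,
    simulate_burrow_trial,
    simulate_force_trace,
    simulate_site_scores,
    simulate_study,
    true_mds,
    write_tiff_stack,
)


def profile_with(**overrides):
    base = dict(name="p", health=0.5, strength_scale=2.0, strength_cv=0.2,
                diameter_mean=60.0, diameter_cv=0.05, burrow_rate=0.03,
                burrow_success=0.6, site_bias=(1.0, 1.0, 1.0, 1.0, 1.0))
    base.update(overrides)
    return StrainProfile(**base)


class TestStrainProfileValidation:
    @pytest.mark.parametrize("bad", [
        {"health": 1.5},
        {"strength_scale": 0.0},
        {"burrow_success": 1.2},
        {"site_bias": (0, 0, 0, 0)},
        {"site_bias": (0, 0, 0, 0, 3.5)},
    ])
    def test_invalid_fields_rejected(self, bad):
        with pytest.raises(ValueError):
            profile_with(**bad)


class TestForceTraceGenerator:
    def test_zero_cv_constant_trace(self):
        trace = simulate_force_trace(profile_with(strength_cv=0.0,
                                                  strength_scale=1.0),
                                     n_frames=300, seed=0)
        assert np.all(trace.forces == 1.0)

    def test_same_seed_identical(self, profile_mid):
        a = simulate_force_trace(profile_mid, seed=42)
        b = simulate_force_trace(profile_mid, seed=42)
        assert np.array_equal(a.forces, b.forces)

    def test_different_seed_differs(self, profile_mid):
        a = simulate_force_trace(profile_mid, seed=1)
        b = simulate_force_trace(profile_mid, seed=2)
        assert not np.array_equal(a.forces, b.forces)

    def test_mean_matches_parameterization(self):
        """Monte-Carlo: sample mean within 3 SE of the nominal 2.0 uN."""
        prof = profile_with(strength_scale=2.0, strength_cv=0.2)
        trace = simulate_force_trace(prof, n_frames=10_000, seed=9)
        se = 2.0 * 0.2 / np.sqrt(10_000)
        assert abs(trace.forces.mean() - 2.0) < 3 * se

    def test_all_positive_right_skewed(self, profile_mid):
        trace = simulate_force_trace(profile_mid, n_frames=5000, seed=3)
        forces = trace.forces
        assert (forces > 0).all()
        skew = np.mean(((forces - forces.mean()) / forces.std()) ** 3)
        assert skew > 0

    def test_nonpositive_frames_rejected(self, profile_mid):
        with pytest.raises(ValueError):
            simulate_force_trace(profile_mid, n_frames=0)

    def test_analytic_f95_close_to_empirical(self, profile_mid):
        trace = simulate_force_trace(profile_mid, n_frames=200_000, seed=5)
        assert f95(trace) == pytest.approx(expected_f95(profile_mid), rel=0.02)


class TestBurrowGenerator:
    def test_no_succeeders_all_zero(self):
        trial = simulate_burrow_trial(profile_with(burrow_success=0.0),
                                      n_worms=50, seed=0)
        assert np.all(trial.counts == 0)

    def test_instantaneous_arrival_limit(self):
        trial = simulate_burrow_trial(
            profile_with(burrow_success=1.0, burrow_rate=np.inf),
            n_worms=25, seed=0)
        assert trial.counts[0] == 25

    def test_counts_non_decreasing_and_bounded(self, profile_mid):
        trial = simulate_burrow_trial(profile_mid, n_worms=40, seed=11)
        assert np.all(np.diff(trial.counts) >= 0)
        assert trial.counts.max() <= 40

    def test_endpoint_fraction_binomial_check(self):
        """With a very fast rate the 2-h endpoint is a plain Bernoulli
        draw at p = burrow_success; check within 3 binomial SE."""
        prof = profile_with(burrow_success=0.5, burrow_rate=1.0)
        trial = simulate_burrow_trial(prof, n_worms=10_000, seed=21)
        frac = trial.counts[-1] / 10_000
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(frac - 0.5) < 3 * se

    def test_expected_endpoint_formula(self):
        prof = profile_with(burrow_success=0.8, burrow_rate=0.02)
        expected = 0.8 * (1 - np.exp(-0.02 * 120))
        assert expected_endpoint_fraction(prof) == pytest.approx(expected)

    def test_invalid_durations_rejected(self, profile_mid):
        with pytest.raises(ValueError):
            simulate_burrow_trial(profile_mid, interval_min=0)
        with pytest.raises(ValueError):
            simulate_burrow_trial(profile_mid, interval_min=45, total_min=120)

    def test_same_seed_identical(self, profile_mid):
        a = simulate_burrow_trial(profile_mid, seed=5)
        b = simulate_burrow_trial(profile_mid, seed=5)
        assert np.array_equal(a.counts, b.counts)


class TestSiteScoreGenerator:
    def test_zero_bias_zero_noise(self):
        rec = simulate_site_scores(profile_with(site_bias=(0,) * 5),
                                   noise_sd=0.0)
        assert rec.mds == 0.0

    def test_saturated_bias_gives_maximum(self):
        rec = simulate_site_scores(profile_with(site_bias=(3,) * 5),
                                   noise_sd=0.0)
        assert rec.mds == 15.0

    def test_half_point_pattern(self):
        """A profile with the (0, 1.5, 0, 0, 1) site pattern scores 2.5."""
        rec = simulate_site_scores(profile_with(site_bias=(0, 1.5, 0, 0, 1)),
                                   noise_sd=0.0)
        assert rec.mds == pytest.approx(2.5)
        assert rec.site_scores == (0.0, 1.5, 0.0, 0.0, 1.0)

    def test_noise_rounds_to_half_steps_in_range(self, profile_mid):
        rec = simulate_site_scores(profile_mid, noise_sd=0.8, seed=7)
        arr = np.asarray(rec.site_scores)
        assert np.allclose(2 * arr, np.round(2 * arr))
        assert arr.min() >= 0 and arr.max() <= 3

    def test_negative_noise_rejected(self, profile_mid):
        with pytest.raises(ValueError):
            simulate_site_scores(profile_mid, noise_sd=-0.1)


class TestArenaRendering:
    def test_seeded_noise_bit_identical(self, arena_small):
        zero = np.zeros((5, 5, 2))
        a = render_arena_frame(arena_small, zero, noise_sd=6.0, seed=4)
        b = render_arena_frame(arena_small, zero, noise_sd=6.0, seed=4)
        assert np.array_equal(a, b)

    def test_overlarge_deflection_refused(self, arena_small):
        dxy = np.zeros((5, 5, 2))
        dxy[0, 0, 0] = 0.6 * arena_small.pitch
        with pytest.raises(ValueError):
            render_arena_frame(arena_small, dxy)

    def test_image_is_uint8_with_dark_disks(self, arena_small):
        img = render_arena_frame(arena_small, np.zeros((5, 5, 2)))
        assert img.dtype == np.uint8
        rest = arena_small.rest_lattice_px()
        cx, cy = rest[0, 0]
        assert img[int(round(cy)), int(round(cx))] < 100
        assert img[5, 5] > 200  # corner background

    def test_tiff_stack_round_trip(self, arena_small, tmp_path):
        import tifffile
        frames = [render_arena_frame(arena_small, np.zeros((5, 5, 2)),
                                     noise_sd=3.0, seed=s) for s in range(3)]
        path = tmp_path / "stack.tif"
        write_tiff_stack(frames, path)
        back = tifffile.imread(path)
        assert back.shape == (3, *arena_small.image_shape)
        assert np.array_equal(back[1], frames[1])


class TestStudySimulation:
    def test_ground_truth_f95_matches_analyzer(self, panel):
        """Generator and analyzer agree by construction: the stored
        per-strain f95 truth is the mean of analyzer-computed per-worm
        f95 values on the generated traces."""
        study = simulate_study(panel[:4], n_worms_strength=5, n_frames=60,
                               seed=2)
        for prof in study.profiles:
            worm_values = [f95(t) for t in study.force_traces
                           if t.strain == prof.name]
            assert study.ground_truth.f95[prof.name] == pytest.approx(
                np.mean(worm_values))

    def test_reproducible_with_seed(self, panel):
        a = simulate_study(panel[:3], n_worms_strength=4, n_frames=50, seed=9)
        b = simulate_study(panel[:3], n_worms_strength=4, n_frames=50, seed=9)
        assert np.array_equal(a.strength_records[0].f95,
                              b.strength_records[0].f95)
        assert np.array_equal(a.burrow_trials[0].counts,
                              b.burrow_trials[0].counts)
        assert a.mds_records[2].site_scores == b.mds_records[2].site_scores

    def test_panel_monotone_in_health(self, panel):
        healths = np.array([p.health for p in panel])
        strength = np.array([p.strength_scale for p in panel])
        endpoint = np.array([expected_endpoint_fraction(p) for p in panel])
        mds_true = np.array([true_mds(p) for p in panel])
        order = np.argsort(healths)
        assert np.all(np.diff(strength[order]) >= 0)
        assert np.all(np.diff(endpoint[order]) >= 0)
        assert np.all(np.diff(mds_true[order]) <= 0)

    def test_profiles_yaml_round_trip(self, panel, tmp_path):
        path = tmp_path / "panel.yaml"
        save_profiles_yaml(panel, path)
        back = load_profiles_yaml(path)
        assert back == panel
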