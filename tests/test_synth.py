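"""Synthetic generators: oscillator, image stacks, tracks, BM traits, studies."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tempoevo import rhythm
from tempoevo.comparative import fit_bm, species_tip_values, standardize_traits
from tempoevo.phylo import Chronogram
from tempoevo.synth import (
    FHNParams,
    IntegrationError,
    PHENOSPACE_PRESETS,
    PlacementError,
    SyntheticStudyConfig,
    pure_birth_chronogram,
    simulate_bm_traits,
    simulate_fhn_series,
    simulate_image_stack,
    simulate_metric_tables,
    simulate_open_field_track,
    simulate_study_dataset,
)


def fhn_ode_period_min(p: FHNParams, t_units: float = 400.0) -> float:
    """Deterministic limit-cycle period via fine ODE integration (oracle)."""

    def f(t, y):
        v, w = y
        return [v - v**3 / 3 - w + p.drive, p.epsilon * (v + p.a - p.b * w)]

    sol = solve_ivp(f, (0, t_units), [0.0, 0.0], rtol=1e-10, atol=1e-12,
                    dense_output=True)
    tt = np.linspace(t_units / 2, t_units, 200_000)
    v = sol.sol(tt)[0]
    up = np.flatnonzero((v[:-1] < 0) & (v[1:] >= 0))
    return float(np.mean(np.diff(tt[up]))) * p.time_unit_min


class TestFHN:
    def test_deterministic_given_seed(self):
        p = FHNParams(noise_sd=0.3, obs_noise_sd=0.1)
        a = simulate_fhn_series(p, 20_000, seed=11)
        b = simulate_fhn_series(p, 20_000, seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_fhn_series(p, 20_000, seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_excitable_regime_settles_to_fixed_point(self):
        p = FHNParams(drive=0.0, noise_sd=0.0, burn_in_s=6 * 3600.0)
        s = simulate_fhn_series(p, p.burn_in_s + 1020 * 30.0, seed=0)
        v = s.values
        rel_range = (v.max() - v.min()) / max(1.0, abs(v.max()))
        assert rel_range < 1e-6

    def test_oscillatory_period_matches_ode_oracle(self):
        p = FHNParams()  # epsilon .08, a .7, b .8, drive .5, noise 0
        oracle = fhn_ode_period_min(p)
        s = simulate_fhn_series(p, p.burn_in_s + 1020 * 30.0, seed=1)
        got = rhythm.series_metrics(s).dominant_period_min
        assert got == pytest.approx(oracle, rel=0.05)

    def test_blowup_reports_step_index(self):
        # a huge effective step makes forward Euler diverge
        p = FHNParams(time_unit_min=1e-4, burn_in_s=10.0)
        with pytest.raises(IntegrationError, match=r"step \d+"):
            simulate_fhn_series(p, 1000.0, seed=0)

    def test_phenospace_presets_span_four_corners(self):
        metrics = {}
        for name, p in PHENOSPACE_PRESETS.items():
            s = simulate_fhn_series(p, p.burn_in_s + 1020 * 30.0, seed=3)
            metrics[name] = rhythm.series_metrics(s)
        betas = {k: m.rhythmicity_beta for k, m in metrics.items()}
        periods = {k: m.dominant_period_min for k, m in metrics.items()}
        assert min(betas["high_beta_short_period"], betas["high_beta_long_period"]) \
            > max(betas["low_beta_short_period"], betas["low_beta_long_period"])
        assert periods["high_beta_short_period"] < periods["high_beta_long_period"]
        assert periods["low_beta_short_period"] < periods["low_beta_long_period"]

    def test_period_monotone_in_time_scaling(self):
        periods = []
        for tu in (0.5, 1.0, 2.0):
            p = FHNParams(noise_sd=0.05, time_unit_min=tu)
            s = simulate_fhn_series(p, p.burn_in_s + 1020 * 30.0, seed=2)
            periods.append(rhythm.series_metrics(s).dominant_period_min)
        assert periods[0] < periods[1] < periods[2]


class TestImageStack:
    def test_static_when_nothing_moves(self):
        stack = simulate_image_stack(10, 5, 0.0, noise_sd=0.0, seed=1)
        for t in range(1, 5):
            np.testing.assert_array_equal(stack.frames[t], stack.frames[0])

    def test_exact_mover_count_by_changed_pixels(self):
        # 3 of 10 blobs jump per transition; each jump swaps two disjoint
        # disks, so the changed-pixel count is exactly 3 x 2 x disk area
        stack = simulate_image_stack(10, 6, 0.3, noise_sd=0.0, seed=4)
        disk_area = (stack.frames[0] < 0.5).sum() / 10
        for t in range(5):
            changed = (stack.frames[t + 1] != stack.frames[t]).sum()
            assert changed == 3 * 2 * disk_area

    def test_placement_error_when_frame_too_small(self):
        with pytest.raises(PlacementError):
            simulate_image_stack(25, 3, 0.5, blob_radius_px=10,
                                 frame_shape=(50, 50))


class TestOpenFieldTrack:
    def test_zero_moving_fraction_is_stationary(self):
        track = simulate_open_field_track(3.0, 20.0, 5.0, 60.0,
                                          moving_fraction=0.0, seed=0)
        assert np.allclose(np.diff(track, axis=0), 0.0)

    def test_bout_step_length_exact(self):
        # 3 BL/s x 20 px / 5 fps = 12 px per moving transition
        track = simulate_open_field_track(3.0, 20.0, 5.0, 120.0,
                                          moving_fraction=0.5, seed=1)
        step = np.sqrt((np.diff(track, axis=0) ** 2).sum(axis=1))
        moving = step > 0
        np.testing.assert_allclose(step[moving], 12.0)
        n_trans = len(step)
        assert moving.sum() == round(0.5 * n_trans)


class TestBMTraits:
    def test_zero_rate_gives_root_state(self, six_tip_tree):
        tips = simulate_bm_traits(six_tip_tree, 0.0, root_state=2.5, seed=0)
        assert all(v == 2.5 for v in tips.values())

    def test_two_tip_star_difference_variance(self):
        tree = Chronogram.from_newick("(A:2.0,B:2.0);")
        draws = simulate_bm_traits(tree, sigma2=1.5, seed=3, n_draws=10_000)
        var = np.var(draws["A"] - draws["B"], ddof=1)
        assert var == pytest.approx(2 * 1.5 * 2.0, rel=0.05)

    def test_tip_covariance_matches_sigma2_C(self, six_tip_tree):
        draws = simulate_bm_traits(six_tip_tree, sigma2=2.0, seed=9,
                                   n_draws=5000)
        C, labels = six_tip_tree.vcv()
        emp = np.cov(draws[labels].to_numpy().T)
        np.testing.assert_allclose(emp, 2.0 * C, atol=0.10 * 2.0 * C.max())

    def test_singular_tree_rejected(self):
        tree = Chronogram.from_newick("((A:0.0,B:0.0):1.0,C:1.0);")
        with pytest.raises(ValueError, match="positive definite"):
            simulate_bm_traits(tree, 1.0, seed=0)


class TestPureBirth:
    def test_shape_and_ultrametricity(self):
        tree = pure_birth_chronogram(22, seed=5)
        assert tree.n_tips == 22
        assert tree.is_ultrametric()
        assert tree.height == pytest.approx(1.0)

    def test_minimum_terminal_branch(self):
        for seed in range(5):
            tree = pure_birth_chronogram(15, seed=seed, min_tip_frac=0.1)
            terminal = [leaf.edge.length for leaf in tree.tree.leaf_node_iter()]
            assert min(terminal) >= 0.1 - 1e-9

    def test_deterministic(self):
        a = pure_birth_chronogram(10, seed=3).to_newick()
        b = pure_birth_chronogram(10, seed=3).to_newick()
        assert a == b


class TestStudyDataset:
    def test_series_count(self):
        cfg = SyntheticStudyConfig(
            n_species=4, colonies_per_species=1, recordings_per_colony=2,
            individuals_per_species=1, colony_series_len=120,
            individual_series_len=80, seed=0)
        ds = simulate_study_dataset(cfg)
        assert len(ds.series) == 4 * (2 + 1)
        assert ds.tree.n_tips == 4
        lens = {(s.level, len(s)) for s in ds.series}
        assert lens == {("colony", 120), ("individual", 80)}

    def test_provenance_and_determinism(self):
        cfg = SyntheticStudyConfig(
            n_species=3, colonies_per_species=1, recordings_per_colony=1,
            individuals_per_species=1, colony_series_len=80,
            individual_series_len=80, seed=7)
        a = simulate_study_dataset(cfg)
        b = simulate_study_dataset(cfg)
        assert a.tree.to_newick() == b.tree.to_newick()
        for sa, sb in zip(a.series, b.series):
            np.testing.assert_array_equal(sa.values, sb.values)
        assert set(a.provenance["species"]) == {"sp01", "sp02", "sp03"}

    def test_metric_tables_shape_and_invariants(self):
        cfg = SyntheticStudyConfig(
            n_species=5, colonies_per_species=2, recordings_per_colony=2,
            individuals_per_species=3, seed=1)
        colony, indiv, tree, prov = simulate_metric_tables(cfg)
        assert len(colony) == 5 * 2 * 2
        assert len(indiv) == 5 * 3
        assert (colony["rhythmicity_beta"] >= 1).all()
        assert (indiv["dominant_period_min"] > 0).all()
        assert tree.n_tips == 5

    def test_rate_ordering_under_3x_interspecific_sd(self):
        # colony rhythm spread 3x the individual spread: the fitted colony
        # rate should exceed the individual rate in nearly every replicate
        wins = 0
        for seed in range(20):
            cfg = SyntheticStudyConfig(
                n_species=16, colonies_per_species=4, recordings_per_colony=1,
                individuals_per_species=4,
                interspecific_sd_colony=(0.6, 0.3),
                interspecific_sd_individual=(0.2, 0.3),
                intraspecific_sd=0.1, seed=seed)
            colony, indiv, tree, _ = simulate_metric_tables(cfg)
            tips_c = standardize_traits(
                species_tip_values(colony, traits=["rhythmicity_beta"]))
            tips_i = standardize_traits(
                species_tip_values(indiv, traits=["rhythmicity_beta"]))
            sc = fit_bm(tree, tips_c["rhythmicity_beta"].to_dict()).sigma2
            si = fit_bm(tree, tips_i["rhythmicity_beta"].to_dict()).sigma2
            wins += sc > si
        assert wins >= 18
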