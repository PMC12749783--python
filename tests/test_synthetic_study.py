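"""Synthetic study generator: bookkeeping, determinism, config echoes."""
import dataclasses

import numpy as np
import pytest

from tonescale.colorspace import LabColor, ita_from_lab
from tonescale.errors import ConfigError
from tonescale.image_color import image_ita, median_rgb
from tonescale.scales import ANATOMIC_SITES, K_MST
from tonescale.synthetic_study import (
    StudyConfig,
    generate,
    implied_kappa,
    rate_with_noise,
    render_patch,
    simulate_scores,
    true_site_color,
)


class TestBookkeeping:
    def test_default_cohort_counts(self, default_study):
        sites = default_study.sites
        assert sites["participant_id"].nunique() == 64
        assert 64 * (5 + 11) <= len(sites) <= 64 * (13 + 11)
        per_part = sites.groupby("participant_id").size()
        assert per_part.min() >= 16 and per_part.max() <= 24
        nonles = sites[sites["site_kind"] == "nonlesional"]
        assert (nonles.groupby("participant_id").size() == 11).all()

    def test_every_site_has_fst(self, default_study):
        assert default_study.sites["fst"].between(1, 6).all()

    def test_colorimeter_coverage_fraction(self, default_study):
        sites = default_study.sites
        measured = sites[sites["colorimeter_L1"].notna()]["participant_id"].nunique()
        assert measured == round(0.734 * 64)

    def test_same_seed_byte_identical(self):
        cfg = StudyConfig(
            participants_per_fst=(1, 1, 1, 1, 1, 1), n_crowd_users=6,
            reads_per_image=4, patch_size=6, master_seed=3,
        )
        s1, s2 = generate(cfg), generate(cfg)
        for attr in ("sites", "images", "crowd", "scores", "truth"):
            assert getattr(s1, attr).to_csv() == getattr(s2, attr).to_csv()
        for key in s1.patches:
            assert (s1.patches[key] == s2.patches[key]).all()

    def test_mean_true_L_decreases_across_mst(self, default_study):
        truth = default_study.truth
        means = truth.groupby("true_mst")["true_L"].mean()
        assert (means.diff().dropna() < 0).all()


class TestTrueSiteColor:
    def test_zero_noise_echoes_class_and_site_mean(self):
        cfg = StudyConfig(mst_within_sd=(0.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        c = true_site_color(cfg, 4, "abdomen", rng)
        assert c.L == pytest.approx(cfg.mst_L_means[3] + cfg.site_L_offsets["abdomen"])
        assert c.b == pytest.approx(cfg.mst_b_means[3] + cfg.site_b_offsets["abdomen"])

    def test_sole_lighter_than_forearm(self):
        cfg = StudyConfig(mst_within_sd=(0.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        sole = true_site_color(cfg, 5, "sole", rng)
        forearm = true_site_color(cfg, 5, "forearm", rng)
        assert sole.L > forearm.L

    def test_empirical_sd_matches_config(self):
        cfg = StudyConfig()
        rng = np.random.default_rng(42)
        draws = np.array(
            [true_site_color(cfg, 5, "chest", rng).L for _ in range(10_000)]
        )
        assert abs(draws.std() - cfg.mst_within_sd[0]) / cfg.mst_within_sd[0] < 0.05


class TestRateWithNoise:
    def test_zero_noise_kernel_is_identity(self, rng):
        truth = rng.integers(1, 11, 100)
        out = rate_with_noise(truth, {0: 1.0}, K_MST, rng)
        assert (out == truth).all()

    def test_kernel_self_convolution_agreement_rate(self):
        # Two independent raters with (0.7, 0.15, 0.15): exact agreement
        # converges to 0.7^2 + 2*0.15^2 = 0.535 away from the scale ends.
        rng = np.random.default_rng(9)
        kernel = {-1: 0.15, 0: 0.70, 1: 0.15}
        truth = np.full(100_000, 5)
        r1 = rate_with_noise(truth, kernel, K_MST, rng)
        r2 = rate_with_noise(truth, kernel, K_MST, rng)
        assert (r1 == r2).mean() == pytest.approx(0.535, abs=0.01)

    def test_clipping_keeps_ratings_in_range(self, rng):
        truth = np.concatenate([np.ones(500, int), np.full(500, 10)])
        out = rate_with_noise(truth, {-2: 0.25, 0: 0.5, 2: 0.25}, K_MST, rng)
        assert out.min() >= 1 and out.max() <= 10


class TestRenderPatch:
    def test_zero_offset_recovers_ita(self):
        lab = LabColor(60.0, 10.0, 16.0)
        got = image_ita(render_patch(lab, (0.0, 0.0), size=8, noise_sd=0.0)).value
        assert abs(got - ita_from_lab(lab).value) <= 1.5

    def test_configured_L_shift_recovered(self):
        from tonescale.colorspace import rgb_to_lab

        lab = LabColor(55.0, 10.0, 16.0)
        dL = 6.0
        shifted = render_patch(lab, (dL, 0.0), size=8, noise_sd=0.0)
        got = rgb_to_lab(median_rgb(shifted))
        assert got.L == pytest.approx(lab.L + dL, abs=1.0)

    def test_mode_offsets_shift_extracted_b(self):
        from tonescale.colorspace import rgb_to_lab

        cfg = StudyConfig()
        lab = LabColor(55.0, 10.0, 16.0)
        pol = rgb_to_lab(median_rgb(render_patch(lab, cfg.dermoscopy_mode_offsets["P-C"], 8, 0.0)))
        nonpol = rgb_to_lab(median_rgb(render_patch(lab, cfg.dermoscopy_mode_offsets["NP-C"], 8, 0.0)))
        assert pol.b > nonpol.b  # polarized renders yellower by construction


class TestSimulateScores:
    def test_scores_within_percent_range(self, rng):
        cfg = StudyConfig()
        s = simulate_scores(rng.integers(1, 11, 1000), cfg, rng)
        assert (s >= 0).all() and (s <= 100).all()

    def test_dark_shade_hump_in_means(self, rng):
        cfg = StudyConfig()
        low = simulate_scores(np.full(1000, 3), cfg, rng).mean()
        high = simulate_scores(np.full(1000, 9), cfg, rng).mean()
        assert high > low

    def test_high_concentration_nearly_constant(self, rng):
        cfg = dataclasses.replace(StudyConfig(), score_concentration=1e7)
        s = simulate_scores(np.full(200, 5), cfg, rng)
        assert s.std() < 0.1


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"participants_per_fst": (1, 1, 1)},
            {"mst_L_means": tuple(np.linspace(30, 75, 10))},  # increasing
            {"mst_rater_kernel": {0: 0.5, 1: 0.4}},  # does not sum to 1
            {"colorimeter_coverage": 1.4},
            {"score_mu": tuple([0.5] * 9 + [1.5])},
            {"mst_within_sd": (-1.0, 0.5, 0.5)},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ConfigError):
            generate(dataclasses.replace(StudyConfig(), **overrides))


class TestImpliedValues:
    def test_zero_noise_kernel_implies_perfect_kappa(self, rng):
        truth = rng.integers(1, 11, 500)
        assert implied_kappa(truth, {0: 1.0}, K_MST) == pytest.approx(1.0)

    def test_noisier_kernel_implies_lower_kappa(self, rng):
        truth = rng.integers(1, 11, 500)
        tight = implied_kappa(truth, {-1: 0.05, 0: 0.9, 1: 0.05}, K_MST)
        loose = implied_kappa(truth, {-1: 0.25, 0: 0.5, 1: 0.25}, K_MST)
        assert tight > loose


def test_lesional_sites_use_standard_anatomic_vocabulary(default_study):
    assert default_study.sites["anatomic_site"].isin(ANATOMIC_SITES).all()
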