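"""Agreement statistics against definition-level oracles and references."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from tonescale.agreement import (
    agreement_heatmap,
    chi_squared_independence,
    concordance_by_class,
    icc_agreement,
    linear_weighted_kappa,
    paired_mean_difference,
)
from tonescale.errors import ZeroExpected, ZeroVariance, ZeroVarianceDifferences

from .oracles import icc_oracle, kappa_oracle


class TestWeightedKappa:
    def test_perfect_agreement(self):
        a = np.array([1, 2, 3, 2, 1, 3])
        assert linear_weighted_kappa(a, a, 3).kappa == pytest.approx(1.0)

    def test_degenerate_marginals_flagged_not_zero(self):
        res = linear_weighted_kappa([2, 2, 2], [2, 2, 2], 5)
        assert res.degenerate and np.isnan(res.kappa)

    def test_three_by_three_example_matches_oracle(self):
        counts = [[4, 1, 0], [1, 4, 1], [0, 1, 4]]
        a, b = [], []
        for i in range(3):
            for j in range(3):
                a += [i + 1] * counts[i][j]
                b += [j + 1] * counts[i][j]
        res = linear_weighted_kappa(a, b, 3)
        assert res.kappa == pytest.approx(kappa_oracle(a, b, 3), abs=1e-12)

    def test_random_instances_match_oracle_and_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(30):
            k = int(rng.integers(2, 8))
            n = int(rng.integers(2, 12))
            a = rng.integers(1, k + 1, n)
            b = rng.integers(1, k + 1, n)
            res = linear_weighted_kappa(a, b, k)
            expected = kappa_oracle(list(a), list(b), k)
            if expected is None:
                assert res.degenerate
                continue
            assert res.kappa == pytest.approx(expected, abs=1e-10)
            ref = cohen_kappa_score(a, b, labels=list(range(1, k + 1)), weights="linear")
            assert res.kappa == pytest.approx(ref, abs=1e-9)

    def test_permuted_ratings_give_chance_level(self, rng):
        a = rng.integers(1, 11, 5000)
        b = rng.permutation(a)
        assert abs(linear_weighted_kappa(a, b, 10).kappa) < 0.05

    def test_symmetric_under_rater_swap(self, rng):
        a = rng.integers(1, 6, 40)
        b = rng.integers(1, 6, 40)
        assert linear_weighted_kappa(a, b, 5).kappa == pytest.approx(
            linear_weighted_kappa(b, a, 5).kappa, abs=1e-12
        )

    def test_never_exceeds_one(self, rng):
        for _ in range(20):
            a = rng.integers(1, 5, 30)
            b = rng.integers(1, 5, 30)
            assert linear_weighted_kappa(a, b, 4).kappa <= 1.0 + 1e-12


class TestIcc:
    def test_identical_repeats_distinct_subjects(self):
        x = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        assert icc_agreement(x).icc == pytest.approx(1.0)

    def test_zero_between_subject_variance_raises(self):
        with pytest.raises(ZeroVariance):
            icc_agreement(np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_seeded_anova_matches_oracle(self, rng):
        subj = rng.normal(0, 2, 4)
        x = subj[:, None] + rng.normal(0, 1, (4, 3))
        assert icc_agreement(x).icc == pytest.approx(icc_oracle(x.tolist()), abs=1e-10)

    def test_random_instances_match_oracle_and_pingouin(self, rng):
        import pingouin as pg

        for _ in range(10):
            n = int(rng.integers(3, 10))
            m = int(rng.integers(2, 5))
            x = rng.normal(0, 1, (n, m)) + rng.normal(0, 2, (n, 1))
            ours = icc_agreement(x).icc
            assert ours == pytest.approx(icc_oracle(x.tolist()), abs=1e-10)
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), m),
                    "rater": np.tile(np.arange(m), n),
                    "value": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(long, "subject", "rater", "value")
            # ICC(A,1): absolute agreement, single measurement == ICC(2,1).
            ref_icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert ours == pytest.approx(ref_icc2, abs=1e-8)

    def test_iid_repeats_converge_to_zero(self, rng):
        x = rng.normal(0, 1, (2000, 3))
        assert abs(icc_agreement(x).icc) < 0.05

    def test_variance_ratio_recovery(self, rng):
        subj = rng.normal(0, 2, 2000)  # sigma_s^2 = 4, sigma_e^2 = 1 -> ICC 0.8
        x = subj[:, None] + rng.normal(0, 1, (2000, 3))
        assert icc_agreement(x).icc == pytest.approx(0.8, abs=0.05)


class TestPairedMeanDifference:
    def test_identical_vectors_convention(self):
        res = paired_mean_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_shift_raises(self):
        with pytest.raises(ZeroVarianceDifferences):
            paired_mean_difference([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_t_statistic_matches_closed_form_and_scipy(self, rng):
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0.5, 1, 10)
        res = paired_mean_difference(x, y)
        d = y - x
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        ref = sstats.ttest_rel(y, x)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_confidence_interval_brackets_mean(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(1.0, 0.5, 30)
        res = paired_mean_difference(x, y)
        assert res.ci_low < res.mean_difference < res.ci_high


class TestChiSquared:
    def test_independent_table_is_zero(self):
        row = np.array([1.0, 2.0, 3.0])
        col = np.array([2.0, 5.0])
        table = np.outer(row, col)
        assert chi_squared_independence(table).statistic == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_two_by_two(self):
        res = chi_squared_independence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1

    def test_dof_of_six_by_four(self):
        table = np.ones((6, 4))
        assert chi_squared_independence(table).dof == 15

    def test_matches_scipy_without_correction(self, rng):
        table = rng.integers(1, 30, (3, 4)).astype(float)
        res = chi_squared_independence(table)
        ref = sstats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 20, (4, 3)).astype(float)
        perm = table[rng.permutation(4)][:, rng.permutation(3)]
        assert chi_squared_independence(table).statistic == pytest.approx(
            chi_squared_independence(perm).statistic, abs=1e-10
        )

    def test_zero_expected_raises(self):
        with pytest.raises(ZeroExpected):
            chi_squared_independence([[1, 0], [2, 0]])


class TestConcordance:
    def test_identity_table(self):
        res = concordance_by_class(np.eye(4) * 5)
        assert res.overall == 100.0
        assert np.allclose(res.per_class, 100.0)

    def test_per_class_fraction(self):
        table = np.array([[5.0, 15.0], [0.0, 10.0]])
        res = concordance_by_class(table)
        assert res.per_class[0] == pytest.approx(25.0)

    def test_overall_trace_over_total(self):
        assert concordance_by_class([[4, 1], [1, 4]]).overall == pytest.approx(80.0)

    def test_empty_row_undefined(self):
        res = concordance_by_class([[3.0, 1.0], [0.0, 0.0]])
        assert np.isnan(res.per_class[1])


class TestAgreementHeatmap:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["anatomic_site", "site_kind", "r1", "r2"])

    def test_perfect_sites_all_ones(self):
        rows = [("arm", "nonlesional", v, v) for v in (1, 2, 3)] + [
            ("leg", "nonlesional", v, v) for v in (2, 3, 4)
        ]
        out = agreement_heatmap(self._frame(rows), "r1", "r2", 5)
        assert np.allclose(out["kappa"].dropna(), 1.0)

    def test_all_row_is_pooled_not_mean(self, rng):
        rows = []
        for site in ("arm", "leg"):
            for _ in range(30):
                a = int(rng.integers(1, 6))
                b = int(np.clip(a + rng.integers(-1, 2), 1, 5))
                rows.append((site, "nonlesional", a, b))
        df = self._frame(rows)
        out = agreement_heatmap(df, "r1", "r2", 5)
        pooled = linear_weighted_kappa(df["r1"], df["r2"], 5).kappa
        all_row = float(out.loc[out["group"] == "all", "kappa"].iloc[0])
        assert all_row == pytest.approx(pooled, abs=1e-12)

    def test_site_ordering_tracks_noise_level(self, rng):
        # Noisier rater pairs at one site must score lower kappa.
        rows = []
        for _ in range(400):
            a = int(rng.integers(1, 11))
            rows.append(("clean", "nonlesional", a, int(np.clip(a + rng.choice([-1, 0, 1], p=[0.05, 0.9, 0.05]), 1, 10))))
            a = int(rng.integers(1, 11))
            rows.append(("noisy", "nonlesional", a, int(np.clip(a + rng.choice([-2, -1, 0, 1, 2]), 1, 10))))
        out = agreement_heatmap(self._frame(rows), "r1", "r2", 10).set_index("group")
        assert out.loc["clean", "kappa"] > out.loc["noisy", "kappa"]

    def test_sparse_site_reported_missing(self):
        rows = [("arm", "nonlesional", 1, 1)] + [
            ("leg", "nonlesional", v, v) for v in (1, 2, 3)
        ]
        out = agreement_heatmap(self._frame(rows), "r1", "r2", 5).set_index("group")
        assert np.isnan(out.loc["arm", "kappa"])
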