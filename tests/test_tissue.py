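"""Pfaffl qPCR ratio, IHC scoring, and genotype-stratified statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwaspeaks.tissue import (
    IhcCore,
    PatientRecord,
    QpcrMeasurement,
    efficiency_from_slope,
    genotype_table_test,
    ihc_patient_score,
    pearson_corr,
    pfaffl_ratio,
    relative_expression_table,
    stratified_expression_report,
    welch_compare,
)


class TestPfafflRatio:
    def test_equal_efficiencies_and_deltas_give_ratio_one(self):
        assert pfaffl_ratio(2.0, 1.3, 2.0, 1.3) == pytest.approx(1.0)

    def test_one_cycle_doubling(self):
        assert pfaffl_ratio(2.0, 1.0, 2.0, 0.0) == pytest.approx(2.0)

    def test_log_space_oracle(self):
        # R computed independently in log space
        want = math.exp(2.5 * math.log(1.9) - 1.0 * math.log(1.85))
        assert pfaffl_ratio(1.9, 2.5, 1.85, 1.0) == pytest.approx(want, rel=1e-12)

    def test_reduces_to_two_power_minus_ddct_when_efficiency_two(self, rng):
        for dct_t, dct_r in rng.normal(0, 3, (100, 2)):
            ddct = dct_r - dct_t  # ΔΔCt with ΔCt = calibrator − sample
            assert pfaffl_ratio(2.0, dct_t, 2.0, dct_r) == pytest.approx(
                2.0 ** (-ddct), rel=1e-12
            )

    def test_efficiency_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            pfaffl_ratio(1.0, 1.0, 2.0, 1.0)

    def test_efficiency_from_standard_curve_slope(self):
        assert efficiency_from_slope(-1 / math.log10(2)) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            efficiency_from_slope(3.32)


class TestIhcScore:
    def _cores(self, pairs, tissue="cancer"):
        return [IhcCore("pt1", tissue, i + 1, inten, pct)
                for i, (inten, pct) in enumerate(pairs)]

    def test_uniform_cores(self):
        assert ihc_patient_score(self._cores([(10, 50)] * 3)) == pytest.approx(500)

    def test_single_core_is_its_own_mean(self):
        assert ihc_patient_score(self._cores([(8, 25)])) == pytest.approx(200)

    def test_mean_of_products_hand_computed(self):
        cores = self._cores([(8, 25), (12, 50), (10, 40)])
        assert ihc_patient_score(cores) == pytest.approx(400)  # mean(200,600,400)

    def test_core_order_invariant_and_bounded_by_max(self, rng):
        pairs = [(float(i), float(p)) for i, p in
                 zip(rng.uniform(0, 20, 3), rng.uniform(0, 100, 3))]
        base = ihc_patient_score(self._cores(pairs))
        assert ihc_patient_score(self._cores(pairs[::-1])) == pytest.approx(base)
        assert base <= max(i * p for i, p in pairs)

    def test_mixed_tissue_types_rejected(self):
        cores = [IhcCore("pt1", "benign", 1, 10, 50),
                 IhcCore("pt1", "cancer", 2, 10, 50)]
        with pytest.raises(ValueError, match="tissue"):
            ihc_patient_score(cores)


def welch_oracle(a, b):
    """Closed-form Welch statistic, Satterthwaite df, and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestGroupComparisons:
    def test_identical_groups_give_t_zero_p_one(self):
        t, df, p = welch_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self, rng):
        a = rng.normal(0, 1e-6, 4)
        b = 1 + rng.normal(0, 1e-6, 4)
        assert welch_compare(a, b)[2] < 1e-6

    def test_welch_matches_closed_form_oracle(self, rng):
        for _ in range(100):
            a = rng.normal(0, 2, int(rng.integers(3, 30)))
            b = rng.normal(1, 1, int(rng.integers(3, 30)))
            got = welch_compare(a, b)
            want = welch_oracle(a, b)
            assert got == pytest.approx(want, abs=1e-10)

    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_matches_t_transform_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, p = pearson_corr(x, y)
            sx, sy = x - x.mean(), y - y.mean()
            r_want = (sx @ sy) / math.sqrt((sx @ sx) * (sy @ sy))
            t = r_want * math.sqrt((n - 2) / (1 - r_want ** 2))
            p_want = 2 * stats.t.sf(abs(t), n - 2)
            assert r == pytest.approx(r_want, abs=1e-10)
            assert p == pytest.approx(p_want, abs=1e-10)

    def test_zero_variance_correlation_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_chi_square_identical_rows_give_zero(self):
        chi2, df, p = genotype_table_test([[10, 20, 30], [10, 20, 30]])
        assert chi2 == pytest.approx(0.0) and df == 2 and p == pytest.approx(1.0)

    def test_chi_square_diagonal_2x2_hand_computed(self):
        chi2, df, p = genotype_table_test([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0) and df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            genotype_table_test([[0, 0], [5, 5]])


class TestStratifiedReport:
    def _cohort(self, genotypes, scores, tissue="cancer"):
        patients = [PatientRecord(f"p{i}", {"rs1": g})
                    for i, g in enumerate(genotypes)]
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(len(scores))],
            "tissue": tissue,
            "score": scores,
        })
        return df, patients

    def test_planted_negative_effect_detected(self, rng):
        genos = ["T/G"] * 50 + ["T/T"] * 50
        scores = np.concatenate([rng.normal(-1, 1, 50), rng.normal(0, 1, 50)])
        df, patients = self._cohort(genos, scores)
        (entry,) = stratified_expression_report(df, patients, "rs1", "G",
                                                strata=("cancer",))
        assert entry["mean_carrier"] < entry["mean_noncarrier"]
        assert entry["p"] < 0.05

    def test_dominant_model_pools_het_and_hom(self, rng):
        genos = ["G/G", "T/G", "T/T", "T/T", "T/G"]
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]
        df, patients = self._cohort(genos, scores)
        (entry,) = stratified_expression_report(df, patients, "rs1", "G",
                                                strata=("all",))
        assert entry["n_carrier"] == 3 and entry["n_noncarrier"] == 2
        assert entry["per_genotype_n"] == {"G/G": 1, "T/G": 2, "T/T": 2}

    def test_single_carrier_stratum_skipped_with_warning(self, rng):
        genos = ["T/G"] + ["T/T"] * 9
        df, patients = self._cohort(genos, list(rng.normal(size=10)))
        with pytest.warns(UserWarning, match="skipped"):
            (entry,) = stratified_expression_report(df, patients, "rs1", "G",
                                                    strata=("all",))
        assert entry["skipped"]


class TestRelativeExpressionTable:
    def test_recovers_known_ratio(self):
        # choose Ct so that the Pfaffl ratio is exactly 4 with E = 2
        ms = [QpcrMeasurement("s1", "target", 23.0, 2.0),   # ΔCt_t = 25−23 = 2
              QpcrMeasurement("s1", "reference", 24.0, 2.0)]  # ΔCt_r = 0
        df = relative_expression_table(ms, 25.0, 24.0)
        assert df.loc[0, "ratio"] == pytest.approx(4.0)

    def test_missing_pair_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            relative_expression_table(
                [QpcrMeasurement("s1", "target", 23.0, 2.0)], 25.0, 24.0
            )
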