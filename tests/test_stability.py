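import math

import numpy as np
import pytest

from cwitnorms import (
    ICCResult,
    RCIMaterials,
    RetestPair,
    Subtest,
    filter_retest,
    icc_a1,
    norwegian_norms,
    rci,
)
from cwitnorms.stability import stability_band, stability_report
from cwitnorms.synthetic_cohort import RetestSpec, SimulationSpec, simulate_cohort


def _pairs(baseline, followup, interval=3.4):
    return [
        RetestPair(id=f"R{i}", baseline=float(b), followup=float(f),
                   interval_years=interval)
        for i, (b, f) in enumerate(zip(baseline, followup))
    ]


class TestFilterRetest:
    def test_all_within_limit(self):
        retained, excluded = filter_retest(_pairs([1, 2, 3], [1, 2, 3]))
        assert len(retained) == 3 and excluded == 0

    def test_one_over_limit(self):
        pairs = [
            RetestPair("a", 10, 11, 3.4),
            RetestPair("b", 10, 11, 6.0),
        ]
        retained, excluded = filter_retest(pairs)
        assert [p.id for p in retained] == ["a"] and excluded == 1

    def test_published_sample_counts(self, rng):
        """357 pairs, 22 beyond the 5-year limit -> 335 analyzed."""
        intervals = np.concatenate([rng.uniform(1, 5, 335), rng.uniform(5.01, 8, 22)])
        rng.shuffle(intervals)
        pairs = [
            RetestPair(f"p{i}", 10, 10, float(iv)) for i, iv in enumerate(intervals)
        ]
        retained, excluded = filter_retest(pairs, max_interval=5.0)
        assert len(retained) == 335 and excluded == 22


def _anova_oracle(data):
    """Direct two-way ANOVA sums of squares for the ICC(A,1) formula."""
    n, k = data.shape
    grand = data.mean()
    msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = (
        np.sum((data - grand) ** 2)
        - k * np.sum((data.mean(axis=1) - grand) ** 2)
        - n * np.sum((data.mean(axis=0) - grand) ** 2)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestICC:
    def test_perfect_agreement(self):
        res = icc_a1(_pairs([3, 7, 9, 12, 15], [3, 7, 9, 12, 15]))
        assert res.icc == pytest.approx(1.0)
        assert res.ci95 == (1.0, 1.0)

    def test_six_subject_toy_matches_anova_oracle(self):
        base = [7, 9, 10, 11, 13, 6]
        follow = [8, 9, 11, 12, 12, 7]
        res = icc_a1(_pairs(base, follow))
        oracle = _anova_oracle(np.column_stack([base, follow]).astype(float))
        assert res.icc == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_icc2(self):
        """Independent library cross-check of both the point estimate and
        the F-based 95% CI."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        base = rng.normal(50, 10, 40)
        follow = 0.8 * (base - 50) + 50 + rng.normal(0, 5, 40)
        res = icc_a1(_pairs(base, follow))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": np.tile(["t1", "t2"], 40),
                "scores": np.column_stack([base, follow]).ravel(),
            }
        )
        icc_tab = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        row = icc_tab.loc["ICC(A,1)"]
        ci_col = "CI95" if "CI95" in icc_tab.columns else "CI95%"
        assert res.icc == pytest.approx(row["ICC"], abs=1e-6)
        # pingouin prints the CI rounded to two decimals
        assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=0.006)
        assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=0.006)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            base = rng.normal(10, 3, n)
            follow = base * 0.7 + rng.normal(0, 2, n)
            res = icc_a1(_pairs(base, follow))
            data = np.column_stack([base, follow])
            assert res.icc == pytest.approx(_anova_oracle(data), abs=1e-10)
            assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_shift_both_occasions_invariant(self, rng):
        base = rng.normal(10, 3, 30)
        follow = base + rng.normal(0, 1.5, 30)
        r1 = icc_a1(_pairs(base, follow))
        r2 = icc_a1(_pairs(base + 7.0, follow + 7.0))
        assert r1.icc == pytest.approx(r2.icc, abs=1e-10)

    def test_shift_one_occasion_lowers_absolute_agreement(self, rng):
        base = rng.normal(10, 3, 60)
        follow = base + rng.normal(0, 1.0, 60)
        r1 = icc_a1(_pairs(base, follow))
        r2 = icc_a1(_pairs(base, follow + 4.0))
        assert r2.icc < r1.icc - 0.1

    def test_degenerate_subject_variance(self):
        with pytest.raises(ValueError, match="variance"):
            icc_a1(_pairs([5, 5, 5, 5, 5], [5, 5, 5, 5, 5]))

    def test_bands(self):
        assert stability_band(0.4) == "poor"
        assert stability_band(0.6) == "moderate"
        assert stability_band(0.8) == "good"
        assert stability_band(0.95) == "excellent"


class TestRCI:
    MATERIALS = RCIMaterials(sd_baseline=3.0, r12=0.75)

    def test_no_change_is_zero(self):
        assert rci(10, 10, self.MATERIALS).statistic == 0.0
        assert rci(10, 10, self.MATERIALS, "practice_adjusted").statistic == 0.0

    def test_closed_form_evaluation(self):
        # SD 3, r .75 -> SEM 1.5, SEdiff = 1.5*sqrt(2) ~ 2.121; change +5
        assert self.MATERIALS.sem == pytest.approx(1.5)
        assert self.MATERIALS.se_diff == pytest.approx(1.5 * math.sqrt(2))
        res = rci(10, 15, self.MATERIALS)
        assert res.statistic == pytest.approx(5 / (1.5 * math.sqrt(2)), abs=1e-6)
        assert res.statistic == pytest.approx(2.357, abs=1e-3)
        assert res.significant

    def test_practice_adjustment_shifts_statistic(self):
        m = RCIMaterials(sd_baseline=3.0, r12=0.75, mean_practice=2.0)
        plain = rci(10, 15, m, "jacobson_truax")
        adj = rci(10, 15, m, "practice_adjusted")
        assert adj.statistic == pytest.approx(plain.statistic - 2.0 / m.se_diff)

    def test_regression_based_zero_at_prediction(self):
        m = RCIMaterials(sd_baseline=3.0, r12=0.75, slope=0.9, intercept=1.5, see=2.0)
        predicted = 0.9 * 12 + 1.5
        res = rci(12, predicted, m, "regression_based")
        assert res.statistic == 0.0 and not res.significant

    def test_methods_coincide_under_identity_regression(self):
        """Slope 1, intercept 0, SEE = SEdiff, no practice effect: all three
        methods give the same statistic."""
        m = RCIMaterials(
            sd_baseline=3.0, r12=0.75, mean_practice=0.0,
            slope=1.0, intercept=0.0, see=RCIMaterials(3.0, 0.75).se_diff,
        )
        for base, follow in [(8, 13), (12, 9), (10, 10)]:
            jt = rci(base, follow, m, "jacobson_truax").statistic
            pa = rci(base, follow, m, "practice_adjusted").statistic
            rb = rci(base, follow, m, "regression_based").statistic
            assert jt == pytest.approx(pa) == pytest.approx(rb)

    def test_invalid_r12(self):
        with pytest.raises(ValueError):
            RCIMaterials(sd_baseline=3.0, r12=1.2)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown"):
            rci(10, 12, self.MATERIALS, "bogus")


class TestStabilityReport:
    def test_identical_baseline_followup_gives_icc_one(self):
        synth = simulate_cohort(SimulationSpec(n=80, seed=3))
        from dataclasses import replace

        records = [
            replace(r, interval_years=3.0, times_followup=dict(r.times))
            for r in synth.cohort
        ]
        from cwitnorms import CohortTable

        cohort = CohortTable(records=records)
        rep = stability_report(cohort, norwegian_norms())
        for st, res in rep.icc.items():
            assert res.icc == pytest.approx(1.0)

    def test_target_icc_recovered_single_seed(self):
        rt = RetestSpec(target_icc={Subtest.CWIT3: 0.76})
        synth = simulate_cohort(
            SimulationSpec(n=335, seed=21, retest=rt), with_retest=True
        )
        rep = stability_report(synth.cohort, norwegian_norms())
        res = rep.icc[Subtest.CWIT3]
        assert res.ci95[0] <= 0.76 <= res.ci95[1]
        assert res.band in ("moderate", "good")

    def test_long_intervals_excluded(self):
        rt = RetestSpec(target_icc={Subtest.CWIT3: 0.7}, p_over_limit=0.3)
        synth = simulate_cohort(
            SimulationSpec(n=200, seed=8, retest=rt), with_retest=True
        )
        rep = stability_report(synth.cohort, norwegian_norms())
        assert rep.n_excluded > 0
        assert rep.icc[Subtest.CWIT3].n < 200

    def test_materials_table_contents(self):
        rt = RetestSpec(target_icc={Subtest.CWIT3: 0.76, Subtest.CWIT4: 0.70})
        synth = simulate_cohort(
            SimulationSpec(n=300, seed=5, retest=rt), with_retest=True
        )
        rep = stability_report(synth.cohort, norwegian_norms())
        m = rep.materials[Subtest.CWIT3]
        assert 0 < m.r12 < 1
        assert m.sd_baseline > 0 and m.see > 0
        cols = set(rep.summary_stats.columns)
        assert {"mean_baseline", "sd_followup", "r12", "icc"} <= cols

    def test_missing_intervals_is_schema_error(self, two_record_cohort):
        with pytest.raises(ValueError, match="longitudinal"):
            stability_report(two_record_cohort, norwegian_norms())
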