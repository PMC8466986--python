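"""Contingency tests, Kaplan-Meier/log-rank, Cox regression, marker scans."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msatprof.clinstats import (
    ClinicalRecord,
    contingency_test,
    cox_fit,
    km_fit,
    logrank_test,
    marker_outcome_scan,
    read_clinical_table,
    records_to_frame,
    truncate_followup,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def exact_2xk_oracle(table):
    """Probability-based two-sided exact p for a 2xK table by exhaustive
    enumeration of all tables with the observed margins."""
    table = np.asarray(table)
    row, col = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()

    def prob(top):
        lp = math.lgamma(row[0] + 1) + math.lgamma(row[1] + 1) - math.lgamma(n + 1)
        for cj, tj in zip(col, top):
            lp += math.lgamma(cj + 1) - math.lgamma(tj + 1) - math.lgamma(cj - tj + 1)
        return math.exp(lp)

    tops = [[]]
    for cj in col[:-1]:
        tops = [t + [x] for t in tops for x in range(cj + 1)]
    tops = [
        t + [row[0] - sum(t)]
        for t in tops
        if 0 <= row[0] - sum(t) <= col[-1]
    ]
    p_obs = prob(table[0])
    return sum(prob(t) for t in tops if prob(t) <= p_obs * (1 + 1e-9))


class TestContingency:
    def test_flat_table_is_null(self):
        stat, p, method = contingency_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert method == "chi-square"

    def test_small_table_switches_to_fisher(self):
        stat, p, method = contingency_test([[1, 9], [8, 2]])
        assert method == "fisher"
        assert p == pytest.approx(fisher_oracle(1, 9, 8, 2))

    @pytest.mark.parametrize(
        "table",
        [[[1, 9], [8, 2]], [[3, 4], [4, 3]], [[0, 5], [5, 0]], [[2, 12], [9, 1]]],
    )
    def test_fisher_matches_enumeration_oracle(self, table):
        _, p, _ = contingency_test(table, method="fisher")
        assert p == pytest.approx(fisher_oracle(*np.ravel(table)), rel=1e-9)

    @pytest.mark.parametrize(
        "table",
        [[[2, 3, 1], [4, 0, 5]], [[1, 1, 4], [3, 2, 0]], [[5, 0, 2], [1, 4, 3]]],
    )
    def test_exact_2xk_matches_enumeration_oracle(self, table):
        _, p, method = contingency_test(table, method="fisher")
        assert method == "exact-2xK"
        assert p == pytest.approx(exact_2xk_oracle(table), rel=1e-9)

    def test_chi2_null_calibration(self):
        """With equal true proportions and ample counts, chi-square p-values
        reject at roughly the nominal rate."""
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.binomial(120, 0.4)
            y = rng.binomial(120, 0.4)
            _, p, _ = contingency_test([[x, 120 - x], [y, 120 - y]], method="chi2")
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test([[0, 0], [5, 5]])


class TestKaplanMeier:
    def test_all_events_equals_empirical_survival(self):
        res = km_fit([1, 2, 3], [1, 1, 1])
        curve = res.curves["0"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        res = km_fit([5, 10, 15], [0, 0, 0])
        assert (res.curves["0"]["survival"] == 1.0).all()

    def test_mixed_set_matches_hand_product_limit(self):
        # subjects: events at 2, 5, 8; censored at 3, 6, 9
        # S(2)=5/6, S(5)=5/6*3/4=0.625, S(8)=0.625*1/2=0.3125
        res = km_fit([2, 3, 5, 6, 8, 9], [1, 0, 1, 0, 1, 0])
        curve = res.curves["0"]
        surv = dict(zip(curve["time"], curve["survival"]))
        assert surv[2.0] == pytest.approx(5 / 6)
        assert surv[5.0] == pytest.approx(5 / 8)
        assert surv[8.0] == pytest.approx(5 / 16)

    def test_curves_are_monotone_from_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        res = km_fit(t, e)
        s = res.curves["0"]["survival"].to_numpy()
        assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_fit([], [])


class TestLogrank:
    def test_duplicated_groups_give_null(self):
        t = [2, 4, 6, 8, 10, 12]
        e = [1, 1, 0, 1, 0, 1]
        stat, p = logrank_test(t + t, e + e, [0] * 6 + [1] * 6)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_toy_statistic_matches_hand_computation(self):
        # group A: events at 1, 2; group B: event at 3, censored at 4
        # observed-minus-expected for A: t=1: 1 - 2/4; t=2: 1 - 1/3;
        # t=3: A no longer at risk, contributes 0 - 0
        # U = 1/2 + 2/3 = 7/6
        # V = (2/4)(2/4) + (1/3)(2/3) = 1/4 + 2/9 = 17/36
        # chi-square = U^2 / V = (7/6)^2 / (17/36) = 49/17
        t = [1, 2, 3, 4]
        e = [1, 1, 1, 0]
        g = ["A", "A", "B", "B"]
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(49 / 17, rel=1e-6)
        assert p == pytest.approx(1 - stats.chi2.cdf(49 / 17, df=1), rel=1e-6)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        g = rng.integers(0, 2, 40)
        stat1, p1 = logrank_test(t, e, g)
        stat2, p2 = logrank_test(t, e, 1 - g)
        assert stat1 == pytest.approx(stat2) and p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


def _survival_frame(rng, n, hr=1.0, prevalence=0.5):
    arm = (rng.random(n) < prevalence).astype(int)
    rate = np.log(2) / 40 * np.where(arm == 1, hr, 1.0)
    true_t = rng.exponential(1 / rate)
    censor = rng.uniform(20, 90, n)
    rows = []
    for i in range(n):
        rows.append(
            ClinicalRecord(
                patient_id=f"P{i}",
                os_months=float(min(true_t[i], censor[i])),
                os_event=bool(true_t[i] <= censor[i]),
                pfs_months=float(min(true_t[i], censor[i])),
                pfs_event=bool(true_t[i] <= censor[i]),
            )
        )
    df = records_to_frame(rows)
    df["arm"] = arm
    return df


class TestCox:
    def test_null_covariate_hr_near_one(self):
        df = _survival_frame(np.random.default_rng(3), 400, hr=1.0)
        res = cox_fit(df, ["arm"], "OS")
        cov = res.covariates["arm"]
        assert cov["ci_low"] < 1.0 < cov["ci_high"]

    def test_recovers_true_log_hazard(self):
        df = _survival_frame(np.random.default_rng(4), 500, hr=2.0)
        res = cox_fit(df, ["arm"], "OS")
        cov = res.covariates["arm"]
        assert abs(cov["coef"] - np.log(2)) <= 3 * cov["se"]

    def test_constant_covariate_dropped_with_flag(self):
        df = _survival_frame(np.random.default_rng(5), 100)
        df["always"] = 1.0
        res = cox_fit(df, ["arm", "always"], "OS")
        assert res.dropped.get("always") == "constant"
        assert "arm" in res.covariates

    def test_collinear_covariate_dropped_with_flag(self):
        df = _survival_frame(np.random.default_rng(6), 100)
        df["arm_copy"] = df["arm"] * 2.0
        res = cox_fit(df, ["arm", "arm_copy"], "OS")
        assert res.dropped.get("arm_copy") == "linearly dependent"

    def test_no_events_rejected(self):
        df = _survival_frame(np.random.default_rng(7), 30)
        df["os_event"] = False
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["arm"], "OS")

    def test_score_test_matches_logrank_on_binary_covariate(self):
        """The Cox score statistic for one binary covariate equals the
        log-rank statistic when there are no tied event times."""
        rng = np.random.default_rng(8)
        df = _survival_frame(rng, 120, hr=1.8)
        res = cox_fit(df, ["arm"], "OS")
        stat, p_lr = logrank_test(
            df["os_months"], df["os_event"].astype(int), df["arm"]
        )
        # Wald and score/log-rank p-values agree to leading order
        assert res.covariates["arm"]["p"] == pytest.approx(p_lr, abs=0.02)


class TestScansAndIO:
    def test_truncation_censors_beyond_horizon(self):
        t, e = truncate_followup([10, 60, 80], [1, 1, 1], 60.0)
        assert list(t) == [10, 60, 60]
        assert list(e) == [1, 1, 0]

    def test_clinical_round_trip(self, tmp_path):
        df = _survival_frame(np.random.default_rng(9), 10)
        path = tmp_path / "clinical.csv"
        out = df.drop(columns=["arm"]).copy()
        for col in ("smoking", "drinking", "lymph_node", "chemotherapy",
                    "os_event", "pfs_event"):
            out[col] = out[col].map(lambda v: "" if v is None else int(v))
        out.to_csv(path, index=False)
        back = read_clinical_table(path)
        assert len(back) == 10
        assert back["os_event"].map(type).eq(bool).all()

    def test_marker_scan_flags_effect_and_skips_empty(self, catalog):
        """A locus whose event triples the hazard is flagged; a locus with
        no events is skipped."""
        from msatprof.simdata import SimConfig, generate_cohort
        from msatprof.calling import call_cohort
        from msatprof.classify import build_profiles

        cfg = SimConfig(
            seed=21,
            n_patients=256,
            msi_prob=0.002,
            msi_prob_per_locus={"MCC-10": 0.10},
            marker_effects={"MCC-10:MSI": np.log(3.0)},
            median_os_months=50.0,
        )
        peaks, clinical, truth = generate_cohort(cfg, catalog)
        profiles = build_profiles(call_cohort(peaks, catalog), catalog)
        scan = marker_outcome_scan(
            profiles, clinical, ["MCC-10", "PTEN-1"], endpoint="OS",
            strata=("all",),
        )
        hit = scan[scan["marker"] == "MCC-10"].iloc[0]
        assert hit["p"] < 0.05
        miss = scan[scan["marker"] == "PTEN-1"].iloc[0]
        assert miss["skipped"] != ""

    def test_null_scan_rejects_at_nominal_rate(self, catalog):
        """With no marker effects, few of the scanned loci reach p<0.05."""
        from msatprof.simdata import SimConfig, generate_cohort
        from msatprof.calling import call_cohort
        from msatprof.classify import build_profiles

        cfg = SimConfig(seed=22, n_patients=150)
        peaks, clinical, _ = generate_cohort(cfg, catalog)
        profiles = build_profiles(call_cohort(peaks, catalog), catalog)
        scan = marker_outcome_scan(
            profiles, clinical, catalog.locus_ids, endpoint="OS",
            strata=("all",), event_type="LOH",
        )
        tested = scan[scan["skipped"] == ""]
        assert len(tested) >= 30
        assert (tested["p"] < 0.05).mean() <= 0.15
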