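import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telorisk.risk import (
    build_cohorts,
    followup_years,
    hazard_ratio,
    km_estimate,
    logistic_fit_univariate,
    logrank_test,
    roc_auc,
    stepwise_select,
    survival_records,
)


# ---------------------------------------------------------------------------
# cohort construction


def _annotation():
    rows = [
        # sample, status, tissue, follow-up years, ttp
        ("met_primary", "metastatic", "primary", 3.0, 400.0),
        ("met_specimen", "metastatic", "metastasis", 3.0, 400.0),
        ("aggr", "aggressive", "primary", 5.0, np.nan),
        ("nm_long", "non-metastatic", "primary", 9.0, np.nan),
        ("nm_mid", "non-metastatic", "primary", 7.0, np.nan),
        ("nm_short", "non-metastatic", "primary", 1.5, np.nan),
        ("nm_unknown", "non-metastatic", "primary", np.nan, np.nan),
    ]
    ann = pd.DataFrame(
        [
            {"status": s, "tissue": t, "follow_up_days": fy * 365.25, "ttp_days": ttp}
            for _, s, t, fy, ttp in rows
        ],
        index=[r[0] for r in rows],
    )
    events = pd.DataFrame({"any_event": False}, index=ann.index)
    return ann, events


class TestBuildCohorts:
    def test_inclusion_rules(self):
        ann, events = _annotation()
        classification, ttp, log = build_cohorts(ann, events)
        assert set(classification.index) == {"met_primary", "nm_long"}
        # 7y: excluded from classification (<8) but in TTP cohort (>=2)
        assert set(ttp.index) == {"met_primary", "nm_long", "nm_mid"}
        rules = log.set_index("sample")["rule"]
        assert rules["met_specimen"] == "metastasis_specimen"
        assert rules["aggr"] == "clinically_aggressive"
        assert rules["nm_unknown"] == "unknown_followup"
        assert (log[log["sample"] == "nm_short"]["rule"] == "followup_lt_2y").any()

    def test_contradictory_record_rejected(self):
        ann, events = _annotation()
        ann.loc["nm_long", "ttp_days"] = 100.0
        with pytest.raises(ValueError, match="non-metastatic"):
            build_cohorts(ann, events)

    def test_survival_records_roles(self):
        ann, events = _annotation()
        _, ttp, _ = build_cohorts(ann, events)
        recs = survival_records(ttp, pd.Series(True, index=ttp.index))
        assert recs.loc["met_primary", "event"] and recs.loc["met_primary", "time"] == 400.0
        assert not recs.loc["nm_mid", "event"]
        assert recs.loc["nm_mid", "time"] == pytest.approx(7.0 * 365.25)


# ---------------------------------------------------------------------------
# logistic regression


class TestLogistic:
    def test_or_equals_table_cross_ratio(self):
        # table (30, 24, 9, 36): OR = 30*36 / (24*9) = 5 exactly
        x = pd.Series([True] * 30 + [False] * 24 + [True] * 9 + [False] * 36)
        y = pd.Series([True] * 54 + [False] * 45)
        fit = logistic_fit_univariate(x, y)
        assert fit.params.loc[fit.params.index[0], "odds_ratio"] == pytest.approx(5.0, rel=1e-6)
        assert not fit.separation

    @given(
        a=st.integers(2, 25), b=st.integers(2, 25), c=st.integers(2, 25), d=st.integers(2, 25)
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_or_matches_cross_ratio_on_random_tables(self, a, b, c, d):
        x = pd.Series([True] * a + [False] * b + [True] * c + [False] * d)
        y = pd.Series([True] * (a + b) + [False] * (c + d))
        fit = logistic_fit_univariate(x, y)
        assert fit.params["odds_ratio"].iloc[0] == pytest.approx(a * d / (b * c), rel=1e-5)

    def test_independent_marker_is_null(self):
        x = pd.Series([True, False] * 40)
        y = pd.Series(([True] * 2 + [False] * 2) * 20)
        fit = logistic_fit_univariate(x, y)
        assert fit.params["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["p"].iloc[0] > 0.05

    def test_separation_flag_and_haldane_fallback(self):
        x = pd.Series([True] * 10 + [False] * 10)
        y = x.copy()  # marker present only in cases
        fit = logistic_fit_univariate(x, y)
        assert fit.separation
        assert fit.fallback_or == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))


class TestStepwise:
    @staticmethod
    def _cohort(seed, informative=True, confounded=False):
        rng = np.random.default_rng(seed)
        n = 160
        signal = rng.random(n) < 0.5
        y = np.where(signal, rng.random(n) < 0.75, rng.random(n) < 0.2)
        X = pd.DataFrame({f"noise{i}": rng.random(n) < 0.3 for i in range(3)})
        if informative:
            X["events"] = signal
        if confounded:
            # correlated with the signal but conditionally uninformative
            X["sdhb"] = np.where(signal, rng.random(n) < 0.6, rng.random(n) < 0.25)
        return X, pd.Series(y)

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({f"n{i}": rng.random(100) < 0.3 for i in range(4)})
        y = pd.Series(rng.random(100) < 0.5)
        assert stepwise_select(X, y).selected == []

    def test_informative_variable_found_in_most_seeds(self):
        found = 0
        for seed in range(40):
            X, y = self._cohort(seed)
            sel = stepwise_select(X, y).selected
            found += "events" in sel
        assert found >= 38  # >= 95% of seeds

    def test_confounded_covariate_dropped_in_favor_of_events(self):
        kept_events, kept_sdhb = 0, 0
        for seed in range(25):
            X, y = self._cohort(seed, confounded=True)
            sel = stepwise_select(X, y).selected
            kept_events += "events" in sel
            kept_sdhb += "sdhb" in sel
        assert kept_events >= 23
        assert kept_sdhb <= 6  # adds no conditional information, rarely retained


# ---------------------------------------------------------------------------
# ROC / AUC


class TestRocAuc:
    def test_perfect_dichotomous_marker(self):
        marker = np.r_[np.ones(20), np.zeros(30)]
        labels = marker.astype(bool)
        assert roc_auc(marker, labels).auc == pytest.approx(1.0)

    def test_closed_form_sens_spec(self):
        # sensitivity 0.60 (30/50), specificity 0.93 (93/100) -> AUC 0.765
        marker = np.r_[np.ones(30), np.zeros(20), np.ones(7), np.zeros(93)]
        labels = np.r_[np.ones(50, bool), np.zeros(100, bool)]
        res = roc_auc(marker, labels)
        assert res.auc == pytest.approx(0.765, abs=1e-12)
        assert res.ci_low <= res.auc <= res.ci_high

    @given(
        tp=st.integers(1, 30), fn=st.integers(1, 30), fp=st.integers(1, 30), tn=st.integers(1, 30)
    )
    @settings(max_examples=100, derandomize=True)
    def test_ranksum_equals_closed_form_for_dichotomous(self, tp, fn, fp, tn):
        marker = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp), np.zeros(tn)]
        labels = np.r_[np.ones(tp + fn, bool), np.zeros(fp + tn, bool)]
        sens = tp / (tp + fn)
        spec = tn / (fp + tn)
        assert roc_auc(marker, labels).auc == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_independent_marker_near_half(self, rng):
        aucs = []
        for _ in range(50):
            marker = rng.normal(size=120)
            labels = rng.random(120) < 0.5
            if labels.all() or not labels.any():
                continue
            aucs.append(roc_auc(marker, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_one_class_absent_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(5), np.ones(5, bool))


# ---------------------------------------------------------------------------
# KM / log-rank / Cox


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([2, 4, 6], [True, True, True])
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[2.0] == pytest.approx(2 / 3)
        assert lookup[4.0] == pytest.approx(1 / 3)
        assert lookup[6.0] == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = km_estimate([5, 6, 7], [False, False, False])
        assert (km["survival"] == 1.0).all()

    def test_textbook_mixed_example(self):
        # events at 1, 3, 4, 6; censored at 2 and 5 — hand product-limit:
        # S(1)=5/6, S(3)=5/6*3/4=0.625, S(4)=0.625*2/3, S(6)=0
        km = km_estimate([1, 2, 3, 4, 5, 6], [True, False, True, True, False, True])
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(5 / 6)
        assert lookup[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert lookup[4.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert lookup[6.0] == pytest.approx(0.0)

    def test_random_uncensored_matches_empirical(self, rng):
        times = rng.exponential(10, size=50)
        km = km_estimate(times, np.ones(50, bool))
        for t, s in zip(km["time"], km["survival"]):
            if t == 0:
                continue
            assert s == pytest.approx((times > t).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        times = np.r_[[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]].astype(float)
        events = np.ones(10, bool)
        groups = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_small_dataset(self):
        # group A: events at 1, 3, censored 5; group B: events at 2, 6, censored 4
        # O_A = 2, E_A = 0.5 + 0.4 + 0.5 + 0 = 1.4, V = 0.25+0.24+0.25 = 0.74
        times = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        events = np.array([True, True, False, True, False, True])
        groups = np.array([True, True, True, False, False, False])
        chi2, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx((2 - 1.4) ** 2 / 0.74, rel=1e-9)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1.0, 2.0], [False, False], [True, False])


class TestHazardRatio:
    @staticmethod
    def _sample(rng, hr, n=150, censor=0.0):
        groups = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        times = rng.exponential(1 / np.where(groups, hr / 1000, 1 / 1000))
        events = np.ones(2 * n, bool)
        if censor:
            cut = np.quantile(times, 1 - censor)
            events = times < cut
            times = np.minimum(times, cut)
        return times, events, groups

    def test_identical_groups_give_unit_hr(self, rng):
        times, events, groups = self._sample(rng, 1.0)
        res = hazard_ratio(times, events, groups)
        assert res.hr == pytest.approx(1.0, abs=0.35)
        assert res.ci_low < 1.0 < res.ci_high

    def test_label_swap_inverts_hr(self, rng):
        times, events, groups = self._sample(rng, 3.0)
        a = hazard_ratio(times, events, groups)
        b = hazard_ratio(times, events, ~groups)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-6)

    def test_agrees_with_lifelines_cox(self, rng):
        """Independent cross-check: lifelines CoxPHFitter on tie-free data
        (Efron and Breslow coincide without ties)."""
        from lifelines import CoxPHFitter

        times, events, groups = self._sample(rng, 2.5, n=120, censor=0.15)
        ours = hazard_ratio(times, events, groups)
        df = pd.DataFrame({"t": times, "e": events.astype(int), "g": groups.astype(int)})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert ours.coef == pytest.approx(float(cph.params_["g"]), rel=1e-4)
        assert ours.se == pytest.approx(float(cph.standard_errors_["g"]), rel=1e-3)

    def test_monotone_likelihood_falls_back_to_oe(self):
        # all events in one group, none in the other, disjoint time ranges
        times = np.r_[np.linspace(1, 2, 8), np.linspace(10, 11, 8)]
        events = np.r_[np.ones(8, bool), np.zeros(8, bool)]
        groups = np.r_[np.ones(8, bool), np.zeros(8, bool)]
        res = hazard_ratio(times, events, groups)
        assert res.method == "oe_ratio"
        assert not res.converged


@pytest.mark.parametrize(
    "days,years",
    [(2800, 7.67), (0, 0.0), (5895, 16.14)],
)
def test_followup_years(days, years):
    assert round(followup_years(days), 2) == years


def test_followup_years_negative_rejected():
    with pytest.raises(ValueError):
        followup_years(-1)
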