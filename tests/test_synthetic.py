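import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telorisk import pipeline
from telorisk.methylation import summarize_samples
from telorisk.synthetic import (
    CohortConfig,
    ConfigError,
    PlantedOutlier,
    _group_rates,
    generate_cohort,
    generate_expression,
    generate_methylation,
    generate_survival,
    load_config,
)


class TestConfigValidation:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError, match="probabilities"):
            CohortConfig(background_outlier_rate=1.5)

    def test_negative_group_size_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_metastatic=-1)

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(hazard_ratio_event=0.0)

    def test_planted_gene_must_be_on_panel(self):
        with pytest.raises(ConfigError, match="panel"):
            CohortConfig(planted=[PlantedOutlier("NOTAGENE", "high", _group_rates(0.1))])

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "n_metastatic: 10\nseed: 3\nplanted:\n"
            "  - gene: NOP10\n    direction: high\n    prob: {metastatic: 0.5}\n"
        )
        cfg = load_config(path)
        assert cfg.n_metastatic == 10 and cfg.planted[0].gene == "NOP10"
        with pytest.raises(ConfigError, match="unknown"):
            (tmp_path / "bad.yaml").write_text("nope: 1\n")
            load_config(tmp_path / "bad.yaml")


class TestDeterminismAndStructure:
    def test_identical_seeds_give_identical_cohorts(self, tmp_path):
        a, b = generate_cohort(CohortConfig(seed=5)), generate_cohort(CohortConfig(seed=5))
        (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a, b = generate_cohort(CohortConfig(seed=5)), generate_cohort(CohortConfig(seed=6))
        assert not a.expression.equals(b.expression)

    def test_group_sizes_match_config(self, default_cohort):
        counts = default_cohort.annotation["group"].value_counts()
        cfg = default_cohort.config
        assert counts["metastatic"] == cfg.n_metastatic
        assert counts["nonmetastatic_long"] == cfg.n_nonmetastatic_long

    def test_every_sample_once_per_table(self, default_cohort):
        c = default_cohort
        idx = c.annotation.index
        assert idx.is_unique
        for table in (c.counts.counts, c.expression, c.cna):
            assert table.index.equals(idx)
        assert set(c.methylation["sample"]) == set(idx)

    def test_no_planted_effects_when_disabled(self):
        cfg = CohortConfig(seed=1, planted=[], background_outlier_rate=0.0)
        cohort = generate_cohort(cfg)
        assert len(cohort.truth.planted_outliers) == 0


class TestExpressionGeneration:
    def test_planted_count_within_binomial_interval(self):
        """~0.3 outlier probability for NOP10 in 63 metastatic -> ≈19 plants."""
        cfg0 = CohortConfig(planted=[PlantedOutlier("NOP10", "high", _group_rates(0.30))],
                            background_outlier_rate=0.0)
        totals = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = CohortConfig(seed=seed, planted=cfg0.planted, background_outlier_rate=0.0)
            cohort = generate_cohort(cfg)
            totals += len(cohort.truth.planted_outliers)
        # aggregate over seeds: Binomial(100*63, 0.3), 99.9% interval
        n, p = n_seeds * 63, 0.30
        sd = np.sqrt(n * p * (1 - p))
        assert abs(totals - n * p) < 3.3 * sd

    def test_truth_consistency_planted_values_are_shifted(self, default_cohort):
        """A planted high outlier's value re-derives as baseline + shift + noise."""
        c = default_cohort
        planted = c.truth.planted_outliers
        for gene in ("NOP10", "FBXO4"):
            flagged = planted.loc[
                (planted["gene"] == gene) & (planted["direction"] == "high"), "sample"
            ]
            rest = c.expression.index.difference(flagged)
            gap = c.expression.loc[flagged, gene].mean() - c.expression.loc[rest, gene].mean()
            assert gap == pytest.approx(c.config.outlier_shift, abs=1.0)

    def test_zero_shift_makes_plants_indistinguishable(self, small_groups):
        cfg = CohortConfig(outlier_shift=0.0)
        _, expr, planted = generate_expression(cfg, small_groups, seed=4)
        flagged = planted.loc[planted["gene"] == "NOP10", "sample"]
        rest = expr.index.difference(flagged)
        if len(flagged) >= 3:
            p = stats.ttest_ind(expr.loc[flagged, "NOP10"], expr.loc[rest, "NOP10"]).pvalue
            assert p > 0.01

    def test_zero_sd_gene_constant_for_nonoutliers(self, small_groups):
        cfg = CohortConfig(
            baseline_sd={"GPX2": 0.0}, planted=[], background_outlier_rate=0.0,
            batch_effect_size=0.0,
        )
        _, expr, _ = generate_expression(cfg, small_groups, seed=0)
        assert expr["GPX2"].nunique() == 1

    def test_no_batch_effect_means_no_preservation_difference(self, small_groups):
        """batch_effect_size=0: FFPE vs frozen means differ only by noise."""
        pvals = []
        for seed in range(50):
            cfg = CohortConfig(batch_effect_size=0.0, planted=[], background_outlier_rate=0.0)
            rng = np.random.default_rng(seed)
            pres = pd.Series(
                np.where(rng.random(len(small_groups)) < 0.5, "FFPE", "frozen"),
                index=small_groups.index,
            )
            _, expr, _ = generate_expression(cfg, small_groups, seed=seed, preservation=pres)
            pvals.append(
                stats.ttest_ind(expr.loc[pres == "FFPE", "DKC1"], expr.loc[pres == "frozen", "DKC1"]).pvalue
            )
        assert np.mean(np.asarray(pvals) < 0.01) < 0.15

    def test_batch_effect_recovered_when_planted(self, small_groups):
        cfg = CohortConfig(batch_effect_size=1.0, planted=[], background_outlier_rate=0.0)
        pres = pd.Series(
            ["FFPE"] * (len(small_groups) // 2) + ["frozen"] * (len(small_groups) - len(small_groups) // 2),
            index=small_groups.index,
        )
        _, expr, _ = generate_expression(cfg, small_groups, seed=1, preservation=pres)
        diff = expr.loc[pres == "frozen"].mean() - expr.loc[pres == "FFPE"].mean()
        assert diff.mean() == pytest.approx(1.0, abs=0.3)

    def test_raw_counts_reproduce_log2cpm_totals(self, default_cohort):
        totals = default_cohort.counts.totals
        cfg = default_cohort.config
        assert (totals >= cfg.total_reads_low).all()
        assert (totals <= cfg.total_reads_high).all()
        assert (default_cohort.counts.amplicon_gene == "TERT").sum() == 3


class TestMethylationGeneration:
    def test_hypermethylated_flags_recover_downstream(self):
        """Flagged samples end >= 16.1% mean UTSS in >=99% of cases."""
        flagged_ok = flagged_total = 0
        for seed in range(60):
            cfg = CohortConfig(seed=seed)
            flags = pd.Series([True] * 10 + [False] * 10, index=[f"s{i}" for i in range(20)])
            table = generate_methylation(cfg, flags, seed)
            summary = summarize_samples(table)
            hyper = summary.loc[flags.index[flags], "utss_mean_pct"]
            flagged_ok += (hyper >= 16.1).sum()
            flagged_total += len(hyper)
            low = summary.loc[flags.index[~flags], "utss_mean_pct"]
            assert (low < 16.1).mean() > 0.9
        assert flagged_ok / flagged_total >= 0.99

    def test_zero_methylation_parameter_gives_all_t_reads(self):
        cfg = CohortConfig(meth_mean_base=(0.0, 0.0))
        table = generate_methylation(cfg, pd.Series({"s": False}), seed=0)
        assert (table["c_reads"] == 0).all()

    def test_zero_coverage_guarded(self):
        with pytest.raises(ConfigError, match="coverage"):
            CohortConfig(meth_coverage=0)


class TestSurvivalGeneration:
    def test_all_censored_when_censor_rate_one(self):
        cfg = CohortConfig(censor_rate=1.0)
        recs = generate_survival(cfg, pd.Series([True] * 5 + [False] * 5), seed=0)
        assert (~recs["event"]).all()
        assert (recs["time"] > 0).all()

    def test_null_hazard_ratio_gives_uniform_logrank_p(self):
        from telorisk.risk import logrank_test

        cfg = CohortConfig(hazard_ratio_event=1.0, censor_rate=0.2)
        flags = pd.Series([True] * 60 + [False] * 60)
        ps = [
            logrank_test(*(lambda r: (r["time"], r["event"], r["group"]))(
                generate_survival(cfg, flags, seed)
            ))[1]
            for seed in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cox_recovers_planted_hazard_ratio(self):
        from telorisk.risk import hazard_ratio

        cfg = CohortConfig(hazard_ratio_event=5.0, censor_rate=0.0)
        flags = pd.Series([True] * 200 + [False] * 200)
        inside = 0
        for seed in range(100):
            recs = generate_survival(cfg, flags, seed)
            hr = hazard_ratio(recs["time"], recs["event"], recs["group"]).hr
            inside += 3.5 <= hr <= 7.2
        assert inside >= 95

    def test_cohort_ttp_only_for_metastatic(self, default_cohort):
        ann = default_cohort.annotation
        assert ann.loc[ann["status"] == "metastatic", "ttp_days"].notna().all()
        assert ann.loc[ann["status"] != "metastatic", "ttp_days"].isna().all()


def test_truth_flags_rederivable_from_generated_tables(default_cohort):
    """Planted molecular events are recoverable from the emitted tables."""
    events, _, _ = pipeline.call_cohort_events(default_cohort)
    truth = default_cohort.truth.sample_events
    # variant-derived flags are exact
    assert (events["tpm"] == truth["tpm"]).all()
    assert (events["atrx_lof"] == truth["atrx_lof"]).all()
    assert (events["cna_gain"] == truth["cna_gain"]).all()
    # stochastic assays recover almost all planted flags
    assert (events["hypermethylated"] == truth["hypermethylated"]).mean() > 0.97
    assert (events["nop10_high_outlier"] == truth["nop10_high_outlier"]).mean() > 0.95
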