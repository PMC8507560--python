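"""End-to-end drivers chaining the pipeline stages on a cohort.

These helpers run the full path a study analyst would: raw counts ->
depth QC -> log2CPM -> batch adjustment -> reference whiskers -> outlier
calls -> molecular-event integration -> screening and risk models. They
operate on a SyntheticCohort (or equivalently structured tables) and are
what the analysis scripts and the acceptance checks call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import counts as counts_mod
from . import events as events_mod
from . import methylation as meth_mod
from . import risk as risk_mod
from . import screening as screening_mod
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort


def normalized_expression(
    cohort: SyntheticCohort,
    qc: counts_mod.QCConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw counts -> downsample -> depth QC -> log2CPM -> batch adjustment.

    Returns (sample × gene adjusted log2CPM matrix, QC discard log).
    """
    qc = qc or counts_mod.QCConfig()
    down = counts_mod.downsample_counts(cohort.counts, qc.downsample_target, seed=seed)
    kept, discarded = counts_mod.qc_filter(down, qc)
    expr = counts_mod.median_center(counts_mod.log2cpm(kept, prior=qc.cpm_prior))
    adjusted = counts_mod.batch_adjust(expr, kept.preservation)
    return adjusted, discarded


def call_cohort_events(
    cohort: SyntheticCohort,
    expr: pd.DataFrame | None = None,
    tert_expression_rule: str = "outlier",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reference whiskers, outlier calls and the integrated event table.

    ``expr`` defaults to the cohort's generator-truth log2CPM matrix; pass
    the output of :func:`normalized_expression` to use the raw-count path.
    Returns (events table, outlier call table, whiskers).
    """
    if expr is None:
        expr = cohort.expression
    reference = cohort.annotation.index[cohort.annotation["group"] == "nonmetastatic_long"]
    reference = reference.intersection(expr.index)
    whiskers = events_mod.reference_whiskers(expr, reference)
    calls = events_mod.call_outliers(expr, whiskers)

    samples = expr.index
    meth_summary = meth_mod.summarize_samples(cohort.methylation)
    tert_pos = counts_mod.tert_positive_per_sample(cohort.counts).reindex(samples)
    events = events_mod.integrate_events(
        samples,
        tert_high_outlier=events_mod.outlier_flags(calls, "TERT", "high"),
        tert_positive=tert_pos,
        tpm=events_mod.detect_tpm(cohort.variants, samples=samples),
        hypermethylated=meth_summary["hypermethylated"].reindex(samples),
        cna_gain=events_mod.call_cna_gain(
            cohort.cna["tert_cn_score"], cohort.cna["preservation"]
        ).reindex(samples),
        atrx_low_outlier=events_mod.outlier_flags(calls, "ATRX", "low"),
        atrx_lof=events_mod.atrx_lof_flags(cohort.variants, samples=samples),
        nop10_high_outlier=events_mod.outlier_flags(calls, "NOP10", "high"),
        tert_expression_rule=tert_expression_rule,
    )
    return events, calls, whiskers


def screen_cohort(
    cohort: SyntheticCohort,
    expr: pd.DataFrame | None = None,
    n_tests: int = screening_mod.N_PANEL_GENES,
    force_include: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Outlier-frequency screen: metastatic vs long-follow-up reference.

    Outliers (either direction) are dichotomized per gene and compared
    between the metastatic and reference groups; aggressive and
    short-follow-up samples are excluded, as in the published design.
    """
    if expr is None:
        expr = cohort.expression
    groups = cohort.annotation["group"]
    keep = groups.isin(["metastatic", "nonmetastatic_long"])
    keep = keep.index[keep].intersection(expr.index)
    reference = cohort.annotation.index[groups == "nonmetastatic_long"].intersection(expr.index)
    whiskers = events_mod.reference_whiskers(expr, reference)
    calls = events_mod.call_outliers(expr.loc[keep], whiskers)
    flags = events_mod.outlier_matrix(calls)
    is_case = groups.loc[keep] == "metastatic"
    return screening_mod.screen_genes(flags, is_case, n_tests=n_tests, force_include=force_include)


def candidate_count(config: CohortConfig, use_count_path: bool = True) -> int:
    """Number of Bonferroni-significant candidate genes for one cohort draw."""
    cohort = generate_cohort(config)
    expr = None
    if use_count_path:
        expr, _ = normalized_expression(cohort, seed=config.seed)
    result = screen_cohort(cohort, expr=expr)
    return int(result["significant"].sum())


def scenario_auc(
    cohort: SyntheticCohort, events: pd.DataFrame, scenario: str
) -> risk_mod.RocResult:
    """ROC/AUC of one scenario marker on the classification cohort."""
    classification, _, _ = risk_mod.build_cohorts(cohort.annotation, events)
    marker = events_mod.scenario_marker(events, scenario).reindex(classification.index)
    labels = classification["status"] == "metastatic"
    return risk_mod.roc_auc(marker.astype(float), labels)


def ttp_analysis(
    cohort: SyntheticCohort, events: pd.DataFrame, scenario: str = "all_three"
) -> dict:
    """KM / log-rank / hazard-ratio summary of a scenario marker.

    Returns a dict with the two KM curves, the log-rank chi-square/p and
    the Cox hazard ratio with CI.
    """
    _, ttp_cohort, _ = risk_mod.build_cohorts(cohort.annotation, events)
    marker = events_mod.scenario_marker(events, scenario)
    records = risk_mod.survival_records(ttp_cohort, marker)
    chi2, p = risk_mod.logrank_test(records["time"], records["event"], records["group"])
    hr = risk_mod.hazard_ratio(records["time"], records["event"], records["group"])
    km_pos = risk_mod.km_estimate(
        records.loc[records["group"], "time"], records.loc[records["group"], "event"]
    )
    km_neg = risk_mod.km_estimate(
        records.loc[~records["group"], "time"], records.loc[~records["group"], "event"]
    )
    return {
        "records": records,
        "logrank_chi2": chi2,
        "logrank_p": p,
        "hazard_ratio": hr,
        "km_event_positive": km_pos,
        "km_event_negative": km_neg,
    }
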