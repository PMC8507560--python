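"""Reference-cohort expression outlier detection and molecular-event integration.

The outlier rule is the boxplot fence: per gene, Q1/Q3 and the IQR are
estimated on the reference cohort (non-metastatic patients with >= 8 years
of follow-up) and any sample strictly beyond Q1 − 1.5·IQR or Q3 + 1.5·IQR
is a low/high expression outlier. All molecular evidence is then folded
into per-sample boolean event flags for the three-gene risk scenarios:

* TERT event  = expression reactivation (whisker outlier and/or probe
  positivity), promoter mutation (C228T/C250T), promoter (UTSS)
  hypermethylation, or 5p copy-number gain;
* ATRX event  = low-expression outlier or loss-of-function mutation;
* NOP10 event = high-expression outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: hg19 chr5 coordinates of the TERT promoter hotspot mutations (C228T, C250T).
TPM_POSITIONS: tuple[int, ...] = (1295228, 1295250)

#: Copy-number gain thresholds by preservation type.
DEFAULT_CNA_THRESHOLDS: dict[str, float] = {"frozen": 4.0, "FFPE": 8.0}


class ReferenceError(ValueError):
    """Raised when a reference distribution cannot be built or is missing genes."""


@dataclass
class CnaConfig:
    """Gain-detection thresholds per preservation type (inclusive >=)."""

    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CNA_THRESHOLDS))

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("CNA gain thresholds must be positive")


def reference_whiskers(
    expr: pd.DataFrame, reference_samples=None, quartile_method: str = "linear"
) -> pd.DataFrame:
    """Per-gene boxplot fences from the reference cohort.

    ``expr`` is a sample × gene log2CPM matrix; ``reference_samples``
    selects the rows used as reference (all rows if None). Quartiles use
    linear interpolation between order statistics by default (numpy's
    "linear", R type 7); the method is exposed because conventions differ.

    Returns a DataFrame indexed by gene with columns q1, q3, iqr, lower,
    upper and n_ref. Requires at least 4 reference samples.
    """
    ref = expr if reference_samples is None else expr.loc[reference_samples]
    n = ref.shape[0]
    if n < 4:
        raise ReferenceError(f"need >=4 reference samples for quartiles, got {n}")
    values = ref.to_numpy(dtype=float)
    q1 = np.quantile(values, 0.25, axis=0, method=quartile_method)
    q3 = np.quantile(values, 0.75, axis=0, method=quartile_method)
    iqr = q3 - q1
    return pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lower": q1 - 1.5 * iqr,
            "upper": q3 + 1.5 * iqr,
            "n_ref": n,
        },
        index=ref.columns,
    )


def call_outliers(expr: pd.DataFrame, whiskers: pd.DataFrame) -> pd.DataFrame:
    """Call every (sample, gene) value against the reference fences.

    Strict inequalities: a value must lie beyond the whisker to be called
    (a value exactly at a fence is not an outlier). Reference samples are
    callable like any others. Returns a long DataFrame with columns
    sample, gene, value, call in {"low", "high", "none"}, lower, upper.
    """
    missing = set(expr.columns) - set(whiskers.index)
    if missing:
        raise ReferenceError(f"genes missing from reference: {sorted(missing)[:5]}")
    w = whiskers.loc[expr.columns]
    vals = expr.to_numpy(dtype=float)
    lower = w["lower"].to_numpy()
    upper = w["upper"].to_numpy()
    call = np.where(vals > upper, "high", np.where(vals < lower, "low", "none"))
    long = pd.DataFrame(
        {
            "sample": np.repeat(expr.index.to_numpy(), expr.shape[1]),
            "gene": np.tile(expr.columns.to_numpy(), expr.shape[0]),
            "value": vals.ravel(),
            "call": call.ravel(),
            "lower": np.tile(lower, expr.shape[0]),
            "upper": np.tile(upper, expr.shape[0]),
        }
    )
    return long


def outlier_flags(calls: pd.DataFrame, gene: str, direction: str) -> pd.Series:
    """Boolean per-sample flag for one gene/direction from a call table."""
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    sub = calls[calls["gene"] == gene]
    return (
        sub.set_index("sample")["call"].eq(direction).rename(f"{gene.lower()}_{direction}_outlier")
    )


def outlier_matrix(calls: pd.DataFrame, direction: str | None = None) -> pd.DataFrame:
    """Sample × gene boolean matrix of outlier status.

    ``direction`` restricts to "low" or "high" calls; None counts either.
    """
    flagged = calls["call"].ne("none") if direction is None else calls["call"].eq(direction)
    wide = calls.assign(flag=flagged).pivot(index="sample", columns="gene", values="flag")
    return wide.astype(bool)


def _normalize_chrom(chrom) -> str:
    return str(chrom).removeprefix("chr")


def detect_tpm(variants: pd.DataFrame, samples=None) -> pd.Series:
    """TERT promoter mutation flag per sample.

    True iff the variant table holds a C>T substitution at chr5:1,295,228
    or chr5:1,295,250 (1-based, GRCh37) for that sample. Malformed rows
    are skipped with a warning. ``samples`` optionally fixes the index of
    the returned Series (samples without variant rows are False).
    """
    flags: dict = {}
    for idx, row in variants.iterrows():
        try:
            sample = row["sample"]
            chrom = _normalize_chrom(row["chrom"])
            pos = int(row["pos"])
            ref = str(row["ref"]).upper()
            alt = str(row["alt"]).upper()
        except (KeyError, TypeError, ValueError):
            logger.warning("skipping malformed variant row %s", idx)
            continue
        hit = chrom == "5" and pos in TPM_POSITIONS and ref == "C" and alt == "T"
        flags[sample] = flags.get(sample, False) or hit
    out = pd.Series(flags, dtype=bool, name="tpm")
    if samples is not None:
        out = out.reindex(samples, fill_value=False)
    return out


def atrx_lof_flags(variants: pd.DataFrame, samples=None) -> pd.Series:
    """ATRX loss-of-function flag per sample from annotated variant rows.

    LoF status is consumed as an input annotation: a row counts if its
    gene is ATRX and either a boolean ``lof`` column is set or its
    ``effect`` is frameshift/nonsense/splice.
    """
    lof_effects = {"frameshift", "nonsense", "splice", "stop_gained", "splice_site"}
    sub = variants[variants.get("gene", pd.Series(dtype=str)) == "ATRX"]
    flags: dict = {}
    for _, row in sub.iterrows():
        is_lof = bool(row["lof"]) if "lof" in row and not pd.isna(row.get("lof")) else (
            str(row.get("effect", "")).lower() in lof_effects
        )
        flags[row["sample"]] = flags.get(row["sample"], False) or is_lof
    out = pd.Series(flags, dtype=bool, name="atrx_lof")
    if samples is not None:
        out = out.reindex(samples, fill_value=False)
    return out


def call_cna_gain(
    scores: pd.Series, preservation: pd.Series, config: CnaConfig | None = None
) -> pd.Series:
    """TERT-locus (5p) gain call from a per-sample gene-level CNA score.

    Inclusive comparison against the preservation-specific threshold
    (4 frozen, 8 FFPE by default).
    """
    config = config or CnaConfig()
    preservation = preservation.reindex(scores.index)
    unknown = set(preservation.dropna().unique()) - set(config.thresholds)
    if unknown:
        raise ValueError(f"unknown preservation labels: {sorted(unknown)}")
    if preservation.isna().any():
        raise ValueError("preservation label missing for some samples")
    thresholds = preservation.map(config.thresholds)
    return (scores >= thresholds).rename("cna_gain")


def integrate_events(
    samples,
    tert_high_outlier: pd.Series | None = None,
    tert_positive: pd.Series | None = None,
    tpm: pd.Series | None = None,
    hypermethylated: pd.Series | None = None,
    cna_gain: pd.Series | None = None,
    atrx_low_outlier: pd.Series | None = None,
    atrx_lof: pd.Series | None = None,
    nop10_high_outlier: pd.Series | None = None,
    tert_expression_rule: str = "outlier",
) -> pd.DataFrame:
    """Fold all molecular evidence into per-sample event flags.

    Missing assays (None inputs, or samples absent from a Series) are
    treated as False, with per-sample missing-assay counts recorded in
    ``n_missing_assays``. ``tert_expression_rule`` selects how the TERT
    expression-reactivation flag is formed: "outlier" (whisker high
    outlier), "probe" (probe positivity), or "outlier_or_probe".

    Integrated flags: tert_event = expression flag | tpm | hypermethylated
    | cna_gain; atrx_event = atrx_low_outlier | atrx_lof; nop10_event =
    nop10_high_outlier; any_event = OR of the three.
    """
    samples = pd.Index(samples)
    if len(samples) == 0:
        raise ValueError("no samples provided")
    inputs = {
        "tert_high_outlier": tert_high_outlier,
        "tert_positive": tert_positive,
        "tpm": tpm,
        "hypermethylated": hypermethylated,
        "cna_gain": cna_gain,
        "atrx_low_outlier": atrx_low_outlier,
        "atrx_lof": atrx_lof,
        "nop10_high_outlier": nop10_high_outlier,
    }
    present_any = pd.Series(False, index=samples)
    table = pd.DataFrame(index=samples)
    missing = pd.Series(0, index=samples)
    for name, series in inputs.items():
        if series is None:
            table[name] = False
            missing += 1
            continue
        series = series.reindex(samples)
        present_any |= series.notna()
        missing += series.isna().astype(int)
        table[name] = series.eq(True)  # NaN (missing assay) compares False
    if not present_any.all():
        orphans = samples[~present_any].tolist()
        raise ValueError(f"samples present in no assay input: {orphans[:5]}")

    if tert_expression_rule == "outlier":
        expr_flag = table["tert_high_outlier"]
    elif tert_expression_rule == "probe":
        expr_flag = table["tert_positive"]
    elif tert_expression_rule == "outlier_or_probe":
        expr_flag = table["tert_high_outlier"] | table["tert_positive"]
    else:
        raise ValueError(f"unknown tert_expression_rule: {tert_expression_rule!r}")

    table["tert_expr_flag"] = expr_flag
    table["tert_event"] = expr_flag | table["tpm"] | table["hypermethylated"] | table["cna_gain"]
    table["atrx_event"] = table["atrx_low_outlier"] | table["atrx_lof"]
    table["nop10_event"] = table["nop10_high_outlier"]
    table["any_event"] = table["tert_event"] | table["atrx_event"] | table["nop10_event"]
    table["n_missing_assays"] = missing
    return table


def scenario_marker(events: pd.DataFrame, scenario: str) -> pd.Series:
    """Dichotomous risk marker for one of the three classification scenarios.

    * ``tert_atrx``   — any event in TERT and/or ATRX;
    * ``nop10_only``  — NOP10 outlier expression excluding TERT/ATRX events;
    * ``all_three``   — any event in any of the three genes.
    """
    if scenario == "tert_atrx":
        return (events["tert_event"] | events["atrx_event"]).rename("marker")
    if scenario == "nop10_only":
        return (
            events["nop10_event"] & ~(events["tert_event"] | events["atrx_event"])
        ).rename("marker")
    if scenario == "all_three":
        return events["any_event"].rename("marker")
    raise ValueError(f"unknown scenario: {scenario!r}")
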