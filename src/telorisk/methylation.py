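"""TERT-promoter UTSS methylation from per-CpG bisulfite read counts.

Bisulfite conversion leaves methylated cytosines as "C" reads and converts
unmethylated ones to "T"; the per-CpG methylation percentage is therefore
100·C/(C+T) from forward-strand tallies. The UTSS region — five CpG sites
upstream of the TERT transcription start site whose average tracks the
whole THOR (TERT hypermethylated oncological region) — is summarized by
the unweighted mean over covered sites, and samples at or above 16.1%
mean UTSS methylation are called hypermethylated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genomic coordinates (hg19, chr5) of the five UTSS CpG sites.
UTSS_POSITIONS: tuple[int, ...] = (1295586, 1295590, 1295593, 1295605, 1295618)

#: Mean UTSS methylation (percent) at or above which a sample is hypermethylated.
HYPERMETHYLATION_THRESHOLD = 16.1


@dataclass
class MethylationConfig:
    utss_positions: tuple[int, ...] = UTSS_POSITIONS
    hypermeth_threshold: float = HYPERMETHYLATION_THRESHOLD
    min_coverage: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.hypermeth_threshold < 100:
            raise ValueError("hypermeth_threshold must be in (0, 100)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def cpg_methylation_pct(c_reads: int, t_reads: int, min_coverage: int = 1) -> float:
    """Percent methylation at one CpG: 100·C/(C+T).

    Returns NaN (with a logged warning) when coverage is below
    ``min_coverage`` — an uncovered site carries no information.
    """
    if c_reads < 0 or t_reads < 0:
        raise ValueError("read counts must be non-negative")
    depth = c_reads + t_reads
    if depth < min_coverage:
        logger.warning("CpG coverage %d below minimum %d; returning NaN", depth, min_coverage)
        return math.nan
    return 100.0 * c_reads / depth


def utss_mean(sample_rows: pd.DataFrame, config: MethylationConfig | None = None) -> tuple[float, int]:
    """Mean UTSS methylation for one sample.

    ``sample_rows`` holds columns ``position``, ``c_reads``, ``t_reads``.
    Rows outside the five UTSS positions are ignored (other THOR amplicon
    positions pass through a methylation table unharmed). The mean is the
    unweighted average of the per-CpG percentages at covered sites; the
    number of covered UTSS CpGs is returned alongside. With no covered
    site the mean is NaN.
    """
    config = config or MethylationConfig()
    rows = sample_rows[sample_rows["position"].isin(config.utss_positions)]
    pcts = [
        cpg_methylation_pct(int(r.c_reads), int(r.t_reads), config.min_coverage)
        for r in rows.itertuples()
    ]
    pcts = [p for p in pcts if not math.isnan(p)]
    if not pcts:
        return math.nan, 0
    return float(np.mean(pcts)), len(pcts)


def call_hypermethylated(
    utss_mean_pct: float, threshold: float = HYPERMETHYLATION_THRESHOLD
) -> bool | float:
    """Hypermethylation call: True iff the mean is >= threshold (inclusive).

    A missing (NaN) mean yields a missing (NaN) call.
    """
    if utss_mean_pct is None or (isinstance(utss_mean_pct, float) and math.isnan(utss_mean_pct)):
        return math.nan
    if not 0 <= utss_mean_pct <= 100:
        raise ValueError("UTSS mean must be a percentage in [0, 100]")
    return bool(utss_mean_pct >= threshold)


def summarize_samples(
    table: pd.DataFrame, config: MethylationConfig | None = None
) -> pd.DataFrame:
    """Per-sample UTSS summary from a long (sample, position, c_reads, t_reads) table.

    Returns a DataFrame indexed by sample with columns ``utss_mean_pct``,
    ``n_covered_cpgs`` and ``hypermethylated``.
    """
    config = config or MethylationConfig()
    required = {"sample", "position", "c_reads", "t_reads"}
    if missing := required - set(table.columns):
        raise ValueError(f"methylation table missing columns: {sorted(missing)}")
    records = []
    for sample, rows in table.groupby("sample", sort=True):
        mean, n_cov = utss_mean(rows, config)
        records.append(
            {
                "sample": sample,
                "utss_mean_pct": mean,
                "n_covered_cpgs": n_cov,
                "hypermethylated": call_hypermethylated(mean, config.hypermeth_threshold),
            }
        )
    return pd.DataFrame.from_records(records).set_index("sample")
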