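"""Candidate-gene screening by dichotomized outlier frequencies.

Per gene, outlier status is compared between the metastatic group and the
long-follow-up non-metastatic reference group in a 2×2 table with a
two-sided Fisher exact test (probability-mass rule) and Bonferroni
correction over the full 29-gene panel. Genes surviving correction at
α = 0.05 are candidates; a forced-include list carries forward markers
kept on prior evidence regardless of their screening p (ATRX in the
original analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Size of the telomere-maintenance panel; the Bonferroni factor.
N_PANEL_GENES = 29


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = group 1 outlier yes/no, (c, d) = group 2 outlier yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_two_sided(table: ContingencyTable2x2 | np.ndarray, warn: bool = True) -> float:
    """Two-sided Fisher exact p-value by the probability-mass rule.

    Sums the hypergeometric probabilities (margins fixed) of all tables
    whose probability does not exceed that of the observed one. A table
    with an empty row or column margin carries no information: p = 1 with
    a warning.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        if warn:
            logger.warning("degenerate 2x2 table with an empty margin; p = 1")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def bonferroni_adjust(p_values, n_tests: int = N_PANEL_GENES) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p·n_tests), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return np.minimum(1.0, p * n_tests)


def screen_genes(
    outlier_flags: pd.DataFrame,
    is_case: pd.Series,
    n_tests: int = N_PANEL_GENES,
    alpha: float = 0.05,
    force_include: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Outlier-frequency screen over a gene panel.

    ``outlier_flags`` is a sample × gene boolean matrix of dichotomized
    outlier status; ``is_case`` labels the metastatic group (True) against
    the reference group (False). Every sample must belong to one of the
    two groups, and aggressive / short-follow-up samples are expected to
    have been excluded upstream.

    Returns a per-gene table with the 2×2 counts, raw and Bonferroni
    p-values, the significance flag at ``alpha`` and the candidate flag
    (significant or force-included).
    """
    is_case = is_case.reindex(outlier_flags.index)
    if is_case.isna().any():
        raise ValueError("group label missing for some samples")
    is_case = is_case.astype(bool)
    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    n_degenerate = 0
    for gene in outlier_flags.columns:
        flag = outlier_flags[gene].astype(bool)
        a = int((flag & is_case).sum())
        b = n_case - a
        c = int((flag & ~is_case).sum())
        d = n_ctrl - c
        n_degenerate += int(a + c == 0)
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d), warn=False)
        rows.append({"gene": gene, "a": a, "b": b, "c": c, "d": d, "p_raw": p})
    if n_degenerate:
        logger.info("%d genes with no outliers in either group (p = 1)", n_degenerate)
    result = pd.DataFrame(rows).set_index("gene")
    result["p_bonferroni"] = bonferroni_adjust(result["p_raw"].to_numpy(), n_tests)
    result["significant"] = result["p_bonferroni"] < alpha
    result["forced"] = result.index.isin(force_include)
    result["candidate"] = result["significant"] | result["forced"]
    return result


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value.

    The p-value comes from the t transform with n−2 degrees of freedom.
    Requires n >= 3, finite values and non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    return float(r), float(p)
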