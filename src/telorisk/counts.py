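"""Raw amplicon-count processing for targeted RNA-seq expression panels.

Implements the depth-normalization path used for the telomerome panel:
random down-sampling of mapped reads to a common depth, read-depth QC,
log2CPM transformation, preservation-batch (FFPE vs frozen) adjustment,
probe-level TERT positivity calling, and the ΔΔCt relative-expression
utility for RT-PCR validation experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default depth every sample is down-sampled to (mapped reads).
DEFAULT_DOWNSAMPLE_TARGET = 170_000
#: Samples averaging fewer reads per amplicon than this are discarded.
DEFAULT_MIN_READS_PER_AMPLICON = 750


class CountMatrixError(ValueError):
    """Raised for structurally invalid amplicon count matrices."""


@dataclass
class QCConfig:
    """Depth-QC and normalization parameters.

    downsample_target
        Common mapped-read depth per sample (reads).
    min_reads_per_amplicon
        Minimum mean reads per amplicon for a sample to be kept.
    cpm_prior
        Pseudocount added to counts before the log2CPM transform.
    year_length
        Days per year used when converting follow-up times.
    """

    downsample_target: int = DEFAULT_DOWNSAMPLE_TARGET
    min_reads_per_amplicon: float = DEFAULT_MIN_READS_PER_AMPLICON
    cpm_prior: float = 0.5
    year_length: float = 365.25

    def __post_init__(self) -> None:
        for name in ("downsample_target", "min_reads_per_amplicon", "cpm_prior", "year_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"QCConfig.{name} must be positive")


@dataclass
class AmpliconCountMatrix:
    """Sample × amplicon raw counts with the amplicon→gene map.

    counts
        DataFrame, rows = samples, columns = amplicons, non-negative ints.
    amplicon_gene
        Series mapping each amplicon id to exactly one gene.
    preservation
        Series per sample, values ``"FFPE"`` or ``"frozen"``.
    """

    counts: pd.DataFrame
    amplicon_gene: pd.Series
    preservation: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise CountMatrixError("empty count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise CountMatrixError("negative counts")
        missing = set(self.counts.columns) - set(self.amplicon_gene.index)
        if missing:
            raise CountMatrixError(f"amplicons without gene mapping: {sorted(missing)[:5]}")
        if self.preservation is None:
            self.preservation = pd.Series("frozen", index=self.counts.index)
        self.preservation = self.preservation.reindex(self.counts.index)

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def totals(self) -> pd.Series:
        """Total mapped reads per sample."""
        return self.counts.sum(axis=1)

    def gene_counts(self) -> pd.DataFrame:
        """Collapse amplicons to genes by summing probe counts."""
        return self.counts.T.groupby(self.amplicon_gene).sum().T


def downsample_counts(
    matrix: AmpliconCountMatrix,
    target: int = DEFAULT_DOWNSAMPLE_TARGET,
    seed: int | np.random.Generator = 0,
) -> AmpliconCountMatrix:
    """Randomly down-sample each sample's reads to a common depth.

    Reads are drawn without replacement (multivariate hypergeometric), so
    the new per-sample total is exactly ``min(target, original total)``;
    samples already at or below the target pass through unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new = _downsample_frame(matrix.counts, int(target), rng)
    return AmpliconCountMatrix(new, matrix.amplicon_gene, matrix.preservation.copy())


def _downsample_frame(counts: pd.DataFrame, target: int, rng: np.random.Generator) -> pd.DataFrame:
    rows = {}
    arr = counts.to_numpy(dtype=np.int64)
    for i, sample in enumerate(counts.index):
        row = arr[i]
        total = int(row.sum())
        if total <= target:
            rows[sample] = row
        else:
            rows[sample] = rng.multivariate_hypergeometric(row, target)
    return pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns).astype(np.int64)


def qc_filter(
    matrix: AmpliconCountMatrix, config: QCConfig | None = None
) -> tuple[AmpliconCountMatrix, pd.DataFrame]:
    """Discard samples with too little read depth.

    A sample is discarded when its total mapped reads fall below the
    down-sampling target, or when its mean reads per amplicon fall below
    ``min_reads_per_amplicon``. Returns the kept matrix and a table of
    discarded samples with the triggering rule.
    """
    config = config or QCConfig()
    totals = matrix.totals
    mean_per_amplicon = totals / matrix.counts.shape[1]
    reasons = []
    for sample in matrix.samples:
        if totals[sample] < config.downsample_target:
            reasons.append((sample, "total_reads", totals[sample]))
        elif mean_per_amplicon[sample] < config.min_reads_per_amplicon:
            reasons.append((sample, "reads_per_amplicon", mean_per_amplicon[sample]))
    discarded = pd.DataFrame(reasons, columns=["sample", "rule", "value"]).set_index("sample")
    keep = matrix.samples.difference(discarded.index, sort=False)
    if len(keep) == 0:
        raise CountMatrixError("all samples discarded by depth QC")
    kept = AmpliconCountMatrix(
        matrix.counts.loc[keep], matrix.amplicon_gene, matrix.preservation.loc[keep]
    )
    return kept, discarded


def log2cpm(
    counts: pd.DataFrame | AmpliconCountMatrix,
    prior: float = 0.5,
    by_gene: bool = True,
) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount prior.

    value = log2((count + prior) / (total + 2*prior) * 1e6), computed per
    sample; with an AmpliconCountMatrix input, amplicons are first summed
    per gene (``by_gene=True``). Strictly increasing in the count at fixed
    total. Raises on zero-total samples.
    """
    if isinstance(counts, AmpliconCountMatrix):
        df = counts.gene_counts() if by_gene else counts.counts
    else:
        df = counts
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise CountMatrixError(f"zero-total samples: {bad[:5]}")
    scaled = (df.add(prior)).div(totals + 2 * prior, axis=0) * 1e6
    return np.log2(scaled)


def median_center(expr: pd.DataFrame) -> pd.DataFrame:
    """Robust per-sample centering of a log2CPM matrix.

    CPM normalization is compositional: a strongly shifted gene changes a
    sample's library composition and offsets every other gene of that
    sample by a constant. Subtracting each sample's median log2CPM (and
    restoring the global median) removes that per-sample offset — the
    log-scale analogue of an effective-library-size correction. With a
    modest panel the median is robust to a few outlier genes.
    """
    med = expr.median(axis=1)
    return expr.sub(med, axis=0) + float(med.median())


def batch_adjust(expr: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Remove per-gene preservation-batch offsets.

    Each batch is mean-centered per gene and the global (pooled) gene mean
    is restored, so per-gene batch means are equal afterwards. An affine
    map per batch: within-batch rank order is preserved, and the transform
    is idempotent. With a single batch this is the identity (logged).
    """
    batches = batches.reindex(expr.index)
    levels = batches.dropna().unique()
    if len(levels) < 2:
        logger.info("batch_adjust: single batch, identity transform")
        return expr.copy()
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError("batch_adjust requires >=2 samples per batch")
    global_mean = expr.mean(axis=0)
    out = expr.copy()
    for level in levels:
        mask = (batches == level).to_numpy()
        out.loc[mask] = expr.loc[mask] - expr.loc[mask].mean(axis=0) + global_mean
    return out


def call_tert_positive(probe_counts) -> bool:
    """TERT expression positivity from its three probe-level raw counts.

    Positive iff every probe has at least 3 raw counts and the mean over
    the three probes is at least 4 — the rule that guards against false
    positives from the low-expressor condition.
    """
    arr = np.asarray(probe_counts, dtype=float)
    if arr.shape != (3,):
        raise ValueError("TERT positivity requires exactly 3 probe counts")
    if (arr < 0).any():
        raise ValueError("negative probe counts")
    return bool(arr.min() >= 3 and arr.mean() >= 4)


def tert_positive_per_sample(matrix: AmpliconCountMatrix, gene: str = "TERT") -> pd.Series:
    """Apply the TERT probe-positivity rule to every sample of a matrix."""
    probes = matrix.amplicon_gene.index[matrix.amplicon_gene == gene]
    if len(probes) != 3:
        raise ValueError(f"expected 3 probes for {gene}, found {len(probes)}")
    sub = matrix.counts[probes]
    return pd.Series(
        [call_tert_positive(row) for row in sub.to_numpy()], index=matrix.samples, name="tert_positive"
    )


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Fold change by the ΔΔCt method: 2^-ΔΔCt.

    ΔΔCt = (Ct_target,sample − Ct_ref,sample) − (Ct_target,control −
    Ct_ref,control), with the reference a housekeeping gene.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
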