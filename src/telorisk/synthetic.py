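"""Synthetic PPGL cohort generation with planted, recoverable effects.

Because no patient-level data are distributed with studies of this kind,
every downstream stage of the pipeline is exercised on synthetic cohorts
whose statistical structure mirrors the analysis assumptions: four
clinical groups (metastatic; long-follow-up non-metastatic reference;
short-follow-up non-metastatic; clinically aggressive), Gaussian
log2CPM expression with additive planted outlier shifts and an FFPE
preservation batch effect, raw amplicon counts back-computed at realistic
sequencing depths, planted TERT promoter mutations / UTSS
hypermethylation / 5p gains / ATRX loss-of-function variants at
configurable per-group frequencies, beta-binomial bisulfite read counts,
and exponential time-to-progression with a configurable hazard ratio for
event-positive patients and administrative censoring.

Every planted effect is recorded in a ground-truth table so recovery can
be verified. One global seed expands into fixed per-table child streams
(annotation, expression, variants, methylation, cna, survival — in that
order, via ``numpy.random.SeedSequence.spawn``), so adding a new table
never perturbs the earlier ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import AmpliconCountMatrix
from .events import TPM_POSITIONS
from .methylation import UTSS_POSITIONS

#: The 29-gene telomere-maintenance ("telomerome") panel.
TELOMEROME_GENES: tuple[str, ...] = (
    # telomerase holoenzyme complex
    "TERT", "TERC", "DKC1", "GAR1", "NOP10", "NHP2",
    # shelterin-telosome complex
    "POT1", "TERF1", "TERF2", "TERF2IP", "TINF2", "TPP1",
    # histone binding / ALT
    "ATRX", "DAXX", "TNKS",
    # non-canonical telomere maintenance
    "ACD", "FBXO4", "GPX2", "MCRS1", "MKRN1", "NAT10", "NFX1",
    "RLIM", "SMG5", "SMG6", "SOX7", "TEP1", "WRAP53", "YLPM1",
)

GROUPS = ("metastatic", "nonmetastatic_long", "nonmetastatic_short", "aggressive")


class ConfigError(ValueError):
    """Raised for invalid cohort configurations."""


def default_baseline_means() -> dict[str, float]:
    """Heterogeneous per-gene baseline log2CPM means.

    Panel genes span roughly 4-11 log2CPM so no single planted outlier
    dominates a sample's read composition (a flat profile would let a
    +4 log2 shift absorb a third of the library and compress itself
    through the CPM normalization). TERT sits low — it is a
    low-expressor outside reactivated tumors.
    """
    means = dict(zip(TELOMEROME_GENES, np.linspace(4.0, 11.0, len(TELOMEROME_GENES))))
    means.update({"TERT": 3.0, "NOP10": 6.0, "FBXO4": 5.5, "ATRX": 7.0})
    return means


def _group_rates(metastatic: float = 0.0, **others: float) -> dict[str, float]:
    rates = {g: 0.0 for g in GROUPS}
    rates["metastatic"] = metastatic
    rates.update(others)
    return rates


@dataclass
class PlantedOutlier:
    """A gene carrying planted expression outliers.

    ``prob`` maps group name -> probability that a sample of that group is
    a planted outlier; ``direction`` is the shift sign ("high" adds
    ``outlier_shift`` log2 units, "low" subtracts it).
    """

    gene: str
    direction: str = "high"
    prob: dict[str, float] = field(default_factory=dict)

    def rate(self, group: str) -> float:
        return float(self.prob.get(group, 0.0))


def default_planted() -> list[PlantedOutlier]:
    """Default planted genes: the screen's three hits plus ATRX down-outliers."""
    return [
        PlantedOutlier("TERT", "high", _group_rates(0.30)),
        PlantedOutlier("NOP10", "high", _group_rates(0.30)),
        PlantedOutlier("FBXO4", "high", _group_rates(0.30)),
        PlantedOutlier("ATRX", "low", _group_rates(0.10)),
    ]


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort. Defaults mirror the study layout:

    63 metastatic vs 45 long-follow-up reference samples in the screening
    comparison, a 29-gene panel, per-sample totals near 170k-250k mapped
    reads, planted high-outliers (prob 0.30 in metastatic) in the three
    screen hits plus ATRX low-outliers, a 2% background outlier rate,
    illustrative per-group molecular-event frequencies, and an
    exponential TTP model with hazard ratio 5 for event-positive patients.
    """

    n_metastatic: int = 63
    n_nonmetastatic_long: int = 45
    n_nonmetastatic_short: int = 20
    n_aggressive: int = 5

    genes: tuple[str, ...] = TELOMEROME_GENES
    baseline_mean: float | dict[str, float] = field(default_factory=default_baseline_means)
    baseline_sd: float | dict[str, float] = 1.0
    outlier_shift: float = 6.0
    planted: list[PlantedOutlier] = field(default_factory=default_planted)
    background_outlier_rate: float = 0.02

    batch_effect_size: float = 0.5
    ffpe_fraction: float = 0.58
    total_reads_low: int = 175_000
    total_reads_high: int = 250_000

    tpm_rate: dict[str, float] = field(default_factory=lambda: _group_rates(0.11))
    hypermeth_rate: dict[str, float] = field(
        default_factory=lambda: _group_rates(0.10, nonmetastatic_short=0.02)
    )
    cna_gain_rate: dict[str, float] = field(
        default_factory=lambda: _group_rates(0.20, nonmetastatic_long=0.05, nonmetastatic_short=0.05)
    )
    atrx_lof_rate: dict[str, float] = field(default_factory=lambda: _group_rates(0.10))
    sdhb_rate_event: float = 0.50
    sdhb_rate_noevent: float = 0.10

    meth_coverage: int = 500
    meth_concentration: float = 80.0
    meth_mean_hyper: tuple[float, float] = (0.25, 0.50)
    meth_mean_base: tuple[float, float] = (0.005, 0.10)

    baseline_hazard_per_day: float = 1.0 / 1500.0
    hazard_ratio_event: float = 5.0
    censor_rate: float = 0.0
    followup_ref_days: tuple[float, float] = (8 * 365.25, 5895.0)
    followup_short_days: tuple[float, float] = (180.0, 8 * 365.25)
    followup_other_days: tuple[float, float] = (365.25, 16 * 365.25)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_metastatic", "n_nonmetastatic_long", "n_nonmetastatic_short", "n_aggressive"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        probs = [self.background_outlier_rate, self.ffpe_fraction, self.censor_rate,
                 self.sdhb_rate_event, self.sdhb_rate_noevent]
        for rates in (self.tpm_rate, self.hypermeth_rate, self.cna_gain_rate, self.atrx_lof_rate):
            probs.extend(rates.values())
        for planted in self.planted:
            if planted.gene not in self.genes:
                raise ConfigError(f"planted gene {planted.gene!r} not in panel")
            if planted.direction not in ("high", "low"):
                raise ConfigError("planted direction must be 'high' or 'low'")
            probs.extend(planted.prob.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.hazard_ratio_event <= 0:
            raise ConfigError("hazard_ratio_event must be > 0")
        if self.baseline_hazard_per_day <= 0:
            raise ConfigError("baseline_hazard_per_day must be > 0")
        if self.meth_coverage <= 0:
            raise ConfigError("meth_coverage must be positive")
        if self.total_reads_low <= 0 or self.total_reads_high < self.total_reads_low:
            raise ConfigError("invalid total-read range")

    # -- helpers ----------------------------------------------------------
    def gene_mean(self, gene: str) -> float:
        if isinstance(self.baseline_mean, dict):
            return float(self.baseline_mean.get(gene, 6.0))
        return float(self.baseline_mean)

    def gene_sd(self, gene: str) -> float:
        if isinstance(self.baseline_sd, dict):
            return float(self.baseline_sd.get(gene, 1.0))
        return float(self.baseline_sd)

    @property
    def n_total(self) -> int:
        return (
            self.n_metastatic
            + self.n_nonmetastatic_long
            + self.n_nonmetastatic_short
            + self.n_aggressive
        )


@dataclass
class CohortTruth:
    """Ground truth of every planted effect."""

    planted_outliers: pd.DataFrame  # long: sample, gene, direction, planted_by
    sample_events: pd.DataFrame  # per-sample boolean truth flags
    hazard_ratio: float


@dataclass
class SyntheticCohort:
    config: CohortConfig
    annotation: pd.DataFrame
    counts: AmpliconCountMatrix
    expression: pd.DataFrame  # generator-truth log2CPM (sample x gene)
    variants: pd.DataFrame
    methylation: pd.DataFrame
    cna: pd.DataFrame
    truth: CohortTruth

    def write(self, outdir: str | Path) -> None:
        """Write all tables as TSV with headers under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
        self.counts.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.counts.amplicon_gene.rename("gene").to_csv(outdir / "amplicon_map.tsv", sep="\t")
        self.expression.to_csv(outdir / "expression_log2cpm.tsv", sep="\t")
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        self.methylation.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
        self.cna.to_csv(outdir / "cna.tsv", sep="\t")
        self.truth.planted_outliers.to_csv(outdir / "truth_outliers.tsv", sep="\t", index=False)
        self.truth.sample_events.to_csv(outdir / "truth_events.tsv", sep="\t")


# ---------------------------------------------------------------------------
# seed plumbing: one child stream per table, fixed order


_STREAMS = ("annotation", "expression", "variants", "methylation", "cna", "survival")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# table generators


def _make_annotation(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    groups = (
        ["metastatic"] * config.n_metastatic
        + ["nonmetastatic_long"] * config.n_nonmetastatic_long
        + ["nonmetastatic_short"] * config.n_nonmetastatic_short
        + ["aggressive"] * config.n_aggressive
    )
    n = len(groups)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    preservation = np.where(rng.random(n) < config.ffpe_fraction, "FFPE", "frozen")
    follow_up = np.empty(n)
    for i, g in enumerate(groups):
        if g == "nonmetastatic_long":
            lo, hi = config.followup_ref_days
        elif g == "nonmetastatic_short":
            lo, hi = config.followup_short_days
        else:
            lo, hi = config.followup_other_days
        follow_up[i] = rng.uniform(lo, hi)
    status = ["metastatic" if g == "metastatic" else "aggressive" if g == "aggressive" else "non-metastatic" for g in groups]
    ann = pd.DataFrame(
        {
            "patient": [f"P{i:04d}" for i in range(1, n + 1)],
            "group": groups,
            "status": status,
            "tissue": "primary",
            "preservation": preservation,
            "follow_up_days": np.round(follow_up, 1),
        },
        index=pd.Index(samples, name="sample"),
    )
    return ann


def generate_expression(
    config: CohortConfig,
    group_labels: pd.Series,
    seed: int | np.random.Generator,
    preservation: pd.Series | None = None,
) -> tuple[AmpliconCountMatrix, pd.DataFrame, pd.DataFrame]:
    """Expression matrix with planted outliers plus back-computed raw counts.

    Baseline values are Gaussian per gene in log2CPM space; planted
    outliers are shifted by ±``outlier_shift``; FFPE samples are shifted
    down by ``batch_effect_size``. Raw amplicon counts are multinomial
    draws whose expected CPMs reproduce the log2CPM matrix at per-sample
    totals in the configured range, with TERT split over its three
    probes. Returns (counts, log2cpm truth matrix, planted-outlier table).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = group_labels.index
    n = len(samples)
    genes = list(config.genes)
    if preservation is None:
        preservation = pd.Series("frozen", index=samples)

    means = np.array([config.gene_mean(g) for g in genes])
    sds = np.array([config.gene_sd(g) for g in genes])
    expr = rng.normal(means, sds, size=(n, len(genes)))

    # planted outliers: targeted genes first, then the background rate
    directions = {(p.gene): p.direction for p in config.planted}
    planted_rows = []
    planted_dir = np.zeros((n, len(genes)))  # +1 high, -1 low
    for p in config.planted:
        j = genes.index(p.gene)
        rates = group_labels.map(lambda g: p.rate(g)).to_numpy(dtype=float)
        hits = rng.random(n) < rates
        planted_dir[hits, j] = 1.0 if p.direction == "high" else -1.0
        for s in samples[hits]:
            planted_rows.append({"sample": s, "gene": p.gene, "direction": p.direction, "planted_by": "targeted"})
    if config.background_outlier_rate > 0:
        bg = rng.random((n, len(genes))) < config.background_outlier_rate
        bg &= planted_dir == 0  # targeted plants take precedence
        for i, j in zip(*np.nonzero(bg)):
            direction = directions.get(genes[j], "high")
            planted_dir[i, j] = 1.0 if direction == "high" else -1.0
            planted_rows.append(
                {"sample": samples[i], "gene": genes[j], "direction": direction, "planted_by": "background"}
            )
    expr = expr + planted_dir * config.outlier_shift

    ffpe = (preservation.reindex(samples) == "FFPE").to_numpy()
    expr[ffpe] -= config.batch_effect_size

    log2cpm_df = pd.DataFrame(expr, index=samples, columns=genes)

    # raw counts: multinomial with probabilities proportional to 2^log2cpm
    totals = rng.integers(config.total_reads_low, config.total_reads_high + 1, size=n)
    weights = np.exp2(expr)
    probs = weights / weights.sum(axis=1, keepdims=True)
    amplicons, amp_gene = [], {}
    for g in genes:
        if g == "TERT":
            for k in (1, 2, 3):
                amplicons.append(f"TERT_p{k}")
                amp_gene[f"TERT_p{k}"] = "TERT"
        else:
            amplicons.append(f"{g}_a1")
            amp_gene[f"{g}_a1"] = g
    count_rows = np.zeros((n, len(amplicons)), dtype=np.int64)
    tert_idx = genes.index("TERT")
    amp_cols = {a: k for k, a in enumerate(amplicons)}
    for i in range(n):
        gene_counts = rng.multinomial(totals[i], probs[i])
        for j, g in enumerate(genes):
            if g == "TERT":
                split = rng.multinomial(gene_counts[tert_idx], [1 / 3] * 3)
                for k in (1, 2, 3):
                    count_rows[i, amp_cols[f"TERT_p{k}"]] = split[k - 1]
            else:
                count_rows[i, amp_cols[f"{g}_a1"]] = gene_counts[j]
    counts = AmpliconCountMatrix(
        pd.DataFrame(count_rows, index=samples, columns=amplicons),
        pd.Series(amp_gene),
        preservation.reindex(samples),
    )
    planted = pd.DataFrame(planted_rows, columns=["sample", "gene", "direction", "planted_by"])
    return counts, log2cpm_df, planted


def generate_methylation(
    config: CohortConfig, hypermeth_flags: pd.Series, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Beta-binomial per-CpG bisulfite counts at the five UTSS positions.

    Hypermethylated samples draw their latent mean methylation fraction
    above the 16.1% call threshold, the rest below it; per-CpG methylation
    fractions are Beta around that mean and read counts Binomial at the
    configured coverage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.meth_coverage <= 0:
        raise ConfigError("meth_coverage must be positive")
    rows = []
    k = config.meth_concentration
    for sample, hyper in hypermeth_flags.items():
        lo, hi = config.meth_mean_hyper if hyper else config.meth_mean_base
        m = rng.uniform(lo, hi)
        for pos in UTSS_POSITIONS:
            if m <= 0:
                p = 0.0
            elif m >= 1:
                p = 1.0
            else:
                p = rng.beta(m * k, (1 - m) * k)
            c = rng.binomial(config.meth_coverage, p)
            rows.append(
                {"sample": sample, "position": pos, "c_reads": int(c), "t_reads": int(config.meth_coverage - c)}
            )
    return pd.DataFrame(rows, columns=["sample", "position", "c_reads", "t_reads"])


def generate_survival(
    config: CohortConfig,
    event_flags: pd.Series,
    seed: int | np.random.Generator,
    metastatic: pd.Series | None = None,
    follow_up_days: pd.Series | None = None,
) -> pd.DataFrame:
    """Exponential time-to-progression records.

    Latent progression times are exponential with hazard h0 for
    event-negative and h0 × ``hazard_ratio_event`` for event-positive
    patients. If ``metastatic`` flags are given, metastatic samples
    observe their progression (event=True at the latent time) and the
    rest are censored administratively at their follow-up time; otherwise
    each sample is independently censored with probability
    ``censor_rate`` at a uniform fraction of its latent time.
    Returns columns time (days, > 0), event (bool), group (event flag).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = event_flags.index
    n = len(samples)
    flags = event_flags.astype(bool).to_numpy()
    hazard = config.baseline_hazard_per_day * np.where(flags, config.hazard_ratio_event, 1.0)
    latent = rng.exponential(1.0 / hazard)
    latent = np.maximum(latent, 0.5)

    if metastatic is not None:
        met = metastatic.reindex(samples).astype(bool).to_numpy()
        if follow_up_days is None:
            raise ConfigError("follow_up_days required when metastatic flags are given")
        fu = follow_up_days.reindex(samples).to_numpy(dtype=float)
        time = np.where(met, latent, np.maximum(fu, 0.5))
        event = met
    else:
        censored = rng.random(n) < config.censor_rate
        ctime = rng.uniform(0.0, 1.0, size=n) * latent
        time = np.where(censored, np.maximum(ctime, 0.25), latent)
        event = ~censored
    return pd.DataFrame(
        {"time": time, "event": event, "group": flags}, index=pd.Index(samples, name="sample")
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort; deterministic for a fixed seed."""
    rngs = _child_rngs(config.seed)
    ann = _make_annotation(config, rngs["annotation"])
    samples = ann.index
    groups = ann["group"]

    counts, expr, planted = generate_expression(
        config, groups, rngs["expression"], preservation=ann["preservation"]
    )

    # molecular events ----------------------------------------------------
    rng_v = rngs["variants"]
    rates = groups.map(config.tpm_rate).to_numpy(dtype=float)
    tpm_truth = rng_v.random(len(samples)) < rates
    rates = groups.map(config.atrx_lof_rate).to_numpy(dtype=float)
    atrx_truth = rng_v.random(len(samples)) < rates
    var_rows = []
    for i, sample in enumerate(samples):
        if tpm_truth[i]:
            pos = TPM_POSITIONS[int(rng_v.integers(0, len(TPM_POSITIONS)))]
            var_rows.append(
                {"sample": sample, "chrom": "chr5", "pos": pos, "ref": "C", "alt": "T",
                 "gene": "TERT", "effect": "promoter", "lof": False}
            )
        if atrx_truth[i]:
            effect = ["frameshift", "nonsense", "splice"][int(rng_v.integers(0, 3))]
            var_rows.append(
                {"sample": sample, "chrom": "chrX", "pos": int(rng_v.integers(76_760_000, 77_041_000)),
                 "ref": "C", "alt": "T", "gene": "ATRX", "effect": effect, "lof": True}
            )
        if rng_v.random() < 0.05:  # benign passenger for parser realism
            var_rows.append(
                {"sample": sample, "chrom": "chrX", "pos": int(rng_v.integers(76_760_000, 77_041_000)),
                 "ref": "G", "alt": "A", "gene": "ATRX", "effect": "missense", "lof": False}
            )
    variants = pd.DataFrame(
        var_rows, columns=["sample", "chrom", "pos", "ref", "alt", "gene", "effect", "lof"]
    )

    rates = groups.map(config.hypermeth_rate).to_numpy(dtype=float)
    hyper_truth = pd.Series(rngs["methylation"].random(len(samples)) < rates, index=samples)
    methylation = generate_methylation(config, hyper_truth, rngs["methylation"])

    rng_c = rngs["cna"]
    rates = groups.map(config.cna_gain_rate).to_numpy(dtype=float)
    gain_truth = rng_c.random(len(samples)) < rates
    ffpe = (ann["preservation"] == "FFPE").to_numpy()
    threshold = np.where(ffpe, 8.0, 4.0)
    score = np.where(
        gain_truth,
        threshold + rng_c.uniform(0.0, 6.0, len(samples)),
        threshold * rng_c.uniform(0.0, 0.85, len(samples)),
    )
    cna = pd.DataFrame(
        {"tert_cn_score": np.round(score, 3), "preservation": ann["preservation"]}, index=samples
    )

    # ground-truth event flags -------------------------------------------
    def _planted_flag(gene: str, direction: str) -> pd.Series:
        sub = planted[(planted["gene"] == gene) & (planted["direction"] == direction)]
        return pd.Series(samples.isin(sub["sample"]), index=samples)

    truth_events = pd.DataFrame(
        {
            "tert_high_outlier": _planted_flag("TERT", "high"),
            "tpm": tpm_truth,
            "hypermethylated": hyper_truth,
            "cna_gain": gain_truth,
            "atrx_low_outlier": _planted_flag("ATRX", "low"),
            "atrx_lof": atrx_truth,
            "nop10_high_outlier": _planted_flag("NOP10", "high"),
        },
        index=samples,
    )
    truth_events["tert_event"] = (
        truth_events["tert_high_outlier"] | truth_events["tpm"]
        | truth_events["hypermethylated"] | truth_events["cna_gain"]
    )
    truth_events["atrx_event"] = truth_events["atrx_low_outlier"] | truth_events["atrx_lof"]
    truth_events["nop10_event"] = truth_events["nop10_high_outlier"]
    truth_events["any_event"] = (
        truth_events["tert_event"] | truth_events["atrx_event"] | truth_events["nop10_event"]
    )

    # survival ------------------------------------------------------------
    rng_s = rngs["survival"]
    surv = generate_survival(
        config,
        truth_events["any_event"],
        rng_s,
        metastatic=ann["status"] == "metastatic",
        follow_up_days=ann["follow_up_days"],
    )
    ann = ann.copy()
    ann["ttp_days"] = np.where(
        ann["status"] == "metastatic", np.round(surv["time"], 1), np.nan
    )
    p_sdhb = np.where(truth_events["any_event"], config.sdhb_rate_event, config.sdhb_rate_noevent)
    ann["sdhb_mutant"] = rng_s.random(len(samples)) < p_sdhb
    ann["cluster"] = np.where(
        ann["sdhb_mutant"], "C1A", np.where(rng_s.random(len(samples)) < 0.4, "C1A", "C2")
    )

    truth = CohortTruth(planted, truth_events, config.hazard_ratio_event)
    return SyntheticCohort(config, ann, counts, expr, variants, methylation, cna, truth)


# ---------------------------------------------------------------------------
# config I/O


def load_config(path: str | Path) -> CohortConfig:
    """Read a CohortConfig from a YAML mapping (keys = field names)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "planted" in raw:
        raw["planted"] = [PlantedOutlier(**p) for p in raw["planted"]]
    field_names = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - field_names
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("genes", "meth_mean_hyper", "meth_mean_base", "followup_ref_days",
                "followup_short_days", "followup_other_days"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return CohortConfig(**raw)
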