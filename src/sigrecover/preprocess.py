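"""Count preprocessing: TMM normalization, expression filtering, logCPM, group summaries.

The pipeline starts from a gene-level count matrix (genes x samples) with a
sample-to-group design. Between-sample normalization uses the trimmed mean of
M-values (TMM): for each sample a scaling factor is computed against a
reference column from gene-wise log expression ratios, after trimming extreme
log-ratios (30% each tail) and extreme average abundances (5% each tail), with
inverse-variance weighting of the surviving genes. Factors are rescaled to
have geometric mean 1, so they redistribute, rather than change, the total
normalization.

Lowly expressed genes are removed with the rule "at least ``min_cpm`` counts
per million (TMM-adjusted) in at least ``min_samples`` samples" and factors
are then recomputed on the filtered matrix. log2 counts-per-million use a
library-size-scaled prior count so zeros stay finite.

Group summaries are geometric-mean CPM per group (back-transformed mean
logCPM; arithmetic mean available), from which log2 fold changes against the
untreated reference group are formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "Roles",
    "CountStudy",
    "GroupExpression",
    "PreprocessResult",
    "tmm_factors",
    "cpm",
    "filter_genes",
    "logcpm",
    "group_mean_expression",
    "log2_fold_changes",
    "preprocess_study",
    "load_study",
]


@dataclass(frozen=True)
class Roles:
    """Study roles: which group is the healthy baseline, which the untreated
    disease reference, and which are treatment arms."""

    naive: str
    reference: str
    treatments: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.naive == self.reference:
            raise ConfigurationError(
                f"roles.naive and roles.reference must differ (both {self.naive!r})"
            )
        object.__setattr__(self, "treatments", tuple(self.treatments))

    @property
    def all_groups(self) -> tuple[str, ...]:
        return (self.naive, self.reference) + self.treatments


@dataclass
class CountStudy:
    """Raw counts plus design; the pipeline's entry point.

    counts: genes x samples non-negative integer DataFrame (index = gene ids).
    design: sample -> group mapping covering every count column.
    roles:  naming of naive / reference / treatment groups within the design.
    """

    counts: pd.DataFrame
    design: pd.Series
    roles: Roles

    def __post_init__(self) -> None:
        self.design = pd.Series(self.design)
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ConfigurationError(f"design is missing samples: {missing}")
        groups = set(self.design.loc[list(self.counts.columns)])
        for role_name, group in (("naive", self.roles.naive), ("reference", self.roles.reference)):
            if group not in groups:
                raise ConfigurationError(
                    f"roles.{role_name} names group {group!r} absent from the design"
                )
        for t in self.roles.treatments:
            if t not in groups:
                raise ConfigurationError(f"treatment group {t!r} absent from the design")
        if not self.counts.index.is_unique:
            raise DataError("gene ids are not unique")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def subset_genes(self, genes: pd.Index) -> "CountStudy":
        return CountStudy(self.counts.loc[genes], self.design, self.roles)


@dataclass
class GroupExpression:
    """Per-gene linear-scale (CPM) mean expression for every group."""

    values: pd.DataFrame  # genes x groups, strictly positive
    roles: Roles

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def x_naive(self) -> pd.Series:
        return self.values[self.roles.naive]

    @property
    def x_pain(self) -> pd.Series:
        """Expression in the untreated disease reference group."""
        return self.values[self.roles.reference]

    def x_scs(self, treatment: str) -> pd.Series:
        if treatment not in self.roles.treatments:
            raise ConfigurationError(f"unknown treatment group {treatment!r}")
        return self.values[treatment]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    log_ratio_trim: float,
    abundance_trim: float,
) -> float:
    # Pairwise TMM factor of `obs` against the reference column, following the
    # standard published procedure: doubly trimmed, inverse-variance weighted
    # mean of per-gene log2 ratios of relative abundances.
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, var = log_r[finite], abs_e[finite], var[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abundance_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_r)
    rank_s = rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    log_ratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, geometric mean 1.

    The reference column is the sample whose upper-quartile relative abundance
    is closest to the mean upper quartile; ties resolve to the smallest sample
    index, so relabeling samples cannot change the result.
    """
    if counts.shape[1] < 2:
        raise DataError("TMM requires at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise DataError(f"sample {counts.columns[zero[0]]!r} has zero total count")
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref], log_ratio_trim, abundance_trim)
            for j in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million with TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.loc[counts.columns]
    return counts / lib * 1e6


def filter_genes(
    study: CountStudy,
    factors: pd.Series | None = None,
    min_cpm: float = 0.5,
    min_samples: int = 4,
) -> pd.Index:
    """Genes retained by the expression filter.

    A gene is kept iff its TMM-adjusted CPM is >= ``min_cpm`` in at least
    ``min_samples`` samples. The filter is monotone in counts: raising any
    count can only add qualifying samples.
    """
    if study.counts.shape[1] < min_samples:
        raise DataError(
            f"filter needs >= {min_samples} samples but the study has {study.counts.shape[1]}"
        )
    if factors is None:
        factors = tmm_factors(study.counts)
    c = cpm(study.counts, factors)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    logger.info("expression filter: retained %d / %d genes", int(keep.sum()), len(keep))
    return study.counts.index[keep]


def logcpm(
    counts: pd.DataFrame,
    factors: pd.Series,
    prior_count: float = 2.0,
) -> pd.DataFrame:
    """log2 counts-per-million with a library-size-scaled prior count.

    The global prior is scaled to each sample's relative effective library
    size, and each effective library size is augmented by twice its scaled
    prior, so the transform is finite everywhere and depth-consistent:

        logCPM = log2( (count + prior_s) / (lib_eff + 2 * prior_s) * 1e6 )
    """
    if prior_count <= 0:
        raise ConfigurationError(f"prior_count must be > 0, got {prior_count}")
    lib = counts.sum(axis=0).astype(float) * factors.loc[counts.columns]
    prior_s = prior_count * lib / lib.mean()
    x = counts.to_numpy(dtype=float)
    val = np.log2((x + prior_s.to_numpy()) / (lib + 2 * prior_s).to_numpy() * 1e6)
    return pd.DataFrame(val, index=counts.index, columns=counts.columns)


def group_mean_expression(
    expr: pd.DataFrame,
    design: pd.Series,
    roles: Roles,
    scale: str = "geometric",
) -> GroupExpression:
    """Per-group linear CPM summaries from a logCPM matrix.

    ``geometric`` back-transforms the group mean logCPM (2**mean); percent
    changes of expression are then ratios of geometric means. ``arithmetic``
    averages the linear CPM values instead.
    """
    if scale not in ("geometric", "arithmetic"):
        raise ConfigurationError(f"mean_scale must be geometric|arithmetic, got {scale!r}")
    cols = {}
    for group in roles.all_groups:
        samples = design.index[design == group]
        samples = [s for s in samples if s in expr.columns]
        if not samples:
            raise ConfigurationError(f"group {group!r} has no samples in the expression matrix")
        if scale == "geometric":
            cols[group] = np.power(2.0, expr[samples].mean(axis=1))
        else:
            cols[group] = np.power(2.0, expr[samples]).mean(axis=1)
    return GroupExpression(pd.DataFrame(cols, index=expr.index), roles)


def log2_fold_changes(ge: GroupExpression, reference: str | None = None) -> pd.DataFrame:
    """log2 fold change of every non-reference group against the reference.

    Column order puts the naive-vs-reference contrast first, then treatments,
    matching the presentation convention of the heat maps.
    """
    ref = reference if reference is not None else ge.roles.reference
    if ref not in ge.values.columns:
        raise ConfigurationError(f"reference group {ref!r} absent from group expression")
    others = [g for g in ge.values.columns if g != ref]
    # naive contrast first when present
    others.sort(key=lambda g: (g != ge.roles.naive,))
    fc = {g: np.log2(ge.values[g] / ge.values[ref]) for g in others}
    return pd.DataFrame(fc, index=ge.values.index)


@dataclass
class PreprocessResult:
    """All preprocessing outputs for one study."""

    factors_initial: pd.Series
    retained_genes: pd.Index
    factors: pd.Series
    logcpm: pd.DataFrame
    group_expression: GroupExpression
    fold_changes: pd.DataFrame
    params: dict = field(default_factory=dict)


def preprocess_study(
    study: CountStudy,
    min_cpm: float = 0.5,
    min_samples: int = 4,
    prior_count: float = 2.0,
    mean_scale: str = "geometric",
) -> PreprocessResult:
    """Full preprocessing: TMM -> filter -> re-TMM -> logCPM -> group means -> fold changes."""
    f0 = tmm_factors(study.counts)
    retained = filter_genes(study, f0, min_cpm=min_cpm, min_samples=min_samples)
    if len(retained) == 0:
        raise DataError("expression filter removed every gene")
    filtered = study.counts.loc[retained]
    f1 = tmm_factors(filtered)
    lc = logcpm(filtered, f1, prior_count=prior_count)
    ge = group_mean_expression(lc, study.design, study.roles, scale=mean_scale)
    fc = log2_fold_changes(ge)
    return PreprocessResult(
        factors_initial=f0,
        retained_genes=retained,
        factors=f1,
        logcpm=lc,
        group_expression=ge,
        fold_changes=fc,
        params={
            "min_cpm": min_cpm,
            "min_samples": min_samples,
            "prior_count": prior_count,
            "mean_scale": mean_scale,
        },
    )


def load_study(counts_tsv, design_tsv, roles: Roles) -> CountStudy:
    """Read a counts TSV (gene_id + one column per sample) and a design TSV
    (sample_id, group) into a CountStudy."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    design_df = pd.read_csv(design_tsv, sep="\t")
    if not {"sample_id", "group"} <= set(design_df.columns):
        raise ConfigurationError(
            f"design file {design_tsv} must have columns sample_id, group"
        )
    design = design_df.set_index("sample_id")["group"]
    return CountStudy(counts, design, roles)
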