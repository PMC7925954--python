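"""Per-gene recovery metrics and per-transcriptome summaries.

For a gene with linear-scale mean expression X_naive (healthy baseline),
X_pain (untreated disease reference) and X_SCS (a treatment arm):

    %C     = (X_pain - X_SCS_ref... ) see percent_change: (x - x_ref)/x_ref * 100
    R_f    = (X_pain - X_SCS) / (X_pain - X_naive)
    %C_SCS = (X_SCS - X_naive) / X_naive * 100

A transcriptome-level summary reports %C_p (share of genes with |%C| at or
above the change threshold), the up/down split among those changed genes,
%R_SCS (share of changed genes whose R_f satisfies the recovery rule) and
%D_n (share of changed genes ending within the near-naive band), plus the
Pearson correlation between the treatment-vs-reference and the
naive-vs-reference log2 fold-change profiles.

Two recovery rules are always computed side by side: ``le_one`` (R_f <= 1,
which also admits genes that moved away from baseline) and ``unit_interval``
(0 <= R_f <= 1, movement strictly toward and not past baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, UndefinedStatisticError
from .preprocess import GroupExpression

logger = logging.getLogger(__name__)

__all__ = [
    "Thresholds",
    "CorrelationResult",
    "TreatmentStats",
    "RecoverySummary",
    "percent_change",
    "recovery_factor",
    "scs_residual",
    "strength_label",
    "correlate_profiles",
    "gene_metrics",
    "summarize_transcriptome",
    "summary_table",
]

RF_RULES = ("le_one", "unit_interval")

# Qualitative labels for |R| on the conventional published scale.
_STRENGTH_BINS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (np.inf, "very strong"),
)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the transcriptome summaries.

    change_min:     minimum |%C| (as a fraction, 0.10 = 10%) for a gene to
                    count as changed by the disease model.
    near_naive_max: |%C_SCS| band (fraction) for a gene to count as ending
                    near baseline.
    rf_cut:         upper cut of the recovery-factor rule (1.0 = full return).
    rf_rule:        'le_one' (R_f <= rf_cut) or 'unit_interval'
                    (0 <= R_f <= rf_cut); both are always reported, this
                    selects which one downstream consumers treat as primary.
    alpha:          significance level for the profile correlations.
    """

    change_min: float = 0.10
    near_naive_max: float = 0.15
    rf_cut: float = 1.0
    rf_rule: str = "le_one"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.change_min < 1:
            raise ConfigurationError(f"change_min must be in (0,1), got {self.change_min}")
        if not 0 < self.near_naive_max < 1:
            raise ConfigurationError(
                f"near_naive_max must be in (0,1), got {self.near_naive_max}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.rf_rule not in RF_RULES:
            raise ConfigurationError(f"rf_rule must be one of {RF_RULES}, got {self.rf_rule!r}")


def percent_change(x, x_ref):
    """Signed percent change of ``x`` relative to ``x_ref``: (x-x_ref)/x_ref*100.

    Undefined (NaN) where the reference is zero; scale-invariant under
    x -> a*x (a > 0) applied to both arguments.
    """
    x = np.asarray(x, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x_ref != 0, (x - x_ref) / x_ref * 100.0, np.nan)
    return out if out.ndim else float(out)


def recovery_factor(x_pain, x_scs, x_naive):
    """Recovery factor R_f = (X_pain - X_SCS) / (X_pain - X_naive).

    1 = full return to baseline, 0 = no movement, negative = moved away,
    > 1 = overshot past baseline. Undefined (NaN) where X_pain == X_naive.
    Invariant under any affine map x -> a*x + b (a != 0) of all three inputs.
    """
    x_pain = np.asarray(x_pain, dtype=float)
    x_scs = np.asarray(x_scs, dtype=float)
    x_naive = np.asarray(x_naive, dtype=float)
    denom = x_pain - x_naive
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (x_pain - x_scs) / denom, np.nan)
    return out if out.ndim else float(out)


def scs_residual(x_scs, x_naive):
    """Residual percent difference from baseline after treatment:
    %C_SCS = (X_SCS - X_naive) / X_naive * 100."""
    return percent_change(x_scs, x_naive)


def strength_label(r: float) -> str:
    """Qualitative label for a correlation magnitude (cosmetic only)."""
    a = abs(r)
    for cut, label in _STRENGTH_BINS:
        if a < cut:
            return label
    return "very strong"  # pragma: no cover


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    significant: bool
    strength: str


def correlate_profiles(
    fc: pd.DataFrame,
    treatment: str,
    genes,
    naive: str | None = None,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson correlation between a treatment's and the naive group's log2
    fold-change profiles (both against the untreated reference), restricted
    to a gene list.

    p-value is the two-sided t-transform with n-2 degrees of freedom.
    """
    if naive is None:
        naive = fc.columns[0]
    for col in (treatment, naive):
        if col not in fc.columns:
            raise ConfigurationError(f"column {col!r} absent from fold-change table")
    sub = fc.loc[[g for g in genes if g in fc.index], [treatment, naive]].dropna()
    n = len(sub)
    if n < 3:
        raise UndefinedStatisticError(
            f"correlation needs >= 3 genes with finite fold changes, got {n}"
        )
    x = sub[treatment].to_numpy()
    y = sub[naive].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            f"correlation undefined: zero variance in the {treatment!r} vs {naive!r} profiles"
        )
    r, p = stats.pearsonr(x, y)
    r, p = float(r), float(p)
    return CorrelationResult(
        r=r, p=p, n=n, significant=bool(p < alpha), strength=strength_label(r)
    )


def gene_metrics(
    ge: GroupExpression,
    genes=None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-gene metric table: %C with direction and changed flag, and per
    treatment R_f and %C_SCS. Genes absent from the expression universe are
    dropped (callers account for them via cross-referencing)."""
    if genes is None:
        idx = ge.gene_ids
    else:
        idx = pd.Index([g for g in genes if g in ge.gene_ids])
    if len(idx) == 0:
        raise DataError("gene_metrics: no requested genes present in the expression universe")
    xp = ge.x_pain.loc[idx]
    xn = ge.x_naive.loc[idx]
    pc = percent_change(xp, xn)
    out = pd.DataFrame(index=idx)
    out["x_naive"] = xn
    out["x_pain"] = xp
    out["pct_change"] = pc
    out["changed"] = np.abs(pc) >= thresholds.change_min * 100.0
    out["direction"] = np.where(pc > 0, "up", np.where(pc < 0, "down", "none"))
    for t in ge.roles.treatments:
        xs = ge.x_scs(t).loc[idx]
        out[f"rf_{t}"] = recovery_factor(xp, xs, xn)
        out[f"cscs_{t}"] = scs_residual(xs, xn)
    return out


@dataclass(frozen=True)
class TreatmentStats:
    """Per-treatment slice of a transcriptome summary."""

    treatment: str
    r: float | None
    p: float | None
    n_corr: int
    significant: bool | None
    strength: str
    pct_recovered_le_one: float | None
    pct_recovered_unit_interval: float | None
    pct_near_naive: float | None
    n_rf_defined: int
    n_rf_undefined: int


@dataclass(frozen=True)
class RecoverySummary:
    """One transcriptome's row of the recovery report."""

    name: str
    n_input: int
    n_absent: int
    n_genes: int
    n_changed: int
    pct_changed: float
    up_share: float | None
    down_share: float | None
    treatments: dict[str, TreatmentStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # exclusion bookkeeping must reconcile
        assert self.n_input == self.n_genes + self.n_absent


def _share(mask: np.ndarray, denom: int) -> float | None:
    return float(100.0 * mask.sum() / denom) if denom else None


def summarize_transcriptome(
    ge: GroupExpression,
    genes,
    thresholds: Thresholds = Thresholds(),
    name: str = "",
    fc: pd.DataFrame | None = None,
) -> RecoverySummary:
    """Summarize one transcriptome's disease response and treatment recovery.

    ``genes`` is the transcriptome's symbol list; symbols absent from the
    expression universe are counted as excluded (n_input = n_used + n_absent).
    %R_SCS and %D_n are computed over the disease-changed genes
    (|%C| >= change threshold); the profile correlations over all genes of
    the transcriptome present in the universe.
    """
    genes = list(genes)
    if not genes:
        raise DataError(f"transcriptome {name!r}: empty gene list")
    present = [g for g in genes if g in ge.gene_ids]
    if not present:
        raise DataError(
            f"transcriptome {name!r}: none of {len(genes)} genes are in the expression universe"
        )
    metrics = gene_metrics(ge, present, thresholds)
    changed = metrics[metrics["changed"]]
    n_changed = len(changed)
    pct_changed = 100.0 * n_changed / len(metrics)
    up = (changed["direction"] == "up").to_numpy()
    up_share = _share(up, n_changed)
    down_share = _share(~up, n_changed)

    if fc is None:
        from .preprocess import log2_fold_changes

        fc = log2_fold_changes(ge)

    per_treatment: dict[str, TreatmentStats] = {}
    for t in ge.roles.treatments:
        rf = changed[f"rf_{t}"].to_numpy()
        defined = np.isfinite(rf)
        n_def = int(defined.sum())
        n_undef = int(n_changed - n_def)
        if n_undef:
            logger.info(
                "%s/%s: %d changed genes with undefined recovery factor excluded",
                name, t, n_undef,
            )
        rf_d = rf[defined]
        cscs = changed[f"cscs_{t}"].to_numpy()[defined]
        try:
            corr = correlate_profiles(
                fc, t, present, naive=ge.roles.naive, alpha=thresholds.alpha
            )
            r, p, n_corr, sig, strength = (
                corr.r, corr.p, corr.n, corr.significant, corr.strength,
            )
        except UndefinedStatisticError as exc:
            logger.warning("%s/%s: correlation undefined (%s)", name, t, exc)
            r = p = sig = None
            n_corr, strength = 0, "undefined"
        per_treatment[t] = TreatmentStats(
            treatment=t,
            r=r,
            p=p,
            n_corr=n_corr,
            significant=sig,
            strength=strength,
            pct_recovered_le_one=_share(rf_d <= thresholds.rf_cut, n_def),
            pct_recovered_unit_interval=_share(
                (rf_d >= 0) & (rf_d <= thresholds.rf_cut), n_def
            ),
            pct_near_naive=_share(
                np.abs(cscs) <= thresholds.near_naive_max * 100.0, n_def
            ),
            n_rf_defined=n_def,
            n_rf_undefined=n_undef,
        )
    return RecoverySummary(
        name=name,
        n_input=len(genes),
        n_absent=len(genes) - len(present),
        n_genes=len(metrics),
        n_changed=n_changed,
        pct_changed=pct_changed,
        up_share=up_share,
        down_share=down_share,
        treatments=per_treatment,
    )


def summary_table(summaries: list[RecoverySummary]) -> pd.DataFrame:
    """Flatten summaries into one row per transcriptome (report shape).

    Raw p-values are reported as in the underlying analysis; a Bonferroni
    column (adjusted across all transcriptome x treatment tests in the table)
    is added for transparency and never gates anything.
    """
    n_tests = sum(len(s.treatments) for s in summaries)
    rows = []
    for s in summaries:
        row: dict = {
            "transcriptome": s.name,
            "n_input": s.n_input,
            "n_absent": s.n_absent,
            "n_genes": s.n_genes,
            "n_changed": s.n_changed,
            "pct_changed": s.pct_changed,
            "up_share": s.up_share,
            "down_share": s.down_share,
        }
        for t, ts in s.treatments.items():
            row[f"r_{t}"] = ts.r
            row[f"p_{t}"] = ts.p
            row[f"p_bonferroni_{t}"] = (
                min(1.0, ts.p * n_tests) if ts.p is not None else None
            )
            row[f"significant_{t}"] = ts.significant
            row[f"strength_{t}"] = ts.strength
            row[f"pct_recovered_le_one_{t}"] = ts.pct_recovered_le_one
            row[f"pct_recovered_unit_interval_{t}"] = ts.pct_recovered_unit_interval
            row[f"pct_near_naive_{t}"] = ts.pct_near_naive
            row[f"n_rf_undefined_{t}"] = ts.n_rf_undefined
        rows.append(row)
    return pd.DataFrame(rows)
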