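"""Heat maps and marker-panel views of fold-change profiles.

Rendering follows the source presentation conventions: one column per
contrast against the untreated reference (naive first, then each treatment),
a diverging palette centered at zero with blue for up-regulation and red for
down-regulation (the inverse of the usual default; ``blue_up=False``
restores standard polarity), and a deterministic gene ordering (by the
naive-contrast fold change by default; hierarchical clustering optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DataError
from .metrics import percent_change
from .preprocess import GroupExpression

logger = logging.getLogger(__name__)

__all__ = [
    "HeatmapSpec",
    "MarkerPanel",
    "ordered_fold_change_matrix",
    "render_heatmap",
    "build_marker_panel",
]

ORDER_POLICIES = ("by_naive_fc", "cluster", "input_order")


@dataclass(frozen=True)
class HeatmapSpec:
    """Presentation choices for a fold-change heat map."""

    order: str = "by_naive_fc"
    blue_up: bool = True
    clip: float | None = None  # symmetric |log2FC| color range; None = data-driven

    def __post_init__(self) -> None:
        if self.order not in ORDER_POLICIES:
            raise DataError(f"order policy must be one of {ORDER_POLICIES}, got {self.order!r}")

    @property
    def cmap(self) -> str:
        # RdBu runs red (low) -> blue (high): blue marks up-regulation.
        return "RdBu" if self.blue_up else "RdBu_r"


def ordered_fold_change_matrix(
    fc: pd.DataFrame, genes, spec: HeatmapSpec = HeatmapSpec()
) -> pd.DataFrame:
    """Fold-change submatrix for a gene list in the spec's display order.

    Genes absent from the table are dropped with a warning; an entirely
    absent list is an error. The clustering policy uses average-linkage
    Euclidean clustering with a fixed leaf order, so reruns are identical.
    """
    genes = list(genes)
    present = [g for g in genes if g in fc.index]
    missing = len(genes) - len(present)
    if not present:
        raise DataError("none of the requested genes are in the fold-change table")
    if missing:
        logger.warning("heat map: dropped %d genes absent from the fold-change table", missing)
    sub = fc.loc[present]
    if spec.order == "by_naive_fc":
        sub = sub.sort_values(sub.columns[0], ascending=False, kind="mergesort")
    elif spec.order == "cluster" and len(sub) > 2:
        link = hierarchy.linkage(pdist(sub.to_numpy()), method="average")
        leaves = hierarchy.leaves_list(link)
        sub = sub.iloc[leaves]
    return sub


def render_heatmap(
    fc: pd.DataFrame,
    genes,
    out_path,
    spec: HeatmapSpec = HeatmapSpec(),
    title: str = "",
) -> Path:
    """Render a fold-change heat map to ``out_path`` and return the path."""
    sub = ordered_fold_change_matrix(fc, genes, spec)
    vmax = spec.clip if spec.clip is not None else float(np.nanmax(np.abs(sub.to_numpy())))
    if vmax == 0:
        vmax = 1.0
    height = min(12.0, max(2.5, 0.18 * len(sub) + 1.5))
    fig, ax = plt.subplots(figsize=(1.2 * sub.shape[1] + 2.5, height))
    sns.heatmap(
        sub,
        cmap=spec.cmap,
        center=0.0,
        vmin=-vmax,
        vmax=vmax,
        yticklabels=len(sub) <= 60,
        cbar_kws={"label": "log2 fold change vs reference"},
        ax=ax,
    )
    if title:
        ax.set_title(title)
    ax.set_xlabel("contrast vs untreated reference")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out_path


@dataclass(frozen=True)
class MarkerPanel:
    """User-supplied marker symbols grouped by functional class.

    Only markers changed by the disease model by strictly more than
    ``threshold`` (fraction; 0.15 = 15%) relative to baseline are displayed.
    """

    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    threshold: float = 0.15


def build_marker_panel(
    ge: GroupExpression,
    panel: MarkerPanel,
    fc: pd.DataFrame | None = None,
    out_path=None,
    spec: HeatmapSpec = HeatmapSpec(order="input_order"),
) -> pd.DataFrame:
    """Filter a marker panel by disease-response magnitude and optionally
    render the retained markers as a grouped heat map.

    A marker is retained iff |%C| > threshold (strict inequality). Returns
    the full marker table with columns marker, group, present, pct_change,
    included; an empty retained set is reported, not an error.
    """
    rows = []
    for group, markers in panel.groups.items():
        for m in markers:
            present = m in ge.gene_ids
            pc = (
                float(percent_change(ge.x_pain.loc[m], ge.x_naive.loc[m]))
                if present
                else np.nan
            )
            rows.append(
                {
                    "marker": m,
                    "group": group,
                    "present": present,
                    "pct_change": pc,
                    "included": bool(present and abs(pc) > panel.threshold * 100.0),
                }
            )
    table = pd.DataFrame(rows)
    retained = table[table["included"]]["marker"].tolist() if len(table) else []
    if not retained:
        logger.warning("marker panel: no marker passes the %.0f%% filter", panel.threshold * 100)
    elif out_path is not None:
        if fc is None:
            from .preprocess import log2_fold_changes

            fc = log2_fold_changes(ge)
        render_heatmap(fc, retained, out_path, spec=spec, title="marker panel")
    return table
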