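"""Two-group comparison statistics for per-image metric tables.

Per metric: Mann–Whitney U with two-sided p (exact enumeration for small
tie-free samples, tie-corrected normal approximation otherwise), Cliff's
delta effect size with the conventional magnitude classes (negligible
< 0.147, small to 0.33, medium to 0.474, large beyond), and ROC-AUC with
the raw metric values as predictor scores (ties count 1/2; the
direction-free ``auc_flipped = max(auc, 1 - auc)`` is reported alongside).
Spearman correlation matrices summarize metric co-dependence within a
condition or timepoint.

No multiple-testing correction is applied by default (raw per-metric
p-values); Benjamini–Hochberg adjustment is available via a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "GroupComparison",
    "mann_whitney",
    "cliffs_delta",
    "classify_magnitude",
    "roc_auc",
    "spearman_matrix",
    "normalize_per_node",
    "compare_groups",
    "significance_stars",
    "MAGNITUDE_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: |delta| cut-points between negligible/small/medium/large.
MAGNITUDE_THRESHOLDS: tuple[float, float, float] = (0.147, 0.33, 0.474)

# largest sample size for which the exact (enumerative) Mann-Whitney p is
# used when the data are tie-free
_EXACT_MAX_N = 8


@dataclass
class GroupComparison:
    """One metric's two-group comparison row."""

    metric: str
    u_statistic: float
    p_value: float
    cliffs_delta: float
    magnitude: str
    auc: float
    auc_flipped: float
    stars: str


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"sample '{name}' is empty")
    return arr


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann–Whitney U statistic of x vs. y and two-sided p-value.

    The exact null distribution is enumerated when min(n, m) <= 8 and the
    pooled sample has no ties; otherwise the normal approximation with tie
    correction (and continuity correction) is used.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= _EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def classify_magnitude(delta: float) -> str:
    """Magnitude class of a Cliff's delta; boundaries fall in the lower class."""
    a = abs(delta)
    lo, mid, hi = MAGNITUDE_THRESHOLDS
    if a <= lo:
        return "negligible"
    if a <= mid:
        return "small"
    if a <= hi:
        return "medium"
    return "large"


def cliffs_delta(x, y) -> tuple[float, str]:
    """Cliff's delta (#{x>y} - #{x<y}) / (n m) and its magnitude class."""
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    diff = x[:, None] - y[None, :]
    delta = float((np.sum(diff > 0) - np.sum(diff < 0)) / diff.size)
    return delta, classify_magnitude(delta)


def roc_auc(scores, labels) -> tuple[float, float]:
    """ROC-AUC of raw metric values against binary group labels.

    Returns ``(auc, auc_flipped)``.  AUC is the probability that a random
    positive-label score outranks a random negative one, ties counting 1/2
    (equivalently U / (n m)); the flipped value max(auc, 1 - auc) measures
    discriminability regardless of direction.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain exactly two classes")
    auc = float(roc_auc_score(labels, scores))
    return auc, max(auc, 1.0 - auc)


def spearman_matrix(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    group_col: str | None = None,
    group: object | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman rho over metric columns, optionally group-filtered.

    Ties are handled by average ranks.  Constant columns have undefined
    correlation and are left as NaN (missing), never coerced to 0.
    """
    if group_col is not None:
        table = table[table[group_col] == group]
    if columns is not None:
        table = table[columns]
    else:
        table = table.select_dtypes(include=[np.number])
    if len(table) < 3:
        raise ValueError("Spearman matrix requires at least 3 rows")
    corr = table.corr(method="spearman")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        logger.warning("constant columns have undefined rho: %s", constant)
    return corr


def normalize_per_node(
    table: pd.DataFrame, which: list[str], suffix: str = "_per_node"
) -> pd.DataFrame:
    """Divide the named metric columns by each image's node count.

    Adds suffixed columns; originals are retained.  Metrics that are
    already per-node averages are divided anyway if requested (caller's
    choice), with a log note.
    """
    if "n_nodes" not in table.columns:
        raise ValueError("table lacks an 'n_nodes' column")
    if (table["n_nodes"] <= 0).any():
        raise ValueError("n_nodes must be positive for per-node normalization")
    out = table.copy()
    for name in which:
        if name.startswith("avg_"):
            logger.info("normalizing '%s', which is already a per-node average", name)
        out[name + suffix] = out[name] / out["n_nodes"]
    return out


def significance_stars(p: float) -> str:
    """Star annotation: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    table: pd.DataFrame,
    group_col: str,
    group_a: object,
    group_b: object,
    metrics: list[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-metric two-group comparison table.

    ``group_b`` is the positive (label 1) class for ROC-AUC, matching the
    sparse = 0 / dense = 1 labeling convention when called as
    ``compare_groups(t, "group", "sparse", "dense")``.  ``fdr`` adds
    Benjamini–Hochberg adjusted p-values.
    """
    labels_present = set(table[group_col].unique())
    for grp in (group_a, group_b):
        if grp not in labels_present:
            raise ValueError(
                f"group {grp!r} not found; available: {sorted(map(str, labels_present))}"
            )
    if metrics is None:
        metrics = [
            c
            for c in table.select_dtypes(include=[np.number]).columns
            if c != group_col
        ]
    a = table[table[group_col] == group_a]
    b = table[table[group_col] == group_b]

    rows = []
    for name in metrics:
        xa = a[name].to_numpy(dtype=float)
        xb = b[name].to_numpy(dtype=float)
        u, p = mann_whitney(xa, xb)
        delta, magnitude = cliffs_delta(xa, xb)
        scores = np.concatenate([xa, xb])
        labels = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
        auc, auc_flipped = roc_auc(scores, labels)
        rows.append(
            GroupComparison(
                metric=name,
                u_statistic=u,
                p_value=p,
                cliffs_delta=delta,
                magnitude=magnitude,
                auc=auc,
                auc_flipped=auc_flipped,
                stars=significance_stars(p),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if fdr:
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    return out
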