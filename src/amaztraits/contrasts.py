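"""Felsenstein's independent contrasts and raw/contrast Pearson correlations.

Related tips do not contribute independent data points, so correlations on
raw genus values overstate the effective sample size.  Independent contrasts
remove this pseudo-replication: on a binary tree each internal node yields
one standardized difference between its two daughter lineages, and under
Brownian motion the n − 1 contrasts are mutually independent with unit
variance.  Correlations between two sets of contrasts are computed without
centering and the fitted line is forced through the origin, because the
sign of every contrast is an arbitrary orientation choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ZeroBranchError
from .phylo_core import Phylogeny

__all__ = ["ContrastSet", "CorrelationResult", "pic", "pearson_raw", "pearson_pic"]


@dataclass
class ContrastSet:
    """Standardized contrasts, one per bifurcating internal node."""

    contrasts: np.ndarray        # (n-1,) standardized contrast values
    node_ids: np.ndarray         # stable node id of the node producing each
    node_values: np.ndarray      # the weighted ancestral value at each node


@dataclass
class CorrelationResult:
    r: float
    n_effective: int             # pairs (raw) or contrasts (PIC)
    p_value: float
    variant: str                 # "raw" | "pic_through_origin"
    slope: float


def pic(
    tree: Phylogeny,
    x: np.ndarray,
    zero_branch_policy: str = "jitter",
) -> ContrastSet:
    """Phylogenetically independent contrasts on a binary tree.

    The post-order recursion at each internal node with daughters (i, j),
    branch lengths (b_i, b_j) after lengthening, computes the contrast
    (x_i − x_j)/√(b_i + b_j), assigns the node the branch-length-weighted
    average of the daughters and lengthens its parent branch by
    b_i·b_j/(b_i + b_j).  Contrast orientation is deterministic: the daughter
    whose subtree contains the lexicographically smallest tip label is the
    minuend (correlations are orientation-invariant regardless).

    Two zero-length daughters (as produced by polytomy resolution) make the
    contrast denominator zero; by default both branches receive a jitter of
    1e-8 × tree depth, while ``zero_branch_policy="strict"`` raises instead.

    Unary pass-through nodes (a pruned tree's root stem) transfer value and
    variance without producing a contrast, so a tree with n tips always
    yields n − 1 contrasts.
    """
    x = np.asarray(x, dtype=float)
    tips = tree.tips
    if len(x) != len(tips):
        raise ValueError("trait vector length must equal the number of tips")
    if any(len(n.children) > 2 for n in tree.internal_nodes):
        raise ValueError(
            "tree contains polytomies; resolve with resolve_polytomies() first"
        )
    jitter = 1e-8 * tree.depth()
    tip_value = {t: x[i] for i, t in enumerate(tips)}

    value: dict = {}
    extra: dict = {}       # added variance accumulated by the recursion
    min_label: dict = {}
    out_contrasts: list[float] = []
    out_ids: list[int] = []
    out_values: list[float] = []

    for node in tree.postorder():
        if node.is_tip:
            value[node] = tip_value[node]
            extra[node] = 0.0
            min_label[node] = node.label
            continue
        if len(node.children) == 1:
            (c,) = node.children
            value[node] = value[c]
            extra[node] = c.length + extra[c]
            min_label[node] = min_label[c]
            continue
        a, b = node.children
        if min_label[b] < min_label[a]:
            a, b = b, a
        va = a.length + extra[a]
        vb = b.length + extra[b]
        if va + vb == 0.0:
            if zero_branch_policy == "strict":
                raise ZeroBranchError(
                    f"zero combined branch length at node {node.id}; use the "
                    "default jitter policy or add branch-length jitter"
                )
            va = vb = jitter
        contrast = (value[a] - value[b]) / np.sqrt(va + vb)
        # precision-weighted average written without per-branch reciprocals,
        # so a single zero-length daughter (weight -> infinity) is exact
        value[node] = (value[a] * vb + value[b] * va) / (va + vb)
        extra[node] = va * vb / (va + vb)
        min_label[node] = min(min_label[a], min_label[b])
        out_contrasts.append(contrast)
        out_ids.append(node.id)
        out_values.append(value[node])

    return ContrastSet(
        np.asarray(out_contrasts), np.asarray(out_ids), np.asarray(out_values)
    )


def pearson_raw(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Ordinary centered Pearson correlation with its two-sided t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    r, p = stats.pearsonr(x, y)
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    return CorrelationResult(float(r), n, float(p), "raw", slope)


def pearson_pic(u: ContrastSet, v: ContrastSet) -> CorrelationResult:
    """Through-origin (uncentered) correlation between two contrast sets.

    r = Σuᵢvᵢ / √(Σuᵢ² Σvᵢ²) with a two-sided t test on n_contrasts − 1
    degrees of freedom (the origin-forced regression estimates one
    parameter, the slope Σuᵢvᵢ/Σuᵢ²).
    """
    if u.node_ids.shape != v.node_ids.shape or not np.array_equal(u.node_ids, v.node_ids):
        raise ValueError("contrast sets come from different trees or node orders")
    uu = float(u.contrasts @ u.contrasts)
    vv = float(v.contrasts @ v.contrasts)
    uv = float(u.contrasts @ v.contrasts)
    if uu == 0 or vv == 0:
        raise ValueError("correlation undefined: all-zero contrasts in an input")
    r = uv / np.sqrt(uu * vv)
    n = len(u.contrasts)
    df = n - 1
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(float(r_clip), n, p, "pic_through_origin", uv / uu)
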