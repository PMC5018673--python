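"""ML ancestral-state reconstruction and the tip-randomization node scan.

Under Brownian motion the maximum-likelihood ancestral value at an internal
node is the generalized-least-squares estimate given the tips —
equivalently, the branch-length-weighted mean obtained by re-rooting the
tree at that node.  Because that estimate is a fixed linear combination of
the tip values, the whole reconstruction is a single matrix product
``W @ x`` with a weight matrix ``W`` that depends only on the tree; ``W``
is computed once by running the two-pass (tip-to-root, then root-to-tip)
recursion on the identity basis.

The scan then asks which lineages carry significantly high or low values:
tip labels are shuffled ``n_perm`` times, the ancestral values recomputed
each time, and each node's observed estimate compared with its permutation
distribution.  ``prob_smaller`` is the fraction of randomizations whose
reconstructed value is strictly smaller than the observed one; a node is
flagged ``high`` when the observed value exceeds 97.5% of randomizations
and ``low`` when it falls below 97.5% of them, with ties counting toward
neither tail so both flags stay conservative.  No multiple-testing correction is
applied across nodes — the report carries node counts so users can correct
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LabelError
from .phylo_core import Phylogeny

__all__ = [
    "AncestralReconstruction",
    "NodeScan",
    "asr_weight_matrix",
    "asr_ml",
    "permutation_scan",
    "scan_report",
]

HIGH_THRESHOLD = 0.975
LOW_THRESHOLD = 0.025


@dataclass
class AncestralReconstruction:
    node_ids: np.ndarray      # stable ids of internal nodes, preorder
    estimates: np.ndarray     # ML ancestral value per internal node

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.node_ids.tolist(), self.estimates.tolist()))


@dataclass
class NodeScan:
    node_ids: np.ndarray
    estimates: np.ndarray     # observed ancestral estimates
    prob_smaller: np.ndarray  # fraction of randomizations strictly below
    classification: np.ndarray  # "high" | "low" | "ns"
    n_perm: int
    seed: int


def asr_weight_matrix(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Weight matrix W with one row per internal node: estimate = W @ tips.

    Upward pass: each node receives the precision-weighted mean of its
    daughters and an added variance b_i·b_j/(b_i + b_j) (the contrasts
    bookkeeping).  Downward pass: each internal node combines its below
    estimate with the rest-of-tree estimate arriving through its parent.
    The root row reproduces the GLS mean μ̂.  Zero-length daughter pairs are
    guarded with a tiny variance floor so zero-length polytomy resolutions
    remain analyzable.
    """
    tips = tree.tips
    n = len(tips)
    tip_index = {t: i for i, t in enumerate(tips)}
    floor = max(1e-12 * tree.depth(), 1e-300)

    below: dict = {}       # node -> (weight vector over tips, variance at node)
    for node in tree.postorder():
        if node.is_tip:
            vec = np.zeros(n)
            vec[tip_index[node]] = 1.0
            below[node] = (vec, 0.0)
        elif len(node.children) == 1:
            (c,) = node.children
            vec, eps = below[c]
            below[node] = (vec, eps + c.length)
        else:
            # precision-weighted combination of any number of daughters
            vs = [max(c.length + below[c][1], floor) for c in node.children]
            w = sum(1.0 / v for v in vs)
            vec = sum(below[c][0] / v for c, v in zip(node.children, vs)) / w
            below[node] = (vec, 1.0 / w)

    # above[node]: rest-of-tree estimate measured at node, or None when the
    # node hangs below a bare root stem and nothing lies above it
    above: dict = {}
    rows: list[np.ndarray] = []
    ids: list[int] = []
    for node in tree.preorder():
        parent = node.parent
        if parent is not None:
            parts = [
                (below[s][0], max(s.length + below[s][1], floor))
                for s in parent.children
                if s is not node
            ]
            parent_above = above.get(parent)
            if parent_above is not None:
                parts.append(parent_above)
            if parts:
                w = sum(1.0 / v for _, v in parts)
                avec = sum(vec / v for vec, v in parts) / w
                above[node] = (avec, 1.0 / w + node.length)
            else:
                above[node] = None
        if node.is_tip:
            continue
        bvec, beps = below[node]
        node_above = above.get(node)
        if parent is None or node_above is None:
            est = bvec       # root (or stem-only ancestor): the GLS mean
        else:
            avec, avar = node_above
            vb = max(beps, floor)
            va = max(avar, floor)
            est = (bvec / vb + avec / va) / (1.0 / vb + 1.0 / va)
        rows.append(est)
        ids.append(node.id)
    W = np.vstack(rows)
    return W, np.asarray(ids)


def asr_ml(tree: Phylogeny, x: np.ndarray) -> AncestralReconstruction:
    """ML (GLS) ancestral value at every internal node; root value is μ̂."""
    x = np.asarray(x, dtype=float)
    if len(x) != tree.n_tips:
        raise ValueError("trait vector length must equal the number of tips")
    W, ids = asr_weight_matrix(tree)
    return AncestralReconstruction(ids, W @ x)


def permutation_scan(
    tree: Phylogeny,
    x: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> NodeScan:
    """Tip-randomization significance scan over all internal nodes.

    Trait values are shuffled across the matched tips ``n_perm`` times with
    an independent child stream per replicate (spawned from one seed
    sequence, so parallel and serial execution agree), ancestral values are
    recomputed for each shuffle, and each node's observed estimate is
    located within its permutation distribution.
    """
    x = np.asarray(x, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    W, ids = asr_weight_matrix(tree)
    observed = W @ x

    n = len(x)
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    X = np.empty((n, n_perm))
    for r, child in enumerate(streams):
        rng = np.random.default_rng(child)
        X[:, r] = x[rng.permutation(n)]
    perm_estimates = W @ X                      # (n_internal, n_perm)
    # ties (within floating-point resolution) count as neither smaller nor
    # greater, so both tails stay conservative: a constant trait, where every
    # permuted reconstruction equals the observed one, flags nothing
    tol = 1e-9 * (1.0 + np.abs(observed))[:, None]
    prob_smaller = (perm_estimates < observed[:, None] - tol).mean(axis=1)
    prob_greater = (perm_estimates > observed[:, None] + tol).mean(axis=1)

    classification = np.full(len(ids), "ns", dtype=object)
    classification[prob_smaller > HIGH_THRESHOLD] = "high"
    classification[prob_greater > HIGH_THRESHOLD] = "low"
    return NodeScan(ids, observed, prob_smaller, classification, n_perm, seed)


def scan_report(
    scan: NodeScan,
    labels: dict[int, str] | None = None,
    include_unlabeled: bool = True,
) -> pd.DataFrame:
    """Tabulate a scan: one row per node with lineage name, estimate,
    prob_smaller and classification, in tree-traversal order.

    ``labels`` maps node ids to lineage names (e.g. family names); unknown
    ids raise.  Unlabeled nodes get a synthetic ``node<id>`` name, or are
    dropped when ``include_unlabeled`` is False.
    """
    labels = labels or {}
    known = set(scan.node_ids.tolist())
    unknown = set(labels) - known
    if unknown:
        raise LabelError(f"labels reference unknown node ids: {sorted(unknown)}")
    rows = []
    for i, nid in enumerate(scan.node_ids.tolist()):
        if nid in labels:
            name = labels[nid]
        elif include_unlabeled:
            name = f"node{nid}"
        else:
            continue
        rows.append(
            {
                "lineage": name,
                "node_id": nid,
                "reconstructed_value": scan.estimates[i],
                "prob_smaller": scan.prob_smaller[i],
                "classification": scan.classification[i],
            }
        )
    return pd.DataFrame(rows)
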