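"""Maximum-likelihood ancestral reconstruction under Brownian motion.

Chromosome number (usually on the log scale) is modelled as Brownian motion
with rate ``sigma2`` per unit time.  Ancestral values are computed with the
standard two-pass message passing on the tree: a tipward pass combines each
node's descendant information into a conditional mean and variance, a
rootward pass propagates everything outside the subtree, and the two
Gaussians are merged per node.  The point estimates are identical to a
generalised-least-squares solve against the full phylogenetic covariance
matrix, but the passes cost O(n) instead of O(n^3).

The root estimate equals the GLS phylogenetically weighted mean of the tip
values; ``sigma2`` is the maximum-likelihood estimate (dividing by n, not
n - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tree import TimeTree

__all__ = ["BMFit", "bm_ancestral", "node_means_at"]


@dataclass
class BMFit:
    """Brownian-motion fit with per-node ancestral estimates.

    ``estimates[v]`` is the posterior (ML) point estimate of the trait at
    node ``v`` (observed value at tips); ``variances[v]`` the corresponding
    variance in trait units (0 at tips).
    """

    sigma2: float
    root_value: float
    estimates: np.ndarray
    variances: np.ndarray
    loglik: float


def bm_ancestral(tree: TimeTree, tip_values: Sequence[float] | np.ndarray) -> BMFit:
    """Fit BM and reconstruct ancestral values at every internal node.

    Zero-length terminal branches are tolerated (the node estimate is then
    pinned to the attached tip); a fully degenerate tree whose branches sum
    to zero has no likelihood and is rejected.
    """
    x = np.asarray(tip_values, dtype=float)
    if x.shape[0] != tree.n_tips:
        raise ValueError("one value per tip required")
    if not np.all(np.isfinite(x)):
        raise ValueError("tip values must be finite")
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips for a BM reconstruction")
    if float(tree.blen.sum()) == 0.0:
        raise ValueError("tree has zero total branch length; BM likelihood degenerate")

    n_nodes = tree.n_nodes
    n = tree.n_tips
    # tipward pass: m[v], d[v] such that x_v | data below v ~ N(m, sigma2 * d)
    m = np.zeros(n_nodes)
    d = np.zeros(n_nodes)
    m[:n] = x
    ss = 0.0  # scaled sum of squares; sigma2_ML = ss / n
    logdet = 0.0
    for v in tree.postorder:
        v = int(v)
        if v < n:
            continue
        kids = tree.children[v]
        vc = np.array([tree.blen[c] + d[c] for c in kids])
        mc = np.array([m[c] for c in kids])
        if np.any(vc == 0.0):
            pinned = mc[vc == 0.0]
            m[v] = float(pinned.mean())
            d[v] = 0.0
            live = vc > 0.0
            ss += float(np.sum((mc[live] - m[v]) ** 2 / vc[live]))
            logdet += float(np.sum(np.log(vc[live])))
            continue
        w = 1.0 / vc
        sw = w.sum()
        m[v] = float((w * mc).sum() / sw)
        d[v] = 1.0 / sw
        ss += float(np.sum(w * (mc - m[v]) ** 2))
        logdet += float(np.sum(np.log(vc)) - math.log(d[v]))
    root = tree.root
    logdet += math.log(d[root]) if d[root] > 0 else 0.0
    mu = float(m[root])
    sigma2 = ss / n
    if sigma2 == 0.0:
        sigma2 = 1e-300  # constant tip values: degenerate but well-defined estimates
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + ss / sigma2)

    # rootward pass: distribution of x_v given data outside v's subtree,
    # stored as (mean a, precision-in-branch-units pa; pa == 0 means flat)
    a = np.zeros(n_nodes)
    pa = np.zeros(n_nodes)
    for v in tree.preorder:
        v = int(v)
        kids = tree.children[v]
        if not kids:
            continue
        for c in kids:
            prec = pa[v]
            mean_num = a[v] * pa[v]
            for s in kids:
                if s == c:
                    continue
                vs = tree.blen[s] + d[s]
                if vs == 0.0:
                    prec = math.inf
                    mean_num = m[s]
                    break
                prec += 1.0 / vs
                mean_num += m[s] / vs
            if math.isinf(prec):
                above_mean, above_var = mean_num, 0.0
            elif prec == 0.0:
                above_mean, above_var = 0.0, math.inf
            else:
                above_mean, above_var = mean_num / prec, 1.0 / prec
            total_var = above_var + tree.blen[c]
            if math.isinf(total_var):
                a[c], pa[c] = 0.0, 0.0
            elif total_var == 0.0:
                a[c], pa[c] = above_mean, math.inf
            else:
                a[c], pa[c] = above_mean, 1.0 / total_var

    est = np.zeros(n_nodes)
    var = np.zeros(n_nodes)
    est[:n] = x
    for v in range(n, n_nodes):
        if v == root:
            est[v] = mu
            var[v] = sigma2 * d[v]
            continue
        if d[v] == 0.0:
            est[v] = m[v]
            var[v] = 0.0
        elif pa[v] == 0.0:
            est[v] = m[v]
            var[v] = sigma2 * d[v]
        elif math.isinf(pa[v]):
            est[v] = a[v]
            var[v] = 0.0
        else:
            prec = 1.0 / d[v] + pa[v]
            est[v] = (m[v] / d[v] + a[v] * pa[v]) / prec
            var[v] = sigma2 / prec
    return BMFit(sigma2=float(sigma2), root_value=mu, estimates=est, variances=var, loglik=loglik)


def node_means_at(tree: TimeTree, fit: BMFit, node_ids: Sequence[int]) -> np.ndarray:
    """Point estimates at the requested internal nodes (tip ids rejected)."""
    ids = np.asarray(node_ids, dtype=np.int64)
    if np.any(ids < tree.n_tips) or np.any(ids >= tree.n_nodes):
        raise ValueError("node_ids must be internal nodes of the tree")
    return fit.estimates[ids]
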