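"""Shared fixtures and independent oracle implementations.

The oracles here (state enumeration, dense GLS, Fitch parsimony, matrix
exponentials) deliberately avoid the algorithms used inside the package so
that agreement between the two routes is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from ploidyshift import SimConfig, TimeTree, simulate_bd_tree


# ---------------------------------------------------------------------- #
# tree helpers
# ---------------------------------------------------------------------- #
def random_tree(n_tips: int, seed: int, jitter: bool = False) -> TimeTree:
    """Random ultrametric tree; with ``jitter`` branch lengths are perturbed
    so tests also cover non-ultrametric inputs."""
    t = simulate_bd_tree(SimConfig(n_tips=max(n_tips, 4), seed=seed))
    if n_tips < 4:
        t, _ = t.prune_to_tips(t.tip_labels[:n_tips])
    if jitter:
        rng = np.random.default_rng(seed + 1)
        bl = t.blen * rng.uniform(0.3, 2.0, t.n_nodes)
        t = TimeTree(t.parent, bl, t.tip_labels)
    return t


@pytest.fixture
def cherry() -> TimeTree:
    return TimeTree.from_newick("(A:1.5,B:0.5);")


@pytest.fixture
def balanced4() -> TimeTree:
    return TimeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


# ---------------------------------------------------------------------- #
# Mk oracles
# ---------------------------------------------------------------------- #
def expm_transition(q01: float, q10: float, t: float) -> np.ndarray:
    Q = np.array([[-q01, q01], [q10, -q10]])
    return expm(Q * t)


def brute_force_loglik(tree: TimeTree, tip_states, q01: float, q10: float,
                       root_mode: str) -> float:
    """Sum over all internal-state assignments of products of numerical
    matrix-exponential transition probabilities and root weights."""
    if root_mode == "fixed_D":
        prior = np.array([1.0, 0.0])
    else:
        prior = np.array([q10, q01]) / (q01 + q10)
    P = {v: expm_transition(q01, q10, float(tree.blen[v])) for v in range(tree.n_nodes)}
    internals = [v for v in range(tree.n_tips, tree.n_nodes)]
    states = {i: int(s) for i, s in enumerate(tip_states)}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internals)):
        s = dict(states)
        s.update(zip(internals, assign))
        p = prior[s[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            p *= P[v][s[int(tree.parent[v])], s[v]]
        total += p
    return math.log(total) if total > 0 else -math.inf


def fitch_count(tree: TimeTree, tip_states) -> int:
    """Fitch parsimony count of state changes (lower bound on any history)."""
    sets: dict[int, frozenset] = {}
    changes = 0
    for v in tree.postorder:
        v = int(v)
        if v < tree.n_tips:
            sets[v] = frozenset([int(tip_states[v])])
            continue
        inter = None
        for c in tree.children[v]:
            inter = sets[c] if inter is None else inter & sets[c]
            if not inter:
                inter = None
                break
        if inter:
            sets[v] = inter
        else:
            union = frozenset()
            for c in tree.children[v]:
                union |= sets[c]
            sets[v] = union
            changes += 1
    return changes


# ---------------------------------------------------------------------- #
# BM oracle
# ---------------------------------------------------------------------- #
def dense_bm_oracle(tree: TimeTree, values: np.ndarray):
    """GLS reconstruction against the full phylogenetic covariance matrix.

    Returns (sigma2_ML, root, per-internal-node estimates, variances).
    """
    n = tree.n_tips
    depths = tree.depths()
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = depths[tree.mrca((i, j))]
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = float(one @ Ci @ values / (one @ Ci @ one))
    resid = values - mu
    sigma2 = float(resid @ Ci @ resid / n)
    est = {}
    var = {}
    for v in range(tree.n_tips, tree.n_nodes):
        cv = np.array([depths[tree.mrca((v, i))] for i in range(n)])
        w = Ci @ cv
        est[v] = mu + float(w @ resid)
        cvv = depths[v]
        var[v] = sigma2 * (
            cvv - float(cv @ Ci @ cv) + (1.0 - float(one @ w)) ** 2 / float(one @ Ci @ one)
        )
    return sigma2, mu, est, var
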