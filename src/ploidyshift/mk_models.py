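"""Two-state Markov (Mk) models of reproductive-system evolution.

The binary character is diplodiploidy (state 0, ``D``) versus haplodiploidy
(state 1, ``H``).  Two models are compared:

* ``two_rate`` — independent gain (``q_DH``) and loss (``q_HD``) rates with
  the root state drawn from the stationary frequencies of the fitted chain;
* ``one_rate`` — irreversible: only D->H transitions are allowed
  (``q_HD = 0``) and the root is fixed in the diplodiploid state.

Likelihoods are computed with the pruning algorithm, using the closed-form
two-state transition probabilities.  Model fit is summarised with the
small-sample corrected AIC (AICc) with the number of tips as the sample
size; model comparison over a tree set reports the per-tree and mean AICc
difference ``two_rate - one_rate`` (negative values favour the reversible
model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .tree import TimeTree

__all__ = [
    "MkRates",
    "MkFit",
    "ModelComparison",
    "binary_transition_matrix",
    "stationary_frequencies",
    "mk_loglik",
    "fit_mk",
    "compare_models_over_trees",
    "drop_tip_sensitivity",
]

_LOG_RATE_BOUNDS = (math.log(1e-8), math.log(1e3))


@dataclass(frozen=True)
class MkRates:
    """Transition rates per unit branch-length time."""

    q_DH: float
    q_HD: float = 0.0

    def __post_init__(self) -> None:
        if self.q_DH < 0 or self.q_HD < 0:
            raise ValueError("transition rates must be >= 0")


def stationary_frequencies(rates: MkRates) -> np.ndarray:
    """Equilibrium frequencies (pi_D, pi_H) of the two-state chain."""
    total = rates.q_DH + rates.q_HD
    if total == 0:
        raise ValueError("stationary distribution undefined when both rates are 0")
    return np.array([rates.q_HD / total, rates.q_DH / total])


def binary_transition_matrix(rates: MkRates, t: float) -> np.ndarray:
    """Closed-form ``expm(Q t)`` for the two-state chain.

    ``P[i, j]`` is the probability of being in state ``j`` after time ``t``
    given state ``i`` now.  For ``q_HD = 0`` this reduces to
    ``P_DD = exp(-q_DH t)`` and an absorbing haplodiploid state.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    q01, q10 = rates.q_DH, rates.q_HD
    total = q01 + q10
    if total == 0:
        return np.eye(2)
    e = math.exp(-total * t)
    pi0, pi1 = q10 / total, q01 / total
    p00 = pi0 + pi1 * e
    p11 = pi1 + pi0 * e
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


def _edge_probs(tree: TimeTree, rates: MkRates) -> tuple[np.ndarray, ...]:
    """Vectorised per-edge transition probabilities (entries of expm(Q t))."""
    q01, q10 = rates.q_DH, rates.q_HD
    total = q01 + q10
    bl = tree.blen
    if total == 0:
        ones = np.ones(tree.n_nodes)
        zeros = np.zeros(tree.n_nodes)
        return ones, zeros, zeros, ones
    e = np.exp(-total * bl)
    pi0, pi1 = q10 / total, q01 / total
    p00 = pi0 + pi1 * e
    p11 = pi1 + pi0 * e
    return p00, 1.0 - p00, 1.0 - p11, p11


def _root_prior(rates: MkRates, root_mode: str) -> np.ndarray:
    if root_mode == "stationary":
        if rates.q_HD == 0:
            raise ValueError(
                "stationary root frequencies are degenerate when q_HD = 0; "
                "use root_mode='fixed_D' for the irreversible model"
            )
        return stationary_frequencies(rates)
    if root_mode == "fixed_D":
        return np.array([1.0, 0.0])
    raise ValueError(f"unknown root_mode {root_mode!r}")


def _partials(tree: TimeTree, tip_states: np.ndarray, rates: MkRates):
    """Per-node conditional likelihoods, normalised node-wise.

    Returns ``(L, logscale)`` where ``L[v]`` is proportional to
    ``P(data below v | state of v)`` and ``logscale`` restores the absolute
    scale of the root row.  ``logscale`` is ``-inf`` when the data are
    impossible under the rates.
    """
    n = tree.n_nodes
    p00, p01, p10, p11 = _edge_probs(tree, rates)
    L0 = np.zeros(n)
    L1 = np.zeros(n)
    st = np.asarray(tip_states)
    L0[: tree.n_tips] = st == 0
    L1[: tree.n_tips] = st == 1
    logscale = 0.0
    children = tree.children
    for v in tree.postorder:
        v = int(v)
        if v < tree.n_tips:
            continue
        a = 1.0
        b = 1.0
        for c in children[v]:
            x0, x1 = L0[c], L1[c]
            a *= p00[c] * x0 + p01[c] * x1
            b *= p10[c] * x0 + p11[c] * x1
        s = a + b
        if s <= 0.0 or not math.isfinite(s):
            return (L0, L1), -math.inf
        L0[v] = a / s
        L1[v] = b / s
        logscale += math.log(s)
    return (L0, L1), logscale


def mk_loglik(
    tree: TimeTree,
    tip_states: Sequence[int] | np.ndarray,
    rates: MkRates,
    root_mode: str = "stationary",
) -> float:
    """Pruning-algorithm log-likelihood of binary tip states.

    ``tip_states`` is aligned with ``tree.tip_labels`` (0 = diplodiploid,
    1 = haplodiploid).  Impossible data (e.g. a haplodiploid tip with
    ``q_DH = 0`` under the irreversible model) yield ``-inf``, never NaN.
    """
    st = np.asarray(tip_states, dtype=np.int64)
    if st.shape[0] != tree.n_tips:
        raise ValueError("one state per tip required")
    if not np.all((st == 0) | (st == 1)):
        raise ValueError("tip states must be 0 (D) or 1 (H)")
    prior = _root_prior(rates, root_mode)
    (L0, L1), logscale = _partials(tree, st, rates)
    if logscale == -math.inf:
        return -math.inf
    r = tree.root
    lik = prior[0] * L0[r] + prior[1] * L1[r]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; ``+inf`` for impossible fits."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    if loglik == -math.inf:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class MkFit:
    """One model fitted to one tree."""

    model: str
    rates: MkRates
    loglik: float
    k: int
    n_tips: int
    aicc: float
    aic: float
    tree_id: int | str | None = None
    boundary: bool = False
    root_mode: str = "stationary"


_MODELS = {"one_rate": (1, "fixed_D"), "two_rate": (2, "stationary")}


def fit_mk(
    tree: TimeTree,
    tip_states: Sequence[int] | np.ndarray,
    model: str = "one_rate",
    tree_id: int | str | None = None,
    n_starts: int = 5,
) -> MkFit:
    """Maximum-likelihood rates by bounded quasi-Newton optimisation.

    Rates are optimised on the log scale within [1e-8, 1e3] per unit branch
    length, from ``n_starts`` Latin-hypercube starting points: likelihood
    surfaces are flat when transitions are rare, and a single start can
    stall on the boundary.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {sorted(_MODELS)}")
    k, root_mode = _MODELS[model]
    st = np.asarray(tip_states, dtype=np.int64)
    monomorphic = len(np.unique(st)) < 2

    def neg(params: np.ndarray) -> float:
        q = np.exp(params)
        rates = MkRates(q[0], q[1] if k == 2 else 0.0)
        ll = mk_loglik(tree, st, rates, root_mode)
        return 1e12 if ll == -math.inf else -ll

    lo, hi = _LOG_RATE_BOUNDS
    sampler = qmc.LatinHypercube(d=k, seed=0)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    best = None
    failures = []
    for x0 in starts:
        try:
            res = minimize(neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * k)
        except Exception as exc:  # pragma: no cover - optimizer pathology
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"Mk optimisation failed from every start: {failures}")
    q = np.exp(best.x)
    rates = MkRates(float(q[0]), float(q[1]) if k == 2 else 0.0)
    ll = mk_loglik(tree, st, rates, root_mode)
    at_bound = bool(np.any(np.abs(best.x - lo) < 1e-6) or np.any(np.abs(best.x - hi) < 1e-6))
    n = tree.n_tips
    return MkFit(
        model=model,
        rates=rates,
        loglik=ll,
        k=k,
        n_tips=n,
        aicc=aicc(ll, k, n),
        aic=-2.0 * ll + 2.0 * k if ll > -math.inf else math.inf,
        tree_id=tree_id,
        boundary=monomorphic or at_bound,
        root_mode=root_mode,
    )


def _states_for(tree: TimeTree, tip_systems) -> np.ndarray:
    """Align a label->state mapping (or an array) with a tree's tip order."""
    if isinstance(tip_systems, Mapping):
        return np.asarray([tip_systems[lab] for lab in tree.tip_labels], dtype=np.int64)
    arr = np.asarray(tip_systems, dtype=np.int64)
    if arr.shape[0] != tree.n_tips:
        raise ValueError("tip_systems length does not match tree")
    return arr


@dataclass
class ModelComparison:
    """AICc comparison of the irreversible and reversible models over trees.

    ``delta_aicc`` is per-tree ``AICc(two_rate) - AICc(one_rate)``; the mean
    is the arithmetic mean over trees, and ``preferred`` is the model with
    the lower mean AICc.
    """

    fits_one: list[MkFit]
    fits_two: list[MkFit]
    delta_aicc: np.ndarray
    mean_delta_aicc: float
    preferred: str
    skipped: list[tuple[int | str | None, str]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for f in self.fits_one + self.fits_two:
            rows.append(
                {
                    "tree_id": f.tree_id,
                    "model": f.model,
                    "q_DH": f.rates.q_DH,
                    "q_HD": f.rates.q_HD,
                    "loglik": f.loglik,
                    "AICc": f.aicc,
                    "AIC": f.aic,
                }
            )
        return pd.DataFrame(rows)


def compare_models_over_trees(
    trees: Sequence[TimeTree],
    tip_systems,
    skip_failures: bool = False,
) -> ModelComparison:
    """Fit both models on every tree and average the AICc difference.

    ``tip_systems`` may be a ``{label: state}`` mapping (recommended when
    tip orders differ between trees) or an array aligned with each tree's
    tip order.
    """
    if len(trees) == 0:
        raise ValueError("need at least one tree")
    fits_one, fits_two, deltas, skipped = [], [], [], []
    for i, tree in enumerate(trees):
        st = _states_for(tree, tip_systems)
        try:
            f1 = fit_mk(tree, st, "one_rate", tree_id=i)
            f2 = fit_mk(tree, st, "two_rate", tree_id=i)
        except Exception as exc:
            if not skip_failures:
                raise
            skipped.append((i, str(exc)))
            warnings.warn(f"tree {i} skipped: {exc}")
            continue
        fits_one.append(f1)
        fits_two.append(f2)
        deltas.append(f2.aicc - f1.aicc)
    if not deltas:
        raise RuntimeError("every tree failed to fit")
    delta = np.asarray(deltas)
    mean_delta = float(delta.mean())
    preferred = "two_rate" if mean_delta < 0 else "one_rate"
    return ModelComparison(fits_one, fits_two, delta, mean_delta, preferred, skipped)


def drop_tip_sensitivity(
    trees: Sequence[TimeTree],
    tip_systems,
    drop_label: str,
) -> ModelComparison:
    """Re-run the model comparison with one tip removed from every tree.

    Used to ask whether a single taxon (e.g. a lone diplodiploid nested in a
    haplodiploid clade) carries all the support for reversibility.
    """
    pruned = []
    for tree in trees:
        if drop_label not in tree.tip_labels:
            raise KeyError(f"tip {drop_label!r} not present in tree")
        keep = [lab for lab in tree.tip_labels if lab != drop_label]
        sub, _ = tree.prune_to_tips(keep)
        pruned.append(sub)
    if isinstance(tip_systems, Mapping):
        systems = {k: v for k, v in tip_systems.items() if k != drop_label}
    else:
        first = trees[0]
        arr = _states_for(first, tip_systems)
        systems = {
            lab: int(s) for lab, s in zip(first.tip_labels, arr) if lab != drop_label
        }
    return compare_models_over_trees(pruned, systems)
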