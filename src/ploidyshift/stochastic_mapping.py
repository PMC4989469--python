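"""Stochastic character mapping of the binary reproductive system.

A *map* is a complete realisation of the two-state Markov chain on the tree,
consistent with the observed tip states: a state for every node plus the
exact transition times along every branch.  Node states are drawn root-to-tip
from their joint conditional distribution (not independent marginals), and
each branch is then filled in with a path bridge conditioned on its two
endpoint states.  Bridges are sampled by rejection of forward simulations,
with an exact uniformization sampler as fallback when rejection is
inefficient; the irreversible case (``q_HD = 0``) is handled in closed form.

Counting the D->H transitions on a map gives one draw of the number of
independent origins of haplodiploidy; summaries pool such counts over maps
and over a tree set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mk_models import (
    MkRates,
    _edge_probs,
    _partials,
    _root_prior,
    _states_for,
    binary_transition_matrix,
    fit_mk,
)
from .tree import TimeTree

__all__ = [
    "SimmapHistory",
    "OriginSummary",
    "marginal_node_posteriors",
    "sample_history",
    "count_origins",
    "summarize_origins",
]

DIPLOID = 0
HAPLODIPLOID = 1

_REJECTION_CAP = 10_000


@dataclass
class SimmapHistory:
    """A tree painted with one complete character history.

    ``events[v]`` lists the transitions on the branch *above* node ``v`` as
    ``(time from branch start, new state)`` pairs, ordered along the branch.
    ``node_states[v]`` is the state at the node itself (the end of its
    branch); the root carries ``root_state``.
    """

    tree: TimeTree
    root_state: int
    events: list[list[tuple[float, int]]]
    node_states: np.ndarray

    def validate(self, tip_states: Sequence[int] | None = None) -> None:
        for v in range(self.tree.n_nodes):
            if v == self.tree.root:
                continue
            prev_t = 0.0
            state = int(self.node_states[self.tree.parent[v]])
            for t, s in self.events[v]:
                if not (prev_t < t <= self.tree.blen[v] + 1e-12):
                    raise ValueError(f"event times on branch {v} not increasing in range")
                if s == state:
                    raise ValueError(f"self-transition on branch {v}")
                prev_t, state = t, s
            if state != self.node_states[v]:
                raise ValueError(f"events on branch {v} inconsistent with node state")
        if tip_states is not None:
            obs = np.asarray(tip_states)
            if not np.array_equal(self.node_states[: self.tree.n_tips], obs):
                raise ValueError("tip end-states do not match observed states")

    def to_simmap_newick(self) -> str:
        """SIMMAP-annotated Newick: branch lengths replaced by
        ``{state,duration:...}`` segments listed rootward to tipward."""
        tree = self.tree

        def seg(v: int) -> str:
            start = int(self.node_states[tree.parent[v]])
            parts = []
            t_prev, state = 0.0, start
            for t, s in self.events[v]:
                parts.append(f"{state},{t - t_prev:.8g}")
                t_prev, state = t, s
            parts.append(f"{state},{tree.blen[v] - t_prev:.8g}")
            return "{" + ":".join(parts) + "}"

        def rec(v: int) -> str:
            if v < tree.n_tips:
                core = tree.tip_labels[v].replace(" ", "_")
            else:
                core = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
            if v == tree.root:
                return core
            return f"{core}:{seg(v)}"

        return rec(tree.root) + ";"


def marginal_node_posteriors(
    tree: TimeTree,
    tip_states: Sequence[int] | np.ndarray,
    rates: MkRates,
    root_mode: str = "stationary",
) -> np.ndarray:
    """Marginal posterior P(state | all tip data) for every node.

    Standard two-pass computation: the pruning pass gives the likelihood of
    the data below each node, an outside pass propagates the likelihood of
    everything else, and the two are combined node by node.  Rows sum to 1;
    tip rows are point masses on the observed states.
    """
    st = np.asarray(tip_states, dtype=np.int64)
    prior = _root_prior(rates, root_mode)
    (L0, L1), logscale = _partials(tree, st, rates)
    if logscale == -math.inf:
        raise ValueError("tip data impossible under these rates")
    p00, p01, p10, p11 = _edge_probs(tree, rates)
    n = tree.n_nodes
    A = np.zeros((n, 2))
    A[tree.root] = prior
    # messages child -> parent, as a function of the parent state
    S0 = p00 * L0 + p01 * L1
    S1 = p10 * L0 + p11 * L1
    for v in tree.preorder:
        v = int(v)
        kids = tree.children[v]
        if not kids:
            continue
        for c in kids:
            sib0, sib1 = A[v, 0], A[v, 1]
            for s in kids:
                if s != c:
                    sib0 *= S0[s]
                    sib1 *= S1[s]
            A[c, 0] = p00[c] * sib0 + p10[c] * sib1
            A[c, 1] = p01[c] * sib0 + p11[c] * sib1
            tot = A[c, 0] + A[c, 1]
            if tot > 0:
                A[c] /= tot
    post = np.stack([L0 * A[:, 0], L1 * A[:, 1]], axis=1)
    post /= post.sum(axis=1, keepdims=True)
    return post


# ---------------------------------------------------------------------- #
# endpoint-conditioned path sampling
# ---------------------------------------------------------------------- #
def _forward_path(rng, state: int, t: float, q: tuple[float, float]):
    """Unconditioned Gillespie path; returns (events, end_state)."""
    events = []
    now = 0.0
    while True:
        rate = q[state]
        if rate == 0:
            return events, state
        now += rng.exponential(1.0 / rate)
        if now >= t:
            return events, state
        state = 1 - state
        events.append((now, state))


def _truncated_exp(rng, rate: float, t: float) -> float:
    u = rng.random()
    return -math.log1p(-u * (1.0 - math.exp(-rate * t))) / rate


def _uniformization_bridge(rng, i: int, j: int, t: float, q: tuple[float, float]):
    """Exact endpoint-conditioned path via uniformization (2-state)."""
    q01, q10 = q
    omega = max(q01, q10)
    if omega == 0:
        if i != j:
            raise ValueError("impossible endpoints with zero rates")
        return []
    Q = np.array([[-q01, q01], [q10, -q10]])
    R = np.eye(2) + Q / omega
    p_end = binary_transition_matrix(MkRates(q01, q10), t)[i, j]
    if p_end <= 0:
        raise ValueError("impossible endpoint pair for this branch")
    # sample the number of uniformized jumps
    mu = omega * t
    m_max = max(20, int(mu + 12.0 * math.sqrt(mu) + 20))
    Rp = [np.eye(2)]
    for _ in range(m_max):
        Rp.append(Rp[-1] @ R)
    u = rng.random() * p_end
    acc = 0.0
    pois = math.exp(-mu)
    m = m_max
    for mm in range(m_max + 1):
        acc += pois * Rp[mm][i, j]
        if u <= acc:
            m = mm
            break
        pois *= mu / (mm + 1)
    # sample the jump chain conditioned on the endpoints
    states = [i]
    for kstep in range(1, m):
        prev = states[-1]
        w0 = R[prev, 0] * Rp[m - kstep][0, j]
        w1 = R[prev, 1] * Rp[m - kstep][1, j]
        tot = w0 + w1
        states.append(0 if rng.random() * tot < w0 else 1)
    if m > 0:
        states.append(j)
    times = np.sort(rng.random(m)) * t
    events = []
    for k in range(1, m + 1):
        if states[k] != states[k - 1]:
            events.append((float(times[k - 1]), states[k]))
    return events


def _sample_branch_path(rng, i: int, j: int, t: float, rates: MkRates):
    """Path on one branch conditioned on endpoint states (i at start, j at
    end).  Rejection of forward simulations (with the first event forced
    when the endpoints differ), uniformization after the rejection cap."""
    q01, q10 = rates.q_DH, rates.q_HD
    q = (q01, q10)
    if t == 0:
        if i != j:
            raise ValueError("state change across a zero-length branch")
        return []
    if q10 == 0.0:
        # irreversible: closed form
        if i == HAPLODIPLOID:
            if j != HAPLODIPLOID:
                raise ValueError(
                    "H->D endpoints are impossible under q_HD=0; inputs corrupted"
                )
            return []
        if j == DIPLOID:
            return []
        if q01 == 0.0:
            raise ValueError("D->H endpoints impossible with q_DH=0")
        return [(_truncated_exp(rng, q01, t), HAPLODIPLOID)]
    if q01 == 0.0 and i == DIPLOID:
        if j != DIPLOID:
            raise ValueError("D->H endpoints impossible with q_DH=0")
        return []
    for _ in range(_REJECTION_CAP):
        if i == j:
            events, end = _forward_path(rng, i, t, q)
        else:
            t1 = _truncated_exp(rng, q[i], t)
            tail, end = _forward_path(rng, 1 - i, t - t1, q)
            events = [(t1, 1 - i)] + [(t1 + tt, s) for tt, s in tail]
        if end == j:
            return events
    return _uniformization_bridge(rng, i, j, t, q)


def sample_history(
    tree: TimeTree,
    tip_states: Sequence[int] | np.ndarray,
    rates: MkRates,
    root_mode: str = "stationary",
    seed: int | np.random.Generator | None = None,
) -> SimmapHistory:
    """Draw one character history conditional on the observed tip states."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    st = np.asarray(tip_states, dtype=np.int64)
    prior = _root_prior(rates, root_mode)
    (L0, L1), logscale = _partials(tree, st, rates)
    if logscale == -math.inf:
        raise ValueError("tip data impossible under these rates; cannot sample a map")
    p00, p01, p10, p11 = _edge_probs(tree, rates)
    states = np.zeros(tree.n_nodes, dtype=np.int64)
    r = tree.root
    w0 = prior[0] * L0[r]
    w1 = prior[1] * L1[r]
    states[r] = 0 if rng.random() * (w0 + w1) < w0 else 1
    for v in tree.preorder:
        v = int(v)
        if v == r:
            continue
        i = states[tree.parent[v]]
        if i == 0:
            w0, w1 = p00[v] * L0[v], p01[v] * L1[v]
        else:
            w0, w1 = p10[v] * L0[v], p11[v] * L1[v]
        states[v] = 0 if rng.random() * (w0 + w1) < w0 else 1
    events: list[list[tuple[float, int]]] = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes):
        if v == r:
            continue
        events[v] = _sample_branch_path(
            rng, int(states[tree.parent[v]]), int(states[v]), float(tree.blen[v]), rates
        )
    return SimmapHistory(tree=tree, root_state=int(states[r]), events=events, node_states=states)


def count_origins(history: SimmapHistory) -> int:
    """Number of D->H transitions in the history.

    A haplodiploid root counts as one origin (the transition happened on the
    unobserved stem lineage); this is a reporting convention of this package.
    """
    n = sum(1 for ev in history.events for _, s in ev if s == HAPLODIPLOID)
    return n + (1 if history.root_state == HAPLODIPLOID else 0)


@dataclass
class OriginSummary:
    """Origin counts pooled over maps and trees.

    ``counts[i, m]`` is the origin count of map ``m`` on tree ``i``.  Both
    the per-tree means and the pooled mean are reported because the number
    of maps per tree and the number of trees are separate averaging levels.
    """

    counts: np.ndarray
    model: str
    per_tree_mean: np.ndarray = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_tree_mean = self.counts.mean(axis=1)
        self.mean = float(self.counts.mean())
        self.sd = float(self.counts.std(ddof=1)) if self.counts.size > 1 else 0.0


def summarize_origins(
    trees: Sequence[TimeTree] | TimeTree,
    tip_systems,
    model: str = "one_rate",
    n_maps: int = 100,
    seed: int | None = None,
) -> OriginSummary:
    """Fit the chosen model per tree, draw ``n_maps`` maps each, and pool
    the origin counts."""
    if isinstance(trees, TimeTree):
        trees = [trees]
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(trees), n_maps), dtype=np.int64)
    for i, tree in enumerate(trees):
        st = _states_for(tree, tip_systems)
        fit = fit_mk(tree, st, model, tree_id=i)
        if fit.boundary:
            warnings.warn(f"tree {i}: rate estimate at boundary; maps may be degenerate")
        for m in range(n_maps):
            hist = sample_history(tree, st, fit.rates, fit.root_mode, rng)
            counts[i, m] = count_origins(hist)
    return OriginSummary(counts=counts, model=model)
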