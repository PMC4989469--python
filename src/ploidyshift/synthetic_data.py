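"""Generators for trees and trait data with known ground truth.

The default configuration emulates the statistical structure of the mite
dataset the analyses are aimed at: time trees of about 100 tips, a binary
reproductive system (diplodiploid ancestral, haplodiploid derived) with a
handful of independent origins and essentially no reversals, diploid
chromosome counts ranging from roughly 4 to 28 with strong phylogenetic
signal, and — in the *causal* regime — a transition hazard to haplodiploidy
that increases as log chromosome number decreases, plus an optional
post-transition downward drift of chromosome number in haplodiploid
lineages.

Every generator takes or derives a seed and is fully reproducible; the
joint-trait generator returns its complete true history so downstream
estimators can be checked against ground truth rather than against each
other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stochastic_mapping import SimmapHistory, count_origins
from .tree import TimeTree
from .tree_io import SYSTEM_STATES, TraitRecord

__all__ = [
    "SimConfig",
    "JointSimResult",
    "simulate_bd_tree",
    "simulate_joint_traits",
    "simulate_mk_tips",
    "assign_taxonomy",
    "make_trait_table",
    "simulate_phylo_gaussian",
    "simulate_threshold_traits",
]

DIPLOID = 0
HAPLODIPLOID = 1


@dataclass(frozen=True)
class SimConfig:
    """Simulation regime for the joint tree + trait generator.

    Defaults give the *independent* (null) regime: the reproductive system
    switches at a constant baseline rate (``beta = 0``) chosen so that a
    100-tip tree typically carries on the order of 5-13 origins, and
    chromosome number evolves as neutral Brownian motion on the log scale,
    centred near 2n = 18 with tip counts spanning roughly 4-28.

    ``causal()`` returns the state-dependent regime in which low chromosome
    number raises the transition hazard (log-linearly, ``q_DH0 *
    exp(-beta * x)`` with ``x = log 2n``) and haplodiploid lineages drift
    towards lower counts by ``ploidy_effect`` on the log scale — about five
    chromosomes at 2n near 18.
    """

    n_tips: int = 100
    birth_rate: float = 1.0
    death_rate: float = 0.0
    q_DH0: float = 0.08
    q_HD: float = 0.0
    beta: float = 0.0
    sigma2: float = 0.03
    x_root: float = math.log(18.0)
    ploidy_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        for name in ("birth_rate", "death_rate", "q_DH0", "q_HD", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def causal(cls, beta: float = 1.0, ploidy_effect: float = -0.3, **kw) -> "SimConfig":
        """State-dependent regime; the baseline rate is rescaled so the
        hazard at the root value matches the null regime's rate."""
        base = cls(**kw)
        q0 = base.q_DH0 * math.exp(beta * base.x_root)
        return replace(base, beta=beta, ploidy_effect=ploidy_effect, q_DH0=q0)


# ---------------------------------------------------------------------- #
# birth-death trees
# ---------------------------------------------------------------------- #
def simulate_bd_tree(config: SimConfig, max_retries: int = 1000) -> TimeTree:
    """Forward birth-death simulation conditioned on the tip count.

    Two lineages start at the root; the process runs until the number of
    extant lineages first reaches ``n_tips``, then all surviving lineages
    are extended by the waiting time to the next (unexecuted) event, so a
    pure-birth tree has the classical Yule root-age expectation
    ``sum_{k=2..n} 1/(k*birth_rate)``.  Extinct lineages are pruned;
    replicates that die out are retried.
    """
    if config.birth_rate <= config.death_rate:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = np.random.default_rng(config.seed)
    b, d, n = config.birth_rate, config.death_rate, config.n_tips
    for _ in range(max_retries):
        parent = [-1, 0, 0]
        t_start = [0.0, 0.0, 0.0]
        t_end = [math.nan, math.nan, math.nan]
        t_end[0] = 0.0
        alive = [1, 2]
        now = 0.0
        ok = False
        while alive:
            if len(alive) == n:
                now += rng.exponential(1.0 / (len(alive) * (b + d)))
                ok = True
                break
            now += rng.exponential(1.0 / (len(alive) * (b + d)))
            v = alive[rng.integers(len(alive))]
            if rng.random() * (b + d) < b:
                t_end[v] = now
                for _ in range(2):
                    parent.append(v)
                    t_start.append(now)
                    t_end.append(math.nan)
                    alive.append(len(parent) - 1)
                alive.remove(v)
            else:
                t_end[v] = now
                alive.remove(v)
        if not ok:
            continue
        for v in alive:
            t_end[v] = now
        # assemble arrays: tips = alive + dead leaves; relabel afterwards
        n_all = len(parent)
        is_leaf = np.ones(n_all, dtype=bool)
        for p in parent[1:]:
            is_leaf[p] = False
        order = [v for v in range(n_all) if is_leaf[v]] + [v for v in range(n_all) if not is_leaf[v]]
        newid = {v: i for i, v in enumerate(order)}
        par = np.array([newid[parent[v]] if parent[v] >= 0 else -1 for v in order])
        blen = np.array([t_end[v] - t_start[v] for v in order])
        labels = [f"leaf{v}" for v in range(n_all) if is_leaf[v]]
        tree = TimeTree(par, blen, labels)
        keep = [f"leaf{v}" for v in alive]
        if len(keep) < tree.n_tips:
            tree, _ = tree.prune_to_tips(keep)
        tree.tip_labels[:] = [f"t{i + 1}" for i in range(tree.n_tips)]
        return tree
    raise RuntimeError(f"could not reach {n} extant tips in {max_retries} attempts")


# ---------------------------------------------------------------------- #
# joint state-dependent simulation
# ---------------------------------------------------------------------- #
@dataclass
class JointSimResult:
    """Ground truth from one joint simulation."""

    systems: np.ndarray  # tip states, 0/1
    count_2n: np.ndarray  # integer tip counts, >= 4
    history: SimmapHistory  # full true character history
    node_x: np.ndarray  # true log-2n at the end of every branch
    tip_x: np.ndarray  # true (unrounded) log-2n at the tips
    n_origins: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_origins = count_origins(self.history)


def simulate_joint_traits(
    tree: TimeTree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> JointSimResult:
    """Co-simulate log chromosome number (BM) and the reproductive system.

    Along every branch ``x = log 2n`` takes Euler steps of at most 1/1000 of
    the tree height; while diplodiploid, the lineage switches to
    haplodiploidy with hazard ``q_DH0 * exp(-beta * x(t))`` (steps are
    subdivided so hazard*dt stays below 0.1); while haplodiploid it may
    switch back at ``q_HD`` and accrues a deterministic drift that shifts
    ``x`` by ``ploidy_effect`` in total, spread linearly over half the tree
    height after the transition.  Tip counts are ``round(exp(x))`` clamped
    to >= 4.  The complete true history is returned.
    """
    if not tree.is_ultrametric(rtol=1e-4):
        raise ValueError("joint simulation expects an ultrametric time tree")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    height = tree.height
    dt0 = height / 1000.0
    drift_span = 0.5 * height  # time over which the ploidy effect accrues
    n_nodes = tree.n_nodes
    node_x = np.zeros(n_nodes)
    node_state = np.zeros(n_nodes, dtype=np.int64)
    node_drift = np.zeros(n_nodes)  # accrued ploidy-effect shift at node
    events: list[list[tuple[float, int]]] = [[] for _ in range(n_nodes)]
    root = tree.root
    node_x[root] = config.x_root
    node_state[root] = DIPLOID
    sq = math.sqrt(config.sigma2)
    for v in tree.preorder:
        v = int(v)
        if v == root:
            continue
        p = int(tree.parent[v])
        x = node_x[p]
        state = int(node_state[p])
        acc = node_drift[p]
        T = float(tree.blen[v])
        pos = 0.0
        while pos < T - 1e-15:
            dt = min(dt0, T - pos)
            if state == DIPLOID:
                hz = config.q_DH0 * math.exp(-config.beta * x)
            else:
                hz = config.q_HD
            if hz * dt > 0.1:
                dt = 0.1 / hz
                dt = min(dt, T - pos)
            x += sq * math.sqrt(dt) * rng.standard_normal()
            if state == HAPLODIPLOID and config.ploidy_effect != 0.0:
                remaining = config.ploidy_effect - acc
                step_shift = config.ploidy_effect * dt / drift_span
                if abs(step_shift) > abs(remaining):
                    step_shift = remaining
                x += step_shift
                acc += step_shift
            if hz > 0.0 and rng.random() < -math.expm1(-hz * dt):
                state = 1 - state
                events[v].append((pos + dt * rng.random(), state))
            pos += dt
        node_x[v] = x
        node_state[v] = state
        node_drift[v] = acc
    # branch event times were recorded within-step; enforce strict ordering
    for v in range(n_nodes):
        events[v].sort(key=lambda e: e[0])
    tip_x = node_x[: tree.n_tips].copy()
    counts = np.maximum(np.rint(np.exp(tip_x)), 4).astype(np.int64)
    systems = node_state[: tree.n_tips].copy()
    hist = SimmapHistory(
        tree=tree, root_state=DIPLOID, events=events, node_states=node_state
    )
    return JointSimResult(
        systems=systems, count_2n=counts, history=hist, node_x=node_x, tip_x=tip_x
    )


# ---------------------------------------------------------------------- #
# plain Mk tip simulation
# ---------------------------------------------------------------------- #
def simulate_mk_tips(
    tree: TimeTree,
    q_DH: float,
    q_HD: float,
    root_state: int = DIPLOID,
    seed: int | np.random.Generator | None = None,
    return_history: bool = False,
):
    """Exact (Gillespie) simulation of the two-state chain along branches."""
    if q_DH < 0 or q_HD < 0:
        raise ValueError("rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = (q_DH, q_HD)
    n_nodes = tree.n_nodes
    states = np.zeros(n_nodes, dtype=np.int64)
    states[tree.root] = root_state
    events: list[list[tuple[float, int]]] = [[] for _ in range(n_nodes)]
    for v in tree.preorder:
        v = int(v)
        if v == tree.root:
            continue
        s = int(states[tree.parent[v]])
        t = float(tree.blen[v])
        now = 0.0
        while True:
            rate = rates[s]
            if rate == 0.0:
                break
            now += rng.exponential(1.0 / rate)
            if now >= t:
                break
            s = 1 - s
            events[v].append((now, s))
        states[v] = s
    tips = states[: tree.n_tips].copy()
    if return_history:
        hist = SimmapHistory(
            tree=tree, root_state=int(root_state), events=events, node_states=states
        )
        return tips, hist
    return tips


def nested_reversal_fixture(
    seed: int = 0, n_tips: int = 60, clade_size: tuple[int, int] = (12, 20)
) -> tuple[TimeTree, dict[str, int], str]:
    """A dataset whose support for reversibility hinges on one tip.

    One clade of the tree is painted haplodiploid except for a single
    diplodiploid tip nested deep inside it (the tip with the shortest
    pendant branch).  Under the irreversible model that tip forces the
    clade's haplodiploidy to be explained by several independent origins,
    so the reversible model is preferred — until the tip is dropped.
    Mirrors the situation where a lone diplodiploid family nested among
    haplodiploids carries all the support for reversals.

    Returns ``(tree, {label: state}, nested_tip_label)``.
    """
    tree = simulate_bd_tree(SimConfig(n_tips=n_tips, seed=seed))
    clade: list[int] | None = None
    for v in range(tree.n_tips, tree.n_nodes):
        tips = tree.tips_below(v)
        if clade_size[0] <= len(tips) <= clade_size[1]:
            clade = tips
    if clade is None:
        raise ValueError("no clade of the requested size; try another seed")
    systems = {lab: DIPLOID for lab in tree.tip_labels}
    for i in clade:
        systems[tree.tip_labels[i]] = HAPLODIPLOID
    inner = min(clade, key=lambda i: float(tree.blen[i]))
    nested_tip = tree.tip_labels[inner]
    systems[nested_tip] = DIPLOID
    return tree, systems, nested_tip


# ---------------------------------------------------------------------- #
# taxonomy and trait tables
# ---------------------------------------------------------------------- #
def assign_taxonomy(
    tree: TimeTree,
    cuts: tuple[float, float, float] = (0.25, 0.55, 0.8),
) -> dict[str, dict[str, str]]:
    """Deterministic nested taxonomy from clade membership.

    Branches crossing a fraction ``cuts[k]`` of the tree height define the
    infraorder / family / genus groups, emulating how ranks partition a real
    phylogeny.  Returns ``{tip label: {"infraorder": ..., "family": ...,
    "genus": ...}}``.
    """
    depths = tree.depths()
    height = tree.height
    names = ("Infraorder", "Family", "Genus")
    out: dict[str, dict[str, str]] = {lab: {} for lab in tree.tip_labels}
    for level, frac in enumerate(cuts):
        cut = frac * height
        group_id = 0
        assigned = np.full(tree.n_tips, -1, dtype=np.int64)
        for v in tree.preorder:
            v = int(v)
            p = int(tree.parent[v])
            crosses = depths[v] >= cut and (p < 0 or depths[p] < cut)
            if crosses:
                for tip in tree.tips_below(v):
                    assigned[tip] = group_id
                group_id += 1
        for i, lab in enumerate(tree.tip_labels):
            gid = assigned[i] if assigned[i] >= 0 else group_id + i
            out[lab][names[level].lower()] = f"{names[level]}{gid + 1}"
    return out


def make_trait_table(
    tree: TimeTree,
    systems: Sequence[int] | np.ndarray,
    count_2n: Sequence[int] | np.ndarray,
    taxonomy: dict[str, dict[str, str]] | None = None,
) -> list[TraitRecord]:
    """Trait records for simulated data, one per tip, in tip order."""
    if taxonomy is None:
        taxonomy = assign_taxonomy(tree)
    recs = []
    for i, lab in enumerate(tree.tip_labels):
        tax = taxonomy.get(lab, {})
        recs.append(
            TraitRecord(
                taxon=lab,
                system=SYSTEM_STATES[int(systems[i])],
                count_2n=float(count_2n[i]),
                infraorder=tax.get("infraorder"),
                family=tax.get("family"),
                genus=tax.get("genus"),
                species=lab,
            )
        )
    return recs


# ---------------------------------------------------------------------- #
# Gaussian helpers for the mixed-model and threshold analyses
# ---------------------------------------------------------------------- #
def _bm_on_tree(tree: TimeTree, rng: np.random.Generator, scale: float) -> np.ndarray:
    """One BM realisation at the tips, rate ``scale`` per unit height."""
    h = tree.height
    vals = np.zeros(tree.n_nodes)
    for v in tree.preorder:
        v = int(v)
        p = int(tree.parent[v])
        if p < 0:
            continue
        vals[v] = vals[p] + math.sqrt(scale * tree.blen[v] / h) * rng.standard_normal()
    return vals[: tree.n_tips]


def simulate_phylo_gaussian(
    tree: TimeTree,
    ploidy: Sequence[int] | np.ndarray,
    beta: float,
    sigma2_phylo: float,
    sigma2_resid: float,
    mu: float = math.log(18.0),
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Response from the animal model ``y = mu + beta*ploidy + u + e`` with
    ``u`` Brownian on the unit-height tree (variance ``sigma2_phylo``) and
    i.i.d. residuals; used to test variance-component recovery."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.asarray(ploidy, dtype=float)
    u = _bm_on_tree(tree, rng, sigma2_phylo)
    e = rng.normal(0.0, math.sqrt(sigma2_resid), tree.n_tips)
    return mu + beta * z + u + e


def simulate_threshold_traits(
    tree: TimeTree,
    corr: float,
    sigma2_y: float = 0.2,
    mu_y: float = math.log(18.0),
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary trait from the sign of a Brownian liability correlated with a
    continuous trait.  Returns ``(ploidy 0/1, y)``; liability variance is 1
    per unit height and the liability root is 0, so groups are roughly
    balanced."""
    if not -1.0 <= corr <= 1.0:
        raise ValueError("corr must be in [-1, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    l_raw = _bm_on_tree(tree, rng, 1.0)
    extra = _bm_on_tree(tree, rng, 1.0)
    y_part = corr * l_raw + math.sqrt(max(0.0, 1.0 - corr**2)) * extra
    y = mu_y + math.sqrt(sigma2_y) * y_part
    ploidy = (l_raw > 0).astype(np.int64)
    return ploidy, y
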