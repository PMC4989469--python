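"""Bayesian mixed models for the ploidy / chromosome-number association.

Three related analyses, all with log-transformed diploid chromosome count as
the Gaussian response and ploidy (diplodiploid = 0, haplodiploid = 1) as the
fixed predictor:

* :func:`phylo_lmm` — the phylogenetic animal model
  ``y = mu + beta * ploidy + u + e`` with ``u ~ N(0, sigma2_p * C)``, where
  ``C`` is the phylogenetic covariance scaled to unit tree height.  Gibbs
  sampling with an inverse-gamma prior on the residual variance and a
  parameter-expanded (heavy-tailed) prior on the phylogenetic variance.
  Phylogenetic heritability ``sigma2_p / (sigma2_p + sigma2_e)`` plays the
  role of Pagel's lambda.
* :func:`taxonomic_lmm` — the same model with nested taxonomic random
  intercepts (infraorder / family / genus) instead of the phylogeny.
* :func:`threshold_model` — the liability threshold model: ploidy is the
  sign of a latent Brownian liability evolving jointly with ``y`` on the
  tree with heritabilities fixed at 1 (no residual term); the quantity of
  interest is the posterior of the liability / log-count correlation.

Fixed effects are summarised with ``P_MCMC``: twice the smaller posterior
tail probability of the effect's sign.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .tree import TimeTree

__all__ = [
    "MixedModelResult",
    "ThresholdResult",
    "phylo_covariance",
    "phylo_lmm",
    "taxonomic_lmm",
    "threshold_model",
    "p_mcmc",
]


def phylo_covariance(tree: TimeTree, normalize: bool = True) -> np.ndarray:
    """Tip covariance under BM: shared root-to-MRCA path lengths.

    With ``normalize`` the matrix is divided by the tree height so variance
    components are comparable across trees of different depths.
    """
    depths = tree.depths()
    n = tree.n_tips
    C = np.zeros((n, n))
    for v in tree.postorder:
        v = int(v)
        if v < n:
            continue
        sets = [tree.tips_below(c) for c in tree.children[v]]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                C[np.ix_(sets[i], sets[j])] = depths[v]
                C[np.ix_(sets[j], sets[i])] = depths[v]
    np.fill_diagonal(C, depths[:n])
    if normalize:
        h = tree.height
        if h <= 0:
            raise ValueError("tree height must be positive")
        C = C / h
    return C


def p_mcmc(samples: Sequence[float] | np.ndarray) -> float:
    """Twice the smaller tail posterior probability of the sign, floored at
    ``2 / n_samples`` so it can never be exactly zero."""
    s = np.asarray(samples, dtype=float)
    if s.size < 100:
        raise ValueError("need at least 100 posterior samples for P_MCMC")
    p_neg = float(np.mean(s < 0))
    p_pos = float(np.mean(s > 0))
    return max(2.0 * min(p_neg, p_pos), 2.0 / s.size)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of a single chain (two halves)."""
    half = x.size // 2
    if half < 10:
        return math.nan
    chains = np.stack([x[:half], x[half : 2 * half]])
    w = chains.var(axis=1, ddof=1).mean()
    b = half * chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return math.nan
    return math.sqrt((half - 1) / half + b / (w * half))


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _ci(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class MixedModelResult:
    """Posterior summary of one mixed-model analysis."""

    beta_mean: float
    beta_ci: tuple[float, float]
    p_mcmc: float
    heritability_mean: float
    heritability_ci: tuple[float, float]
    v_components: dict[str, float]
    v_resid_mean: float
    samples: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ThresholdResult:
    """Posterior of the liability / log-count correlation."""

    corr_mean: float
    corr_ci: tuple[float, float]
    samples: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------- #
# phylogenetic animal model
# ---------------------------------------------------------------------- #
def _phylo_lmm_chain(
    C: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    n_iter: int,
    burnin: int,
    thin: int,
    rng: np.random.Generator,
    ig_shape: float,
    ig_rate: float,
    alpha_var: float,
) -> pd.DataFrame:
    n = y.size
    K = np.linalg.inv(C + 1e-10 * np.eye(n))
    X = np.column_stack([np.ones(n), z])
    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    v = np.zeros(n)
    alpha = 1.0
    resid = y - X @ b
    sig_e = float(resid.var()) / 2 + 1e-6
    phi = float(resid.var()) / 2 + 1e-6
    out = []
    for it in range(n_iter):
        # fixed effects
        r = y - alpha * v
        bhat = np.linalg.solve(XtX, X.T @ r)
        cov = sig_e * np.linalg.inv(XtX)
        b = rng.multivariate_normal(bhat, cov)
        # expanded random effect
        r = y - X @ b
        prec = (alpha**2 / sig_e) * np.eye(n) + K / phi
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, (alpha / sig_e) * r)
        v = mean + np.linalg.solve(L.T, rng.standard_normal(n))
        # expansion scalar
        pa = v @ v / sig_e + 1.0 / alpha_var
        ma = (v @ r / sig_e) / pa
        alpha = ma + rng.standard_normal() / math.sqrt(pa)
        # variances
        phi = _inv_gamma(rng, ig_shape + n / 2, ig_rate + 0.5 * float(v @ (K @ v)))
        e = r - alpha * v
        sig_e = _inv_gamma(rng, ig_shape + n / 2, ig_rate + 0.5 * float(e @ e))
        if it >= burnin and (it - burnin) % thin == 0:
            sig_p = alpha**2 * phi
            out.append(
                {
                    "beta": b[1],
                    "mu": b[0],
                    "v_phylo": sig_p,
                    "v_resid": sig_e,
                    "heritability": sig_p / (sig_p + sig_e),
                }
            )
    return pd.DataFrame(out)


def phylo_lmm(
    tree: TimeTree | Sequence[TimeTree],
    log2n: Sequence[float] | np.ndarray,
    ploidy: Sequence[int] | np.ndarray,
    n_iter: int = 50_000,
    burnin: int = 10_000,
    thin: int = 10,
    seed: int | None = None,
    ig_shape: float = 0.001,
    ig_rate: float = 0.001,
    alpha_var: float = 1000.0,
) -> MixedModelResult:
    """Gibbs sampler for the Gaussian phylogenetic animal model.

    ``log2n`` and ``ploidy`` are aligned with the tip order of the tree(s);
    when a tree set is given, one chain is run per tree and the posteriors
    pooled, marginalising the inference over phylogenetic uncertainty.  The
    default chain length (50k, 10k burn-in) is a desk-scale choice; raise it
    for production runs.
    """
    trees = [tree] if isinstance(tree, TimeTree) else list(tree)
    y = np.asarray(log2n, dtype=float)
    z = np.asarray(ploidy, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("log2n must be complete (no missing values)")
    ss = np.random.SeedSequence(seed)
    frames = []
    for t, child in zip(trees, ss.spawn(len(trees))):
        C = phylo_covariance(t)
        if np.linalg.matrix_rank(C) < C.shape[0]:
            raise ValueError("singular phylogenetic covariance (duplicate tips?)")
        rng = np.random.default_rng(child)
        frames.append(
            _phylo_lmm_chain(C, y, z, n_iter, burnin, thin, rng, ig_shape, ig_rate, alpha_var)
        )
    samples = pd.concat(frames, ignore_index=True)
    beta = samples["beta"].to_numpy()
    h2 = samples["heritability"].to_numpy()
    rhat = _split_rhat(beta)
    diags = {"split_rhat_beta": rhat, "n_samples": len(samples), "n_trees": len(trees)}
    if np.isfinite(rhat) and rhat > 1.1:
        warnings.warn(f"poor mixing for beta: split-Rhat = {rhat:.3f}")
    return MixedModelResult(
        beta_mean=float(beta.mean()),
        beta_ci=_ci(beta),
        p_mcmc=p_mcmc(beta),
        heritability_mean=float(h2.mean()),
        heritability_ci=_ci(h2),
        v_components={"phylo": float(samples["v_phylo"].mean())},
        v_resid_mean=float(samples["v_resid"].mean()),
        samples=samples,
        diagnostics=diags,
    )


# ---------------------------------------------------------------------- #
# taxonomic mixed model
# ---------------------------------------------------------------------- #
def taxonomic_lmm(
    table: pd.DataFrame,
    n_iter: int = 50_000,
    burnin: int = 10_000,
    thin: int = 10,
    seed: int | None = None,
    levels: tuple[str, ...] = ("infraorder", "family", "genus"),
    ig_shape: float = 0.001,
    ig_rate: float = 0.001,
    alpha_var: float = 1000.0,
) -> MixedModelResult:
    """Same model with nested taxonomic random intercepts.

    ``table`` needs columns ``system``, ``count_2n`` and the taxonomy
    levels.  A level whose groups are all singletons is confounded with the
    residual and dropped with a warning.  "Heritability" is reported as the
    summed taxonomic variance fraction.
    """
    df = table.dropna(subset=["count_2n", "system"]).reset_index(drop=True)
    y = np.log(df["count_2n"].to_numpy(dtype=float))
    z = (df["system"] == "haplodiploid").to_numpy(dtype=float)
    n = y.size
    idx: dict[str, np.ndarray] = {}
    for lev in levels:
        codes = pd.factorize(df[lev].fillna("__missing__"))[0]
        counts = np.bincount(codes)
        if counts.max() <= 1:
            warnings.warn(f"taxonomic level {lev!r} has only singleton groups; absorbed "
                          "into the residual")
            continue
        idx[lev] = codes
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), z])
    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    u = {lev: np.zeros(codes.max() + 1) for lev, codes in idx.items()}
    alpha = {lev: 1.0 for lev in idx}
    phi = {lev: float(y.var()) / (len(idx) + 1) + 1e-6 for lev in idx}
    sig_e = float(y.var()) / (len(idx) + 1) + 1e-6
    out = []
    for it in range(n_iter):
        contrib = {lev: alpha[lev] * u[lev][codes] for lev, codes in idx.items()}
        total_u = sum(contrib.values()) if idx else np.zeros(n)
        r = y - total_u
        bhat = np.linalg.solve(XtX, X.T @ r)
        b = rng.multivariate_normal(bhat, sig_e * np.linalg.inv(XtX))
        fixed = X @ b
        for lev, codes in idx.items():
            others = y - fixed - (total_u - contrib[lev])
            ng = np.bincount(codes)
            ssum = np.bincount(codes, weights=others)
            prec = (alpha[lev] ** 2) * ng / sig_e + 1.0 / phi[lev]
            mean = (alpha[lev] * ssum / sig_e) / prec
            u[lev] = mean + rng.standard_normal(ng.size) / np.sqrt(prec)
            ul = u[lev][codes]
            pa = ul @ ul / sig_e + 1.0 / alpha_var
            ma = (ul @ others / sig_e) / pa
            alpha[lev] = ma + rng.standard_normal() / math.sqrt(pa)
            phi[lev] = _inv_gamma(
                rng, ig_shape + u[lev].size / 2, ig_rate + 0.5 * float(u[lev] @ u[lev])
            )
            contrib[lev] = alpha[lev] * u[lev][codes]
            total_u = sum(contrib.values())
        e = y - fixed - total_u
        sig_e = _inv_gamma(rng, ig_shape + n / 2, ig_rate + 0.5 * float(e @ e))
        if it >= burnin and (it - burnin) % thin == 0:
            row = {"beta": b[1], "mu": b[0], "v_resid": sig_e}
            v_tax = 0.0
            for lev in idx:
                vl = alpha[lev] ** 2 * phi[lev]
                row[f"v_{lev}"] = vl
                v_tax += vl
            row["heritability"] = v_tax / (v_tax + sig_e)
            out.append(row)
    samples = pd.DataFrame(out)
    beta = samples["beta"].to_numpy()
    h2 = samples["heritability"].to_numpy()
    comps = {lev: float(samples[f"v_{lev}"].mean()) for lev in idx}
    return MixedModelResult(
        beta_mean=float(beta.mean()),
        beta_ci=_ci(beta),
        p_mcmc=p_mcmc(beta),
        heritability_mean=float(h2.mean()),
        heritability_ci=_ci(h2),
        v_components=comps,
        v_resid_mean=float(samples["v_resid"].mean()),
        samples=samples,
        diagnostics={"split_rhat_beta": _split_rhat(beta), "n_samples": len(samples)},
    )


# ---------------------------------------------------------------------- #
# threshold model
# ---------------------------------------------------------------------- #
def _rtrunc_std_lower(rng: np.random.Generator, a: float) -> float:
    """Standard normal truncated to [a, inf); robust in the far tail."""
    if a < 0.5:
        while True:
            zv = rng.standard_normal()
            if zv >= a:
                return zv
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        zv = a + rng.exponential(1.0 / alpha)
        if rng.random() <= math.exp(-0.5 * (zv - alpha) ** 2):
            return zv


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, positive: bool) -> float:
    if positive:
        return mean + sd * _rtrunc_std_lower(rng, (0.0 - mean) / sd)
    return mean - sd * _rtrunc_std_lower(rng, (mean - 0.0) / sd)


def threshold_model(
    tree: TimeTree,
    log2n: Sequence[float] | np.ndarray,
    ploidy: Sequence[int] | np.ndarray,
    n_iter: int = 4000,
    burnin: int = 1000,
    thin: int = 2,
    seed: int | None = None,
    iw_df: float = 3.0,
    iw_scale: float = 0.01,
) -> ThresholdResult:
    """Data-augmentation MCMC for the phylogenetic threshold model.

    The latent liability ``l`` (ploidy = [l > 0]) and ``y = log 2n`` are
    jointly Brownian on the unit-height tree with a 2x2 between-trait
    covariance and no residual variance (both heritabilities fixed at 1).
    The sampler alternates single-site truncated-normal liability updates,
    Gaussian updates of the two ancestral means, and an inverse-Wishart
    update of the covariance; after each covariance draw the liabilities are
    rescaled to unit liability variance (a parameter-expansion move that
    fixes the scale without changing the correlation, which is the reported
    quantity).
    """
    y = np.asarray(log2n, dtype=float)
    zb = np.asarray(ploidy, dtype=np.int64)
    n = y.size
    if n != tree.n_tips:
        raise ValueError("one observation per tip required")
    C = phylo_covariance(tree)
    K = np.linalg.inv(C + 1e-10 * np.eye(n))
    Kdiag = np.diag(K).copy()
    one_K_one = float(np.sum(K))
    rng = np.random.default_rng(seed)
    ell = np.where(zb == 1, 0.7, -0.7).astype(float)
    mu_l, mu_y = 0.0, float(y.mean())
    Sigma = np.array([[1.0, 0.0], [0.0, max(float(y.var()), 1e-4)]])
    out = []
    n_escaped = 0
    for it in range(n_iter):
        S = np.linalg.inv(Sigma)
        s11, s12 = S[0, 0], S[0, 1]
        dl = ell - mu_l
        dy = y - mu_y
        gl = K @ dl
        gy = K @ dy
        for i in range(n):
            prec = s11 * Kdiag[i]
            m_i = mu_l - (s11 * (gl[i] - Kdiag[i] * dl[i]) + s12 * gy[i]) / prec
            new = _trunc_normal(rng, m_i, 1.0 / math.sqrt(prec), positive=zb[i] == 1)
            delta = new - ell[i]
            if delta != 0.0:
                ell[i] = new
                dl[i] += delta
                gl += K[:, i] * delta
        # ancestral means: GLS posterior, covariance Sigma / (1'K1)
        mhat = np.array([float(np.sum(K @ ell)), float(np.sum(K @ y))]) / one_K_one
        Lm = np.linalg.cholesky(Sigma / one_K_one)
        mu_l, mu_y = mhat + Lm @ rng.standard_normal(2)
        # between-trait covariance
        W = np.column_stack([ell - mu_l, y - mu_y])
        Ssc = W.T @ (K @ W)
        Sigma = invwishart.rvs(df=iw_df + n, scale=iw_scale * np.eye(2) + Ssc, random_state=rng)
        # parameter expansion: pin the liability scale at 1
        c = math.sqrt(Sigma[0, 0])
        ell /= c
        mu_l /= c
        D = np.diag([1.0 / c, 1.0])
        Sigma = D @ Sigma @ D
        if np.max(np.abs(ell)) > 50:
            n_escaped += 1
        if it >= burnin and (it - burnin) % thin == 0:
            r = Sigma[0, 1] / math.sqrt(Sigma[0, 0] * Sigma[1, 1])
            out.append({"corr": r, "v_y": Sigma[1, 1], "mu_y": mu_y})
    if n_escaped > 0.05 * n_iter:
        warnings.warn(
            "liabilities escaping to extreme values (possible complete separation); "
            "the prior may dominate the correlation posterior"
        )
    samples = pd.DataFrame(out)
    corr = samples["corr"].to_numpy()
    return ThresholdResult(
        corr_mean=float(corr.mean()),
        corr_ci=_ci(corr),
        samples=samples,
        diagnostics={"split_rhat_corr": _split_rhat(corr), "n_samples": len(samples)},
    )
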