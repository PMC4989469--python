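"""End-to-end orchestration: match -> model comparison -> mapping -> tests.

A single YAML config drives the whole analysis; every stage derives its seed
from one master seed, inputs are hashed into a manifest, and the report
(Markdown + JSON) contains only numbers the stages actually computed, so a
rerun with the same config reproduces the report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .mk_models import ModelComparison, compare_models_over_trees, drop_tip_sensitivity
from .origin_test import (
    AggregatedOriginTest,
    aggregate_origin_tests,
    infraorder_test,
    monte_carlo_origin_test,
)
from .phylo_mixed import phylo_lmm, taxonomic_lmm, threshold_model
from .stochastic_mapping import OriginSummary, summarize_origins
from .tree import TimeTree
from .tree_io import MatchedDataset, match_tips, read_trait_table, read_tree_set

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "make_figures"]


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``variant`` selects the full matched dataset (species + genus + family
    matches) or the stricter species-only subset.
    """

    trees: str
    traits: str
    outdir: str
    variant: str = "full"
    seed: int = 1
    max_trees: int | None = None
    drop_tip: str | None = None
    n_maps: int = 20
    origin_test_maps: int = 5
    null_reps: int = 100
    lmm_iter: int = 20_000
    lmm_burnin: int = 4_000
    lmm_thin: int = 10
    lmm_trees: int = 3
    threshold_iter: int = 3_000
    threshold_burnin: int = 800
    threshold_thin: int = 2
    stages: tuple[str, ...] = ("mk", "origins", "origin_test", "lmm", "taxonomic", "threshold", "infraorder")

    def __post_init__(self) -> None:
        if self.variant not in ("full", "species_only"):
            raise ValueError("variant must be 'full' or 'species_only'")
        for p in (self.trees, self.traits):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """Everything a run produced, for reporting and figures."""

    config: RunConfig
    trees: list[TimeTree]
    matched: MatchedDataset
    comparison: ModelComparison | None = None
    drop_comparison: ModelComparison | None = None
    origins: dict[str, OriginSummary] = field(default_factory=dict)
    origin_test: AggregatedOriginTest | None = None
    lmm: Any = None
    taxonomic: Any = None
    threshold: Any = None
    infraorder: Any = None
    errors: dict[str, str] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(master: int, names: tuple[str, ...]) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def run_pipeline(config: RunConfig | str | Path) -> ReportBundle:
    """Run every configured stage; failures are recorded per stage and
    independent stages continue."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    cfg = config
    outdir = Path(cfg.outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)

    trees = read_tree_set(cfg.trees)
    if cfg.max_trees:
        trees = trees[: cfg.max_trees]
    records = read_trait_table(cfg.traits)
    matched_list = [match_tips(t, records) for t in trees]
    matched = matched_list[0]
    if cfg.variant == "species_only":
        keep = matched.traits.loc[matched.traits["match_level"] == "species", "taxon"].tolist()
        pruned = []
        for ds in matched_list:
            sub, _ = ds.tree.prune_to_tips([k for k in keep if k in ds.tree.tip_labels])
            pruned.append(sub)
        traits = matched.traits[matched.traits["taxon"].isin(keep)].reset_index(drop=True)
        order = {lab: i for i, lab in enumerate(pruned[0].tip_labels)}
        traits = traits.sort_values("taxon", key=lambda s: s.map(order)).reset_index(drop=True)
        matched = MatchedDataset(tree=pruned[0], traits=traits, metadata=matched.metadata)
        work_trees = pruned
    else:
        work_trees = [ds.tree for ds in matched_list]

    systems_map = dict(zip(matched.traits["taxon"], (matched.traits["system"] == "haplodiploid").astype(int)))
    counts_map = dict(zip(matched.traits["taxon"], matched.traits["count_2n"]))
    seeds = _stage_seeds(cfg.seed, ("origins", "origin_test", "lmm", "taxonomic", "threshold"))
    bundle = ReportBundle(config=cfg, trees=work_trees, matched=matched)
    rep: dict[str, Any] = {
        "variant": cfg.variant,
        "n_trees": len(work_trees),
        "n_tips": matched.tree.n_tips,
        "match_levels": {
            k: int(v) for k, v in matched.traits["match_level"].value_counts().items()
        },
        "seeds": seeds,
    }

    def stage(name):
        return name in cfg.stages

    if stage("mk"):
        try:
            comp = compare_models_over_trees(work_trees, systems_map)
            bundle.comparison = comp
            rep["mk"] = {
                "mean_delta_aicc": comp.mean_delta_aicc,
                "preferred": comp.preferred,
                "per_tree_delta_aicc": [float(x) for x in comp.delta_aicc],
            }
            comp.to_frame().to_csv(outdir / "tables" / "mk_fits.csv", index=False)
            if cfg.drop_tip:
                dropped = drop_tip_sensitivity(work_trees, systems_map, cfg.drop_tip)
                bundle.drop_comparison = dropped
                rep["mk_drop_tip"] = {
                    "dropped": cfg.drop_tip,
                    "mean_delta_aicc": dropped.mean_delta_aicc,
                    "preferred": dropped.preferred,
                }
        except Exception as exc:
            bundle.errors["mk"] = str(exc)

    if stage("origins"):
        try:
            for model in ("one_rate", "two_rate"):
                summ = summarize_origins(
                    work_trees, systems_map, model=model, n_maps=cfg.n_maps, seed=seeds["origins"]
                )
                bundle.origins[model] = summ
            rep["origins"] = {
                m: {"mean": s.mean, "sd": s.sd, "per_tree_mean": [float(x) for x in s.per_tree_mean]}
                for m, s in bundle.origins.items()
            }
        except Exception as exc:
            bundle.errors["origins"] = str(exc)

    if stage("origin_test"):
        try:
            results = []
            for i, t in enumerate(work_trees):
                sy = np.array([systems_map[lab] for lab in t.tip_labels])
                cn = np.array([counts_map[lab] for lab in t.tip_labels], dtype=float)
                results.extend(
                    monte_carlo_origin_test(
                        t, sy, cn, model="one_rate", n_maps=cfg.origin_test_maps,
                        R=cfg.null_reps, seed=seeds["origin_test"] + i, tree_id=i,
                    )
                )
            agg = aggregate_origin_tests(results, seed=seeds["origin_test"])
            bundle.origin_test = agg
            rep["origin_test"] = {
                "observed_mean_2n": agg.observed_mean,
                "expected_mean_2n": agg.expected_mean,
                "p_value": agg.p_value,
                "n_map_results": agg.n_results,
            }
        except Exception as exc:
            bundle.errors["origin_test"] = str(exc)

    complete = matched.traits["count_2n"].notna().to_numpy()
    if stage("lmm"):
        try:
            sub_trees = work_trees[: cfg.lmm_trees]
            t0 = sub_trees[0]
            y = np.log(np.array([counts_map[lab] for lab in t0.tip_labels], dtype=float))
            z = np.array([systems_map[lab] for lab in t0.tip_labels], dtype=float)
            res = phylo_lmm(
                sub_trees, y, z, n_iter=cfg.lmm_iter, burnin=cfg.lmm_burnin,
                thin=cfg.lmm_thin, seed=seeds["lmm"],
            )
            bundle.lmm = res
            rep["phylo_lmm"] = {
                "beta_ploidy": res.beta_mean,
                "beta_ci": list(res.beta_ci),
                "p_mcmc": res.p_mcmc,
                "heritability": res.heritability_mean,
                "heritability_ci": list(res.heritability_ci),
            }
        except Exception as exc:
            bundle.errors["lmm"] = str(exc)

    if stage("taxonomic"):
        try:
            res = taxonomic_lmm(
                matched.traits[complete], n_iter=cfg.lmm_iter, burnin=cfg.lmm_burnin,
                thin=cfg.lmm_thin, seed=seeds["taxonomic"],
            )
            bundle.taxonomic = res
            rep["taxonomic_lmm"] = {
                "beta_ploidy": res.beta_mean,
                "beta_ci": list(res.beta_ci),
                "p_mcmc": res.p_mcmc,
                "heritability": res.heritability_mean,
            }
        except Exception as exc:
            bundle.errors["taxonomic"] = str(exc)

    if stage("threshold"):
        try:
            t0 = work_trees[0]
            y = np.log(np.array([counts_map[lab] for lab in t0.tip_labels], dtype=float))
            z = np.array([systems_map[lab] for lab in t0.tip_labels], dtype=int)
            res = threshold_model(
                t0, y, z, n_iter=cfg.threshold_iter, burnin=cfg.threshold_burnin,
                thin=cfg.threshold_thin, seed=seeds["threshold"],
            )
            bundle.threshold = res
            rep["threshold"] = {"corr": res.corr_mean, "corr_ci": list(res.corr_ci)}
        except Exception as exc:
            bundle.errors["threshold"] = str(exc)

    if stage("infraorder"):
        try:
            res = infraorder_test(matched.traits)
            bundle.infraorder = res
            rep["infraorder"] = {
                "mean_2n_with_haplodiploids": res.group_mean_with,
                "mean_2n_without_haplodiploids": res.group_mean_without,
                "t": res.t,
                "df": res.df,
                "p_value": res.p_value,
            }
        except Exception as exc:
            bundle.errors["infraorder"] = str(exc)

    rep["errors"] = dict(bundle.errors)
    bundle.report = rep
    manifest = {
        "ploidyshift_version": __version__,
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__ if k != "stages"},
        "stages": list(cfg.stages),
        "inputs": {"trees": _sha256(cfg.trees), "traits": _sha256(cfg.traits)},
        "seeds": seeds,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(rep, fh, indent=2, sort_keys=True, default=float)
    with open(outdir / "report.md", "w") as fh:
        fh.write(_render_markdown(rep))
    return bundle


def _render_markdown(rep: dict) -> str:
    lines = ["# ploidyshift analysis report", ""]
    lines.append(f"Dataset variant: **{rep['variant']}** "
                 f"({rep['n_tips']} tips, {rep['n_trees']} trees)")
    lines.append("")
    if "mk" in rep:
        lines += [
            "## Reproductive-system model comparison",
            "",
            f"Mean AICc difference (two_rate - one_rate): **{rep['mk']['mean_delta_aicc']:.3f}**;"
            f" preferred model: **{rep['mk']['preferred']}**.",
            "",
        ]
    if "mk_drop_tip" in rep:
        d = rep["mk_drop_tip"]
        lines += [
            f"With tip `{d['dropped']}` removed: mean AICc difference "
            f"{d['mean_delta_aicc']:.3f}, preferred model {d['preferred']}.",
            "",
        ]
    if "origins" in rep:
        lines.append("## Origins of haplodiploidy (stochastic mapping)")
        lines.append("")
        for m, s in rep["origins"].items():
            lines.append(f"- {m}: mean {s['mean']:.2f} origins (SD {s['sd']:.2f})")
        lines.append("")
    if "origin_test" in rep:
        o = rep["origin_test"]
        lines += [
            "## Chromosome number at origin nodes",
            "",
            f"Observed mean 2n at origin nodes: **{o['observed_mean_2n']:.2f}**; "
            f"expected under independence: **{o['expected_mean_2n']:.2f}** "
            f"(one-sided P = {o['p_value']:.4f}).",
            "",
        ]
    for key, title in (("phylo_lmm", "Phylogenetic mixed model"),
                       ("taxonomic_lmm", "Taxonomic mixed model")):
        if key in rep:
            r = rep[key]
            lines += [
                f"## {title}",
                "",
                f"beta(ploidy) = {r['beta_ploidy']:.3f} "
                f"[{r['beta_ci'][0]:.3f}, {r['beta_ci'][1]:.3f}], "
                f"P_MCMC = {r['p_mcmc']:.4f}; heritability = {r['heritability']:.3f}.",
                "",
            ]
    if "threshold" in rep:
        r = rep["threshold"]
        lines += [
            "## Threshold model",
            "",
            f"Liability correlation r = {r['corr']:.3f} "
            f"[{r['corr_ci'][0]:.3f}, {r['corr_ci'][1]:.3f}].",
            "",
        ]
    if "infraorder" in rep:
        r = rep["infraorder"]
        lines += [
            "## Infraorder comparison",
            "",
            f"Mean diploid 2n: {r['mean_2n_with_haplodiploids']:.2f} (infraorders with "
            f"haplodiploids) vs {r['mean_2n_without_haplodiploids']:.2f} (without); "
            f"Welch t({r['df']:.2f}) = {r['t']:.3f}, P = {r['p_value']:.4f}.",
            "",
        ]
    if rep.get("errors"):
        lines.append("## Stage errors")
        lines.append("")
        for k, v in rep["errors"].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)


def make_figures(bundle: ReportBundle, outdir: str | Path | None = None) -> list[Path]:
    """Scatter + two tree paintings from a completed run; stages that failed
    simply skip their figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir if outdir is not None else bundle.config.outdir) / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    from .brownian_asr import bm_ancestral
    from .plotting import plot_tree

    paths: list[Path] = []
    traits = bundle.matched.traits
    tree = bundle.matched.tree

    # 1. scatter of counts by system, with mixed-model prediction if present
    fig, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)
    for j, system in enumerate(("diplodiploid", "haplodiploid")):
        vals = traits.loc[traits["system"] == system, "count_2n"].dropna().to_numpy(dtype=float)
        ax.scatter(j + rng.uniform(-0.12, 0.12, vals.size), vals, s=12, alpha=0.6,
                   color="#b2182b" if j == 0 else "#2166ac", label=system)
    if bundle.lmm is not None:
        s = bundle.lmm.samples
        for j, pred in enumerate((s["mu"], s["mu"] + s["beta"])):
            est = np.exp(pred.to_numpy())
            lo, hi = np.percentile(est, [2.5, 97.5])
            ax.errorbar([j + 0.25], [est.mean()], yerr=[[est.mean() - lo], [hi - est.mean()]],
                        fmt="D", color="black", capsize=3)
    ax.set_xticks([0, 1], ["diplodiploid", "haplodiploid"])
    ax.set_ylabel("diploid chromosome number (2n)")
    fig.tight_layout()
    p = outdir / "counts_by_system.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    # 2. ancestral state posterior painting
    if bundle.comparison is not None and bundle.comparison.fits_one:
        from .stochastic_mapping import marginal_node_posteriors as mnp

        fit = bundle.comparison.fits_one[0]
        systems = (traits["system"] == "haplodiploid").astype(int).to_numpy()
        post = mnp(tree, systems, fit.rates, fit.root_mode)
        fig, ax = plt.subplots(figsize=(5, 7))
        sc = plot_tree(ax, tree, node_values=post[:, 1], cmap="coolwarm_r", vmin=0, vmax=1)
        fig.colorbar(sc, ax=ax, label="P(haplodiploid)", shrink=0.5)
        fig.tight_layout()
        p = outdir / "system_asr.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)

    # 3. chromosome-number reconstruction painting
    counts = traits["count_2n"].to_numpy(dtype=float)
    if np.all(np.isfinite(counts)):
        bm = bm_ancestral(tree, np.log(counts))
        fig, ax = plt.subplots(figsize=(5, 7))
        sc = plot_tree(ax, tree, node_values=np.exp(bm.estimates), cmap="viridis")
        fig.colorbar(sc, ax=ax, label="reconstructed 2n", shrink=0.5)
        fig.tight_layout()
        p = outdir / "count_asr.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths
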