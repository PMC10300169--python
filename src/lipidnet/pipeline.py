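"""End-to-end pipeline orchestration.

Stages (in order): simulate/load -> preprocess -> screen -> network ->
importance -> selection -> score -> pca. Every stage writes its artifact
under the output directory and can be re-run from the saved artifacts of
its upstream stages, reproducing the single-shot outputs exactly; a
manifest records the seed, resolved config hash and per-stage shapes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import CohortSpec, MatchedCohort, generate_cohort, read_cohort, write_cohort
from .preprocess import blom_transform, impute_half_min, strata_deviation
from .screen import DEFAULT_COVARIATES, screen_lipids
from .network import LipidNetwork, split_half_network
from .importance import RFParams, rank_clusters
from .score import CVParams, build_loocv_score, enet_across_clusters, enet_within_clusters
from .factors import fit_pca_controls, project_scores, quartile_association

log = logging.getLogger("lipidnet")

ALL_STAGES = ["simulate", "preprocess", "screen", "network", "importance", "selection", "score", "pca"]

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "ALL_STAGES"]


@dataclass
class PipelineConfig:
    output_dir: str = "lipidnet_run"
    cohort_dir: str | None = None  # None -> simulate a synthetic cohort
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 1
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    # synthetic cohort (used only when cohort_dir is None)
    n_strata: int = 512
    n_lipids: int = 216
    n_clusters: int = 12
    within_cluster_rho: float = 0.5
    missing_rate: float = 0.02
    true_effects: dict = field(default_factory=dict)  # lipid index -> log-odds per SD
    # network
    alpha: float = 0.05
    max_order: int = 3
    partial_corr_threshold: float = 0.1
    walktrap_steps: int = 4
    # random forest
    n_trees: int = 500
    sample_rate: float = 2.0 / 3.0
    n_permutations: int = 10
    top_k_clusters: int = 7
    # elastic net
    cv_folds: int = 10
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    # pca
    eigenvalue_threshold: float = 2.0
    loading_threshold: float = 0.40

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.l1_ratios, list):
            cfg.l1_ratios = tuple(cfg.l1_ratios)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["l1_ratios"] = list(self.l1_ratios)
        d["true_effects"] = {str(k): v for k, v in self.true_effects.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one; toggling one stage never
    shifts another stage's randomness."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31)
    )


def _read_matrix(path: Path) -> pd.DataFrame:
    # round_trip parsing so reloaded artifacts equal the in-memory doubles
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    # %.17g round-trips doubles exactly, so reloading an artifact reproduces
    # the in-memory values bit for bit
    df.to_csv(path, sep="\t", float_format="%.17g")


def _load_cohort_and_blom(out: Path, config: PipelineConfig) -> tuple[MatchedCohort, pd.DataFrame]:
    cohort = read_cohort(out / "cohort")
    blom = _read_matrix(out / "blom.tsv")
    return cohort, blom


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the in-memory result bundle.

    Disabled stages are loaded from their saved artifacts in
    ``config.output_dir``, so re-running a downstream stage alone
    reproduces the single-shot outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"output_dir": str(out)}
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_run": [s for s in config.stages if s in ALL_STAGES],
        "stage_info": {},
    }
    stages = set(config.stages)

    def done(stage: str, **info):
        manifest["stage_info"][stage] = info
        log.info("stage %s: %s", stage, info)

    # ---- cohort ---------------------------------------------------------
    if "simulate" in stages and config.cohort_dir is None:
        spec = CohortSpec(
            n_strata=config.n_strata,
            n_lipids=config.n_lipids,
            n_clusters=config.n_clusters,
            within_cluster_rho=config.within_cluster_rho,
            missing_rate=config.missing_rate,
            true_effects={int(k): float(v) for k, v in config.true_effects.items()},
            seed=stage_seed(config.seed, "simulate"),
        )
        cohort = generate_cohort(spec)
        write_cohort(cohort, out / "cohort")
        done("simulate", n_subjects=len(cohort.subjects), n_lipids=cohort.lipids.shape[1])
    elif config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir)
        write_cohort(cohort, out / "cohort")
        done("simulate", loaded_from=str(config.cohort_dir), n_subjects=len(cohort.subjects))
    else:
        cohort = read_cohort(out / "cohort")
    bundle["cohort"] = cohort

    # ---- preprocess -----------------------------------------------------
    if "preprocess" in stages:
        imputed = impute_half_min(cohort.lipids)
        blom = blom_transform(imputed)
        deviations = strata_deviation(blom, cohort.strata)
        _write_matrix(blom.values, out / "blom.tsv")
        _write_matrix(deviations.values, out / "deviations.tsv")
        (out / "preprocess_provenance.json").write_text(json.dumps(deviations.provenance))
        done("preprocess", provenance=deviations.provenance, shape=list(blom.values.shape))
        blom_df, dev_df = blom.values, deviations.values
    elif stages & {"screen", "network", "importance", "selection", "score", "pca"}:
        blom_df = _read_matrix(out / "blom.tsv")
        dev_df = _read_matrix(out / "deviations.tsv")
    else:
        blom_df = dev_df = None
    bundle["blom"] = blom_df
    bundle["deviations"] = dev_df

    # ---- per-lipid screen -----------------------------------------------
    if "screen" in stages:
        screen = screen_lipids(cohort, blom_df, config.covariates)
        screen.table.to_csv(out / "screen.tsv", sep="\t", index=False)
        done(
            "screen",
            n_features=screen.n_features,
            n_nominal=int((screen.table["p_raw"] < 0.05).sum()),
            min_p_by=float(np.nanmin(screen.table["p_by"])),
        )
        bundle["screen"] = screen.table
    elif (out / "screen.tsv").exists():
        bundle["screen"] = pd.read_csv(out / "screen.tsv", sep="\t")

    # ---- network + clusters ---------------------------------------------
    if "network" in stages:
        net = split_half_network(
            blom_df,
            cohort.strata,
            alpha=config.alpha,
            max_order=config.max_order,
            threshold=config.partial_corr_threshold,
            walktrap_steps=config.walktrap_steps,
            seed=stage_seed(config.seed, "network"),
        )
        edges = pd.DataFrame(net.edges, columns=["node_a", "node_b", "partial_correlation", "robust"])
        edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        part = pd.DataFrame(
            {"feature": list(net.partition), "cluster_id": list(net.partition.values())}
        )
        part.to_csv(out / "network_partition.tsv", sep="\t", index=False)
        (out / "network_params.json").write_text(json.dumps(net.algorithm_params, default=str))
        g = net.graph()
        g.vs["cluster_id"] = [net.partition[v] for v in net.nodes]
        g.write_graphml(str(out / "network.graphml"))
        done("network", n_edges=len(edges), n_clusters=int(part["cluster_id"].nunique()))
        partition = net.partition
        bundle["network"] = net
    elif stages & {"importance", "selection"}:
        part = pd.read_csv(out / "network_partition.tsv", sep="\t")
        partition = dict(zip(part["feature"].astype(str), part["cluster_id"].astype(int)))
    else:
        partition = None
    bundle["partition"] = partition

    # ---- cluster importance ---------------------------------------------
    if "importance" in stages:
        imp = rank_clusters(
            dev_df,
            cohort.is_case,
            partition,
            RFParams(
                n_trees=config.n_trees,
                sample_rate=config.sample_rate,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, "importance"),
            ),
        )
        tab = imp.table.copy()
        tab["member_features"] = [",".join(imp.members[c]) for c in tab["cluster_id"]]
        tab.sort_values("rank").to_csv(out / "importance.tsv", sep="\t", index=False)
        (out / "importance_baseline.json").write_text(
            json.dumps({"baseline_oob_error": imp.baseline_oob_error})
        )
        done("importance", baseline_oob_error=imp.baseline_oob_error, n_clusters=len(tab))
        imp_table = tab
    elif "selection" in stages:
        imp_table = pd.read_csv(out / "importance.tsv", sep="\t")
    else:
        imp_table = None
    bundle["importance"] = imp_table

    # ---- elastic-net selection ------------------------------------------
    if "selection" in stages:
        top = imp_table.sort_values("rank")["cluster_id"].head(config.top_k_clusters).tolist()
        cv = CVParams(
            folds=config.cv_folds,
            l1_ratios=config.l1_ratios,
            seed=stage_seed(config.seed, "selection"),
        )
        within = enet_within_clusters(dev_df, cohort.is_case, partition, top, cv)
        selection = enet_across_clusters(dev_df, cohort.is_case, within, cv)
        sel_tab = pd.DataFrame(
            {
                "feature": selection.across_cluster_selected,
                "cluster_id": [partition[f] for f in selection.across_cluster_selected],
                "enet_coefficient": [
                    selection.enet_coefficients[f] for f in selection.across_cluster_selected
                ],
            }
        )
        sel_tab.to_csv(out / "selection.tsv", sep="\t", index=False)
        (out / "selection_within.json").write_text(
            json.dumps({str(k): v for k, v in selection.within_cluster_selected.items()})
        )
        done(
            "selection",
            n_within=sum(len(v) for v in selection.within_cluster_selected.values()),
            n_across=len(selection.across_cluster_selected),
        )
        selected = selection.across_cluster_selected
        bundle["selection"] = sel_tab
    elif "score" in stages:
        sel_tab = pd.read_csv(out / "selection.tsv", sep="\t")
        selected = sel_tab["feature"].astype(str).tolist()
        bundle["selection"] = sel_tab

    # ---- LOOCV score -----------------------------------------------------
    if "score" in stages:
        if not selected:
            (out / "score_summary.json").write_text(json.dumps({"no_predictors_selected": True}))
            done("score", skipped="no predictors selected")
            bundle["score"] = None
        else:
            model = build_loocv_score(cohort, blom_df, selected, config.covariates)
            weights = pd.DataFrame(
                {
                    "feature": model.selected,
                    "enet_coefficient": [
                        bundle["selection"].set_index("feature")["enet_coefficient"].get(f, np.nan)
                        for f in model.selected
                    ],
                    "loocv_median_weight": [model.weight_medians[f] for f in model.selected],
                }
            )
            weights.to_csv(out / "score_weights.tsv", sep="\t", index=False)
            model.subject_scores.rename_axis("subject_id").to_frame().to_csv(
                out / "scores.tsv", sep="\t", float_format="%.17g"
            )
            summary = {
                "or_per_sd": model.or_per_sd,
                "ci95": list(model.ci95),
                "p": model.p,
                "interaction_wald": model.interaction_wald,
                "n_selected": len(model.selected),
                "n_failed_folds": model.n_failed_folds,
            }
            (out / "score_summary.json").write_text(json.dumps(summary, indent=1))
            done("score", or_per_sd=model.or_per_sd, ci95=list(model.ci95))
            bundle["score"] = model
    elif (out / "score_summary.json").exists():
        bundle["score_summary"] = json.loads((out / "score_summary.json").read_text())

    # ---- PCA factors -----------------------------------------------------
    if "pca" in stages:
        fm = fit_pca_controls(
            blom_df,
            cohort.is_case == 0,
            eigenvalue_threshold=config.eigenvalue_threshold,
            loading_threshold=config.loading_threshold,
        )
        load_tab = pd.DataFrame(
            fm.loadings, index=fm.feature_names,
            columns=[f"factor_{k+1}" for k in range(fm.retained)],
        )
        load_tab["max_abs_loading_flag"] = (np.abs(fm.loadings) > fm.loading_threshold).any(axis=1) if fm.retained else False
        _write_matrix(load_tab, out / "factor_loadings.tsv")
        if fm.retained > 0:
            scores = project_scores(fm, blom_df)
            assoc = quartile_association(cohort, scores, config.covariates)
            assoc.to_csv(out / "factor_associations.tsv", sep="\t", index=False)
        else:
            assoc = pd.DataFrame()
        (out / "pca_summary.json").write_text(
            json.dumps(
                {
                    "retained": fm.retained,
                    "variance_explained": fm.variance_explained,
                    "eigenvalues_head": [float(e) for e in fm.eigenvalues[: max(fm.retained, 5)]],
                }
            )
        )
        done("pca", retained=fm.retained, variance_explained=fm.variance_explained)
        bundle["factors"] = fm
        bundle["factor_associations"] = assoc
    elif (out / "factor_associations.tsv").exists():
        bundle["factor_associations"] = pd.read_csv(out / "factor_associations.tsv", sep="\t")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle


def make_report(output_dir: str | Path) -> str:
    """Human-readable summary of a pipeline run from its saved artifacts."""
    out = Path(output_dir)
    lines = ["lipidnet pipeline report", "=" * 40]

    def have(name: str) -> bool:
        return (out / name).exists()

    if have("screen.tsv"):
        scr = pd.read_csv(out / "screen.tsv", sep="\t")
        n_nom = int((scr["p_raw"] < 0.05).sum())
        n_fdr = int((scr["p_by"] < 0.05).sum())
        lines.append(f"\nPer-lipid screen: {len(scr)} lipids, {n_nom} nominally associated (p<0.05)")
        lines.append(
            f"  after Benjamini-Yekutieli adjustment: "
            + (f"{n_fdr} significant" if n_fdr else "no FDR-significant lipids")
        )
    else:
        lines.append("\n[screen results missing]")

    if have("importance.tsv"):
        imp = pd.read_csv(out / "importance.tsv", sep="\t").sort_values("rank")
        lines.append("\nMost important lipid clusters (OOB error increase under joint permutation):")
        for _, r in imp.head(7).iterrows():
            feats = str(r.get("member_features", ""))
            short = feats if len(feats) < 70 else feats[:67] + "..."
            lines.append(f"  rank {int(r['rank'])}: cluster {int(r['cluster_id'])} "
                         f"({r['oob_error_increase']:+.4f})  {short}")
    else:
        lines.append("\n[cluster importance missing]")

    if have("score_weights.tsv"):
        w = pd.read_csv(out / "score_weights.tsv", sep="\t")
        lines.append("\nSelected predictors (elastic-net coefficient / LOOCV median weight):")
        for _, r in w.iterrows():
            lines.append(
                f"  {r['feature']}: {r['enet_coefficient']:+.3f} / {r['loocv_median_weight']:+.3f}"
            )
    if have("score_summary.json"):
        s = json.loads((out / "score_summary.json").read_text())
        if s.get("no_predictors_selected"):
            lines.append("\nMultilipid score: no predictors selected")
        else:
            lo, hi = s["ci95"]
            lines.append(
                f"\nMultilipid score: OR per SD = {s['or_per_sd']:.2f} "
                f"(95% CI {lo:.2f}-{hi:.2f}; p = {s['p']:.2g})"
            )
            iw = s.get("interaction_wald", {})
            if iw and np.isfinite(iw.get("p", np.nan)):
                lines.append(
                    f"  score x intervention interaction: Wald chi2 = "
                    f"{iw['statistic']:.2f} ({iw['df']} df), p = {iw['p']:.2g}"
                )
    else:
        lines.append("\n[score missing]")

    if have("pca_summary.json"):
        s = json.loads((out / "pca_summary.json").read_text())
        lines.append(
            f"\nPCA factors: {s['retained']} retained (eigenvalue > 2), "
            f"explaining {100 * s['variance_explained']:.0f}% of total variance"
        )
        if have("factor_associations.tsv"):
            fa = pd.read_csv(out / "factor_associations.tsv", sep="\t")
            sig = fa[fa["p_trend"] < 0.05] if "p_trend" in fa else fa.iloc[0:0]
            if len(sig):
                for _, r in sig.iterrows():
                    lines.append(
                        f"  {r['factor']}: Q4 vs Q1 OR = {r['or_q4']:.2f} "
                        f"({r['ci_low_q4']:.2f}-{r['ci_high_q4']:.2f}), trend p = {r['p_trend']:.3f}"
                    )
            else:
                lines.append("  no factor reached a trend p < 0.05")
    else:
        lines.append("\n[PCA results missing]")

    return "\n".join(lines) + "\n"
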