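"""Config-driven orchestration of the full analysis.

Stages run in dependency order -- cohort, clinical summary, OTU processing,
diversity (alpha/beta/PERMANOVA/SIMPER), AG subgroup analysis, co-occurrence
networks with keystone differencing, association screens (Mantel/OLS/ROC),
the MLP classifier, and the two-latent structural model -- each wrapped so a
stage failure marks the section failed and skips its dependents instead of
aborting the run.  A manifest records the config hash and seed; identical
config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, classifier, clinical_stats, diversity, network
from . import latent_model as lm
from .otu_processing import OtuTable, fb_ratio, filter_by_total, incidence_summary, relative_abundance
from .synthetic_data import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "subgroup_analysis"]

_CLINICAL_FEATURES = ["age", "AG", "UAG", "ag_uag_ratio", "AAGR", "insulin",
                      "MMSE", "MoCA", "GADL", "HADS_A", "HADS_D"]


@dataclass
class RunConfig:
    clinical_csv: str | None = None
    otu_tsv: str | None = None
    synthetic: dict | None = None
    min_total: int = 10
    incidence_threshold: float = 0.01
    top_n: int = 15
    edge_threshold: float = 0.3
    node_min_total: int = 10
    sparcc_iterations: int = 20
    r2_threshold: float = 0.55
    roc_cutoff_clinical: float = 0.65
    roc_cutoff_microbe: float = 0.70
    n_permutations: int = 999
    ag_cutpoint: float = 1.0
    lv1_indicators: list | None = None
    lv2_indicators: list | None = None
    seed: int = 0
    outdir: str = "gutbrain_out"

    def __post_init__(self) -> None:
        has_files = self.clinical_csv is not None and self.otu_tsv is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError("config must give exactly one of input files or synthetic block")
        for name, lo, hi in [("incidence_threshold", 0, 1), ("edge_threshold", 0, 1),
                             ("r2_threshold", 0, 1), ("roc_cutoff_clinical", 0, 1),
                             ("roc_cutoff_microbe", 0, 1)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if has_files:
            for p in (self.clinical_csv, self.otu_tsv):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        # the output directory is not part of the analysis identity
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    sections: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def failed_stages(self) -> list[str]:
        return [k for k, v in self.sections.items()
                if isinstance(v, dict) and v.get("status") == "failed"]


def _load_cohort(config: RunConfig) -> SyntheticCohort:
    if config.synthetic is not None:
        synth = dict(config.synthetic)
        synth.setdefault("seed", config.seed)
        if "basis_correlation" in synth:
            synth["basis_correlation"] = {
                tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                for k, v in synth["basis_correlation"].items()
            }
        return generate_cohort(CohortConfig(**synth))
    clinical = pd.read_csv(config.clinical_csv, index_col="subject")
    groups = clinical["group"].to_dict()
    otu = OtuTable.from_tsv(config.otu_tsv, sample_group=groups)
    return SyntheticCohort(clinical=clinical, otu=otu, truth={})


def subgroup_analysis(
    cohort: SyntheticCohort,
    variable: str = "AG",
    cutpoint: float = 1.0,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Alpha/beta diversity between case-group strata split at ``cutpoint``.

    Values strictly greater than the cutpoint go to the high stratum; values
    equal to the cutpoint go low.  An empty stratum skips the section.
    """
    case_samples = [s for s in cohort.otu.samples
                    if cohort.clinical.loc[s, "group"] == "dementia"]
    vals = cohort.clinical.loc[case_samples, variable]
    high = [s for s in case_samples if vals[s] > cutpoint]
    low = [s for s in case_samples if vals[s] <= cutpoint]
    if not high or not low:
        logger.warning("subgroup_analysis: empty stratum at cutpoint %s", cutpoint)
        return {"status": "skipped", "reason": "empty stratum",
                "n_high": len(high), "n_low": len(low)}
    counts = cohort.otu.counts[case_samples]
    alpha = diversity.alpha_diversity_table(counts)
    strata = pd.Series(["high" if s in high else "low" for s in case_samples],
                       index=case_samples)
    alpha_tests = {}
    for idx in ("richness", "shannon", "simpson", "pielou"):
        a = alpha.loc[strata == "high", idx].dropna()
        b = alpha.loc[strata == "low", idx].dropna()
        try:
            res = clinical_stats.compare_groups(a, b)
            alpha_tests[idx] = {"statistic": res.statistic, "p_value": res.p_value}
        except ValueError as exc:
            alpha_tests[idx] = {"error": str(exc)}
    out = {"status": "ok", "n_high": len(high), "n_low": len(low),
           "alpha_tests": alpha_tests}
    if len(high) >= 2 and len(low) >= 2:
        dm = diversity.bray_curtis_matrix(counts.T)
        res = diversity.permanova(dm, strata.values, n_perm=n_perm, seed=seed)
        out["permanova"] = {"pseudo_F": res.pseudo_F, "p_value": res.p_value,
                            "r_squared": res.r_squared}
    return out


def _auto_latent_spec(simper_table: pd.DataFrame) -> lm.LatentModelSpec:
    """Default SEM spec from the SIMPER table: top case-enriched species load
    lv1 (positive effect), top control-enriched load lv2 with age and AG."""
    cols = [c for c in simper_table.columns if c.startswith("mean_")]
    case_col = next((c for c in cols if "dementia" in c), cols[-1])
    ctrl_col = next((c for c in cols if c != case_col), cols[0])
    up = simper_table[simper_table[case_col] > simper_table[ctrl_col]]
    down = simper_table[simper_table[case_col] <= simper_table[ctrl_col]]
    lv1 = list(up.index[:2])
    lv2 = list(down.index[:2]) + ["age", "AG"]
    return lm.LatentModelSpec(lv1_indicators=lv1, lv2_indicators=lv2)


def run_pipeline(config: RunConfig, force: bool = False) -> ReportBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != config.hash():
            raise RuntimeError(
                f"{outdir} holds results for a different config "
                f"({old.get('config_hash')}); pass force=True to overwrite"
            )
    bundle = ReportBundle()
    seed = config.seed
    rng = np.random.default_rng(seed)
    stage_seeds = {name: int(rng.integers(2**31)) for name in
                   ["permanova", "network_c", "network_d", "mantel",
                    "classifier", "latent", "subgroup"]}

    def stage(name, fn, *deps):
        t0 = time.perf_counter()
        for d in deps:
            sec = bundle.sections.get(d)
            if not isinstance(sec, dict) or sec.get("status") not in ("ok",):
                bundle.sections[name] = {"status": "skipped",
                                         "reason": f"dependency {d} not ok"}
                logger.info("stage=%s status=skipped dep=%s", name, d)
                return None
        try:
            result = fn()
            bundle.sections[name] = {"status": "ok", **(result or {})}
            logger.info("stage=%s status=ok seed=%s wall=%.2fs",
                        name, seed, time.perf_counter() - t0)
            return bundle.sections[name]
        except Exception as exc:
            bundle.sections[name] = {"status": "failed", "error": str(exc)}
            logger.error("stage=%s status=failed error=%s", name, exc)
            return None

    state: dict = {}

    def s_cohort():
        cohort = _load_cohort(config)
        state["cohort"] = cohort
        cohort.clinical.to_csv(outdir / "clinical.csv", index_label="subject")
        cohort.otu.to_tsv(outdir / "otu_table.tsv")
        return {"n_subjects": len(cohort.clinical),
                "n_taxa": len(cohort.otu.taxa),
                "n_microbiome_samples": len(cohort.otu.samples)}

    def s_table1():
        summary = clinical_stats.table1_summary(state["cohort"].clinical)
        summary.to_csv(outdir / "table1_summary.tsv", sep="\t")
        return {"n_variables": len(summary)}

    def s_otu():
        cohort = state["cohort"]
        filtered = filter_by_total(cohort.otu, config.min_total)
        state["filtered"] = filtered
        props = relative_abundance(filtered)
        state["props"] = props
        groups = filtered.sample_group
        summary = incidence_summary(props, groups, config.incidence_threshold,
                                    config.top_n)
        summary.to_csv(outdir / "incidence_summary.tsv", sep="\t", index=False)
        fb = fb_ratio(filtered)
        fb.to_csv(outdir / "fb_ratio.tsv", sep="\t", header=["ln_fb_ratio"])
        a = fb[groups == "control"].dropna()
        b = fb[groups == "dementia"].dropna()
        fb_test = None
        if len(a) >= 2 and len(b) >= 2:
            res = clinical_stats.compare_groups(a, b)
            fb_test = {"statistic": res.statistic, "p_value": res.p_value}
        return {"n_taxa_retained": len(filtered.taxa), "fb_test": fb_test}

    def s_diversity():
        filtered, props = state["filtered"], state["props"]
        groups = filtered.sample_group
        alpha = diversity.alpha_diversity_table(filtered.counts)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        alpha_tests = {}
        for idx in ("richness", "shannon", "simpson", "pielou"):
            a = alpha.loc[groups == "control", idx].dropna()
            b = alpha.loc[groups == "dementia", idx].dropna()
            res = clinical_stats.compare_groups(a, b)
            alpha_tests[idx] = {"statistic": res.statistic, "p_value": res.p_value}
        dm = diversity.bray_curtis_matrix(props.T)
        state["bc"] = dm
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            outdir / "bray_curtis.tsv", sep="\t")
        coords, eigvals, prop = diversity.pcoa(dm)
        coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        perm = diversity.permanova(dm, groups.values, config.n_permutations,
                                   seed=stage_seeds["permanova"])
        simper_table = diversity.simper(props.T, groups.values)
        state["simper"] = simper_table
        simper_table.to_csv(outdir / "simper.tsv", sep="\t")
        return {"alpha_tests": alpha_tests,
                "permanova": {"pseudo_F": perm.pseudo_F, "p_value": perm.p_value,
                              "r_squared": perm.r_squared},
                "pcoa_prop_explained": list(np.round(prop[:2], 4))}

    def s_subgroup():
        return subgroup_analysis(state["cohort"], "AG", config.ag_cutpoint,
                                 config.n_permutations, stage_seeds["subgroup"])

    def s_networks():
        filtered = state["filtered"]
        groups = filtered.sample_group
        nets = {}
        for g, sname in (("control", "network_c"), ("dementia", "network_d")):
            sub = filtered.subset_samples(list(groups[groups == g].index))
            corr = network.sparcc_correlations(
                sub, outer_iterations=config.sparcc_iterations,
                seed=stage_seeds[sname])
            net = network.build_cooccurrence_network(
                corr, sub, config.node_min_total, config.edge_threshold)
            if net.graph.number_of_edges() > 0:
                network.louvain_partition(net, seed=stage_seeds[sname])
            nets[g] = net
            net.edge_list().to_csv(outdir / f"network_{g}_edges.tsv",
                                   sep="\t", index=False)
            net.to_graphml(outdir / f"network_{g}.graphml")
        state["networks"] = nets
        reps = {g: network.representative_species(n) if n.community else {}
                for g, n in nets.items()}
        delta = network.centrality_difference(nets["control"], nets["dementia"])
        delta.to_csv(outdir / "centrality_delta.tsv", sep="\t")
        return {
            "representatives": {g: {str(k): v for k, v in r.items()}
                                for g, r in reps.items()},
            "n_outliers": int(delta["outlier"].sum()),
            "modularity": {g: nets[g].modularity for g in nets},
        }

    def s_association():
        cohort, filtered, props = state["cohort"], state["filtered"], state["props"]
        groups = filtered.sample_group
        clin_cols = [c for c in _CLINICAL_FEATURES if c in cohort.clinical.columns]
        top_species = list(state["simper"].index[:5])
        mantel_rows = []
        rng_m = np.random.default_rng(stage_seeds["mantel"])
        for g in ("control", "dementia"):
            samples = list(groups[groups == g].index)
            clin = cohort.clinical.loc[samples, clin_cols]
            for sp in top_species:
                dx = association.euclidean_clinical_distance(
                    props.loc[[sp], samples].T)
                for var in clin_cols:
                    dy = association.euclidean_clinical_distance(clin[[var]])
                    try:
                        res = association.mantel_test(
                            dx, dy, config.n_permutations,
                            seed=int(rng_m.integers(2**31)))
                    except ValueError:
                        continue
                    mantel_rows.append({"group": g, "species": sp, "variable": var,
                                        "r": res.r, "r_squared": res.r_squared,
                                        "p_value": res.p_value})
        mantel_df = pd.DataFrame(mantel_rows)
        mantel_df.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
        screens = {}
        for g in ("control", "dementia"):
            samples = list(groups[groups == g].index)
            scr = association.species_clinical_screen(
                props[samples].T, cohort.clinical.loc[samples, clin_cols],
                config.r2_threshold, keep_all=True)
            scr.insert(0, "group", g)
            screens[g] = scr
        screen_df = pd.concat(screens.values(), ignore_index=True)
        screen_df.to_csv(outdir / "ols_screen.tsv", sep="\t", index=False)
        roc_rows = []
        labels = groups.values
        for sp in top_species:
            x = props.loc[sp].to_numpy(float)
            span = x.max() - x.min()
            scaled = (x - x.min()) / span if span > 0 else x * 0
            res = association.roc_auc(scaled, labels, config.roc_cutoff_microbe)
            roc_rows.append({"feature": sp, "kind": "microbe", "auc": res.auc,
                             "cutoff": res.cutoff})
        ag = cohort.clinical.loc[list(groups.index), "AG"].to_numpy(float)
        span = ag.max() - ag.min()
        res = association.roc_auc((ag - ag.min()) / span, labels,
                                  config.roc_cutoff_clinical)
        roc_rows.append({"feature": "AG", "kind": "clinical", "auc": res.auc,
                         "cutoff": res.cutoff})
        pd.DataFrame(roc_rows).to_csv(outdir / "roc.tsv", sep="\t", index=False)
        n_ret = int(screen_df["retained"].sum()) if len(screen_df) else 0
        return {"n_mantel_pairs": len(mantel_df), "n_ols_retained": n_ret,
                "roc_auc": {r["feature"]: round(r["auc"], 4) for r in roc_rows}}

    def s_classifier():
        cohort = state["cohort"]
        clin_cols = [c for c in _CLINICAL_FEATURES if c in cohort.clinical.columns]
        features = cohort.clinical[clin_cols].copy()
        groups = state["filtered"].sample_group
        per_class = groups.value_counts() if groups is not None else pd.Series(dtype=int)
        if len(per_class) == 2 and per_class.min() >= 10:
            props = state["props"]
            features = features.loc[list(props.columns)].join(props.T)
        labels = cohort.clinical.loc[features.index, "group"]
        splits = classifier.prepare_features(features, labels,
                                             seed=stage_seeds["classifier"])
        model, metrics = classifier.train_mlp(splits, seed=stage_seeds["classifier"])
        contrib = classifier.feature_contributions(
            model, splits.X_test, splits.y_test, splits.feature_names,
            seed=stage_seeds["classifier"])
        contrib.to_csv(outdir / "feature_contributions.tsv", sep="\t",
                       header=["contribution_pct"])
        (outdir / "classifier_metrics.json").write_text(
            json.dumps(metrics, indent=1, sort_keys=True))
        return {"metrics": metrics, "top_feature": contrib.index[0]}

    def s_latent():
        cohort, props = state["cohort"], state["props"]
        samples = list(props.columns)
        data = props.T.join(cohort.clinical.loc[samples, ["age", "AG"]])
        data["dementia"] = (cohort.clinical.loc[samples, "group"] == "dementia").astype(int)
        if config.lv1_indicators and config.lv2_indicators:
            spec = lm.LatentModelSpec(list(config.lv1_indicators),
                                      list(config.lv2_indicators))
        else:
            spec = _auto_latent_spec(state["simper"])
        spec = lm.prune_indicators(data, spec, seed=stage_seeds["latent"])
        fit = lm.fit_two_factor_model(data, spec, seed=stage_seeds["latent"])
        scores = fit.factor_scores
        scores_out = scores.copy()
        scores_out["group"] = cohort.clinical.loc[samples, "group"].values
        scores_out.to_csv(outdir / "factor_scores.tsv", sep="\t")
        tests = lm.compare_factor_scores(scores, scores_out["group"])
        summary = {
            "loadings": {k: round(v, 4) for k, v in fit.loadings.items()},
            "structural": [round(v, 4) for v in fit.structural],
            "chi_square": round(fit.chi_square, 4), "df": fit.df,
            "gfi": round(fit.gfi, 4), "cfi": round(fit.cfi, 4),
            "converged": fit.converged,
            "score_tests": {lv: {"statistic": t.statistic, "p_value": t.p_value}
                            for lv, t in tests.items()},
        }
        (outdir / "latent_model.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        return summary

    stage("cohort", s_cohort)
    stage("table1", s_table1, "cohort")
    stage("otu", s_otu, "cohort")
    stage("diversity", s_diversity, "otu")
    stage("subgroup", s_subgroup, "otu")
    stage("networks", s_networks, "otu")
    stage("association", s_association, "diversity")
    stage("classifier", s_classifier, "otu")
    stage("latent", s_latent, "diversity")

    bundle.manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {k: v.get("status") for k, v in bundle.sections.items()},
    }
    manifest_path.write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
    (outdir / "report.json").write_text(
        json.dumps(bundle.sections, indent=1, sort_keys=True, default=str))
    return bundle
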