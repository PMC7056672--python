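"""End-to-end orchestration: simulate/read inputs, then filter, rarefy,
aggregate, diversity, differential abundance, network, correlation, and the
case classifier, with per-stage seeds fanned out from one global seed."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta_ordination, clinical_correlation, gdm_classifier, lefse_da
from . import preprocess_diversity as prep
from . import sparcc_network
from .io_formats import (
    OtuTable,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    read_tree,
    write_distance_matrix,
    write_metadata,
    write_otu_table,
    write_taxonomy,
    write_tree,
)
from .synthetic_cohort import CohortSimConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with the
    global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    simulate: CohortSimConfig | None = None
    otu_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    clinical_columns: list = field(default_factory=list)

    filter_min_fraction: float = 0.00005
    rarefaction_depth: int = 36000
    metrics: list = field(default_factory=lambda: list(beta_ordination.METRICS))
    permanova_permutations: int = 999
    lefse_p_cutoff: float = 0.05
    lefse_lda_cutoff: float = 2.0
    sparcc_n_iterations: int = 20
    sparcc_n_resamples: int = 20
    sparcc_n_bootstraps: int = 100
    network_rho_cutoff: float = 0.3
    network_p_cutoff: float = 0.05
    classifier_clinical_candidates: list = field(
        default_factory=lambda: ["FGB", "GGT", "BMI", "SBP", "DBP", "INS", "TG"]
    )
    classifier_max_features: int = 10
    classifier_min_prevalence: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("simulate"):
            d["simulate"] = CohortSimConfig.from_dict(d["simulate"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: repr(v) for k, v in sorted(self.__dict__.items())},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_lefse(results, path) -> None:
    df = pd.DataFrame([{
        "feature": r.feature_id, "kw_p": r.kw_p, "lda_score": r.lda_score,
        "enriched_group": r.enriched_group, "significant": r.significant,
    } for r in results])
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage, writing plain TSV/JSON per stage plus a manifest.

    Any stage failure aborts with the stage name; earlier outputs remain on
    disk for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}
    timings: dict[str, float] = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        log.info("stage %s done in %.2fs", name, timings[name])
        return result

    # --- inputs -----------------------------------------------------------
    def load_inputs():
        if config.simulate is not None:
            sim_cfg = config.simulate
            cohort = simulate_cohort(sim_cfg)
            inputs = out / "inputs"
            inputs.mkdir(exist_ok=True)
            write_otu_table(cohort.table, inputs / "otu.tsv")
            write_taxonomy(cohort.taxonomy, inputs / "taxonomy.tsv")
            write_metadata(cohort.metadata, inputs / "metadata.tsv")
            write_tree(cohort.tree, inputs / "tree.nwk")
            return cohort.table, cohort.taxonomy, cohort.metadata, cohort.tree
        table = read_otu_table(config.otu_path)
        taxonomy = read_taxonomy(config.taxonomy_path)
        metadata = read_metadata(config.metadata_path, config.clinical_columns)
        tree = read_tree(config.tree_path) if config.tree_path else None
        return table, taxonomy, metadata, tree

    table, taxonomy, metadata, tree = run_stage("inputs", load_inputs)

    # --- filter + rarefy + aggregate -------------------------------------
    def do_filter():
        filtered, removed = prep.filter_rare_otus(table, config.filter_min_fraction)
        (out / "filtered_features.txt").write_text("\n".join(removed) + "\n")
        return filtered

    filtered = run_stage("filter", do_filter)

    def do_rarefy():
        r = prep.rarefy(filtered, config.rarefaction_depth,
                        seed=stage_seed(config.seed, "rarefy"))
        write_otu_table(r, out / "rarefied.tsv")
        return r

    rarefied = run_stage("rarefy", do_rarefy)

    def do_aggregate():
        g = prep.aggregate_to_rank(rarefied, taxonomy, "genus")
        write_otu_table(g, out / "genus.tsv")
        return g

    genus = run_stage("aggregate", do_aggregate)

    disc_ids = [s for s in rarefied.sample_ids
                if s in set(metadata.samples_in_set("discovery"))]
    val_ids = [s for s in rarefied.sample_ids
               if s in set(metadata.samples_in_set("validation"))]
    disc_groups = metadata.groups_for(disc_ids)

    # --- alpha ------------------------------------------------------------
    def do_alpha():
        at = prep.alpha_table(rarefied)
        at.to_csv(out / "alpha.tsv", sep="\t")
        tests = prep.compare_alpha(at.loc[disc_ids], disc_groups)
        tests.to_csv(out / "alpha_tests.tsv", sep="\t")
        return at

    run_stage("alpha", do_alpha)

    # --- beta -------------------------------------------------------------
    def do_beta():
        disc_table = rarefied.select_samples(disc_ids)
        rows = []
        for metric in config.metrics:
            dm = beta_ordination.distance_matrix(
                disc_table, metric,
                tree=tree if "unifrac" in metric else None,
                weighted_normalized=True,
            )
            write_distance_matrix(dm, out / f"distance_{metric}.tsv")
            res = beta_ordination.pcoa(dm, k=2)
            pd.DataFrame(
                res.coordinates, index=res.sample_ids,
                columns=[f"PC{i + 1}" for i in range(res.coordinates.shape[1])],
            ).to_csv(out / f"pcoa_{metric}.tsv", sep="\t")
            perm = beta_ordination.permanova(
                dm, disc_groups, config.permanova_permutations,
                seed=stage_seed(config.seed, f"permanova_{metric}"),
            )
            rows.append({"metric": metric, "pseudo_F": perm.pseudo_f,
                         "p": perm.p, "R2": perm.r_squared,
                         "n_permutations": perm.n_permutations})
        pd.DataFrame(rows).to_csv(out / "permanova.tsv", sep="\t", index=False)

    run_stage("beta", do_beta)

    # --- LEfSe ------------------------------------------------------------
    def do_lefse():
        res = lefse_da.lefse(
            genus.select_samples(disc_ids), disc_groups,
            p_cutoff=config.lefse_p_cutoff, lda_cutoff=config.lefse_lda_cutoff,
            seed=stage_seed(config.seed, "lefse"),
        )
        _write_lefse(res, out / "lefse.tsv")
        return [r.feature_id for r in res if r.significant]

    differential = run_stage("lefse", do_lefse)

    # --- SparCC network on differential genera ---------------------------
    def do_sparcc():
        feats = differential
        if len(feats) < 4:
            (out / "network_edges.tsv").write_text(
                "source\ttarget\tweight\tsign\tp\n")
            manifest["stages"].setdefault("sparcc", {})
            return []
        sub = genus.select_samples(disc_ids).select_features(feats)
        corr = sparcc_network.sparcc_correlations(
            sub, n_iterations=config.sparcc_n_iterations,
            n_dirichlet_resamples=config.sparcc_n_resamples,
            seed=stage_seed(config.seed, "sparcc"),
        )
        withp = sparcc_network.sparcc_pvalues(
            sub, corr, n_bootstraps=config.sparcc_n_bootstraps,
            seed=stage_seed(config.seed, "sparcc_boot"),
        )
        pd.DataFrame(withp.corr, index=feats, columns=feats).to_csv(
            out / "sparcc_corr.tsv", sep="\t")
        pd.DataFrame(withp.pvals, index=feats, columns=feats).to_csv(
            out / "sparcc_pvals.tsv", sep="\t")
        edges = sparcc_network.build_network(
            withp, config.network_rho_cutoff, config.network_p_cutoff)
        pd.DataFrame([{
            "source": e.feature_a, "target": e.feature_b, "weight": e.rho,
            "sign": e.sign, "p": e.p,
        } for e in edges]).to_csv(out / "network_edges.tsv", sep="\t",
                                  index=False)
        return edges

    run_stage("sparcc", do_sparcc)

    # --- clinical correlation --------------------------------------------
    def do_correlate():
        feats = differential if differential else list(genus.feature_ids)
        disc_meta_ids = [s for s in disc_ids if s in metadata.sample_ids]
        sub = genus.select_samples(disc_meta_ids)
        grid = clinical_correlation.correlation_grid(sub, metadata, feats)
        grid.to_csv(out / "correlation_grid.tsv", sep="\t", index=False)

    run_stage("correlate", do_correlate)

    # --- classifier -------------------------------------------------------
    def do_classify():
        feats_frame = gdm_classifier.genus_feature_frame(
            genus, config.classifier_min_prevalence)
        clin = metadata.frame[list(metadata.clinical_columns)]
        Xall = feats_frame.join(clin)
        genus_cands = [c for c in feats_frame.columns]
        clin_cands = [c for c in config.classifier_clinical_candidates
                      if c in Xall.columns]
        Xd = Xall.loc[disc_ids].dropna(axis=1)
        yd = metadata.groups_for(disc_ids)
        results = {}
        if val_ids:
            Xv = Xall.loc[val_ids]
            yv = metadata.groups_for(val_ids)
            results = gdm_classifier.compare_models(
                Xd, yd, Xv, yv,
                [c for c in genus_cands if c in Xd.columns],
                [c for c in clin_cands if c in Xd.columns],
                max_features=config.classifier_max_features,
            )
        rows = []
        for name, r in results.items():
            rows.append({
                "pool": name,
                "n_features": len(r["model"].selected_features),
                "features": ",".join(r["model"].selected_features),
                "discovery_auc": r["discovery"].auc,
                "discovery_ci_low": r["discovery"].ci_low,
                "discovery_ci_high": r["discovery"].ci_high,
                "validation_auc": r["validation"].auc,
                "validation_ci_low": r["validation"].ci_low,
                "validation_ci_high": r["validation"].ci_high,
                "validation_accuracy": r["validation"].accuracy,
                "validation_sensitivity": r["validation"].sensitivity,
                "validation_specificity": r["validation"].specificity,
            })
            if name == "combined":
                r["model"].to_json(out / "model.json")
        pd.DataFrame(rows).to_csv(out / "classifier.tsv", sep="\t", index=False)

    run_stage("classify", do_classify)

    manifest["runtimes_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
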