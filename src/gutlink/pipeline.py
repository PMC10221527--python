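"""End-to-end orchestration: configuration, stage execution, manifests.

Stages run in order community -> metabolome QC -> association scans (per
location) -> variance explained -> cross-location sharing -> biomarker
panel. Every threshold is a named config field; a run manifest records
the config hash, package version and per-stage outputs so a rerun with
the same config and seed is byte-identical (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import ScanPolicy, run_association_scan, validate_with_spearman
from .biomarker import build_panel
from .community import alpha_diversity, bray_curtis, filter_taxa, rarefy
from .containers import MetaboFeatureMatrix, TaxaTable
from .crosslocation import shared_associations, venn_counts
from .metabolome import (drift_correct, missingness_filter, rsd_filter,
                         select_annotated)
from .simulate import ImplantedEffect, SimConfig, simulate_cohort
from .variance import variance_explained

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one serializable object."""

    out_dir: str = "gutlink_out"
    seed: int = 0
    # input paths (taxa per location; None -> simulate a demo cohort)
    taxa_paths: dict[str, str] | None = None
    metabolite_path: str | None = None
    annotation_path: str | None = None
    metadata_path: str | None = None
    # community stage
    rarefy_depth: int | None = 19_000
    min_mean_relabund: float = 0.0005
    min_prevalence: float = 0.05
    # metabolome stage
    max_test_missing: float = 0.80
    max_qc_missing: float = 0.50
    min_test_presence: float = 0.50
    max_qc_rsd: float = 0.30
    msi_levels: tuple[int, ...] = (1, 2)
    # association stage
    fdr: float = 0.05
    min_present: int = 10
    quant_only_prevalence: float = 0.95
    # variance stage
    cv_rounds: int = 100
    cv_test_frac: float = 0.10
    varexp_top_k: int = 5
    # biomarker stage
    vip_threshold: float = 1.0
    diff_p_threshold: float = 0.05
    group_size: int = 15

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "msi_levels" in raw:
            raw["msi_levels"] = tuple(raw["msi_levels"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


FIXTURE_CONFIG = SimConfig(
    n_samples=60, n_taxa=40, n_metabolites=30,
    # demo-scale cohort: effects strong enough to surface at n=60
    effect_table=[
        ImplantedEffect(taxon=0, metabolite=0, binary_effect=2.0, quant_effect=1.2),
        ImplantedEffect(taxon=1, metabolite=1, binary_effect=2.0, quant_effect=1.2),
        ImplantedEffect(taxon=2, metabolite=2, binary_effect=1.8, quant_effect=1.0,
                        locations=("cecum",)),
        ImplantedEffect(taxon=3, metabolite=3, binary_effect=1.8, quant_effect=1.0,
                        locations=("faeces",)),
        ImplantedEffect(taxon=4, metabolite=4, binary_effect=-1.8, quant_effect=-1.0,
                        locations=("ileum", "cecum")),
    ],
    fatness_effects={0: 1.2, 1: 1.2, 2: -1.2, 3: -1.2},
    drift_slope=0.002,
    emit_counts=True,
    seed=0,
)


def regenerate_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> Path:
    """Write the small demo cohort (60 pigs x 40 taxa x 30 features,
    3 locations, 5 implanted effects, 4 fatness markers) as TSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(FIXTURE_CONFIG, seed=seed)
    taxa, metab, meta, truth = simulate_cohort(cfg)
    for loc, table in taxa.items():
        table.to_tsv(out / f"taxa_{loc}.tsv", out / f"taxonomy_{loc}.tsv")
    metab.to_tsv(out / "metabolites.tsv", out / "annotation.tsv")
    meta.to_csv(out / "metadata.tsv", sep="\t", float_format="%.10g")
    (out / "truth.json").write_text(json.dumps(
        [dataclasses.asdict(e) for e in truth], indent=1))
    return out


def _load_inputs(config: PipelineConfig):
    if config.taxa_paths is None:
        log.info("no input paths configured; simulating the demo cohort")
        cfg = dataclasses.replace(FIXTURE_CONFIG, seed=config.seed)
        return simulate_cohort(cfg)[:3]
    taxa = {loc: TaxaTable.from_tsv(path, location=loc)
            for loc, path in config.taxa_paths.items()}
    metab = MetaboFeatureMatrix.from_tsv(config.metabolite_path,
                                         config.annotation_path)
    meta = pd.read_csv(config.metadata_path, sep="\t", index_col=0)
    return taxa, metab, meta


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__,
                      "config_hash": config.config_hash(),
                      "config": dataclasses.asdict(config),
                      "stages": {}}
    config.to_yaml(out / "config.yaml")

    try:
        taxa, metab, meta = _load_inputs(config)

        # ---- community stage --------------------------------------------
        stage: dict = {}
        filtered_taxa: dict[str, TaxaTable] = {}
        for loc, table in taxa.items():
            if config.rarefy_depth and table.is_count_table():
                totals = table.data.sum(axis=1)
                if (totals < config.rarefy_depth).any():
                    raise ValueError(
                        f"{loc}: rarefaction depth {config.rarefy_depth} exceeds the "
                        f"smallest sample total ({int(totals.min())}); lower "
                        "rarefy_depth or set it to null")
                table = rarefy(table, config.rarefy_depth, seed=config.seed)
            ft = filter_taxa(table, config.min_mean_relabund, config.min_prevalence)
            filtered_taxa[loc] = ft
            ft.to_tsv(out / f"taxa_filtered_{loc}.tsv")
            alpha_diversity(ft).to_csv(out / f"alpha_{loc}.tsv", sep="\t",
                                       float_format="%.10g")
            bray_curtis(ft).to_csv(out / f"braycurtis_{loc}.tsv", sep="\t",
                                   float_format="%.10g")
            stage[loc] = {"n_samples": ft.n_samples, "n_taxa": ft.n_taxa}
        manifest["stages"]["community"] = stage

        # ---- metabolome stage -------------------------------------------
        mm = missingness_filter(metab, config.max_test_missing,
                                config.max_qc_missing, config.min_test_presence)
        mm = drift_correct(mm)
        mm = rsd_filter(mm, config.max_qc_rsd)
        annotated = select_annotated(mm, set(config.msi_levels))
        mm.to_tsv(out / "metabolites_qc.tsv", out / "annotation_qc.tsv")
        manifest["stages"]["metabolome"] = {
            "n_features_in": len(metab.feature_ids),
            "n_features_qc": len(mm.feature_ids),
            "n_annotated": len(annotated.feature_ids)}
        scan_matrix = annotated if len(annotated.feature_ids) else mm

        # ---- association stage ------------------------------------------
        policy = ScanPolicy(min_present=config.min_present,
                            quant_only_prevalence=config.quant_only_prevalence)
        results: dict[str, pd.DataFrame] = {}
        stage = {}
        for loc, table in filtered_taxa.items():
            res = run_association_scan(table, scan_matrix, meta, policy=policy)
            res.to_csv(out / f"associations_{loc}.tsv", sep="\t", index=False,
                       float_format="%.10g")
            rep = validate_with_spearman(res, table, scan_matrix, meta,
                                         q_threshold=config.fdr)
            results[loc] = res
            frac = rep["replication_fraction"]
            stage[loc] = {"n_pairs": len(res),
                          "n_significant": int((res["q_value"] < config.fdr).sum()),
                          "spearman_replication": None if np.isnan(frac) else frac}
        manifest["stages"]["association"] = stage

        # ---- variance-explained stage -----------------------------------
        from .metabolome import transform_matrix
        stage = {}
        var_rows = []
        transformed = transform_matrix(scan_matrix.test_data())
        for loc, table in filtered_taxa.items():
            res = results[loc]
            sig = res[res["q_value"] < config.fdr]
            top = (sig.groupby("metabolite_id")["p_value"].min()
                   .nsmallest(config.varexp_top_k).index)
            for met_id in top:
                est = variance_explained(
                    transformed[met_id], table, meta,
                    n_rounds=config.cv_rounds, test_frac=config.cv_test_frac,
                    seed=config.seed, metabolite_id=met_id)
                var_rows.append({"metabolite_id": met_id, "location": loc,
                                 "r2_cv": est.r2_cv, "percent": est.percent,
                                 "n_rounds": est.n_rounds})
            stage[loc] = {"n_estimates": int(len(top))}
        pd.DataFrame(var_rows, columns=["metabolite_id", "location", "r2_cv",
                                        "percent", "n_rounds"]
                     ).to_csv(out / "variance_explained.tsv", sep="\t",
                              index=False, float_format="%.10g")
        manifest["stages"]["variance"] = stage

        # ---- cross-location stage ---------------------------------------
        if len(results) >= 2:
            report = shared_associations(results, q_threshold=config.fdr)
            report.summary().to_csv(out / "shared_associations.tsv", sep="\t",
                                    index=False)
            sig_sets = {loc: set(zip(df.loc[df["q_value"] < config.fdr, "taxon_id"],
                                     df.loc[df["q_value"] < config.fdr, "metabolite_id"]))
                        for loc, df in results.items()}
            (out / "venn_counts.json").write_text(
                json.dumps(venn_counts(sig_sets), indent=1, sort_keys=True))
            manifest["stages"]["crosslocation"] = {
                "per_location": report.per_location_counts,
                "three_way_shared": len(report.three_way())}

        # ---- biomarker stage --------------------------------------------
        if "fatness_group" in meta.columns:
            extremes = (meta.sort_values("backfat_score")
                        if "backfat_score" in meta.columns else meta)
            low = extremes.head(config.group_size).index
            high = extremes.tail(config.group_size).index
            sel = low.union(high)
            X = scan_matrix.test_data().loc[scan_matrix.test_data().index.intersection(sel)]
            yv = meta.loc[X.index, "fatness_group"]
            panel = build_panel(X, yv, vip_threshold=config.vip_threshold,
                                p_threshold=config.diff_p_threshold)
            panel.differential_table.to_csv(out / "differential_metabolites.tsv",
                                            sep="\t", float_format="%.10g")
            panel.roc.to_csv(out / "panel_roc.tsv", sep="\t", index=False,
                             float_format="%.10g")
            (out / "biomarker_panel.json").write_text(json.dumps(
                {"members": panel.members, "intercept": panel.intercept,
                 "coefficients": panel.coefficients,
                 "panel_auc": panel.panel_auc, "loo_auc": panel.loo_auc,
                 "single_aucs": panel.single_aucs,
                 "ridge_fallback": panel.ridge_fallback},
                indent=1, sort_keys=True))
            manifest["stages"]["biomarker"] = {
                "n_differential": int(panel.differential_table["differential"].sum()),
                "panel_size": len(panel.members),
                "panel_auc": panel.panel_auc}
        manifest["status"] = "complete"
    except Exception as exc:  # manifest records partial completion and cause
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True, default=str))
    return manifest
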