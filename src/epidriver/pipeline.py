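"""End-to-end orchestration: activities → OLS screen → IV stage → enrichment
→ phenotype → survival → network.

Every stage writes a TSV under the output directory and records its status
in ``manifest.json``. A rerun with the same config and seed reproduces all
tables byte-identically (the manifest additionally carries wall times and
versions, which are informational).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ConfigurationError, ValidationError
from .synthetic import (
    GeneratorConfig,
    generate_annotation,
    generate_cohort,
    generate_downstream_assets,
    generate_peak_files,
    standardize_columns,
)
from .peaks import (
    assign_target_genes,
    build_activity_matrix,
    intersect_peaks,
    loci_to_frame,
    read_peak_file,
)
from .ols import screen_candidates, candidates_to_frame
from .iv import run_iv_stage, results_to_frame
from .enrich import (
    GeneSetCollection,
    bin_genes_by_ceres,
    enrichment_to_frame,
    fisher_enrichment,
    hypergeom_enrichment,
    read_gmt,
)
from .phenotype import (
    class_level_summary,
    drug_assoc_to_frame,
    drug_response_assoc,
    pearson_by_cancer,
)
from .surv import km_estimate, km_to_frame, logrank, median_split, survival_at
from .network import graph_summary, hub_nodes, load_interactions, subgraph

logger = logging.getLogger(__name__)

ALL_STAGES = ("peaks", "screen", "iv", "enrichment", "phenotype", "survival", "network")


@dataclass
class PipelineConfig:
    """Run configuration: mode, stage toggles, and all analysis thresholds."""

    out_dir: str | Path = "results/pipeline"
    mode: str = "synthetic"                      # "synthetic" | "files"
    seed: int = 0
    generator: GeneratorConfig | None = None     # synthetic mode; defaults from seed
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    q_threshold: float = 0.1                     # FDR and FDRweak gates
    score_threshold: float = 700.0
    min_degree: int = 5
    min_avg_weight: float = 0.05
    ceres_bin_width: float = 0.4
    ceres_range: tuple[float, float] = (-2.0, 0.0)
    survival_horizon: float = 60.0               # months (5-year OS)
    promoter_window: int = 1000
    enhancer_window: int = 2000
    inputs: dict[str, str] = field(default_factory=dict)   # files mode paths

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for name in ("q_threshold", "score_threshold", "min_avg_weight", "ceres_bin_width",
                     "survival_horizon"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        if self.mode == "files":
            missing = [
                f"{key}={path}" for key, path in self.inputs.items() if not Path(path).exists()
            ]
            if missing:
                raise ConfigurationError(f"missing input paths: {', '.join(missing)}")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)


def validate_inputs(config: PipelineConfig) -> pd.DataFrame:
    """Structural pre-flight: all findings collected (never first-failure),
    each labeled fatal or warning."""
    findings: list[dict] = []

    def add(severity: str, message: str) -> None:
        findings.append({"severity": severity, "message": message})

    try:
        config.validate()
    except ConfigurationError as exc:
        add("fatal", str(exc))
        return pd.DataFrame(findings, columns=["severity", "message"])

    if config.mode == "synthetic":
        return pd.DataFrame(findings, columns=["severity", "message"])

    tables: dict[str, pd.DataFrame] = {}
    for key in ("mutation", "expression", "metadata"):
        path = config.inputs.get(key)
        if path is None:
            add("fatal", f"files mode requires an {key!r} input path")
        else:
            tables[key] = pd.read_csv(path, sep="\t", index_col=0)
    if {"mutation", "expression", "metadata"} <= set(tables):
        cells = set(tables["metadata"].index)
        for key in ("mutation", "expression"):
            missing = cells - set(tables[key].index)
            for cell in sorted(missing):
                add("fatal", f"{key} matrix missing cell line {cell}")
        bad_mut = tables["mutation"] if "mutation" in tables else None
        if bad_mut is not None and not bad_mut.isin([0, 1]).all().all():
            add("fatal", "mutation matrix has entries outside {0, 1}")
    inter_path = config.inputs.get("interactions")
    if inter_path:
        try:
            load_interactions(inter_path, config.score_threshold)
        except ValidationError as exc:
            add("fatal", f"interaction table: {exc}")
    return pd.DataFrame(findings, columns=["severity", "message"])


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    Raises ConfigurationError before touching the output directory when the
    config (or, in files mode, a fatal validation finding) is invalid. A
    stage failure is recorded in the manifest and re-raised after the
    manifest is flushed, so partial outputs survive.
    """
    report = validate_inputs(config)
    fatal = report[report["severity"] == "fatal"] if not report.empty else report
    if len(fatal):
        raise ConfigurationError("; ".join(fatal["message"]))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": {},
        "counts": {},
    }

    def finish(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        manifest["counts"].update(counts)

    def skip(stage: str) -> None:
        manifest["stages"][stage] = {"status": "skipped"}

    current_stage = "setup"
    try:
        # ---------------- data layer ----------------
        gen = config.generator or GeneratorConfig(seed=config.seed)
        if config.mode == "synthetic":
            cohort = generate_cohort(gen)
            annotation = generate_annotation(gen)
            assets = generate_downstream_assets(cohort, annotation)
            mutation, expression = cohort.mutation, cohort.expression
            cancer_type = cohort.cancer_type
            hm_ids = list(cohort.hm_activity.columns)
        else:
            cohort = None
            mutation = pd.read_csv(config.inputs["mutation"], sep="\t", index_col=0)
            expression = pd.read_csv(config.inputs["expression"], sep="\t", index_col=0)
            meta = pd.read_csv(config.inputs["metadata"], sep="\t", index_col=0)
            cancer_type = meta.iloc[:, 0]
            annotation = (
                pd.read_csv(config.inputs["annotation"], sep="\t")
                if "annotation" in config.inputs
                else pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"])
            )
            assets = None

        current_stage = "peaks"
        peak_sets: dict[tuple[str, str], object] = {}
        if config.enabled("peaks"):
            t0 = time.perf_counter()
            if config.mode == "synthetic":
                manifest_df = generate_peak_files(cohort, out / "peaks", annotation)
            else:
                manifest_df = pd.read_csv(config.inputs["peaks_manifest"], sep="\t")
            for rec in manifest_df.itertuples():
                ps = read_peak_file(
                    rec.path, rec.dialect, rec.sample_id, rec.factor_id, rec.factor_class
                )
                peak_sets[(rec.sample_id, rec.factor_id)] = ps
            activity = build_activity_matrix(peak_sets.values())
            tf_act = activity.by_class("TF")
            hm_act = activity.by_class("HM")
            activity.values.to_csv(out / "activity_matrix.tsv", sep="\t", float_format="%.10g")
            finish("peaks", t0, n_peak_files=len(manifest_df))
        else:
            skip("peaks")
            if config.mode == "files":
                raise ConfigurationError("files mode requires the peaks stage")
            tf_act = standardize_columns(cohort.tf_activity)
            hm_act = standardize_columns(cohort.hm_activity)
        if config.mode == "synthetic":
            hm_ids = list(hm_act.columns)

        # ---------------- screen ----------------
        current_stage = "screen"
        candidates = []
        if config.enabled("screen"):
            t0 = time.perf_counter()
            candidates = screen_candidates(
                tf_act, hm_act, expression, cancer_type, q_threshold=config.q_threshold
            )
            _write(candidates_to_frame(candidates), out / "candidates.tsv")
            finish(
                "screen", t0,
                n_pairs_tested=len(candidates),
                n_candidates=sum(c.selected for c in candidates),
            )
        else:
            skip("screen")

        # ---------------- IV ----------------
        current_stage = "iv"
        drivers: list = []
        if config.enabled("iv") and candidates:
            t0 = time.perf_counter()
            selected = [c for c in candidates if c.selected]
            results = run_iv_stage(
                selected, tf_act, hm_act, mutation, expression, cancer_type, q=config.q_threshold
            )
            _write(results_to_frame(results), out / "drivers.tsv")
            drivers = [r for r in results if r.driver]
            finish("iv", t0, n_iv_tested=len(results), n_drivers=len(drivers))
        else:
            skip("iv")

        # ---------------- target genes for driver pairs ----------------
        target_genes: dict[tuple[str, str], set[str]] = {}
        pair_loci: dict[tuple[str, str], pd.DataFrame] = {}
        if drivers and peak_sets and not annotation.empty:
            cells = sorted({s for s, _f in peak_sets})
            for r in drivers:
                loci = []
                for cell in cells:
                    tf_ps = peak_sets.get((cell, r.tf_id))
                    hm_ps = peak_sets.get((cell, r.hm_id))
                    if tf_ps is None or hm_ps is None:
                        continue
                    loci.extend(intersect_peaks(tf_ps, hm_ps))
                pair_loci[(r.tf_id, r.hm_id)] = loci_to_frame(loci)
                target_genes[(r.tf_id, r.hm_id)] = assign_target_genes(
                    loci, annotation, r.hm_id, config.promoter_window, config.enhancer_window
                )
        elif drivers and config.mode == "synthetic" and assets is not None:
            target_genes = {
                k: set(v)
                for k, v in assets.truth["pair_target_genes"].items()
                if k in {(r.tf_id, r.hm_id) for r in drivers}
            }
        all_targets = sorted(set().union(*target_genes.values())) if target_genes else []

        # ---------------- enrichment ----------------
        current_stage = "enrichment"
        if config.enabled("enrichment") and target_genes:
            t0 = time.perf_counter()
            if config.mode == "synthetic":
                ceres = assets.ceres
                collection = GeneSetCollection(assets.gene_sets, assets.gene_universe)
            else:
                ceres = pd.read_csv(config.inputs["ceres"], sep="\t", index_col=0)
                collection = read_gmt(config.inputs["gene_sets"])
            lo, hi = config.ceres_range
            bins = bin_genes_by_ceres(ceres, config.ceres_bin_width, lo, hi)
            universe = set(ceres.index)
            bin_rows, path_rows = [], []
            for (tf, hm), genes in sorted(target_genes.items()):
                tset = genes & universe
                if tset:
                    for label, members in bins.items():
                        row = fisher_enrichment(tset, members & universe, universe)
                        row.name = label
                        rec = enrichment_to_frame([row]).iloc[0].to_dict()
                        rec.update(tf=tf, hm=hm)
                        bin_rows.append(rec)
                in_universe = genes & collection.universe
                if in_universe:
                    for row in hypergeom_enrichment(in_universe, collection):
                        rec = enrichment_to_frame([row]).iloc[0].to_dict()
                        rec.update(tf=tf, hm=hm)
                        path_rows.append(rec)
            _write(pd.DataFrame(bin_rows), out / "enrichment_ceres_bins.tsv")
            _write(pd.DataFrame(path_rows), out / "enrichment_pathways.tsv")
            finish("enrichment", t0, n_target_genes=len(all_targets))
        else:
            skip("enrichment")

        # ---------------- phenotype ----------------
        current_stage = "phenotype"
        if config.enabled("phenotype") and drivers:
            t0 = time.perf_counter()
            corr_rows = []
            for (tf, hm), loci_df in sorted(pair_loci.items()):
                if loci_df.empty:
                    continue
                per_cancer = pearson_by_cancer(loci_df, cancer_type)
                per_cancer.insert(0, "hm", hm)
                per_cancer.insert(0, "tf", tf)
                corr_rows.append(per_cancer)
            if corr_rows:
                _write(pd.concat(corr_rows, ignore_index=True), out / "pearson_by_cancer.tsv")
            if config.mode == "synthetic" and all_targets:
                mean_expr = assets.gene_expression[all_targets].mean(axis=1)
                rows = drug_response_assoc(assets.ic50, mean_expr, cancer_type, assets.drug_class)
                _write(drug_assoc_to_frame(rows), out / "drug_assoc.tsv")
                _write(class_level_summary(rows), out / "drug_class_summary.tsv")
                finish("phenotype", t0, n_drugs_tested=len(rows))
            elif config.mode == "files" and "ic50" in config.inputs and all_targets:
                ic50 = pd.read_csv(config.inputs["ic50"], sep="\t", index_col=0)
                gene_expr = pd.read_csv(config.inputs["gene_expression"], sep="\t", index_col=0)
                classes = (
                    pd.read_csv(config.inputs["drug_classes"], sep="\t", index_col=0).iloc[:, 0]
                    if "drug_classes" in config.inputs
                    else None
                )
                usable = [g for g in all_targets if g in gene_expr.columns]
                mean_expr = gene_expr[usable].mean(axis=1)
                rows = drug_response_assoc(ic50, mean_expr, cancer_type, classes)
                _write(drug_assoc_to_frame(rows), out / "drug_assoc.tsv")
                _write(class_level_summary(rows), out / "drug_class_summary.tsv")
                finish("phenotype", t0, n_drugs_tested=len(rows))
            else:
                finish("phenotype", t0, n_drugs_tested=0)
        else:
            skip("phenotype")

        # ---------------- survival ----------------
        current_stage = "survival"
        if config.enabled("survival"):
            surv_table = None
            if config.mode == "synthetic":
                surv_table = assets.survival
            elif "survival" in config.inputs:
                surv_table = pd.read_csv(config.inputs["survival"], sep="\t")
            if surv_table is not None:
                t0 = time.perf_counter()
                curves, tests = [], []
                for group_col, split in (
                    ("mutation_group", None),
                    ("expression_group", "expression_score"),
                ):
                    tbl = surv_table.copy()
                    if split is not None:
                        if split not in tbl.columns:
                            continue
                        tbl[group_col] = median_split(tbl[split])
                    if group_col not in tbl.columns or tbl[group_col].nunique() != 2:
                        continue
                    chi2, p = logrank(tbl, group_col)
                    for label, grp in tbl.groupby(group_col):
                        curve = km_estimate(grp)
                        cf = km_to_frame(curve)
                        cf.insert(0, "group", f"{group_col}:{label}")
                        curves.append(cf)
                        est, (lo, hi), extrap = survival_at(curve, config.survival_horizon)
                        tests.append(
                            {
                                "comparison": group_col,
                                "group": label,
                                "n": len(grp),
                                "logrank_chi2": chi2,
                                "logrank_p": p,
                                "horizon_months": config.survival_horizon,
                                "os_at_horizon": est,
                                "os_ci_lower": lo,
                                "os_ci_upper": hi,
                                "extrapolated": extrap,
                            }
                        )
                _write(pd.concat(curves, ignore_index=True), out / "survival_curves.tsv")
                _write(pd.DataFrame(tests), out / "survival_tests.tsv")
                finish("survival", t0, n_patients=len(surv_table))
            else:
                skip("survival")
        else:
            skip("survival")

        # ---------------- network ----------------
        current_stage = "network"
        if config.enabled("network"):
            inter = None
            if config.mode == "synthetic":
                inter = assets.interactions
            elif "interactions" in config.inputs:
                inter = config.inputs["interactions"]
            if inter is not None:
                t0 = time.perf_counter()
                graph = load_interactions(inter, config.score_threshold)
                target_graph = subgraph(graph, set(all_targets)) if all_targets else graph
                hubs = hub_nodes(target_graph, config.min_degree)
                summary = graph_summary(target_graph, config.min_degree, config.min_avg_weight)
                _write(
                    pd.DataFrame(
                        {"hub": hubs, "degree": [target_graph.degree[h] for h in hubs]}
                    ),
                    out / "network_hubs.tsv",
                )
                edge_rows = [
                    {"protein1": u, "protein2": v, "weight": d["weight"]}
                    for u, v, d in sorted(target_graph.edges(data=True))
                ]
                _write(
                    pd.DataFrame(edge_rows, columns=["protein1", "protein2", "weight"]),
                    out / "network_edges.tsv",
                )
                manifest["counts"]["network"] = {
                    k: v for k, v in summary.items() if k != "hubs"
                }
                finish("network", t0)
            else:
                skip("network")
        else:
            skip("network")

    except ConfigurationError:
        raise
    except Exception as exc:
        manifest["stages"][current_stage] = {"status": "failed", "error": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
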