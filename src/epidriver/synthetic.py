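"""Synthetic cohorts with a known mutation → TF activity → histone-mark causal chain.

The generator encodes the structural causal model the analysis assumes:

    TF_ij  = a1·Mut_ij + a2·E_ij + γ·U_p + c_tf(type_i, j) + ε_tf
    HM_ik  = Σ_p β1_p·TF_i,tf(p) + δ·U_p + c_hm(type_i, k) + ε_hm

where ``Mut`` is binary mutation status (the instrument), ``E`` is TF
expression, ``U_p`` is a latent standard-normal confounder private to each
planted (TF, HM) pair, and the cancer-type effects ``c`` are random
intercepts. Ordinary least squares of HM on TF is therefore biased by
``γδ/Var(TF ⟂ controls)`` for planted pairs, while two-stage least squares
through ``Mut`` remains consistent — the property every downstream test
exploits. Unplanted pairs carry no confounder and no effect: they are true
nulls.

All randomness flows from ``numpy.random.SeedSequence([seed, stream])`` with
fixed stream ids (0 cohort, 1 annotation, 2 peak placement, 3 downstream
assets), so a config + seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

#: The seven histone marks the analysis screens; cohort HM columns are the
#: first ``n_hms`` of these.
HISTONE_MARKS = (
    "H3K4me3",
    "H3K4me1",
    "H3K27ac",
    "H3K36me3",
    "H3K79me2",
    "H3K9ac",
    "H4K20me1",
)

#: Toy genome used for emitted peak files: chrom name -> length (bp).
TOY_GENOME = {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}

_TF_PEAK_HALF = 150      # TF narrow peaks are 300 bp
_HM_PEAK_HALF = 500      # HM broad peaks are 1 kb


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Defaults describe a deliberately small pan-cancer cohort: 60 cell lines
    across 3 cancer types, 12 TFs × 3 marks (36 tested pairs), two planted
    causal pairs with effect 1.5 on the activity scale, a strong binary
    instrument (mutation probability 0.3, first-stage effect 2.0) and unit
    confounding on both arms.
    """

    n_cell_lines: int = 60
    n_cancer_types: int = 3
    n_tfs: int = 12
    n_hms: int = 3
    planted_pairs: tuple[tuple[int, int, float], ...] = ((0, 0, 1.5), (1, 1, 1.5))
    mutation_prob: float = 0.3
    instrument_strength: float = 2.0    # a1: mutation -> TF activity
    confounder_tf: float = 1.2          # gamma: U -> TF activity
    confounder_hm: float = 0.7          # delta: U -> HM activity
    expression_effect: float = 0.5      # a2: expression -> TF activity
    cancer_effect_sd: float = 0.5
    noise_sd_tf: float = 1.0
    noise_sd_hm: float = 0.7
    n_loci_per_pair: int = 30
    n_background_peaks: int = 30
    n_genes: int = 400
    n_target_genes: int = 60
    n_drugs: int = 30
    n_planted_drugs: int = 10
    drug_coupling: float = 1.0
    n_patients: int = 300
    hazard_ratio: float = 2.0
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "n_cancer_types": self.n_cancer_types,
            "n_tfs": self.n_tfs,
            "n_hms": self.n_hms,
            "n_genes": self.n_genes,
            "n_drugs": self.n_drugs,
            "n_patients": self.n_patients,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if not 0.0 < self.mutation_prob < 1.0:
            raise ConfigurationError("mutation_prob must lie in (0, 1)")
        if self.noise_sd_tf <= 0 or self.noise_sd_hm <= 0:
            raise ConfigurationError("noise standard deviations must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1)")
        if self.n_hms > len(HISTONE_MARKS):
            raise ConfigurationError(f"at most {len(HISTONE_MARKS)} histone marks supported")
        if self.n_target_genes > self.n_genes:
            raise ConfigurationError("n_target_genes cannot exceed n_genes")
        for tf_i, hm_i, _beta in self.planted_pairs:
            if not (0 <= tf_i < self.n_tfs and 0 <= hm_i < self.n_hms):
                raise ConfigurationError(f"planted pair ({tf_i}, {hm_i}) out of range")

    # -- derived labels ---------------------------------------------------
    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i:03d}" for i in range(self.n_cell_lines)]

    @property
    def tfs(self) -> list[str]:
        return [f"TF{j:02d}" for j in range(self.n_tfs)]

    @property
    def hms(self) -> list[str]:
        return list(HISTONE_MARKS[: self.n_hms])

    @property
    def cancer_types(self) -> list[str]:
        return [f"cancer_{t}" for t in range(self.n_cancer_types)]


@dataclass
class CohortTruth:
    """Ground truth recorded alongside a cohort: enough to recompute the
    expected OLS bias and to verify instrument validity directly."""

    config: GeneratorConfig
    confounders: pd.DataFrame          # cell line × planted pair, realized U
    cancer_effects_tf: pd.DataFrame    # cancer type × TF
    cancer_effects_hm: pd.DataFrame    # cancer type × HM
    noise_tf: pd.DataFrame
    noise_hm: pd.DataFrame


@dataclass
class SyntheticCohort:
    """Generated cohort: activity, mutation and expression matrices sharing
    one cell-line index, plus the ground-truth record."""

    tf_activity: pd.DataFrame
    hm_activity: pd.DataFrame
    mutation: pd.DataFrame
    expression: pd.DataFrame
    cancer_type: pd.Series
    truth: CohortTruth

    @property
    def config(self) -> GeneratorConfig:
        return self.truth.config


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def expected_ols_bias(config: GeneratorConfig, pair_index: int = 0) -> float:
    """Expected asymptotic bias of the OLS HM~TF slope for a planted pair.

    The screen regression controls expression and cancer type, so the
    relevant exposure variance is the part orthogonal to those controls:
    Var(TF⊥) = a1²·p(1−p) + γ²·m + σ_tf², with m the number of planted pairs
    sharing the TF. The bias is then γδ·Var(U)/Var(TF⊥) with Var(U)=1.
    """
    tf_i = config.planted_pairs[pair_index][0]
    m = sum(1 for (t, _h, _b) in config.planted_pairs if t == tf_i)
    p = config.mutation_prob
    var_perp = (
        config.instrument_strength**2 * p * (1 - p)
        + config.confounder_tf**2 * m
        + config.noise_sd_tf**2
    )
    return config.confounder_tf * config.confounder_hm * m / var_perp


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort from the structural model. Deterministic in (config, seed)."""
    rng = _rng(config.seed, 0)
    n, n_tfs, n_hms = config.n_cell_lines, config.n_tfs, config.n_hms
    pairs = config.planted_pairs

    # Draw order is fixed; adding draws must append, never reorder.
    cancer_idx = rng.integers(0, config.n_cancer_types, size=n)
    mutation = rng.binomial(1, config.mutation_prob, size=(n, n_tfs))
    expression = rng.standard_normal((n, n_tfs))
    c_tf = rng.normal(0.0, config.cancer_effect_sd, size=(config.n_cancer_types, n_tfs))
    c_hm = rng.normal(0.0, config.cancer_effect_sd, size=(config.n_cancer_types, n_hms))
    confounders = rng.standard_normal((n, len(pairs))) if pairs else np.zeros((n, 0))
    noise_tf = rng.normal(0.0, config.noise_sd_tf, size=(n, n_tfs))
    noise_hm = rng.normal(0.0, config.noise_sd_hm, size=(n, n_hms))

    tf_act = (
        config.instrument_strength * mutation
        + config.expression_effect * expression
        + c_tf[cancer_idx, :]
        + noise_tf
    )
    for p_idx, (tf_i, _hm_i, _beta) in enumerate(pairs):
        tf_act[:, tf_i] += config.confounder_tf * confounders[:, p_idx]

    hm_act = c_hm[cancer_idx, :] + noise_hm
    for p_idx, (tf_i, hm_i, beta1) in enumerate(pairs):
        hm_act[:, hm_i] += beta1 * tf_act[:, tf_i]
        hm_act[:, hm_i] += config.confounder_hm * confounders[:, p_idx]

    cells, tfs, hms = config.cell_lines, config.tfs, config.hms
    truth = CohortTruth(
        config=config,
        confounders=pd.DataFrame(
            confounders, index=cells, columns=[f"pair_{i}" for i in range(len(pairs))]
        ),
        cancer_effects_tf=pd.DataFrame(c_tf, index=config.cancer_types, columns=tfs),
        cancer_effects_hm=pd.DataFrame(c_hm, index=config.cancer_types, columns=hms),
        noise_tf=pd.DataFrame(noise_tf, index=cells, columns=tfs),
        noise_hm=pd.DataFrame(noise_hm, index=cells, columns=hms),
    )
    return SyntheticCohort(
        tf_activity=pd.DataFrame(tf_act, index=cells, columns=tfs),
        hm_activity=pd.DataFrame(hm_act, index=cells, columns=hms),
        mutation=pd.DataFrame(mutation, index=cells, columns=tfs),
        expression=pd.DataFrame(expression, index=cells, columns=tfs),
        cancer_type=pd.Series(
            [config.cancer_types[t] for t in cancer_idx], index=cells, name="cancer_type"
        ),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Gene annotation and peak files
# ---------------------------------------------------------------------------

def generate_annotation(config: GeneratorConfig) -> pd.DataFrame:
    """Toy gene annotation: (gene_id, chrom, tss, strand) on the toy genome.

    The first ``n_target_genes`` genes are the designated targets whose TSSs
    anchor the planted co-bound loci.
    """
    rng = _rng(config.seed, 1)
    chrom_names = list(TOY_GENOME)
    chroms = rng.integers(0, len(chrom_names), size=config.n_genes)
    margin = 2 * _HM_PEAK_HALF + 100
    tss = np.array(
        [rng.integers(margin, TOY_GENOME[chrom_names[c]] - margin) for c in chroms]
    )
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(config.n_genes)],
            "chrom": [chrom_names[c] for c in chroms],
            "tss": tss,
            "strand": strand,
        }
    )


def pair_target_genes(config: GeneratorConfig, annotation: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Round-robin split of designated target genes among planted pairs.

    Each planted pair receives up to ``n_loci_per_pair`` genes; planted peak
    files place a co-bound locus over each such gene's TSS.
    """
    targets = list(annotation["gene_id"].iloc[: config.n_target_genes])
    out: dict[tuple[str, str], list[str]] = {}
    n_pairs = max(len(config.planted_pairs), 1)
    for p_idx, (tf_i, hm_i, _beta) in enumerate(config.planted_pairs):
        share = targets[p_idx::n_pairs][: config.n_loci_per_pair]
        out[(config.tfs[tf_i], config.hms[hm_i])] = share
    return out


def _signal_targets(activity: pd.DataFrame) -> pd.DataFrame:
    # Per-factor positive affine shift: preserves the z-score (build_activity_matrix
    # standardizes per factor) while keeping log2(1+signal) strictly positive.
    return activity - activity.min(axis=0) + 1.0


def generate_peak_files(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Emit one narrowPeak file per (cell line, TF) and one broadPeak file per
    (cell line, HM), with per-file constant signal chosen so that the mean
    log2(1+signal) score round-trips to the cohort's (standardized) activity.

    Returns a manifest DataFrame (sample_id, factor_id, factor_class,
    dialect, n_peaks, path).
    """
    config = cohort.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if annotation is None:
        annotation = generate_annotation(config)
    anno_ix = annotation.set_index("gene_id")
    ptg = pair_target_genes(config, annotation)

    rng = _rng(config.seed, 2)
    chrom_names = list(TOY_GENOME)

    # Background peak placement is shared across cell lines per factor so that
    # only signals (not coordinates) differ between cell lines of one factor.
    def background(half_width: int) -> list[tuple[str, int, int]]:
        out = []
        for _ in range(config.n_background_peaks):
            c = chrom_names[rng.integers(0, len(chrom_names))]
            center = int(rng.integers(half_width + 1, TOY_GENOME[c] - half_width - 1))
            out.append((c, center - half_width, center + half_width))
        return out

    tf_bg = {tf: background(_TF_PEAK_HALF) for tf in config.tfs}
    hm_bg = {hm: background(_HM_PEAK_HALF) for hm in config.hms}

    planted_tf: dict[str, list[tuple[str, int, int]]] = {tf: [] for tf in config.tfs}
    planted_hm: dict[str, list[tuple[str, int, int]]] = {hm: [] for hm in config.hms}
    for (tf, hm), genes in ptg.items():
        for g in genes:
            row = anno_ix.loc[g]
            c, t = row["chrom"], int(row["tss"])
            planted_tf[tf].append((c, t - _TF_PEAK_HALF, t + _TF_PEAK_HALF))
            planted_hm[hm].append((c, t - _HM_PEAK_HALF, t + _HM_PEAK_HALF))

    tf_targets = _signal_targets(cohort.tf_activity)
    hm_targets = _signal_targets(cohort.hm_activity)

    records = []
    for factor_class, factors, planted, bg, targets, dialect in (
        ("TF", config.tfs, planted_tf, tf_bg, tf_targets, "narrowPeak"),
        ("HM", config.hms, planted_hm, hm_bg, hm_targets, "broadPeak"),
    ):
        for cell in config.cell_lines:
            for factor in factors:
                intervals = sorted(set(planted[factor] + bg[factor]))
                t = float(targets.loc[cell, factor])
                signal = 2.0**t - 1.0
                path = out_dir / f"{cell}__{factor}.{dialect}"
                with open(path, "w") as fh:
                    for i, (c, s, e) in enumerate(intervals):
                        base = (
                            f"{c}\t{s}\t{e}\t{cell}_{factor}_{i}\t0\t.\t"
                            f"{signal:.12f}\t-1\t-1"
                        )
                        if dialect == "narrowPeak":
                            base += f"\t{(e - s) // 2}"
                        fh.write(base + "\n")
                records.append(
                    {
                        "sample_id": cell,
                        "factor_id": factor,
                        "factor_class": factor_class,
                        "dialect": dialect,
                        "n_peaks": len(intervals),
                        "path": str(path),
                    }
                )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Downstream assets: CERES, gene sets, expression, IC50, survival, interactions
# ---------------------------------------------------------------------------

@dataclass
class AssetBundle:
    """Everything the post-IV characterization stages consume, plus truth."""

    annotation: pd.DataFrame
    ceres: pd.DataFrame               # gene × cell line
    gene_sets: dict[str, set[str]]
    gene_universe: set[str]
    gene_expression: pd.DataFrame     # cell line × gene (log scale)
    ic50: pd.DataFrame                # drug × cell line
    drug_class: pd.Series             # drug -> pathway label
    survival: pd.DataFrame            # patient_id, time, event, mutation_group, expression_score, cancer_type
    interactions: pd.DataFrame        # protein1, protein2, combined_score
    truth: dict = field(default_factory=dict)


def generate_downstream_assets(
    cohort: SyntheticCohort, annotation: pd.DataFrame | None = None
) -> AssetBundle:
    """Generate CERES scores, GMT gene sets, gene expression, IC50s, a
    survival table and an interaction graph consistent with the cohort.

    Planted structure: the designated target genes form a dependency block
    (CERES centered at −1); one gene set is enriched in them; one drug class
    has IC50 linearly coupled (slope ``drug_coupling``) to the mean
    target-gene expression; survival hazard is ``hazard_ratio``-fold higher
    for carriers of the first planted TF's mutation; the interaction table
    contains one hub of degree ≥ 6 above score 700.
    """
    config = cohort.config
    if annotation is None:
        annotation = generate_annotation(config)
    rng = _rng(config.seed, 3)
    genes = list(annotation["gene_id"])
    targets = genes[: config.n_target_genes]
    cells = config.cell_lines

    # CERES: dependency block centered below zero.
    gene_center = rng.normal(0.05, 0.15, size=config.n_genes)
    gene_center[: config.n_target_genes] = rng.normal(-1.0, 0.25, size=config.n_target_genes)
    ceres = pd.DataFrame(
        gene_center[:, None] + rng.normal(0.0, 0.1, size=(config.n_genes, len(cells))),
        index=genes,
        columns=cells,
    )

    # Gene sets: one planted (mostly target genes), nine decoys.
    planted_members = set(rng.choice(targets, size=min(30, len(targets)), replace=False))
    planted_members |= set(rng.choice(genes, size=min(5, len(genes)), replace=False))
    gene_sets: dict[str, set[str]] = {"PLANTED_TARGETS": planted_members}
    decoy_size = min(40, max(2, config.n_genes // 4))
    for s in range(9):
        gene_sets[f"DECOY_SET_{s}"] = set(rng.choice(genes, size=decoy_size, replace=False))

    # Gene expression: target genes load on their pair's TF activity.
    expr = rng.standard_normal((len(cells), config.n_genes))
    ptg = pair_target_genes(config, annotation)
    tf_z = (cohort.tf_activity - cohort.tf_activity.mean()) / cohort.tf_activity.std(ddof=1)
    load = 0.7
    gene_pos = {g: i for i, g in enumerate(genes)}
    for (tf, _hm), share in ptg.items():
        for g in share:
            expr[:, gene_pos[g]] = (
                load * tf_z[tf].to_numpy()
                + math.sqrt(1 - load**2) * expr[:, gene_pos[g]]
            )
    gene_expression = pd.DataFrame(expr, index=cells, columns=genes)

    # IC50: planted drug class coupled to mean target-gene expression.
    mean_target_expr = gene_expression[targets].mean(axis=1)
    drugs = [f"D{d:03d}" for d in range(config.n_drugs)]
    ic50 = pd.DataFrame(
        rng.normal(1.0, 0.5, size=(config.n_drugs, len(cells))), index=drugs, columns=cells
    )
    n_planted = min(config.n_planted_drugs, config.n_drugs)
    for d in range(n_planted):
        ic50.iloc[d] = (
            1.0
            + config.drug_coupling * mean_target_expr.to_numpy()
            + rng.normal(0.0, 0.5, size=len(cells))
        )
    classes = ["PLANTED_PATHWAY"] * n_planted + [
        f"OTHER_PATHWAY_{d % 3}" for d in range(config.n_drugs - n_planted)
    ]
    drug_class = pd.Series(classes, index=drugs, name="pathway")

    # Survival: exponential times, hazard ratio on mutation of the first
    # planted TF (or TF00 when nothing is planted); censored subjects get a
    # Uniform(0, T) observation time.
    surv_tf = config.tfs[config.planted_pairs[0][0]] if config.planted_pairs else config.tfs[0]
    mut = rng.binomial(1, config.mutation_prob, size=config.n_patients)
    base_scale = 60.0 / math.log(2)  # baseline median survival 60 months
    times = rng.exponential(base_scale / np.where(mut == 1, config.hazard_ratio, 1.0))
    censored = rng.random(config.n_patients) < config.censoring_rate
    observed = np.where(censored, rng.random(config.n_patients) * times, times)
    expr_score = -0.5 * mut + rng.standard_normal(config.n_patients)
    survival = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(config.n_patients)],
            "time": observed,
            "event": (~censored).astype(int),
            "mutation_group": np.where(mut == 1, "mutated", "wild"),
            "expression_score": expr_score,
            "cancer_type": [
                config.cancer_types[t]
                for t in rng.integers(0, config.n_cancer_types, size=config.n_patients)
            ],
        }
    )

    # Interactions: planted hub = first target gene, six strong spokes.
    hub = targets[0]
    edges: dict[tuple[str, str], int] = {}
    for g in targets[1:7]:
        edges[tuple(sorted((hub, g)))] = int(rng.integers(850, 1000))
    n_random = 3 * len(targets)
    for _ in range(n_random):
        a, b = rng.choice(targets, size=2, replace=False)
        key = tuple(sorted((a, b)))
        if key not in edges:
            edges[key] = int(rng.integers(150, 990))
    interactions = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["protein1", "protein2", "combined_score"],
    )

    return AssetBundle(
        annotation=annotation,
        ceres=ceres,
        gene_sets=gene_sets,
        gene_universe=set(genes),
        gene_expression=gene_expression,
        ic50=ic50,
        drug_class=drug_class,
        survival=survival,
        interactions=interactions,
        truth={
            "planted_set": "PLANTED_TARGETS",
            "planted_drug_class": "PLANTED_PATHWAY",
            "drug_coupling": config.drug_coupling,
            "planted_hub": hub,
            "hazard_ratio": config.hazard_ratio,
            "survival_tf": surv_tf,
            "pair_target_genes": ptg,
            "target_genes": targets,
        },
    )


def standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores with sample sd (ddof=1); constant columns map to 0."""
    sd = df.std(ddof=1).replace(0.0, np.nan)
    out = (df - df.mean()) / sd
    return out.fillna(0.0)
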