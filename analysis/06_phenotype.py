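"""Per-cancer co-binding correlations and drug-response associations.

For each driver pair, pools its co-bound locus signals within each cancer
type and reports Pearson r / r²; then regresses each drug's IC50 on the
standardized mean expression of the pooled target genes (plus cancer-type
dummies) and summarizes per drug class.
"""

import json
from pathlib import Path

import pandas as pd

from epidriver.phenotype import (
    class_level_summary,
    drug_assoc_to_frame,
    drug_response_assoc,
    pearson_by_cancer,
)

OUT = Path("results/analysis")


def main() -> None:
    cancer = pd.read_csv(OUT / "metadata.tsv", sep="\t", index_col=0)["cancer_type"]
    targets = json.loads((OUT / "target_genes.json").read_text())

    corr_frames = []
    for pair, _genes in sorted(targets.items()):
        tf, hm = pair.split(":")
        loci = pd.read_csv(OUT / f"loci_{tf}_{hm}.tsv", sep="\t")
        if loci.empty:
            continue
        per_cancer = pearson_by_cancer(loci, cancer)
        per_cancer.insert(0, "hm", hm)
        per_cancer.insert(0, "tf", tf)
        corr_frames.append(per_cancer)
    corr = pd.concat(corr_frames, ignore_index=True)
    corr.to_csv(OUT / "pearson_by_cancer.tsv", sep="\t", index=False, float_format="%.10g")

    gene_expr = pd.read_csv(OUT / "gene_expression.tsv", sep="\t", index_col=0)
    ic50 = pd.read_csv(OUT / "ic50.tsv", sep="\t", index_col=0)
    classes = pd.read_csv(OUT / "drug_classes.tsv", sep="\t", index_col=0)["pathway"]
    all_targets = sorted({g for genes in targets.values() for g in genes if g in gene_expr.columns})
    mean_expr = gene_expr[all_targets].mean(axis=1)
    rows = drug_response_assoc(ic50, mean_expr, cancer, classes)
    drug_assoc_to_frame(rows).to_csv(OUT / "drug_assoc.tsv", sep="\t", index=False, float_format="%.10g")
    summary = class_level_summary(rows)
    summary.to_csv(OUT / "drug_class_summary.tsv", sep="\t", index=False, float_format="%.10g")

    best = corr[corr["evaluable"]].sort_values("r_squared", ascending=False).head(4)
    print("strongest per-cancer co-binding correlations:")
    print(best[["tf", "hm", "cancer", "r", "r_squared", "n_loci"]].to_string(index=False))
    print("\ndrug-class summary (median exp(beta1), Fisher-combined p):")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
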