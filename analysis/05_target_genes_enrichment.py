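"""Target genes of each driver pair and their gene-set enrichment.

Intersects each driver pair's TF and mark peaks per cell line into co-bound
loci, assigns target genes by TSS windows, then tests (i) fold enrichment
across CERES dependency bins (width 0.4 on [−2, 0)) with Fisher's exact
test and (ii) hypergeometric enrichment against the gene-set collection.
"""

import json
from pathlib import Path

import pandas as pd

from epidriver.enrich import (
    bin_genes_by_ceres,
    enrichment_to_frame,
    fisher_enrichment,
    hypergeom_enrichment,
    read_gmt,
)
from epidriver.peaks import assign_target_genes, intersect_peaks, loci_to_frame, read_peak_file

OUT = Path("results/analysis")


def pair_loci_and_targets():
    manifest = pd.read_csv(OUT / "peaks_manifest.tsv", sep="\t")
    annotation = pd.read_csv(OUT / "annotation.tsv", sep="\t")
    drivers = pd.read_csv(OUT / "drivers.tsv", sep="\t")
    drivers = drivers[drivers["driver"]]
    sets = {
        (r.sample_id, r.factor_id): read_peak_file(r.path, r.dialect, r.sample_id, r.factor_id)
        for r in manifest.itertuples()
    }
    cells = sorted({s for s, _f in sets})
    out = {}
    for r in drivers.itertuples():
        loci = []
        for cell in cells:
            loci.extend(intersect_peaks(sets[(cell, r.tf)], sets[(cell, r.hm)]))
        targets = assign_target_genes(loci, annotation, r.hm)
        out[(r.tf, r.hm)] = (loci_to_frame(loci), targets)
    return out


def main() -> None:
    ceres = pd.read_csv(OUT / "ceres.tsv", sep="\t", index_col=0)
    collection = read_gmt(OUT / "gene_sets.gmt")
    bins = bin_genes_by_ceres(ceres)
    universe = set(ceres.index)

    pairs = pair_loci_and_targets()
    targets_json, bin_rows, path_rows = {}, [], []
    for (tf, hm), (loci_df, targets) in sorted(pairs.items()):
        loci_df.to_csv(OUT / f"loci_{tf}_{hm}.tsv", sep="\t", index=False)
        targets_json[f"{tf}:{hm}"] = sorted(targets)
        if not targets & universe:
            print(f"{tf}:{hm} — no target genes in the dependency universe; enrichment skipped")
            continue
        for label, members in bins.items():
            row = fisher_enrichment(targets & universe, members & universe, universe)
            row.name = label
            rec = enrichment_to_frame([row]).iloc[0].to_dict()
            rec.update(tf=tf, hm=hm)
            bin_rows.append(rec)
        for row in hypergeom_enrichment(targets & collection.universe, collection):
            rec = enrichment_to_frame([row]).iloc[0].to_dict()
            rec.update(tf=tf, hm=hm)
            path_rows.append(rec)

    (OUT / "target_genes.json").write_text(json.dumps(targets_json, indent=2))
    pd.DataFrame(bin_rows).to_csv(OUT / "enrichment_ceres_bins.tsv", sep="\t", index=False)
    pd.DataFrame(path_rows).to_csv(OUT / "enrichment_pathways.tsv", sep="\t", index=False)

    for (tf, hm), (loci_df, targets) in sorted(pairs.items()):
        print(f"{tf}:{hm} — {len(loci_df)} co-bound loci, {len(targets)} target genes")
    top = pd.DataFrame(path_rows).sort_values("p_value").head(3)
    print("top gene sets:")
    print(top[["tf", "hm", "name", "overlap", "fold_enrichment", "p_value", "fdr"]].to_string(index=False))


if __name__ == "__main__":
    main()
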