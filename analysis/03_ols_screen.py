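"""Pan-cancer OLS screen of every TF–mark pair.

Fits mark-activity ~ TF-activity·C + expression + cancer type per pair,
adjusts the TF coefficient p-values by Benjamini–Hochberg across all pairs,
and keeps pairs with FDR < 0.1 as candidates for the instrumental stage.
"""

from pathlib import Path

import pandas as pd

from epidriver.ols import candidates_to_frame, screen_candidates

OUT = Path("results/analysis")


def main() -> None:
    activity = pd.read_csv(OUT / "activity_matrix.tsv", sep="\t", index_col=0)
    hm_cols = [c for c in activity.columns if c.startswith(("H3K", "H4K"))]
    tf_cols = [c for c in activity.columns if c not in hm_cols]
    expression = pd.read_csv(OUT / "expression.tsv", sep="\t", index_col=0)
    cancer = pd.read_csv(OUT / "metadata.tsv", sep="\t", index_col=0)["cancer_type"]

    candidates = screen_candidates(activity[tf_cols], activity[hm_cols], expression, cancer)
    frame = candidates_to_frame(candidates)
    frame.to_csv(OUT / "candidates.tsv", sep="\t", index=False, float_format="%.10g")

    kept = frame[frame["selected"]]
    print(f"tested {len(frame)} TF–mark pairs; {len(kept)} candidates at FDR < 0.1:")
    print(kept[["tf", "hm", "beta", "p", "fdr"]].to_string(index=False))


if __name__ == "__main__":
    main()
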