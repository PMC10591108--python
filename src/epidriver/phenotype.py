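"""Per-cancer correlation of co-bound signals and drug-sensitivity models.

The correlation layer pools a pair's co-bound loci across all cell lines of
one cancer type and reports Pearson r (and r²) between TF and HM signal —
the per-cancer consistency readout. The drug layer regresses each drug's
IC50 on the standardized mean expression of the pair's target genes plus
cancer-type dummies, and summarizes per drug class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ols import fit_ols

logger = logging.getLogger(__name__)


def pearson_by_cancer(
    loci: pd.DataFrame,
    cancer_of_cell_line: pd.Series,
    min_loci: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of (tf_signal, hm_signal) pooled per cancer type.

    ``loci`` needs columns tf_signal, hm_signal, cell_line. Cancers with
    fewer than ``min_loci`` loci or zero-variance signals are reported with
    ``evaluable=False`` (never NaN propagation into downstream tables).
    """
    work = loci.copy()
    work["cancer"] = work["cell_line"].map(cancer_of_cell_line)
    rows = []
    for cancer, grp in work.groupby("cancer", dropna=False):
        x = grp["tf_signal"].to_numpy(dtype=float)
        y = grp["hm_signal"].to_numpy(dtype=float)
        if len(grp) < min_loci or np.std(x) == 0 or np.std(y) == 0:
            rows.append(
                {
                    "cancer": cancer, "r": np.nan, "r_squared": np.nan,
                    "p_value": np.nan, "n_loci": len(grp), "evaluable": False,
                }
            )
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {
                "cancer": cancer, "r": float(r), "r_squared": float(r**2),
                "p_value": float(p), "n_loci": len(grp), "evaluable": True,
            }
        )
    return pd.DataFrame(rows, columns=["cancer", "r", "r_squared", "p_value", "n_loci", "evaluable"])


@dataclass
class DrugAssocRow:
    drug_id: str
    pathway: str
    beta1: float        # slope on standardized mean target-gene expression
    p_value: float
    or_value: float     # exp(beta1)
    n: int


def drug_response_assoc(
    ic50: pd.DataFrame,
    mean_target_expr: pd.Series,
    cancer_type: pd.Series,
    drug_class: pd.Series | None = None,
) -> list[DrugAssocRow]:
    """Per-drug OLS: IC50 ~ standardized mean target-gene expression +
    cancer-type dummies. Drugs with constant IC50 or too few complete cases
    are skipped with a warning."""
    rows: list[DrugAssocRow] = []
    for drug in ic50.index:
        sub = pd.DataFrame(
            {"ic50": ic50.loc[drug], "expr": mean_target_expr, "cancer": cancer_type}
        ).dropna()
        n_levels = sub["cancer"].nunique()
        k = 2 + max(n_levels - 1, 0)
        if len(sub) < k + 2:
            logger.warning("drug %s: too few complete cases (%d); skipped", drug, len(sub))
            continue
        if sub["ic50"].nunique() < 2:
            logger.warning("drug %s: constant IC50; skipped", drug)
            continue
        sd = sub["expr"].std(ddof=1)
        if sd == 0:
            logger.warning("drug %s: constant expression score; skipped", drug)
            continue
        X = pd.DataFrame(index=sub.index)
        X["intercept"] = 1.0
        X["expr_z"] = (sub["expr"] - sub["expr"].mean()) / sd
        if n_levels >= 2:
            dummies = pd.get_dummies(sub["cancer"], prefix="cancer", dtype=float)
            X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
        fit = fit_ols(sub["ic50"], X)
        beta1 = float(fit.params["expr_z"])
        rows.append(
            DrugAssocRow(
                drug_id=str(drug),
                pathway=str(drug_class.get(drug, "unknown")) if drug_class is not None else "unknown",
                beta1=beta1,
                p_value=float(fit.pvalues["expr_z"]),
                or_value=float(np.exp(beta1)),
                n=fit.n,
            )
        )
    return rows


def drug_assoc_to_frame(rows: list[DrugAssocRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": r.drug_id, "pathway": r.pathway, "beta1": r.beta1,
                "p_value": r.p_value, "or_exp_beta1": r.or_value, "n": r.n,
            }
            for r in rows
        ],
        columns=["drug", "pathway", "beta1", "p_value", "or_exp_beta1", "n"],
    )


def class_level_summary(rows: list[DrugAssocRow]) -> pd.DataFrame:
    """Per drug class: median exp(beta1), drug count, and Fisher-combined p
    (−2Σlog p ~ χ² with 2m df). Empty classes are simply absent."""
    frame = drug_assoc_to_frame(rows)
    out = []
    for pathway, grp in frame.groupby("pathway"):
        p = grp["p_value"].to_numpy(dtype=float)
        stat, combined = stats.combine_pvalues(np.clip(p, 1e-300, 1.0), method="fisher")
        out.append(
            {
                "pathway": pathway,
                "n_drugs": len(grp),
                "median_or": float(grp["or_exp_beta1"].median()),
                "fisher_stat": float(stat),
                "combined_p": float(combined),
            }
        )
    return pd.DataFrame(out, columns=["pathway", "n_drugs", "median_or", "fisher_stat", "combined_p"])
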