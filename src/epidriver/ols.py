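"""Pan-cancer OLS screen: HM activity ~ TF activity + expression + cancer type.

For every (TF, HM) pair the screen fits

    HM_ik ~ β·(TF_ij · C_k) + α1·E_ij + cancer-type dummies + ε,

where C_k is +1 for "activated" marks and −1 for "silent" marks, and keeps
pairs with Benjamini–Hochberg FDR < 0.1 on the TF coefficient as candidates
for the instrumental-variable stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearityError

logger = logging.getLogger(__name__)

#: Mark classification entering the C_k coding. No repressive mark survives
#: the upstream data filter, so all seven in-scope marks default to activated;
#: pass a custom map to ``build_design``/``screen_candidates`` to override.
DEFAULT_HM_CLASS = {
    m: "activated"
    for m in ("H3K4me3", "H3K4me1", "H3K27ac", "H3K36me3", "H3K79me2", "H3K9ac", "H4K20me1")
}

TF_TERM = "tf_activity_x_class"


@dataclass
class OLSFit:
    """Classical OLS fit: coefficients, σ̂²(XᵀX)⁻¹ standard errors, Student-t
    two-sided p-values."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid_var: float
    n: int
    columns: list[str]
    resid: np.ndarray


@dataclass
class CandidatePair:
    tf_id: str
    hm_id: str
    beta: float
    p_value: float
    fdr: float
    selected: bool
    n: int


def build_design(
    tf: pd.Series,
    hm_class: str,
    expression: pd.Series,
    cancer_type: pd.Series,
    drop_cancer_term: bool = False,
) -> pd.DataFrame:
    """Design matrix: intercept, TF·C, expression, cancer-type dummies
    (reference level = lexicographically first).

    Raises :class:`CollinearityError` naming the offending columns when the
    result is rank deficient.
    """
    if not (len(tf) == len(expression) == len(cancer_type)):
        raise ValueError("tf, expression and cancer_type must have equal length")
    if hm_class not in ("activated", "silent"):
        raise ValueError(f"hm_class must be 'activated' or 'silent', got {hm_class!r}")
    c = 1.0 if hm_class == "activated" else -1.0
    X = pd.DataFrame(index=tf.index)
    X["intercept"] = 1.0
    X[TF_TERM] = tf * c
    X["expression"] = expression.astype(float)
    levels = sorted(cancer_type.unique())
    if len(levels) < 2 and not drop_cancer_term:
        raise ValueError(
            "cancer_type has a single level; pass drop_cancer_term=True to omit it"
        )
    if not drop_cancer_term:
        dummies = pd.get_dummies(
            pd.Categorical(cancer_type, categories=levels), prefix="cancer", dtype=float
        )
        dummies.index = cancer_type.index
        X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # Name columns whose removal restores full column rank.
        offending = [
            col
            for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank
        ]
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns", columns=offending
        )


def fit_ols(y: pd.Series | np.ndarray, X: pd.DataFrame) -> OLSFit:
    """Classical OLS with σ̂² = RSS/(n−k) and Student-t inference."""
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k, got n={n}, k={k}")
    _check_rank(X)
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    cols = list(X.columns)
    return OLSFit(
        params=pd.Series(res.params, index=cols),
        bse=pd.Series(res.bse, index=cols),
        tvalues=pd.Series(res.tvalues, index=cols),
        pvalues=pd.Series(res.pvalues, index=cols),
        resid_var=float(res.mse_resid),
        n=n,
        columns=cols,
        resid=np.asarray(res.resid),
    )


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family (with a warning) and reinserted
    as NaN; ties share adjusted values by construction of the step-up rule.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    mask = np.isnan(arr)
    if mask.any():
        logger.warning("bh_adjust: excluding %d NaN p-values from the family", mask.sum())
    valid = arr[~mask]
    if ((valid < 0) | (valid > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(arr, np.nan)
    if valid.size:
        out[~mask] = multipletests(valid, method="fdr_bh")[1]
    return out


def screen_candidates(
    tf_activity: pd.DataFrame,
    hm_activity: pd.DataFrame,
    expression: pd.DataFrame,
    cancer_type: pd.Series,
    hm_class: dict[str, str] | None = None,
    q_threshold: float = 0.1,
) -> list[CandidatePair]:
    """Fit one OLS per (TF, HM) pair over complete cases, BH-adjust the TF
    coefficient p-values jointly, and select pairs with FDR < ``q_threshold``.

    Pairs with too few complete cases are skipped (logged) and excluded from
    the BH family.
    """
    hm_class = dict(DEFAULT_HM_CLASS, **(hm_class or {}))
    records: list[dict] = []
    for tf in tf_activity.columns:
        for hm in hm_activity.columns:
            sub = pd.DataFrame(
                {
                    "tf": tf_activity[tf],
                    "hm": hm_activity[hm],
                    "expr": expression[tf],
                    "cancer": cancer_type,
                }
            ).dropna()
            n_levels = sub["cancer"].nunique()
            k = 3 + max(n_levels - 1, 0)
            if len(sub) < k + 2:
                logger.warning(
                    "pair (%s, %s): %d complete cases < %d required; skipped", tf, hm, len(sub), k + 2
                )
                continue
            X = build_design(
                sub["tf"],
                hm_class.get(hm, "activated"),
                sub["expr"],
                sub["cancer"],
                drop_cancer_term=n_levels < 2,
            )
            fit = fit_ols(sub["hm"], X)
            records.append(
                {
                    "tf": tf,
                    "hm": hm,
                    "beta": float(fit.params[TF_TERM]),
                    "p": float(fit.pvalues[TF_TERM]),
                    "n": fit.n,
                }
            )
    if not records:
        return []
    fdr = bh_adjust([r["p"] for r in records])
    return [
        CandidatePair(
            tf_id=r["tf"],
            hm_id=r["hm"],
            beta=r["beta"],
            p_value=r["p"],
            fdr=float(q),
            selected=bool(q < q_threshold),
            n=r["n"],
        )
        for r, q in zip(records, fdr)
    ]


def candidates_to_frame(candidates: list[CandidatePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf": c.tf_id,
                "hm": c.hm_id,
                "beta": c.beta,
                "p": c.p_value,
                "fdr": c.fdr,
                "selected": c.selected,
                "n": c.n,
            }
            for c in candidates
        ],
        columns=["tf", "hm", "beta", "p", "fdr", "selected", "n"],
    )
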