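"""Two-stage least squares with mutation status as the instrument.

For a candidate (TF, HM) pair the model is

    HM_ik = β0 + β1·TF_ij + E_ij + T_i | Mut_ij + E_ij + T_i + ε,

a just-identified design: one endogenous regressor (TF activity), one
excluded binary instrument (mutation status). Stage 1 regresses TF on
[exog, Mut]; stage 2 regresses HM on [exog, fitted TF]. Second-stage
standard errors use residuals formed with the ORIGINAL TF column (the
standard 2SLS correction), in classical and HC1-robust flavors.

Diagnostics:

* weak-instrument F — the squared HC1-robust first-stage t of the excluded
  instrument, which in the just-identified single-instrument case equals the
  Kleibergen–Paap rank Wald F; p from F(1, n − k₁).
* Wu–Hausman — control-function form: append the first-stage residual v̂ to
  the OLS of HM on [exog, TF] and F-test its coefficient (1 numerator df).

A pair is flagged a driver when both BH-adjusted families pass:
FDR(Wald) < 0.1 and FDR(weak) < 0.1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import IdentificationError
from .ols import OLSFit, bh_adjust, fit_ols

logger = logging.getLogger(__name__)


@dataclass
class IVFit:
    """Full 2SLS record for one pair."""

    beta0: float
    beta1: float
    params: pd.Series                  # all second-stage coefficients
    beta1_se: float                    # classical
    beta1_se_robust: float             # HC1
    wald_p: float                      # two-sided, classical SE, t(n-k)
    model_wald_p: float                # model-level Wald (all slopes = 0)
    first_stage: OLSFit
    weak_F: float
    weak_p: float
    wu_hausman_stat: float
    wu_hausman_p: float
    wu_hausman_defined: bool
    n: int


@dataclass
class PairResult:
    """One row of the driver table (Table-1-style layout)."""

    tf_id: str
    hm_id: str
    beta1: float
    or_value: float                    # exp(beta1); explicitly labeled reading
    wald_p: float
    weak_p: float
    wu_hausman_p: float
    fdr: float
    fdr_weak: float
    driver: bool
    n: int


def effect_to_or(beta1: float) -> float:
    """exp(β1) — the odds-ratio-style rescaling of the linear causal effect.

    One plausible reading of an "OR" column for a linear activity model;
    output tables label the column ``or_exp_beta1`` to keep the definition
    explicit.
    """
    if not math.isfinite(beta1):
        raise ValueError(f"beta1 must be finite, got {beta1}")
    return math.exp(beta1)


def _hc1_cov(X: np.ndarray, resid: np.ndarray) -> np.ndarray:
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * resid[:, None] ** 2)
    return n / (n - k) * xtx_inv @ meat @ xtx_inv


def fit_2sls(
    y: pd.Series | np.ndarray,
    endog: pd.Series | np.ndarray,
    exog: pd.DataFrame,
    instrument: pd.Series | np.ndarray,
) -> IVFit:
    """Just-identified 2SLS of ``y`` on ``endog`` with one excluded instrument.

    ``exog`` must contain the intercept. Raises
    :class:`IdentificationError` when the instrument is constant or lies in
    the span of the exogenous block.
    """
    y = np.asarray(y, dtype=float)
    endog_arr = np.asarray(endog, dtype=float)
    z = np.asarray(instrument, dtype=float)
    Xe = exog.to_numpy(dtype=float)
    n, k_exog = Xe.shape
    if np.all(z == z[0]):
        raise IdentificationError("instrument is constant: model not identified")
    if n <= k_exog + 2 + 1:
        raise IdentificationError(f"too few observations (n={n}) for {k_exog}+2 parameters")

    Z = np.column_stack([Xe, z])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise IdentificationError("instrument is collinear with the exogenous covariates")

    # Stage 1: endog on [exog, instrument]; HC1-robust t of the instrument.
    fs_cols = list(exog.columns) + ["instrument"]
    first_stage = fit_ols(endog_arr, pd.DataFrame(Z, columns=fs_cols))
    endog_hat = Z @ first_stage.params.to_numpy()
    v_hat = endog_arr - endog_hat

    robust_cov_fs = _hc1_cov(Z, first_stage.resid)
    t_rob = first_stage.params.iloc[-1] / math.sqrt(robust_cov_fs[-1, -1])
    weak_F = float(t_rob**2)
    weak_p = float(stats.f.sf(weak_F, 1, n - Z.shape[1]))

    # Stage 2 on the fitted endogenous column.
    X2 = np.column_stack([Xe, endog_hat])
    cols2 = list(exog.columns) + ["endog"]
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        raise IdentificationError("second stage rank deficient (weak/degenerate instrument)")
    params = np.linalg.lstsq(X2, y, rcond=None)[0]

    # SEs from residuals with the ORIGINAL endogenous column.
    X_orig = np.column_stack([Xe, endog_arr])
    resid = y - X_orig @ params
    k2 = X2.shape[1]
    sigma2 = float(resid @ resid) / (n - k2)
    xtx_inv = np.linalg.inv(X2.T @ X2)
    cov_classical = sigma2 * xtx_inv
    cov_robust = _hc1_cov(X2, resid)

    beta1 = float(params[-1])
    beta1_se = math.sqrt(cov_classical[-1, -1])
    beta1_se_robust = math.sqrt(cov_robust[-1, -1])
    t_stat = beta1 / beta1_se
    wald_p = float(2.0 * stats.t.sf(abs(t_stat), n - k2))

    # Model-level Wald: all non-intercept coefficients jointly zero.
    slope_ix = [i for i, c in enumerate(cols2) if c != "intercept"]
    R = np.eye(k2)[slope_ix]
    rb = R @ params
    w = float(rb @ np.linalg.solve(R @ cov_classical @ R.T, rb))
    model_wald_p = float(stats.chi2.sf(w, len(slope_ix)))

    wu_stat, wu_p, wu_defined = _wu_hausman_from_parts(y, endog_arr, Xe, v_hat, list(exog.columns))

    return IVFit(
        beta0=float(params[0]) if "intercept" in exog.columns else float("nan"),
        beta1=beta1,
        params=pd.Series(params, index=cols2),
        beta1_se=beta1_se,
        beta1_se_robust=beta1_se_robust,
        wald_p=wald_p,
        model_wald_p=model_wald_p,
        first_stage=first_stage,
        weak_F=weak_F,
        weak_p=weak_p,
        wu_hausman_stat=wu_stat,
        wu_hausman_p=wu_p,
        wu_hausman_defined=wu_defined,
        n=n,
    )


def _wu_hausman_from_parts(
    y: np.ndarray,
    endog: np.ndarray,
    Xe: np.ndarray,
    v_hat: np.ndarray,
    exog_names: list[str],
) -> tuple[float, float, bool]:
    n = len(y)
    if np.max(np.abs(v_hat)) < 1e-12 * max(1.0, float(np.max(np.abs(endog)))):
        logger.warning("Wu–Hausman undefined: first stage spans the endogenous regressor")
        return float("nan"), float("nan"), False
    cols = exog_names + ["endog", "vhat"]
    X_aux = pd.DataFrame(np.column_stack([Xe, endog, v_hat]), columns=cols)
    fit = fit_ols(y, X_aux)
    t_v = float(fit.tvalues["vhat"])
    stat = t_v**2
    p = float(stats.f.sf(stat, 1, n - X_aux.shape[1]))
    return stat, p, True


def weak_instrument_F(
    endog: pd.Series | np.ndarray,
    exog: pd.DataFrame,
    instrument: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Robust first-stage F on the excluded instrument (= squared HC1 t; the
    Kleibergen–Paap rank Wald F in the just-identified case)."""
    endog_arr = np.asarray(endog, dtype=float)
    z = np.asarray(instrument, dtype=float)
    Z = np.column_stack([exog.to_numpy(dtype=float), z])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise IdentificationError("first stage rank deficient")
    fs = fit_ols(endog_arr, pd.DataFrame(Z, columns=list(exog.columns) + ["instrument"]))
    cov = _hc1_cov(Z, fs.resid)
    coef = fs.params.iloc[-1]
    if coef == 0.0:
        return 0.0, 1.0
    F = float(coef**2 / cov[-1, -1])
    p = float(stats.f.sf(F, 1, len(endog_arr) - Z.shape[1]))
    return F, p


def wu_hausman(
    y: pd.Series | np.ndarray,
    endog: pd.Series | np.ndarray,
    exog: pd.DataFrame,
    instrument: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Control-function Wu–Hausman endogeneity test (1 numerator df)."""
    y = np.asarray(y, dtype=float)
    endog_arr = np.asarray(endog, dtype=float)
    Xe = exog.to_numpy(dtype=float)
    Z = np.column_stack([Xe, np.asarray(instrument, dtype=float)])
    coef = np.linalg.lstsq(Z, endog_arr, rcond=None)[0]
    v_hat = endog_arr - Z @ coef
    stat, p, defined = _wu_hausman_from_parts(y, endog_arr, Xe, v_hat, list(exog.columns))
    if not defined:
        raise IdentificationError("Wu–Hausman test undefined: instrument spans the regressor")
    return stat, p


def fit_pair(
    tf: pd.Series,
    hm: pd.Series,
    expression: pd.Series,
    cancer_type: pd.Series,
    mutation: pd.Series,
    hm_class: str = "activated",
) -> IVFit:
    """Convenience wrapper: build the pair's exogenous design and run 2SLS."""
    X = pd.DataFrame(index=tf.index)
    X["intercept"] = 1.0
    X["expression"] = expression.astype(float)
    levels = sorted(cancer_type.unique())
    if len(levels) >= 2:
        dummies = pd.get_dummies(
            pd.Categorical(cancer_type, categories=levels), prefix="cancer", dtype=float
        )
        dummies.index = cancer_type.index
        X = pd.concat([X, dummies.iloc[:, 1:]], axis=1)
    c = 1.0 if hm_class == "activated" else -1.0
    return fit_2sls(hm, tf * c, X, mutation)


def run_iv_stage(
    candidates,
    tf_activity: pd.DataFrame,
    hm_activity: pd.DataFrame,
    mutation: pd.DataFrame,
    expression: pd.DataFrame,
    cancer_type: pd.Series,
    hm_class: dict[str, str] | None = None,
    q: float = 0.1,
) -> list[PairResult]:
    """2SLS per candidate pair, BH applied separately to the Wald-p and
    weak-p families, and the dual FDR driver gate.

    Candidates whose TF has no mutation variation among complete cases are
    skipped, logged, and excluded from both BH families. An empty candidate
    list (or all-skipped) returns [] — "ran, nothing testable".
    """
    from .ols import DEFAULT_HM_CLASS

    hm_class = dict(DEFAULT_HM_CLASS, **(hm_class or {}))
    fits: list[tuple[str, str, IVFit]] = []
    for cand in candidates:
        tf, hm = cand.tf_id, cand.hm_id
        sub = pd.DataFrame(
            {
                "tf": tf_activity[tf],
                "hm": hm_activity[hm],
                "expr": expression[tf],
                "mut": mutation[tf],
                "cancer": cancer_type,
            }
        ).dropna()
        if sub["mut"].nunique() < 2:
            logger.warning("pair (%s, %s): mutation status constant; skipped from IV stage", tf, hm)
            continue
        try:
            fit = fit_pair(
                sub["tf"], sub["hm"], sub["expr"], sub["cancer"], sub["mut"],
                hm_class.get(hm, "activated"),
            )
        except IdentificationError as exc:
            logger.warning("pair (%s, %s): %s; skipped", tf, hm, exc)
            continue
        fits.append((tf, hm, fit))
    if not fits:
        return []
    fdr = bh_adjust([f.wald_p for _, _, f in fits])
    fdr_weak = bh_adjust([f.weak_p for _, _, f in fits])
    results = [
        PairResult(
            tf_id=tf,
            hm_id=hm,
            beta1=f.beta1,
            or_value=effect_to_or(f.beta1),
            wald_p=f.wald_p,
            weak_p=f.weak_p,
            wu_hausman_p=f.wu_hausman_p,
            fdr=float(q1),
            fdr_weak=float(q2),
            driver=bool(q1 < q and q2 < q),
            n=f.n,
        )
        for (tf, hm, f), q1, q2 in zip(fits, fdr, fdr_weak)
    ]
    results.sort(key=lambda r: (r.tf_id, r.hm_id))
    return results


def results_to_frame(results: list[PairResult]) -> pd.DataFrame:
    """Driver table in the Table-1-style column layout."""
    return pd.DataFrame(
        [
            {
                "tf": r.tf_id,
                "hm": r.hm_id,
                "p_value": r.wald_p,
                "or_exp_beta1": r.or_value,
                "wald_p": r.wald_p,
                "weak_instruments_p": r.weak_p,
                "wu_hausman_p": r.wu_hausman_p,
                "beta1": r.beta1,
                "fdr": r.fdr,
                "fdr_weak": r.fdr_weak,
                "driver": r.driver,
                "n": r.n,
            }
            for r in results
        ],
        columns=[
            "tf", "hm", "p_value", "or_exp_beta1", "wald_p", "weak_instruments_p",
            "wu_hausman_p", "beta1", "fdr", "fdr_weak", "driver", "n",
        ],
    )
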