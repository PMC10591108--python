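"""2SLS engine: instrument-moment closed-form oracle, sandwich-variance
oracle for the weak-instrument F, step-by-step Wu–Hausman oracle, and the
driver-stage behavior on planted cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epidriver.exceptions import IdentificationError
from epidriver.iv import (
    effect_to_or,
    fit_2sls,
    fit_pair,
    run_iv_stage,
    results_to_frame,
    weak_instrument_F,
    wu_hausman,
)
from epidriver.ols import screen_candidates
from epidriver.synthetic import expected_ols_bias, generate_cohort

from conftest import fit_pair_from_cohort, ols_pair_slope, single_pair_config


def _instance(rng, n=50, beta1=1.0, confounded=True):
    z = rng.binomial(1, 0.4, n).astype(float)
    u = rng.standard_normal(n)
    exog = pd.DataFrame({"intercept": np.ones(n), "w": rng.standard_normal(n)})
    x = 1.5 * z + 0.5 * exog["w"].to_numpy() + (u if confounded else 0) + rng.standard_normal(n)
    y = beta1 * x - 0.3 * exog["w"].to_numpy() + (u if confounded else 0) + rng.standard_normal(n)
    return y, x, exog, z


def closed_form_beta(y, x, exog, z):
    """Instrument-moment solve: [Z'X] b = Z'y with Z = [exog, z], X = [exog, x]."""
    Z = np.column_stack([exog.to_numpy(), z])
    X = np.column_stack([exog.to_numpy(), x])
    return np.linalg.solve(Z.T @ X, Z.T @ y)


def test_exogenous_instrument_equals_ols(rng):
    y, x, exog, _ = _instance(rng, confounded=False)
    fit = fit_2sls(y, x, exog, x)  # instrument ≡ endog
    X = np.column_stack([exog.to_numpy(), x])
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert fit.beta1 == pytest.approx(beta_ols[-1], abs=1e-10)


def test_exact_proportionality_recovered(rng):
    _, x, exog, z = _instance(rng)
    fit = fit_2sls(2.0 * x, x, exog, z)
    assert fit.beta1 == pytest.approx(2.0, abs=1e-10)
    assert fit.wald_p < 1e-20


def test_beta1_matches_moment_closed_form(rng):
    for _ in range(100):
        y, x, exog, z = _instance(rng)
        fit = fit_2sls(y, x, exog, z)
        assert fit.beta1 == pytest.approx(closed_form_beta(y, x, exog, z)[-1], abs=1e-8)


def test_constant_instrument_rejected(rng):
    y, x, exog, _ = _instance(rng)
    with pytest.raises(IdentificationError):
        fit_2sls(y, x, exog, np.ones(len(y)))
    with pytest.raises(IdentificationError):
        fit_2sls(y, x, exog, exog["w"])  # collinear with exog


# ---------------------------------------------------------------------------
# weak-instrument F
# ---------------------------------------------------------------------------

def _sandwich_F(endog, exog, z):
    """Independent HC1 sandwich computation of the squared first-stage t."""
    Z = np.column_stack([exog.to_numpy(), z])
    n, k = Z.shape
    beta = np.linalg.solve(Z.T @ Z, Z.T @ endog)
    e = endog - Z @ beta
    bread = np.linalg.inv(Z.T @ Z)
    meat = Z.T @ np.diag(e**2) @ Z
    cov = n / (n - k) * bread @ meat @ bread
    return beta[-1] ** 2 / cov[-1, -1]


def test_orthogonal_instrument_gives_zero_F(rng):
    n = 40
    exog = pd.DataFrame({"intercept": np.ones(n)})
    endog = rng.standard_normal(n)
    z = rng.standard_normal(n)
    # Project out exog and endog so the first-stage coefficient is exactly 0.
    A = np.column_stack([np.ones(n), endog])
    z_orth = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]
    F, p = weak_instrument_F(endog, exog, z_orth)
    assert F == pytest.approx(0.0, abs=1e-16)
    assert p == pytest.approx(1.0)


def test_weak_F_matches_sandwich_oracle(rng):
    for _ in range(20):
        y, x, exog, z = _instance(rng, n=10)
        F, _ = weak_instrument_F(x, exog, z)
        assert F == pytest.approx(_sandwich_F(x, exog, z), abs=1e-8)


def test_strong_instrument_exceeds_conventional_bar():
    hits = 0
    for seed in range(100):
        cfg = single_pair_config(n_cell_lines=1000, instrument_strength=2.0, seed=seed)
        fit = fit_pair_from_cohort(generate_cohort(cfg))
        hits += fit.weak_F > 10
    assert hits >= 99


# ---------------------------------------------------------------------------
# Wu–Hausman
# ---------------------------------------------------------------------------

def _wu_oracle(y, x, exog, z):
    """Step-by-step auxiliary regression: stage-1 residual appended to the
    OLS of y on [exog, x]; squared t of its coefficient, F(1, n-k-1) p."""
    Z = np.column_stack([exog.to_numpy(), z])
    v = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    X_aux = np.column_stack([exog.to_numpy(), x, v])
    n, k = X_aux.shape
    beta = np.linalg.solve(X_aux.T @ X_aux, X_aux.T @ y)
    e = y - X_aux @ beta
    sigma2 = e @ e / (n - k)
    cov = sigma2 * np.linalg.inv(X_aux.T @ X_aux)
    stat = beta[-1] ** 2 / cov[-1, -1]
    return stat, stats.f.sf(stat, 1, n - k)


def test_wu_hausman_matches_auxiliary_oracle(rng):
    for _ in range(20):
        y, x, exog, z = _instance(rng, n=10)
        stat, p = wu_hausman(y, x, exog, z)
        o_stat, o_p = _wu_oracle(y, x, exog, z)
        assert stat == pytest.approx(o_stat, abs=1e-8)
        assert p == pytest.approx(o_p, abs=1e-8)


def test_wu_hausman_scale_invariant(rng):
    y, x, exog, z = _instance(rng)
    s1, _ = wu_hausman(y, x, exog, z)
    s2, _ = wu_hausman(10.0 * y, x, exog, z)
    assert s1 == pytest.approx(s2, abs=1e-8)


def test_wu_hausman_undefined_when_instrument_spans_endog(rng):
    y, x, exog, _ = _instance(rng)
    with pytest.raises(IdentificationError):
        wu_hausman(y, x, exog, x)


def test_wu_hausman_detects_planted_confounding():
    cfg = single_pair_config(n_cell_lines=2000)
    fit = fit_pair_from_cohort(generate_cohort(cfg))
    assert fit.wu_hausman_p < 0.01


# ---------------------------------------------------------------------------
# driver stage
# ---------------------------------------------------------------------------

def test_parameter_recovery_and_ols_bias_over_cohorts():
    """20 planted cohorts (n=200): driver flagged ≥90%, mean 2SLS β̂1 near
    1.5, and the OLS slope biased by at least half the analytic prediction."""
    beta_iv, beta_ols, flagged = [], [], 0
    cfg0 = single_pair_config()
    for seed in range(20):
        cfg = single_pair_config(seed=seed)
        c = generate_cohort(cfg)
        cands = screen_candidates(c.tf_activity, c.hm_activity, c.expression, c.cancer_type)
        res = run_iv_stage(cands, c.tf_activity, c.hm_activity, c.mutation, c.expression, c.cancer_type)
        assert len(res) == 1
        flagged += res[0].driver
        beta_iv.append(res[0].beta1)
        beta_ols.append(ols_pair_slope(c))
    bias = expected_ols_bias(cfg0)
    assert flagged >= 18
    assert np.mean(beta_iv) == pytest.approx(1.5, abs=0.1)
    assert np.mean(beta_ols) - 1.5 > 0.5 * bias


def test_estimator_consistency_in_n():
    errs = {}
    for n in (100, 400, 1600):
        e = []
        for seed in range(30):
            fit = fit_pair_from_cohort(generate_cohort(single_pair_config(n_cell_lines=n, seed=seed)))
            e.append(abs(fit.beta1 - 1.5))
        errs[n] = float(np.median(e))
    assert errs[100] > errs[400] > errs[1600]


def test_no_testable_candidates_returns_empty(default_cohort):
    assert run_iv_stage(
        [],
        default_cohort.tf_activity,
        default_cohort.hm_activity,
        default_cohort.mutation,
        default_cohort.expression,
        default_cohort.cancer_type,
    ) == []


def test_constant_mutation_pair_skipped(default_cohort):
    from epidriver.ols import CandidatePair

    c = default_cohort
    mut = c.mutation.copy()
    mut["TF00"] = 0
    cand = CandidatePair("TF00", "H3K4me3", 1.0, 1e-5, 1e-4, True, 60)
    assert run_iv_stage([cand], c.tf_activity, c.hm_activity, mut, c.expression, c.cancer_type) == []


def test_effect_to_or():
    assert effect_to_or(0.0) == pytest.approx(1.0)
    assert effect_to_or(1.0) == pytest.approx(np.e)
    assert effect_to_or(np.log(0.653)) == pytest.approx(0.653, abs=1e-12)
    with pytest.raises(ValueError):
        effect_to_or(float("inf"))


def test_results_table_layout(default_cohort):
    c = default_cohort
    cands = screen_candidates(c.tf_activity, c.hm_activity, c.expression, c.cancer_type)
    res = run_iv_stage(
        [x for x in cands if x.selected],
        c.tf_activity, c.hm_activity, c.mutation, c.expression, c.cancer_type,
    )
    frame = results_to_frame(res)
    assert list(frame.columns[:7]) == [
        "tf", "hm", "p_value", "or_exp_beta1", "wald_p", "weak_instruments_p", "wu_hausman_p"
    ]
    assert (frame["or_exp_beta1"] > 0).all()
    assert list(frame["tf"]) == sorted(frame["tf"])
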