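"""OLS screen: design construction, the closed-form normal-equations
oracle, BH step-up against brute force, and screen-level error control."""

import numpy as np
import pandas as pd
import pytest

from epidriver.exceptions import CollinearityError
from epidriver.ols import (
    TF_TERM,
    bh_adjust,
    build_design,
    candidates_to_frame,
    fit_ols,
    screen_candidates,
)
from epidriver.synthetic import generate_cohort

from conftest import single_pair_config


def _inputs(n=30, n_cancers=2, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"c{i}" for i in range(n)]
    tf = pd.Series(rng.standard_normal(n), index=idx)
    expr = pd.Series(rng.standard_normal(n), index=idx)
    cancer = pd.Series(rng.choice([f"t{j}" for j in range(n_cancers)], n), index=idx)
    return tf, expr, cancer


def test_two_cancer_types_one_dummy():
    tf, expr, cancer = _inputs(n_cancers=2)
    X = build_design(tf, "activated", expr, cancer)
    assert sum(c.startswith("cancer_") for c in X.columns) == 1


def test_activated_coding_keeps_tf_column():
    tf, expr, cancer = _inputs()
    X = build_design(tf, "activated", expr, cancer)
    pd.testing.assert_series_equal(X[TF_TERM], tf, check_names=False)
    Xs = build_design(tf, "silent", expr, cancer)
    pd.testing.assert_series_equal(Xs[TF_TERM], -tf, check_names=False)


def test_collinearity_error_names_columns():
    tf, expr, cancer = _inputs()
    with pytest.raises(CollinearityError) as err:
        build_design(tf, "activated", tf.copy(), cancer)  # expression duplicates TF
    assert set(err.value.columns) & {TF_TERM, "expression"}


def test_design_rank_matches_numpy_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(15, 40))
        tf, expr, cancer = _inputs(n=n, n_cancers=int(rng.integers(2, 4)), seed=int(rng.integers(1e6)))
        X = build_design(tf, "activated", expr, cancer)
        assert np.linalg.matrix_rank(X.to_numpy(dtype=float)) == X.shape[1]


def test_exact_linear_fit_zero_residuals():
    tf, expr, cancer = _inputs()
    X = build_design(tf, "activated", expr, cancer)
    y = 2.0 * X[TF_TERM] - 1.0 * X["expression"] + 0.5
    fit = fit_ols(y, X)
    assert np.allclose(fit.resid, 0, atol=1e-10)
    assert fit.params[TF_TERM] == pytest.approx(2.0, abs=1e-10)


def test_intercept_only_returns_mean(rng):
    y = rng.standard_normal(20)
    X = pd.DataFrame({"intercept": np.ones(20)})
    assert fit_ols(y, X).params["intercept"] == pytest.approx(y.mean(), abs=1e-12)


def test_fixed_dataset_matches_normal_equations():
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        {"intercept": np.ones(8), "x1": rng.standard_normal(8), "x2": rng.standard_normal(8)}
    )
    y = rng.standard_normal(8)
    fit = fit_ols(y, X)
    A = X.to_numpy()
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)


def test_slope_invariant_to_rescaling_other_columns():
    tf, expr, cancer = _inputs(seed=5)
    rng = np.random.default_rng(1)
    y = pd.Series(rng.standard_normal(len(tf)), index=tf.index)
    X = build_design(tf, "activated", expr, cancer)
    b0 = fit_ols(y, X).params
    X2 = X.copy()
    X2["expression"] = X2["expression"] * 10.0
    b1 = fit_ols(y, X2).params
    assert b1[TF_TERM] == pytest.approx(b0[TF_TERM], abs=1e-10)
    assert b1["expression"] == pytest.approx(b0["expression"] / 10.0, abs=1e-10)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    """Direct step-up evaluation: q_i = min over p_(j) ≥ p_(i) of min(1, m·p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    out = np.empty(m)
    for i, pi in enumerate(p):
        cands = []
        for j_rank, pj in enumerate(np.sort(p), start=1):
            if pj >= pi - 1e-15:
                cands.append(min(1.0, m * pj / j_rank))
        out[i] = min(cands)
    return out


def test_bh_worked_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5], atol=1e-12
    )


def test_bh_degenerate_cases():
    assert bh_adjust([0.123]) == pytest.approx([0.123])
    np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5, atol=1e-12)


def test_bh_nan_excluded_and_reinserted():
    out = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], brute_force_bh([0.01, 0.5]), atol=1e-12)


def test_bh_matches_brute_force_on_random_vectors(rng):
    for _ in range(50):
        p = rng.random(int(rng.integers(1, 30)))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_bh_permutation_equivariant(rng):
    p = rng.random(25)
    perm = rng.permutation(25)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def test_null_screen_controls_selections():
    """No planted pairs, no confounding: across pooled null pairs the
    selected fraction stays within Monte-Carlo range of the FDR level."""
    selected = total = 0
    for seed in range(10):
        cfg = single_pair_config(
            n_cell_lines=50, n_tfs=5, n_hms=4, planted_pairs=(), seed=seed,
            confounder_tf=0.0, confounder_hm=0.0,
        )
        c = generate_cohort(cfg)
        cands = screen_candidates(c.tf_activity, c.hm_activity, c.expression, c.cancer_type)
        selected += sum(x.selected for x in cands)
        total += len(cands)
    rate = selected / total
    sd = np.sqrt(0.1 * 0.9 / total)
    assert rate <= 0.1 + 3 * sd


def test_planted_pair_power():
    hits = 0
    for seed in range(100):
        c = generate_cohort(single_pair_config(seed=seed))
        cands = screen_candidates(c.tf_activity, c.hm_activity, c.expression, c.cancer_type)
        hits += cands[0].selected
    assert hits >= 95


def test_zero_threshold_selects_nothing(default_cohort):
    c = default_cohort
    cands = screen_candidates(
        c.tf_activity, c.hm_activity, c.expression, c.cancer_type, q_threshold=0.0
    )
    assert not any(x.selected for x in cands)
    frame = candidates_to_frame(cands)
    assert list(frame.columns) == ["tf", "hm", "beta", "p", "fdr", "selected", "n"]
    assert len(frame) == 36
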