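import numpy as np
import pandas as pd
import pytest

from epidriver.synthetic import (
    GeneratorConfig,
    generate_annotation,
    generate_cohort,
    generate_downstream_assets,
)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_assets(default_cohort):
    annotation = generate_annotation(default_cohort.config)
    return generate_downstream_assets(default_cohort, annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def single_pair_config(**kw) -> GeneratorConfig:
    """One TF, one HM, one planted pair — the minimal IV simulation unit."""
    base = dict(
        n_cell_lines=200,
        n_tfs=1,
        n_hms=1,
        planted_pairs=((0, 0, 1.5),),
        n_genes=10,
        n_target_genes=2,
        n_drugs=2,
        n_patients=10,
        seed=0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


def fit_pair_from_cohort(cohort, tf="TF00", hm="H3K4me3"):
    from epidriver.iv import fit_pair

    return fit_pair(
        cohort.tf_activity[tf],
        cohort.hm_activity[hm],
        cohort.expression[tf],
        cohort.cancer_type,
        cohort.mutation[tf],
    )


def ols_pair_slope(cohort, tf="TF00", hm="H3K4me3") -> float:
    """Brute-force OLS slope of HM on TF with expression + cancer controls,
    straight from the normal equations."""
    X = pd.DataFrame({"const": 1.0, "tf": cohort.tf_activity[tf], "expr": cohort.expression[tf]})
    dummies = pd.get_dummies(cohort.cancer_type, dtype=float)
    X = pd.concat([X, dummies.iloc[:, 1:]], axis=1).to_numpy(dtype=float)
    y = cohort.hm_activity[hm].to_numpy(dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1])
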