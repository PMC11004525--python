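import numpy as np
import pytest

from aecopd import (
    desk_scale_config,
    generate_cohort,
    glm_rank_risk_factors,
    lasso_select,
)


@pytest.fixture(scope="session")
def desk_cohort():
    """One desk-scale cohort with planted signal, shared across tests."""
    return generate_cohort(desk_scale_config(seed=11))


@pytest.fixture(scope="session")
def separable_cohort():
    """Strong-signal cohort on which classifiers should be near-perfect."""
    return generate_cohort(desk_scale_config(seed=12, effect_size=2.0))


@pytest.fixture(scope="session")
def selected(separable_cohort):
    """(X_sel, labels, risk factors) from the separable cohort."""
    table, _ = separable_cohort
    sel = lasso_select(table.values, table.labels, seed=0)
    X = table.values[:, sel.selected_indices]
    risk = glm_rank_risk_factors(X, table.labels, k=3)
    return X, table.labels, risk, sel


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
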