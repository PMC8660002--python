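import numpy as np
import pandas as pd
import pytest

from painconn.glm import OLSFit, TERM_INTER, TERM_WPINT, TERM_X, EdgeModelResult
from painconn.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_pain=40, n_control=21, n_rois=10, n_networks=3,
                      n_frames=120, seed=11)


@pytest.fixture(scope="session")
def cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def pain_subjects(cohort):
    return cohort[cohort["group"] == "pain"].reset_index(drop=True)


def random_moderation_fit(rng, df=30):
    """A synthetic surviving-interaction edge fit with random PD covariance.

    Covers the term set (const, X, WPINT, WPINT:X) that the moderation
    machinery expects; coefficient scales roughly match Fisher-z outcomes.
    """
    names = ["const", TERM_X, TERM_WPINT, TERM_INTER]
    a = rng.standard_normal((4, 4)) * 0.05
    cov = a @ a.T + 1e-4 * np.eye(4)
    params = rng.standard_normal(4) * 0.2
    se = np.sqrt(np.diag(cov))
    fit = OLSFit(
        names=names, params=params, cov_params=cov, se=se,
        tvalues=params / se, pvalues=np.full(4, 0.5), df_resid=df,
        n=df + 4, r_squared=0.5, rss=1.0,
    )
    return EdgeModelResult(
        edge=(0, 1), coding="log", step=1,
        surviving_terms=(TERM_X, TERM_WPINT, TERM_INTER), fit=fit,
        qvalues={TERM_INTER: 0.01},
    )


@pytest.fixture
def moderation_fit_factory():
    return random_moderation_fit


@pytest.fixture
def control_subjects():
    rng = np.random.default_rng(5)
    n = 21
    return pd.DataFrame(
        {
            "subject_id": [f"c{i}" for i in range(n)],
            "group": "control",
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(61, 90, n),
            "moca": rng.integers(20, 30, n).astype(float),
            "pain_med": np.nan,
            "scanner_pain": np.nan,
            "wpdur": np.nan,
            "wpint": np.nan,
        }
    )
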