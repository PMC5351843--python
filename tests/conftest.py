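import numpy as np
import pandas as pd
import pytest

import prodshift as ps


@pytest.fixture
def brood_csv(tmp_path):
    """Factory writing a brood-table CSV from a list of row tuples."""

    def _write(rows, name="brood.csv"):
        path = tmp_path / name
        df = pd.DataFrame(rows, columns=["population", "brood_year", "spawners", "recruits"])
        df.to_csv(path, index=False)
        return path

    return _write


@pytest.fixture
def simple_brood():
    """Three clean brood years for one population."""
    return ps.BroodTable(
        pd.DataFrame(
            {
                "population": "pws",
                "brood_year": [1981, 1982, 1983],
                "spawners": [100.0, 200.0, 300.0],
                "recruits": [250.0, 100.0, 300.0],
            }
        )
    )


@pytest.fixture
def random_frame_factory():
    """Random aligned model frames (log_rs, spawners, covariate) for oracle checks."""

    def _make(rng, n=25, years_start=1981):
        years = np.arange(years_start, years_start + n)
        spawners = rng.uniform(500, 5000, size=n)
        x = rng.normal(size=n)
        log_rs = (
            rng.normal(1.5, 0.5)
            + rng.normal(-2e-4, 5e-5) * spawners
            + rng.normal(0, 0.5) * x
            + rng.normal(0, 0.4, size=n)
        )
        return pd.DataFrame(
            {"log_rs": log_rs, "spawners": spawners, "x": x},
            index=pd.Index(years, name="brood_year"),
        )

    return _make


def ols_oracle(frame, columns):
    """Independent normal-equations least-squares fit: intercept + columns.

    Returns (coefficients led by the intercept, ml_sigma, loglik) computed
    directly from the textbook formulas, independent of the fitting engine.
    """
    y = frame["log_rs"].to_numpy()
    X = np.column_stack([np.ones(len(y))] + [frame[c].to_numpy() for c in columns])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n = len(y)
    sigma = np.sqrt(np.sum(resid**2) / n)
    ll = np.sum(
        -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (resid / sigma) ** 2
    )
    return beta, sigma, ll
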