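import numpy as np
import pandas as pd
import pytest

from epibehave.behavior import preset_profile
from epibehave.epidemic import DiseaseParams


@pytest.fixture(scope="session")
def default_params() -> DiseaseParams:
    return DiseaseParams()


@pytest.fixture(scope="session")
def profile0():
    return preset_profile("0")


@pytest.fixture(scope="session")
def full_grid() -> pd.DataFrame:
    """The complete deterministic simulation grid (all nine profiles,
    ten in-group pairs, full factorial over beta0, pi, tau, kappa)."""
    from epibehave.experiment import default_design, run_grid

    return run_grid(default_design())


def make_synthetic_severity_table(n: int, rng: np.random.Generator,
                                  waves_coef: dict, peak_coef: dict,
                                  final_coef: dict, peak_dispersion: float = 0.1,
                                  final_phi: float = 5.0, final_p_one: float = 0.05):
    """Grid-shaped table with severity responses drawn from known models.

    Used to check that the summary regressions recover the coefficients
    that generated the data.
    """
    from epibehave.experiment import ALPHA_PAIRS, PROFILE_IDS

    profiles = rng.choice(PROFILE_IDS, size=n)
    pairs = [ALPHA_PAIRS[i] for i in rng.integers(0, len(ALPHA_PAIRS), size=n)]
    df = pd.DataFrame({
        "profile": profiles,
        "alpha_m1": [p[0] for p in pairs],
        "alpha_p1": [p[1] for p in pairs],
        "beta0": rng.choice([0.5, 1.0, 2.0, 3.0], size=n),
        "pi": rng.choice([0.25, 0.5, 2 / 3, 0.75], size=n),
        "tau": rng.choice([1.0, 3.0, 5.0, 7.0], size=n),
        "kappa": rng.choice([0.5, 0.6, 0.75, 0.9, 0.95, 1.0], size=n),
        "error": "",
    })
    df["delta_alpha"] = df["alpha_m1"] - df["alpha_p1"]

    def linpred(coefs):
        eta = np.full(n, coefs["Intercept"], dtype=float)
        for term in ("alpha_m1", "delta_alpha", "kappa", "tau", "pi", "beta0"):
            eta += coefs.get(term, 0.0) * df[term].to_numpy(float)
        for pid, c in coefs.get("profile", {}).items():
            eta += c * (df["profile"] == pid).to_numpy(float)
        return eta

    df["n_secondary"] = rng.poisson(np.exp(linpred(waves_coef)))
    mu_peak = np.exp(linpred(peak_coef))
    shape = 1.0 / peak_dispersion
    df["peak_height"] = rng.gamma(shape, mu_peak / shape)
    mu_f = 1.0 / (1.0 + np.exp(-linpred(final_coef)))
    y = rng.beta(mu_f * final_phi, (1.0 - mu_f) * final_phi)
    y = np.clip(y, 1e-9, 1.0 - 1e-9)  # continuous part stays off the unit mass
    ones = rng.random(n) < final_p_one
    y[ones] = 1.0
    df["final_size"] = y
    df["epidemic"] = True
    df["n_waves"] = df["n_secondary"] + 1
    df["peak_time"] = 50.0
    df["time_to_curb"] = 50.0
    return df
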