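"""Simulation-experiment grid and summary regressions.

The experiment crosses nine population profiles (five homogeneous response
profiles 0, A, B, C, D and the four half-and-half mixtures 0xA..0xD) with
ten in-group parameter pairs drawn from {0.1, 1, 2, 3} and a full factorial
over beta0 in {1/2, 1, 2, 3}, pi in {1/4, 1/2, 2/3, 3/4}, tau in
{1, 3, 5, 7} days and kappa in {1/2, 3/5, 3/4, 9/10, 19/20, 1} - 384 runs
per profile and alpha pair, each solved to 1,000 days and summarized by the
severity measures.  Everything is deterministic.

Severity measures are then summarized descriptively and with three
generalized linear models: Poisson (log link) for the number of secondary
waves, gamma (log link) for the peak size, and a one-inflated beta model
(logit link, constant precision and constant point mass at one) for the
final epidemic size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.special import expit, gammaln
from statsmodels.base.model import GenericLikelihoodModel

from .behavior import BehaviorProfile, preset_profile
from .dde import SolverSettings, solve
from .epidemic import DiseaseParams, StateVector
from .severity import WaveRules, severity_summary

__all__ = [
    "ExperimentDesign",
    "default_design",
    "population_profiles",
    "run_grid",
    "descriptive_stats",
    "OneInflatedBeta",
    "SummaryModelFits",
    "fit_summary_models",
]

PROFILE_IDS = ("0", "A", "B", "C", "D", "0xA", "0xB", "0xC", "0xD")

# All unordered in-group pairs from {0.1, 1, 2, 3}, oriented so the
# low-standard group S_{-1} carries the smaller (more pro-prophylactic)
# alpha, matching the displayed pairs (0.1, 1), (1, 2), (1, 3).
ALPHA_PAIRS = (
    (0.1, 0.1), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0),
    (0.1, 1.0), (0.1, 2.0), (0.1, 3.0), (1.0, 2.0), (1.0, 3.0), (2.0, 3.0),
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factor levels of the simulation experiment.

    ``delta_alpha_convention`` selects the sign of the heterogeneity
    covariate: "m1" gives delta_alpha = alpha_{-1} - alpha_{+1} (the
    primary definition), "p1" the reversed difference.
    """

    profiles: tuple[str, ...] = PROFILE_IDS
    alpha_pairs: tuple[tuple[float, float], ...] = ALPHA_PAIRS
    beta0: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0)
    pi: tuple[float, ...] = (0.25, 0.5, float(Fraction(2, 3)), 0.75)
    tau: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    kappa: tuple[float, ...] = (0.5, 0.6, 0.75, 0.9, 0.95, 1.0)
    horizon: float = 1000.0
    delta_alpha_convention: str = "m1"

    def __post_init__(self) -> None:
        if self.delta_alpha_convention not in ("m1", "p1"):
            raise ValueError("delta_alpha_convention must be 'm1' or 'p1'")
        unknown = set(self.profiles) - set(PROFILE_IDS)
        if unknown:
            raise ValueError(f"unknown profiles {sorted(unknown)}")

    @property
    def cell_size(self) -> int:
        """Runs per (profile, alpha pair) cell."""
        return len(self.beta0) * len(self.pi) * len(self.tau) * len(self.kappa)

    @property
    def n_runs(self) -> int:
        return len(self.profiles) * len(self.alpha_pairs) * self.cell_size

    def delta_alpha(self, alpha_m1: float, alpha_p1: float) -> float:
        d = alpha_m1 - alpha_p1
        return d if self.delta_alpha_convention == "m1" else -d


def default_design(**overrides) -> ExperimentDesign:
    return ExperimentDesign(**overrides)


def population_profiles(
    profile_id: str, alpha_m1: float, alpha_p1: float, m0: float = 0.05
) -> tuple[BehaviorProfile, BehaviorProfile]:
    """Profiles of the two susceptible groups for a population id.

    Homogeneous ids assign the same weights to both groups; mixture ids
    "0xX" put the reference profile 0 on the low-standard group S_{-1} and
    the variant X on S_{+1}.
    """
    if profile_id.startswith("0x"):
        return (preset_profile("0", alpha=alpha_m1, m0=m0),
                preset_profile(profile_id[2:], alpha=alpha_p1, m0=m0))
    return (preset_profile(profile_id, alpha=alpha_m1, m0=m0),
            preset_profile(profile_id, alpha=alpha_p1, m0=m0))


def _run_one(profile_id, alpha_m1, alpha_p1, beta0, pi, tau, kappa,
             horizon, settings, rules) -> dict:
    params = DiseaseParams(beta0=beta0, pi=pi, tau=tau, kappa=kappa)
    profiles = population_profiles(profile_id, alpha_m1, alpha_p1)
    traj = solve(profiles, params, initial=StateVector(), horizon=horizon,
                 settings=settings)
    return severity_summary(traj, rules=rules).to_dict()


def run_grid(
    design: ExperimentDesign | None = None,
    settings: SolverSettings | None = None,
    rules: WaveRules | None = None,
    checkpoint: str | Path | None = None,
    checkpoint_every: int = 500,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full factorial experiment and return one row per run.

    Individual solver failures are recorded in the ``error`` column rather
    than aborting the sweep.  When ``checkpoint`` names a CSV file, partial
    results are written there periodically and completed rows are skipped
    on resume; the sweep is deterministic and order-free, so resumed and
    fresh runs yield identical tables.
    """
    design = design or default_design()
    settings = settings or SolverSettings()

    done: dict[tuple, dict] = {}
    cpath = Path(checkpoint) if checkpoint is not None else None
    key_cols = ["profile", "alpha_m1", "alpha_p1", "beta0", "pi", "tau", "kappa"]
    if cpath is not None and cpath.exists():
        prev = pd.read_csv(cpath)
        for _, r in prev.iterrows():
            k = (r["profile"], r["alpha_m1"], r["alpha_p1"], r["beta0"],
                 r["pi"], r["tau"], r["kappa"])
            done[k] = r.to_dict()

    combos = list(itertools.product(design.profiles, design.alpha_pairs,
                                    design.beta0, design.pi, design.tau,
                                    design.kappa))
    rows = []
    iterator = enumerate(combos)
    if progress:
        from tqdm import tqdm
        iterator = enumerate(tqdm(combos, desc="grid"))
    since_flush = 0
    for _, (pid, (a_m1, a_p1), beta0, pi, tau, kappa) in iterator:
        key = (pid, a_m1, a_p1, beta0, pi, tau, kappa)
        if key in done:
            rows.append(done[key])
            continue
        row = {"profile": pid, "alpha_m1": a_m1, "alpha_p1": a_p1,
               "delta_alpha": design.delta_alpha(a_m1, a_p1),
               "beta0": beta0, "pi": pi, "tau": tau, "kappa": kappa}
        try:
            row.update(_run_one(pid, a_m1, a_p1, beta0, pi, tau, kappa,
                                design.horizon, settings, rules))
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - per-row failures are data
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        since_flush += 1
        if cpath is not None and since_flush >= checkpoint_every:
            pd.DataFrame(rows).to_csv(cpath, index=False)
            since_flush = 0
    out = pd.DataFrame(rows)
    if cpath is not None:
        out.to_csv(cpath, index=False)
    return out


_MEASURES = {
    "Epidemic?": "epidemic",
    "Nb2. waves": "n_secondary",
    "Peak time": "peak_time",
    "Peak size": "peak_height",
    "Time to curb": "time_to_curb",
    "Final size": "final_size",
}


def descriptive_stats(rows: pd.DataFrame, by: str = "profile") -> pd.DataFrame:
    """Median / mean / SD of the severity measures per group.

    ``by`` is a column name ("profile") or "alpha_pair" to group on the
    (alpha_m1, alpha_p1) pair.  NaN entries (e.g. undefined time to curb)
    are excluded measure-wise; empty groups are omitted with a warning.
    """
    df = rows.copy()
    if "error" in df.columns:
        df = df[df["error"].fillna("") == ""]
    if by == "alpha_pair":
        df = df.assign(alpha_pair=list(zip(df["alpha_m1"], df["alpha_p1"])))
        by = "alpha_pair"
    out = {}
    for gname, g in df.groupby(by, sort=True):
        if g.empty:  # pragma: no cover - groupby drops empty groups
            import warnings
            warnings.warn(f"empty group {gname!r} omitted")
            continue
        block = {}
        for label, col in _MEASURES.items():
            v = pd.to_numeric(g[col], errors="coerce").astype(float)
            block[(label, "Median")] = v.median()
            block[(label, "Mean")] = v.mean()
            block[(label, "SD")] = v.std() if v.count() > 1 else 0.0
        out[gname] = block
    res = pd.DataFrame(out).T
    res.columns = pd.MultiIndex.from_tuples(res.columns)
    res.index.name = by
    return res


class OneInflatedBeta(GenericLikelihoodModel):
    """Beta regression with a point mass at one (logit mean link).

    The response y in (0, 1] is 1 with constant probability nu and
    otherwise beta-distributed with mean mu = expit(X b) and precision
    phi (constant).  Parameters are [b, log(phi), logit(nu)], estimated by
    maximum likelihood.  With no response equal to one the likelihood
    reduces to ordinary beta regression (nu pinned at zero).
    """

    def __init__(self, endog, exog, eps: float = 1e-10, **kwargs):
        endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if np.any(endog <= 0) or np.any(endog > 1):
            raise ValueError("response must lie in (0, 1]")
        self._eps = eps
        self._has_ones = bool(np.any(endog >= 1.0 - eps))
        names = kwargs.pop("exog_names", None)
        super().__init__(endog, exog, **kwargs)
        if names is not None:
            self.data.xnames = list(names)
        extra = ["log_phi", "logit_nu"] if self._has_ones else ["log_phi"]
        self.data.xnames = list(self.data.xnames) + extra
        k = exog.shape[1]
        self.df_model = k - 1 + (2 if self._has_ones else 1)
        self.df_resid = len(endog) - k - (2 if self._has_ones else 1)

    def _unpack(self, params):
        k = self.exog.shape[1]
        b = params[:k]
        phi = math.exp(min(params[k], 30.0))
        nu = expit(params[k + 1]) if self._has_ones else 0.0
        return b, phi, nu

    @staticmethod
    def _beta_logpdf(y, mu, phi):
        a = mu * phi
        b = (1.0 - mu) * phi
        return (gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))

    def loglikeobs(self, params):
        b, phi, nu = self._unpack(params)
        y = self.endog
        mu = np.clip(expit(self.exog @ b), self._eps, 1.0 - self._eps)
        is_one = y >= 1.0 - self._eps
        ll = np.empty_like(y)
        if self._has_ones:
            ll[is_one] = math.log(max(nu, 1e-300))
            cont = ~is_one
            ll[cont] = (math.log(max(1.0 - nu, 1e-300))
                        + self._beta_logpdf(y[cont], mu[cont], phi))
        else:
            ll[:] = self._beta_logpdf(y, mu, phi)
        return ll

    def fit(self, start_params=None, maxiter=2000, disp=0, **kwargs):
        if start_params is None:
            k = self.exog.shape[1]
            y = np.clip(self.endog, self._eps, 1.0 - self._eps)
            # crude logit-scale least squares start
            z = np.log(y / (1.0 - y))
            b0, *_ = np.linalg.lstsq(self.exog, z, rcond=None)
            frac_one = float(np.mean(self.endog >= 1.0 - self._eps))
            start_params = np.concatenate([
                b0, [math.log(5.0)],
                [math.log(max(frac_one, 1e-3) / max(1 - frac_one, 1e-3))]
                if self._has_ones else [],
            ]) if self._has_ones else np.concatenate([b0, [math.log(5.0)]])
        method = kwargs.pop("method", "bfgs")
        res = super().fit(start_params=start_params, maxiter=maxiter,
                          disp=disp, method=method, **kwargs)
        if not res.mle_retvals.get("converged", True):
            res = super().fit(start_params=res.params, maxiter=maxiter,
                              disp=disp, method="nm", **kwargs)
            res = super().fit(start_params=res.params, maxiter=maxiter,
                              disp=disp, method="bfgs", **kwargs)
        return res

    # -- deviance helpers -------------------------------------------------
    def saturated_loglike(self, params) -> float:
        """Log-likelihood with mu_i = y_i (shared phi and nu from params)."""
        b, phi, nu = self._unpack(params)
        y = self.endog
        is_one = y >= 1.0 - self._eps
        ll = 0.0
        if self._has_ones:
            n1 = int(is_one.sum())
            ll += n1 * math.log(max(nu, 1e-300))
            ll += (len(y) - n1) * math.log(max(1.0 - nu, 1e-300))
        yc = np.clip(y[~is_one], self._eps, 1.0 - self._eps)
        ll += float(np.sum(self._beta_logpdf(yc, yc, phi)))
        return ll


def _deviance_r2(res) -> float:
    """Deviance-based pseudo-R2 of a fitted GLM, 1 - D/D_null."""
    if res.null_deviance <= 0:
        return 0.0
    return float(1.0 - res.deviance / res.null_deviance)


@dataclass
class SummaryModelFits:
    """Fitted summary regressions and their diagnostics.

    ``waves`` (Poisson), ``peak`` (gamma) and ``final_size`` (one-inflated
    beta) results; ``pseudo_r2`` maps model name to the deviance-based
    pseudo-R2; ``gof`` maps model name to (deviance, df_resid).
    """

    waves: object
    peak: object
    final_size: object
    pseudo_r2: dict = field(default_factory=dict)
    gof: dict = field(default_factory=dict)
    n_excluded_peak: int = 0

    def coefficient_table(self) -> pd.DataFrame:
        def as_series(values, res):
            if isinstance(values, pd.Series):
                return values
            return pd.Series(np.asarray(values), index=res.model.exog_names)

        tabs = {}
        for name, res in (("waves", self.waves), ("peak", self.peak),
                          ("final_size", self.final_size)):
            tabs[(name, "coef")] = as_series(res.params, res)
            tabs[(name, "se")] = as_series(res.bse, res)
        return pd.concat(tabs, axis=1)


_FORMULA_RHS = ("C(profile, Treatment('0')) + alpha_m1 + delta_alpha"
                " + kappa + tau + pi + beta0")


def _design_matrix(df: pd.DataFrame):
    import patsy

    return patsy.dmatrix(_FORMULA_RHS, df, return_type="dataframe")


def fit_summary_models(rows: pd.DataFrame) -> SummaryModelFits:
    """Fit the three severity regressions on a grid-result table.

    Predictors: profile indicators (reference profile 0), alpha_m1,
    delta_alpha, kappa, tau, pi and beta0.  Runs with solver errors are
    dropped; runs with peak size below 1 case/day are excluded from the
    gamma fit (positive support).
    """
    df = rows.copy()
    if "error" in df.columns:
        df = df[df["error"].fillna("") == ""]
    if df.empty:
        raise ValueError("no completed runs to fit")
    df["n_secondary"] = df["n_secondary"].astype(int)

    waves = smf.glm(f"n_secondary ~ {_FORMULA_RHS}", data=df,
                    family=sm.families.Poisson()).fit()

    peak_df = df[df["peak_height"] >= 1.0]
    n_excl = len(df) - len(peak_df)
    peak = smf.glm(f"peak_height ~ {_FORMULA_RHS}", data=peak_df,
                   family=sm.families.Gamma(link=sm.families.links.Log())).fit()

    y = np.clip(df["final_size"].to_numpy(float), 1e-12, 1.0)
    X = _design_matrix(df)
    oib_model = OneInflatedBeta(y, X.to_numpy(), exog_names=list(X.columns))
    oib = oib_model.fit()
    X0 = np.ones((len(y), 1))
    oib0 = OneInflatedBeta(y, X0).fit()

    # Mixed discrete/continuous likelihood: the GLM-style saturated
    # deviance is ill-defined at the unit boundary, so use the
    # likelihood-ratio (Cox-Snell) form of the deviance pseudo-R2.
    oib_r2 = float(1.0 - math.exp(-2.0 * (oib.llf - oib0.llf) / len(y)))

    fits = SummaryModelFits(
        waves=waves, peak=peak, final_size=oib,
        pseudo_r2={
            "waves": _deviance_r2(waves),
            "peak": _deviance_r2(peak),
            "final_size": oib_r2,
        },
        gof={
            "waves": (float(waves.deviance), int(waves.df_resid)),
            "peak": (float(peak.deviance), int(peak.df_resid)),
            "final_size": (float(-2.0 * oib.llf), int(oib_model.df_resid)),
        },
        n_excluded_peak=n_excl,
    )
    return fits
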