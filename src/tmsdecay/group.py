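"""Decay and linear fits to group-level mean trajectories.

Published TMS trials report arm-level mean symptom ratings by week.
:class:`GroupDecayModel` fits the three-parameter exponential decay to
one such trajectory by nonlinear least squares (B on the log scale);
:class:`GroupLinearModel` is the straight-line comparator.  Both report
the Gaussian maximum-likelihood log-likelihood of their residuals so
AIC/BIC comparisons between the families are on a common footing (the
decay family counts 4 parameters: A, B, C and the residual sd; the
linear family 3).  Mean trajectories are treated as homoscedastic
observations: arm sizes and standard errors of the source trials are
not modelled.

:func:`fit_multigroup_nlme` reuses the patient-level NLME machinery
with treatment groups as the grouping level (e.g. the four response
trajectories of the THREE-D secondary analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize

from .decay import DecayParams
from .nlme import ExponentialDecayModel, NLMEResults, _start_values
from .series import RatingSeries

__all__ = [
    "GroupDecayModel",
    "GroupLinearModel",
    "GroupNLSResults",
    "GroupOLSResults",
    "fit_multigroup_nlme",
    "compare_group_fits",
]


def _gaussian_ml_loglik(rss: float, n: int) -> float:
    """Profile (ML) Gaussian log-likelihood with sigma^2 = RSS / n."""
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


@dataclass
class GroupNLSResults:
    """Nonlinear least-squares decay fit to one mean trajectory."""

    group_id: str
    params: DecayParams
    se: dict
    residual_sd: float
    llf: float
    n_params: int
    n_obs: int
    converged: bool
    time_constant_identified: bool
    message: str = ""
    name: str = "NLS(exponential decay)"

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.llf + 2.0 * self.n_params
        self.bic = -2.0 * self.llf + self.n_params * np.log(self.n_obs)

    @property
    def loglik(self) -> float:
        return self.llf

    def predict(self, t):
        from .decay import predict_score

        return predict_score(self.params, t)

    def to_dict(self) -> dict:
        return {
            "group": self.group_id,
            "model": self.name,
            "amplitude": self.params.amplitude,
            "time_constant": self.params.time_constant,
            "floor": self.params.floor,
            "se": self.se,
            "residual_sd": self.residual_sd,
            "loglik": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "time_constant_identified": bool(self.time_constant_identified),
            "message": self.message,
        }


@dataclass
class GroupOLSResults:
    """Ordinary least-squares linear fit to one mean trajectory."""

    group_id: str
    intercept: float
    slope: float
    se: dict
    residual_sd: float
    llf: float
    n_params: int
    n_obs: int
    converged: bool = True
    name: str = "OLS(linear trend)"

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.llf + 2.0 * self.n_params
        self.bic = -2.0 * self.llf + self.n_params * np.log(self.n_obs)

    @property
    def loglik(self) -> float:
        return self.llf

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def to_dict(self) -> dict:
        return {
            "group": self.group_id,
            "model": self.name,
            "intercept": self.intercept,
            "slope": self.slope,
            "se": self.se,
            "residual_sd": self.residual_sd,
            "loglik": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
        }


class GroupDecayModel:
    """Exponential-decay fit to a single group-mean rating series."""

    def __init__(self, series: RatingSeries):
        if len(series) < 4:
            raise ValueError(
                "at least 4 time points are required for a 3-parameter decay fit"
            )
        self.series = series

    def fit(self) -> GroupNLSResults:
        s = self.series
        t, y = s.times, s.scores
        n = len(s)
        if np.ptp(y) == 0:
            # flat series: amplitude zero, floor equal to the constant, B undefined
            return GroupNLSResults(
                group_id=s.subject_id,
                params=DecayParams(0.0, 1.0, float(y[0])),
                se={"amplitude": 0.0, "time_constant": np.nan, "floor": 0.0},
                residual_sd=float(np.sqrt(max(1e-300, 0.0))),
                llf=_gaussian_ml_loglik(0.0, n),
                n_params=4,
                n_obs=n,
                converged=True,
                time_constant_identified=False,
                message="flat series: time constant unidentifiable",
            )
        a0, logb0, c0, _, _, _ = _start_values([s])

        def residuals(theta):
            a, logb, c = theta
            return y - (a * np.exp(-t / np.exp(logb)) + c)

        lo, hi = -7.0, 7.0
        sol = optimize.least_squares(
            residuals,
            x0=np.array([a0, logb0, c0]),
            bounds=([-np.inf, lo, -np.inf], [np.inf, hi, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        a, logb, c = sol.x
        rss = float(2.0 * sol.cost)
        sigma2 = rss / n
        # asymptotic ses from the Jacobian at the optimum
        se = {"amplitude": np.nan, "time_constant": np.nan, "floor": np.nan}
        identified = abs(a) > 1e-8 and lo + 1e-6 < logb < hi - 1e-6
        try:
            J = sol.jac
            cov = sigma2 * np.linalg.inv(J.T @ J)
            d = np.diag(cov)
            if np.all(d >= 0):
                se = {
                    "amplitude": float(np.sqrt(d[0])),
                    "time_constant": float(np.exp(logb) * np.sqrt(d[1])),
                    "floor": float(np.sqrt(d[2])),
                }
        except np.linalg.LinAlgError:
            identified = False
        if not identified:
            warnings.warn(
                f"group {s.subject_id}: time constant weakly identified "
                "(amplitude near zero or estimate at the search boundary)",
                stacklevel=2,
            )
        return GroupNLSResults(
            group_id=s.subject_id,
            params=DecayParams(float(a), float(np.exp(logb)), float(c)),
            se=se,
            residual_sd=float(np.sqrt(sigma2)),
            llf=_gaussian_ml_loglik(rss, n),
            n_params=4,
            n_obs=n,
            converged=bool(sol.success),
            time_constant_identified=identified,
            message="" if sol.success else str(sol.message),
        )


class GroupLinearModel:
    """Straight-line comparator for a group-mean rating series."""

    def __init__(self, series: RatingSeries):
        if len(series) < 3:
            raise ValueError("at least 3 time points are required for a linear fit")
        self.series = series

    def fit(self) -> GroupOLSResults:
        s = self.series
        X = sm.add_constant(s.times)
        ols = sm.OLS(s.scores, X).fit()
        rss = float(np.sum(ols.resid**2))
        n = len(s)
        return GroupOLSResults(
            group_id=s.subject_id,
            intercept=float(ols.params[0]),
            slope=float(ols.params[1]),
            se={"intercept": float(ols.bse[0]), "slope": float(ols.bse[1])},
            residual_sd=float(np.sqrt(rss / n)),
            llf=_gaussian_ml_loglik(rss, n),
            n_params=3,
            n_obs=n,
        )


def fit_multigroup_nlme(groups, random_effects="AC", **kwargs) -> NLMEResults:
    """NLME over group-mean trajectories (groups as the grouping level).

    Identical machinery to the patient-level model; with five or fewer
    groups the variance components are only weakly identified, which is
    flagged with a warning (the fit itself proceeds).
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    if len(groups) <= 5:
        warnings.warn(
            f"only {len(groups)} groups: random-effect variance components are "
            "weakly identified",
            stacklevel=2,
        )
    model = ExponentialDecayModel(groups)
    res = model.fit(random_effects=random_effects, **kwargs)
    res.name = res.name.replace("NLME", "NLME[groups]")
    return res


def compare_group_fits(series: RatingSeries) -> dict:
    """Fit both families to one trajectory and tabulate the comparison."""
    nls = GroupDecayModel(series).fit()
    ols = GroupLinearModel(series).fit()
    return {
        "group": series.subject_id,
        "decay": nls.to_dict(),
        "linear": ols.to_dict(),
        "delta_aic": nls.aic - ols.aic,
        "delta_bic": nls.bic - ols.bic,
        "preferred_aic": nls.name if nls.aic < ols.aic else ols.name,
        "preferred_bic": nls.name if nls.bic < ols.bic else ols.name,
    }
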