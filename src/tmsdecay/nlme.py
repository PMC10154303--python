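"""Maximum-likelihood mixed-effects fitting of the decay model.

Two model families share one marginal-likelihood engine:

* :class:`ExponentialDecayModel` — the nonlinear mixed-effects (NLME)
  model ``y_ij = (A + a_i) * exp(-t_ij / B_i) + (C + c_i) + e_ij`` with
  patient-level random effects on a chosen subset of {A, B, C} (the B
  effect acts on log B) and iid Gaussian residuals.
* :class:`LinearResponseModel` — the linear mixed-effects (LME)
  comparator ``y_ij = (b0 + u_i) + (b1 + v_i) * t_ij + e_ij`` with
  correlated random intercept and slope.

Random effects are integrated out of the likelihood by a Laplace
approximation around the per-subject posterior modes, computed by a
damped Gauss-Newton iteration (Lindstrom-Bates style).  When the random
subset excludes B the conditional mean is linear in the random effects,
the marginal distribution is exactly Gaussian, and a closed-form path
(GLS profiling of the fixed effects) is used; the Laplace approximation
is exact there.  The random-effect covariance is parameterized through
its log-Cholesky factor so positive semidefiniteness is automatic, and
B is always optimized on the log scale.

Model comparison (AIC/BIC deltas and the likelihood-ratio statistic)
and the nested random-effects selection rule live here too.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.tools import numdiff

from .decay import DecayParams
from .series import RatingSeries

__all__ = [
    "RandomEffectsSpec",
    "ExponentialDecayModel",
    "LinearResponseModel",
    "NLMEResults",
    "LMEResults",
    "ModelComparison",
    "compare_models",
    "select_random_effects",
    "marginal_loglik",
]

_RE_ORDER = ("A", "B", "C")
_BIG = 1e10  # objective penalty for numerically infeasible parameter points


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Which decay parameters carry patient-level random effects.

    ``which`` is a nonempty subset of {"A", "B", "C"}; the B effect is
    on the log scale.  ``covariance_structure`` is ``"unstructured"``
    (full log-Cholesky) or ``"diagonal"`` (independent effects).
    """

    which: tuple[str, ...] = ("A", "C")
    covariance_structure: str = "unstructured"

    def __post_init__(self) -> None:
        which = tuple(w for w in _RE_ORDER if w in {s.upper() for s in self.which})
        if not which:
            raise ValueError("random-effects subset must be a nonempty subset of {A, B, C}")
        object.__setattr__(self, "which", which)
        if self.covariance_structure not in ("unstructured", "diagonal"):
            raise ValueError("covariance_structure must be 'unstructured' or 'diagonal'")

    @classmethod
    def coerce(cls, value) -> "RandomEffectsSpec":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            return cls(which=tuple(value.replace(",", "").replace(" ", "")))
        return cls(which=tuple(value))

    @property
    def q(self) -> int:
        return len(self.which)

    @property
    def has_b(self) -> bool:
        return "B" in self.which

    @property
    def n_cov_params(self) -> int:
        q = self.q
        return q * (q + 1) // 2 if self.covariance_structure == "unstructured" else q

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple("log(B)" if w == "B" else w for w in self.which)


# ---------------------------------------------------------------------------
# covariance packing (log-Cholesky)

def _psi_from_packed(v: np.ndarray, q: int, structure: str) -> np.ndarray:
    if structure == "diagonal":
        return np.diag(np.exp(2.0 * v))
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(v[k]) if i == j else v[k]
            k += 1
    return L @ L.T


def _packed_from_psi(psi: np.ndarray, structure: str, floor: float = 1e-8) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    q = psi.shape[0]
    if structure == "diagonal":
        return 0.5 * np.log(np.maximum(np.diag(psi), floor))
    L = np.linalg.cholesky(psi + floor * np.eye(q))
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(max(L[i, j], floor)) if i == j else L[i, j])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# cohort bookkeeping

def _group_patterns(cohort: Sequence[RatingSeries]):
    """Group subjects sharing an identical visit schedule for vectorized work."""
    groups: dict[tuple, list[int]] = {}
    for idx, s in enumerate(cohort):
        groups.setdefault(tuple(np.round(s.times, 10)), []).append(idx)
    out = []
    for key, idxs in groups.items():
        t = np.asarray(key, dtype=float)
        Y = np.vstack([cohort[i].scores for i in idxs])
        out.append((t, Y, np.asarray(idxs)))
    return out


def _obs_fingerprint(cohort: Sequence[RatingSeries]) -> str:
    rows = sorted(
        (s.subject_id, float(t), float(y))
        for s in cohort
        for t, y in zip(s.times, s.scores)
    )
    return hashlib.sha256(repr(rows).encode()).hexdigest()


# ---------------------------------------------------------------------------
# exact marginal likelihood when the conditional mean is linear in the REs

def _linear_nll(theta, patterns, design, re_cols, q, structure, n_extra, beta=None):
    """Gaussian marginal negative log-likelihood, optionally GLS-profiling beta.

    ``theta`` is ``[extra..., cov-params..., log sigma]`` when ``beta``
    is given, else the fixed effects are profiled out by GLS.  ``design``
    maps (times, extra) to the fixed-effect design matrix whose columns
    ``re_cols`` carry the random effects.  Returns ``(nll, beta)``.
    """
    extra = theta[:n_extra]
    v = theta[n_extra:n_extra + (q * (q + 1) // 2 if structure == "unstructured" else q)]
    sigma2 = np.exp(2.0 * theta[-1])
    psi = _psi_from_packed(v, q, structure)
    try:
        cache = []
        xtvx = None
        xtvy = None
        for t, Y, _ in patterns:
            X = design(t, extra)
            Z = X[:, re_cols]
            V = Z @ psi @ Z.T + sigma2 * np.eye(t.size)
            cho = linalg.cho_factor(V, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            ViX = linalg.cho_solve(cho, X)
            m = Y.shape[0]
            if beta is None:
                p = X.shape[1]
                if xtvx is None:
                    xtvx, xtvy = np.zeros((p, p)), np.zeros(p)
                xtvx += m * (X.T @ ViX)
                xtvy += ViX.T @ Y.sum(axis=0)
            cache.append((X, Y, cho, logdet, m))
        b = np.linalg.solve(xtvx, xtvy) if beta is None else np.asarray(beta, dtype=float)
        nll = 0.0
        for X, Y, cho, logdet, m in cache:
            R = Y - (X @ b)[None, :]
            quad = float(np.sum(R * linalg.cho_solve(cho, R.T).T))
            nll += 0.5 * (m * t_size(X) * np.log(2.0 * np.pi) + m * logdet + quad)
        if not np.isfinite(nll):
            return _BIG, b
        return nll, b
    except (np.linalg.LinAlgError, ValueError):
        return _BIG, None


def t_size(X: np.ndarray) -> int:
    return X.shape[0]


def _decay_design(t: np.ndarray, extra) -> np.ndarray:
    b = np.exp(np.clip(extra[0], -30.0, 30.0))
    return np.column_stack([np.exp(-t / b), np.ones_like(t)])


def _lme_design(t: np.ndarray, extra) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t])


_SIGMA2_FLOOR = 1e-24


def _profiled_linear_nll(theta, patterns, design, re_cols, q, structure, n_extra):
    """Exact marginal nll with beta GLS-profiled and sigma^2 profiled out.

    The random-effect covariance is parameterized *relative* to the
    residual variance (Psi = sigma^2 G, lme4-style), which removes the
    ill-conditioned joint sigma/Psi valley near degenerate fits.
    ``theta`` is ``[extra..., packed G]``.  Returns
    ``(nll, beta, sigma2, G)``.
    """
    extra = theta[:n_extra]
    G = _psi_from_packed(theta[n_extra:], q, structure)
    try:
        cache = []
        xtvx = None
        xtvy = None
        n_total = 0
        logdet_total = 0.0
        for t, Y, _ in patterns:
            X = design(t, extra)
            Z = X[:, re_cols]
            V0 = Z @ G @ Z.T + np.eye(t.size)
            cho = linalg.cho_factor(V0, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            ViX = linalg.cho_solve(cho, X)
            m = Y.shape[0]
            p = X.shape[1]
            if xtvx is None:
                xtvx, xtvy = np.zeros((p, p)), np.zeros(p)
            xtvx += m * (X.T @ ViX)
            xtvy += ViX.T @ Y.sum(axis=0)
            n_total += m * t.size
            logdet_total += m * logdet
            cache.append((X, Y, cho))
        beta = np.linalg.solve(xtvx, xtvy)
        quad = 0.0
        for X, Y, cho in cache:
            R = Y - (X @ beta)[None, :]
            quad += float(np.sum(R * linalg.cho_solve(cho, R.T).T))
        sigma2 = max(quad / n_total, _SIGMA2_FLOOR)
        nll = 0.5 * (
            n_total * np.log(2.0 * np.pi * sigma2) + logdet_total + quad / sigma2
        )
        if not np.isfinite(nll):
            return _BIG, None, None, None
        return nll, beta, sigma2, G
    except (np.linalg.LinAlgError, ValueError):
        return _BIG, None, None, None


def _profiled_laplace_nll(theta, stacked, re_cols, q, structure,
                          mode_cache=None, return_state=False):
    """Laplace marginal nll with sigma^2 profiled out (Psi = sigma^2 G).

    The inner penalized least-squares problem is sigma-free: the modes
    minimize ``rss + b' G^-1 b``.  ``theta`` is ``[A, logB, C, packed G]``.
    """
    T, Y, W = stacked
    beta = theta[:3]
    G = _psi_from_packed(theta[3:], q, structure)
    try:
        cho = linalg.cho_factor(G, lower=True)
    except np.linalg.LinAlgError:
        return (_BIG, None, None, None) if return_state else _BIG
    logdet_g = 2.0 * np.sum(np.log(np.diag(cho[0])))
    g_inv = linalg.cho_solve(cho, np.eye(q))
    b0 = mode_cache.get("modes") if mode_cache is not None else None
    found = _find_modes(T, Y, W, beta, g_inv, 1.0, re_cols, b0=b0)
    if found is None:
        return (_BIG, None, None, None) if return_state else _BIG
    b, obj, H0 = found
    if mode_cache is not None:
        mode_cache["modes"] = b
    sign, logdet_h = np.linalg.slogdet(H0)
    if np.any(sign <= 0):
        return (_BIG, None, None, None) if return_state else _BIG
    m = Y.shape[0]
    n_total = float(W.sum())
    sigma2 = max(2.0 * float(np.sum(obj)) / n_total, _SIGMA2_FLOOR)
    nll = float(
        0.5 * n_total * np.log(2.0 * np.pi * sigma2)
        + np.sum(obj) / sigma2
        + 0.5 * m * logdet_g
        + 0.5 * np.sum(logdet_h)
    )
    if not np.isfinite(nll):
        return (_BIG, None, None, None) if return_state else _BIG
    return (nll, b, sigma2, G) if return_state else nll


# ---------------------------------------------------------------------------
# Laplace path (random effect on log B present)


def _stack_cohort(cohort: Sequence[RatingSeries]):
    """Pad all subjects to a common visit count; W masks real observations."""
    m = len(cohort)
    nmax = max(len(s) for s in cohort)
    T = np.zeros((m, nmax))
    Y = np.zeros((m, nmax))
    W = np.zeros((m, nmax))
    for i, s in enumerate(cohort):
        n = len(s)
        T[i, :n] = s.times
        Y[i, :n] = s.scores
        W[i, :n] = 1.0
    return T, Y, W


def _curve_parts(T, beta, b, re_cols):
    m = b.shape[0]
    A = np.full(m, beta[0])
    lB = np.full(m, beta[1])
    C = np.full(m, beta[2])
    for j, col in enumerate(re_cols):
        if col == 0:
            A = A + b[:, j]
        elif col == 1:
            lB = lB + b[:, j]
        else:
            C = C + b[:, j]
    B = np.exp(np.clip(lB, -30.0, 30.0))
    E = np.exp(-T / B[:, None])
    f = A[:, None] * E + C[:, None]
    return f, A, B, E


def _jacobian(T, A, B, E, W, re_cols):
    cols = []
    for col in re_cols:
        if col == 0:
            cols.append(E * W)
        elif col == 1:
            cols.append(A[:, None] * E * (T / B[:, None]) * W)
        else:
            cols.append(W)
    return np.stack(cols, axis=2)


def _find_modes(T, Y, W, beta, psi_inv, sigma2, re_cols, b0=None, max_iter=200,
                tol=1e-10):
    """Batched damped Gauss-Newton search for the per-subject posterior modes."""
    m = Y.shape[0]
    q = len(re_cols)
    b = np.zeros((m, q)) if b0 is None else np.array(b0, dtype=float)

    def evaluate(bb):
        f, A, B, E = _curve_parts(T, beta, bb, re_cols)
        r = (Y - f) * W
        obj = 0.5 * np.sum(r * r, axis=1) / sigma2 + 0.5 * np.einsum(
            "ij,jk,ik->i", bb, psi_inv, bb
        )
        return obj, r, A, B, E

    obj, r, A, B, E = evaluate(b)
    for _ in range(max_iter):
        J = _jacobian(T, A, B, E, W, re_cols)
        H = np.einsum("inq,inp->iqp", J, J) / sigma2 + psi_inv[None, :, :]
        g = -np.einsum("inq,in->iq", J, r) / sigma2 + b @ psi_inv
        try:
            delta = -np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return None
        if float(np.max(np.abs(delta))) < tol:
            break
        step = np.ones(m)
        for _ in range(20):
            b_new = b + step[:, None] * delta
            obj_new, r_new, A_new, B_new, E_new = evaluate(b_new)
            bad = ~(obj_new <= obj + 1e-12)
            if not bad.any():
                break
            step[bad] *= 0.5
        if bad.any():
            # revert subjects the damped step could not improve
            step[bad] = 0.0
            b_new = b + step[:, None] * delta
            obj_new, r_new, A_new, B_new, E_new = evaluate(b_new)
        moved = float(np.max(np.abs(step[:, None] * delta)))
        b, obj, r, A, B, E = b_new, obj_new, r_new, A_new, B_new, E_new
        if moved < tol:
            break
    J = _jacobian(T, A, B, E, W, re_cols)
    H = np.einsum("inq,inp->iqp", J, J) / sigma2 + psi_inv[None, :, :]
    return b, obj, H


def _laplace_nll(theta, stacked, re_cols, q, structure, return_modes=False,
                 mode_cache=None):
    """Laplace-approximate marginal negative log-likelihood (full parameters).

    ``stacked`` is the padded (T, Y, W) cohort representation.  A
    ``mode_cache`` dict warm-starts the inner Gauss-Newton searches
    across nearby evaluations during optimization.
    """
    T, Y, W = stacked
    ncov = q * (q + 1) // 2 if structure == "unstructured" else q
    beta = theta[:3]
    psi = _psi_from_packed(theta[3:3 + ncov], q, structure)
    sigma2 = np.exp(2.0 * theta[-1])
    try:
        cho = linalg.cho_factor(psi, lower=True)
    except np.linalg.LinAlgError:
        return (_BIG, None) if return_modes else _BIG
    logdet_psi = 2.0 * np.sum(np.log(np.diag(cho[0])))
    psi_inv = linalg.cho_solve(cho, np.eye(q))
    b0 = mode_cache.get("modes") if mode_cache is not None else None
    found = _find_modes(T, Y, W, beta, psi_inv, sigma2, re_cols, b0=b0)
    if found is None:
        return (_BIG, None) if return_modes else _BIG
    b, obj, H = found
    if mode_cache is not None:
        mode_cache["modes"] = b
    sign, logdet_h = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        return (_BIG, None) if return_modes else _BIG
    m = Y.shape[0]
    n_total = float(W.sum())
    nll = float(
        np.sum(obj)
        + 0.5 * n_total * np.log(2.0 * np.pi * sigma2)
        + 0.5 * m * logdet_psi
        + 0.5 * np.sum(logdet_h)
    )
    if not np.isfinite(nll):
        return (_BIG, None) if return_modes else _BIG
    return (nll, b) if return_modes else nll


# ---------------------------------------------------------------------------
# starting values (deterministic)

def _start_values(cohort: Sequence[RatingSeries]):
    firsts = np.array([s.baseline for s in cohort])
    lasts = np.array([s.final for s in cohort])
    c0 = float(lasts.mean())
    a0 = float(firsts.mean() - lasts.mean())
    best_b, best_rss = 1.0, np.inf
    for b in (0.5, 1.0, 2.0, 4.0):
        rss = sum(
            float(np.sum((s.scores - (a0 * np.exp(-s.times / b) + c0)) ** 2))
            for s in cohort
        )
        if rss < best_rss:
            best_b, best_rss = b, rss
    n_obs = sum(len(s) for s in cohort)
    sigma0 = max(0.3, np.sqrt(best_rss / n_obs) / 2.0)
    var_a = max(np.var(firsts - lasts, ddof=1) if len(cohort) > 1 else 1.0, 1e-2)
    var_c = max(np.var(lasts, ddof=1) if len(cohort) > 1 else 1.0, 1e-2)
    return a0, float(np.log(best_b)), c0, float(var_a), float(var_c), float(sigma0)


def _start_psi(spec: RandomEffectsSpec, var_a: float, var_c: float) -> np.ndarray:
    diag = {"A": var_a, "B": 0.04, "C": var_c}
    return np.diag([diag[w] for w in spec.which])


# ---------------------------------------------------------------------------
# results containers


def _wald(est, se):
    z = est / se if se and np.isfinite(se) and se > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return z, p


@dataclass
class NLMEResults:
    """Fitted nonlinear mixed-effects decay model.

    AIC and BIC follow the identities ``-2 llf + 2 k`` and
    ``-2 llf + k log(n_obs)`` with ``k`` counting fixed effects,
    covariance parameters and the residual sd.
    """

    fixed: DecayParams
    fixed_se: dict
    pvalues: dict
    re_spec: RandomEffectsSpec
    re_covariance: pd.DataFrame
    residual_sd: float
    llf: float
    n_params: int
    n_obs: int
    n_subjects: int
    subject_estimates: pd.DataFrame
    converged: bool
    message: str = ""
    name: str = "NLME(exponential decay)"
    obs_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.llf + 2.0 * self.n_params
        self.bic = -2.0 * self.llf + self.n_params * np.log(self.n_obs)
        psi = self.re_covariance.to_numpy()
        if np.min(np.linalg.eigvalsh((psi + psi.T) / 2.0)) < -1e-8:
            raise ValueError("random-effect covariance is not positive semidefinite")
        if self.residual_sd <= 0:
            raise ValueError("residual sd must be positive")

    @property
    def loglik(self) -> float:
        return self.llf

    def predict(self, t, subject_id: str | None = None):
        """Population curve, or a subject's empirical-Bayes curve."""
        from .decay import predict_score

        if subject_id is None:
            return predict_score(self.fixed, t)
        row = self.subject_estimates.set_index("subject_id").loc[subject_id]
        return predict_score(
            DecayParams(row["amplitude"], row["time_constant"], row["floor"]), t
        )

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "random_effects": list(self.re_spec.which),
            "covariance_structure": self.re_spec.covariance_structure,
            "fixed": {
                "amplitude": self.fixed.amplitude,
                "time_constant": self.fixed.time_constant,
                "floor": self.fixed.floor,
            },
            "fixed_se": self.fixed_se,
            "pvalues": self.pvalues,
            "re_covariance": self.re_covariance.to_dict(),
            "residual_sd": self.residual_sd,
            "loglik": self.llf,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "aic": self.aic,
            "bic": self.bic,
            "converged": bool(self.converged),
            "message": self.message,
        }

    def summary(self) -> str:
        f, se, p = self.fixed, self.fixed_se, self.pvalues
        lines = [
            f"{self.name}  [random effects: {', '.join(self.re_spec.which)}; "
            f"{self.re_spec.covariance_structure}]",
            f"  subjects: {self.n_subjects}   observations: {self.n_obs}   "
            f"converged: {self.converged}",
            f"  loglik: {self.llf:.3f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            "  fixed effects (est, se, p):",
            f"    amplitude A      {f.amplitude:9.3f}  {se.get('amplitude', np.nan):8.3f}"
            f"  {p.get('amplitude', np.nan):.2e}",
            f"    time constant B  {f.time_constant:9.3f}  "
            f"{se.get('time_constant', np.nan):8.3f}  {p.get('time_constant', np.nan):.2e}",
            f"    floor C          {f.floor:9.3f}  {se.get('floor', np.nan):8.3f}"
            f"  {p.get('floor', np.nan):.2e}",
            f"  residual sd: {self.residual_sd:.3f}",
            "  random-effect covariance:",
        ]
        lines += [
            "    " + line for line in self.re_covariance.round(4).to_string().splitlines()
        ]
        return "\n".join(lines)

    def plot(self, subject_ids=None, ax=None):
        """Observed points and fitted curves for a handful of subjects."""
        import matplotlib.pyplot as plt

        est = self.subject_estimates.set_index("subject_id")
        if subject_ids is None:
            subject_ids = list(est.index[:9])
        if ax is None:
            _, ax = plt.subplots()
        tgrid = np.linspace(0, float(self._times_max), 100)
        for sid in subject_ids:
            obs = self._observations[sid]
            pts = ax.plot(obs[0], obs[1], "o", mfc="none")
            ax.plot(tgrid, self.predict(tgrid, sid), color=pts[0].get_color())
        ax.set_xlabel("weeks of treatment")
        ax.set_ylabel("symptom score")
        return ax

    # populated by the model, used only for plotting
    _observations: dict = field(default_factory=dict, repr=False)
    _times_max: float = 6.0


@dataclass
class LMEResults:
    """Fitted linear mixed-effects comparator (random intercept and slope)."""

    intercept: float
    slope: float
    fixed_se: dict
    pvalues: dict
    re_covariance: pd.DataFrame
    residual_sd: float
    llf: float
    n_params: int
    n_obs: int
    n_subjects: int
    converged: bool
    message: str = ""
    name: str = "LME(linear trend)"
    obs_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.llf + 2.0 * self.n_params
        self.bic = -2.0 * self.llf + self.n_params * np.log(self.n_obs)
        if self.residual_sd <= 0:
            raise ValueError("residual sd must be positive")

    @property
    def loglik(self) -> float:
        return self.llf

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "intercept": self.intercept,
            "slope": self.slope,
            "fixed_se": self.fixed_se,
            "pvalues": self.pvalues,
            "re_covariance": self.re_covariance.to_dict(),
            "residual_sd": self.residual_sd,
            "loglik": self.llf,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "converged": bool(self.converged),
            "message": self.message,
        }

    def summary(self) -> str:
        lines = [
            f"{self.name}",
            f"  subjects: {self.n_subjects}   observations: {self.n_obs}   "
            f"converged: {self.converged}",
            f"  loglik: {self.llf:.3f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            f"  intercept: {self.intercept:.3f} (se {self.fixed_se.get('intercept', np.nan):.3f})"
            f"   slope: {self.slope:.3f}/week (se {self.fixed_se.get('slope', np.nan):.3f})",
            f"  residual sd: {self.residual_sd:.3f}",
            "  random-effect covariance:",
        ]
        lines += [
            "    " + line for line in self.re_covariance.round(4).to_string().splitlines()
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model classes


class ExponentialDecayModel:
    """Nonlinear mixed-effects exponential-decay model of a cohort.

    Parameters
    ----------
    cohort : sequence of RatingSeries
        At least two subjects rated on a common scale.

    Examples
    --------
    >>> from tmsdecay import CohortConfig, generate_cohort
    >>> model = ExponentialDecayModel(generate_cohort(CohortConfig(seed=1)))
    >>> res = model.fit(random_effects="AC")
    >>> round(res.fixed.time_constant, 1)  # doctest: +SKIP
    1.2
    """

    def __init__(self, cohort: Sequence[RatingSeries]):
        cohort = list(cohort)
        if len(cohort) < 2:
            raise ValueError("at least 2 subjects are required for a mixed-effects fit")
        scales = {s.scale.name for s in cohort}
        if len(scales) > 1:
            raise ValueError(f"cohort mixes rating scales: {sorted(scales)}")
        self.cohort = cohort
        self.scale = cohort[0].scale
        self.patterns = _group_patterns(cohort)
        self.stacked = _stack_cohort(cohort)
        self.n_obs = sum(len(s) for s in cohort)
        self.obs_fingerprint = _obs_fingerprint(cohort)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale=None, time_unit: str = "weeks"):
        """Build from a long-format table (subject_id, time, score[, scale])."""
        from .io import frame_to_cohort

        return cls(frame_to_cohort(df, scale=scale, time_unit=time_unit))

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        random_effects="AC",
        covariance_structure: str = "unstructured",
        start: NLMEResults | None = None,
        allow_fallback: bool = True,
    ) -> NLMEResults:
        """Maximize the (Laplace) marginal likelihood.

        ``start`` warm-starts the optimizer from a previous fit on
        similar data (used by cross-validation).  If an unstructured
        random-effect covariance comes back singular the fit is retried
        with a diagonal structure (with a warning) unless
        ``allow_fallback`` is false.
        """
        spec = RandomEffectsSpec.coerce(random_effects)
        if covariance_structure != "unstructured":
            spec = RandomEffectsSpec(spec.which, covariance_structure)
        res = self._fit_spec(spec, start)
        psi = res.re_covariance.to_numpy()
        if (
            allow_fallback
            and spec.covariance_structure == "unstructured"
            and spec.q > 1
            and _is_singular(psi)
        ):
            warnings.warn(
                "estimated random-effect covariance is singular; refitting with a "
                "diagonal structure",
                stacklevel=2,
            )
            res = self._fit_spec(RandomEffectsSpec(spec.which, "diagonal"), start)
            res.message = (res.message + " (diagonal fallback)").strip()
        return res

    def _fit_spec(self, spec: RandomEffectsSpec, start) -> NLMEResults:
        a0, logb0, c0, var_a, var_c, sigma0 = _start_values(self.cohort)
        psi0 = _start_psi(spec, var_a, var_c)
        if start is not None:
            a0 = start.fixed.amplitude
            logb0 = float(np.log(start.fixed.time_constant))
            c0 = start.fixed.floor
            sigma0 = max(start.residual_sd, 1e-4)
            if tuple(start.re_spec.which) == spec.which:
                psi0 = start.re_covariance.to_numpy() + 1e-6 * np.eye(spec.q)
        # covariance optimized relative to the residual variance (Psi = sigma^2 G)
        packed0 = _packed_from_psi(psi0 / sigma0**2, spec.covariance_structure)
        re_cols_full = [_RE_ORDER.index(w) for w in spec.which]

        if spec.has_b:
            theta0 = np.r_[[a0, logb0, c0], packed0]
            bounds = [(-1e4, 1e4), (-7.0, 7.0), (-1e4, 1e4)] + _cov_bounds(spec)
            cache: dict = {}
            fun = lambda th: _profiled_laplace_nll(
                th, self.stacked, re_cols_full, spec.q, spec.covariance_structure,
                mode_cache=cache,
            )
            opt = _minimize_restarting(
                fun, theta0, bounds,
                {"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8, "eps": 1e-7},
            )
            nll, modes, sigma2, G = _profiled_laplace_nll(
                opt.x, self.stacked, re_cols_full, spec.q, spec.covariance_structure,
                return_state=True,
            )
            beta = opt.x[:3]
        else:
            # conditionally linear: exact marginal likelihood, (A, C) and
            # sigma^2 profiled out
            lin_cols = [0 if w == "A" else 1 for w in spec.which]
            theta0 = np.r_[[logb0], packed0]
            bounds = [(-7.0, 7.0)] + _cov_bounds(spec)
            fun = lambda th: _profiled_linear_nll(
                th, self.patterns, _decay_design, lin_cols, spec.q,
                spec.covariance_structure, 1,
            )[0]
            opt = _minimize_restarting(
                fun, theta0, bounds, {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8}
            )
            nll, beta_ac, sigma2, G = _profiled_linear_nll(
                opt.x, self.patterns, _decay_design, lin_cols, spec.q,
                spec.covariance_structure, 1,
            )
            beta = np.array([beta_ac[0], opt.x[0], beta_ac[1]])  # (A, logB, C)
            modes = self._linear_modes(opt.x[0], lin_cols, spec, G, beta_ac)

        if G is None or sigma2 is None:
            raise RuntimeError(
                f"NLME fit failed numerically (RE={{{','.join(spec.which)}}}): "
                f"{opt.message}"
            )
        psi = sigma2 * G
        theta_full = np.r_[
            beta, _packed_from_psi(psi, spec.covariance_structure),
            [0.5 * np.log(sigma2)],
        ]
        converged = bool(opt.success) and nll < _BIG / 2
        if not converged:
            warnings.warn(
                f"NLME fit did not converge: {opt.message} (status {opt.status})",
                stacklevel=3,
            )
        sigma = float(np.sqrt(sigma2))
        fixed = DecayParams(float(beta[0]), float(np.exp(beta[1])), float(beta[2]))
        se, pv = self._wald_stats(theta_full, spec, re_cols_full)
        subj = self._subject_table(fixed, modes, spec)
        res = NLMEResults(
            fixed=fixed,
            fixed_se=se,
            pvalues=pv,
            re_spec=spec,
            re_covariance=pd.DataFrame(psi, index=spec.labels, columns=spec.labels),
            residual_sd=sigma,
            llf=float(-nll),
            n_params=3 + spec.n_cov_params + 1,
            n_obs=self.n_obs,
            n_subjects=len(self.cohort),
            subject_estimates=subj,
            converged=converged,
            message="" if converged else str(opt.message),
            name=f"NLME(exponential decay, RE={{{','.join(spec.which)}}})",
            obs_fingerprint=self.obs_fingerprint,
        )
        res._observations = {s.subject_id: (s.times, s.scores) for s in self.cohort}
        res._times_max = max(s.final_time for s in self.cohort)
        return res

    def _linear_modes(self, logb, lin_cols, spec, G, beta_ac):
        """Posterior means of the random effects on the exact-linear path.

        Uses the relative covariance G: Psi Z' V^-1 = G Z' (Z G Z' + I)^-1.
        """
        modes = np.zeros((len(self.cohort), spec.q))
        if G is None:
            return modes
        for t, Y, idx in self.patterns:
            X = _decay_design(t, [logb])
            Z = X[:, lin_cols]
            V0 = Z @ G @ Z.T + np.eye(t.size)
            R = Y - (X @ beta_ac)[None, :]
            bhat = (G @ Z.T @ np.linalg.solve(V0, R.T)).T
            modes[idx] = bhat
        return modes

    def _subject_table(self, fixed: DecayParams, modes, spec) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.cohort):
            b = modes[i] if modes is not None else None
            a, lb, c = fixed.amplitude, np.log(fixed.time_constant), fixed.floor
            if b is not None:
                for j, w in enumerate(spec.which):
                    if w == "A":
                        a += b[j]
                    elif w == "B":
                        lb += b[j]
                    else:
                        c += b[j]
            rows.append((s.subject_id, a, float(np.exp(lb)), c))
        return pd.DataFrame(
            rows, columns=["subject_id", "amplitude", "time_constant", "floor"]
        )

    def _wald_stats(self, theta_full, spec, re_cols_full):
        """Wald standard errors/p-values from the observed information."""
        se = {k: np.nan for k in ("amplitude", "time_constant", "floor")}
        pv = dict(se)
        try:
            if spec.has_b:
                cache: dict = {}
                fun = lambda th: _laplace_nll(
                    th, self.stacked, re_cols_full, spec.q, spec.covariance_structure,
                    mode_cache=cache,
                )
            else:
                lin_cols = [0 if w == "A" else 1 for w in spec.which]

                def fun(th):
                    beta = np.array([th[0], th[2]])
                    rest = np.r_[th[1:2], th[3:]]
                    return _linear_nll(
                        rest, self.patterns, _decay_design, lin_cols, spec.q,
                        spec.covariance_structure, 1, beta=beta,
                    )[0]

                # reorder to (A, logB, C, ...) for a common interface
                fun_full = fun
                fun = lambda th: fun_full(th)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hess = numdiff.approx_hess(theta_full, fun)
                cov = np.linalg.pinv((hess + hess.T) / 2.0)
            var = np.diag(cov)
            if np.all(var[:3] > 0):
                b_est = float(np.exp(theta_full[1]))
                se = {
                    "amplitude": float(np.sqrt(var[0])),
                    "time_constant": float(b_est * np.sqrt(var[1])),  # delta method
                    "floor": float(np.sqrt(var[2])),
                }
                # Wald tests against 0 on the natural scale (delta method for B)
                est = {
                    "amplitude": theta_full[0],
                    "time_constant": b_est,
                    "floor": theta_full[2],
                }
                pv = {k: _wald(est[k], se[k])[1] for k in est}
        except (np.linalg.LinAlgError, ValueError):
            pass
        return se, pv

    def loglik(self, fixed: DecayParams, re_covariance, residual_sd,
               random_effects="AC") -> float:
        """Marginal log-likelihood at given parameter values (no fitting)."""
        return marginal_loglik(
            self.cohort, fixed, re_covariance, residual_sd, random_effects
        )


def _minimize_restarting(fun, x0, bounds, options, n_restarts: int = 2):
    """L-BFGS-B with restart-on-abort.

    A line-search abort at a variance boundary is rechecked by
    restarting from the stopping point (which resets the Hessian
    memory); if no meaningful progress is possible (relative objective
    change below 1e-8) the point is accepted as converged.
    """
    opt = optimize.minimize(
        fun, x0, method="L-BFGS-B", bounds=bounds, options=options
    )
    for _ in range(n_restarts):
        if opt.success:
            return opt
        opt2 = optimize.minimize(
            fun, opt.x, method="L-BFGS-B", bounds=bounds, options=options
        )
        if opt.fun - opt2.fun < 1e-8 * max(1.0, abs(opt.fun)):
            best = opt2 if opt2.fun <= opt.fun else opt
            best.success = True
            return best
        opt = opt2
    return opt


def _cov_bounds(spec: RandomEffectsSpec):
    if spec.covariance_structure == "diagonal":
        return [(-12.0, 12.0)] * spec.q
    out = []
    for i in range(spec.q):
        for j in range(i + 1):
            out.append((-12.0, 12.0) if i == j else (-50.0, 50.0))
    return out


def _is_singular(psi: np.ndarray, tol: float = 1e-6) -> bool:
    d = np.sqrt(np.diag(psi))
    if np.any(d <= 1e-8 * max(d.max(), 1.0)):
        return True
    corr = psi / np.outer(d, d)
    off = corr[~np.eye(psi.shape[0], dtype=bool)]
    return bool(off.size and np.max(np.abs(off)) > 1.0 - tol)


class LinearResponseModel:
    """Linear mixed-effects comparator: score ~ intercept + slope * weeks.

    Random intercept and slope are correlated across patients; the
    marginal likelihood is the exact multivariate-Gaussian density and
    is maximized with the fixed effects profiled out by GLS.
    """

    def __init__(self, cohort: Sequence[RatingSeries]):
        cohort = list(cohort)
        if len(cohort) < 2:
            raise ValueError("at least 2 subjects are required for a mixed-effects fit")
        self.cohort = cohort
        self.patterns = _group_patterns(cohort)
        self.n_obs = sum(len(s) for s in cohort)
        self.obs_fingerprint = _obs_fingerprint(cohort)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale=None, time_unit: str = "weeks"):
        from .io import frame_to_cohort

        return cls(frame_to_cohort(df, scale=scale, time_unit=time_unit))

    def fit(self, covariance_structure: str = "unstructured") -> LMEResults:
        spec = RandomEffectsSpec(("A", "C"), covariance_structure)  # 2-d RE bookkeeping
        firsts = np.array([s.baseline for s in self.cohort])
        slopes = np.array(
            [(s.final - s.baseline) / max(s.final_time, 1e-6) for s in self.cohort]
        )
        var_i = max(np.var(firsts, ddof=1), 1e-2)
        var_s = max(np.var(slopes, ddof=1), 1e-2)
        sigma0 = max(0.5, float(np.std(np.concatenate([s.scores for s in self.cohort])) / 4))
        # relative covariance (Psi = sigma^2 G); sigma and beta profiled out
        theta0 = _packed_from_psi(
            np.diag([var_i, var_s]) / sigma0**2, covariance_structure
        )
        bounds = _cov_bounds(spec)
        fun = lambda th: _profiled_linear_nll(
            th, self.patterns, _lme_design, [0, 1], 2, covariance_structure, 0
        )[0]
        opt = _minimize_restarting(
            fun, theta0, bounds, {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8}
        )
        nll, beta, sigma2, G = _profiled_linear_nll(
            opt.x, self.patterns, _lme_design, [0, 1], 2, covariance_structure, 0
        )
        if G is None or sigma2 is None:
            raise RuntimeError(f"LME fit failed numerically: {opt.message}")
        converged = bool(opt.success) and nll < _BIG / 2
        if not converged:
            warnings.warn(
                f"LME fit did not converge: {opt.message} (status {opt.status})",
                stacklevel=2,
            )
        psi = sigma2 * G
        sigma = float(np.sqrt(sigma2))
        theta_abs = np.r_[
            beta, _packed_from_psi(psi, covariance_structure), [0.5 * np.log(sigma2)]
        ]
        se, pv = self._wald_stats(theta_abs, covariance_structure)
        labels = ("intercept", "slope")
        return LMEResults(
            intercept=float(beta[0]),
            slope=float(beta[1]),
            fixed_se=se,
            pvalues=pv,
            re_covariance=pd.DataFrame(psi, index=labels, columns=labels),
            residual_sd=sigma,
            llf=float(-nll),
            n_params=2 + spec.n_cov_params + 1,
            n_obs=self.n_obs,
            n_subjects=len(self.cohort),
            converged=converged,
            message="" if converged else str(opt.message),
            obs_fingerprint=self.obs_fingerprint,
        )

    def _wald_stats(self, theta_full, structure):
        se = {"intercept": np.nan, "slope": np.nan}
        pv = dict(se)
        try:
            def fun(th):
                return _linear_nll(
                    th[2:], self.patterns, _lme_design, [0, 1], 2, structure, 0,
                    beta=th[:2],
                )[0]

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hess = numdiff.approx_hess(theta_full, fun)
                cov = np.linalg.pinv((hess + hess.T) / 2.0)
            var = np.diag(cov)[:2]
            if np.all(var > 0):
                se = {"intercept": float(np.sqrt(var[0])), "slope": float(np.sqrt(var[1]))}
                pv = {
                    "intercept": _wald(theta_full[0], se["intercept"])[1],
                    "slope": _wald(theta_full[1], se["slope"])[1],
                }
        except (np.linalg.LinAlgError, ValueError):
            pass
        return se, pv


# ---------------------------------------------------------------------------
# standalone likelihood evaluation (oracle hooks, diagnostics)


def marginal_loglik(cohort, fixed: DecayParams, re_covariance, residual_sd,
                    random_effects="AC") -> float:
    """Marginal log-likelihood of a cohort at given population parameters.

    Random effects on the given subset are integrated out (exactly when
    the subset excludes B, by Laplace approximation otherwise).  Pass a
    zero covariance to recover the independent-errors nonlinear
    least-squares Gaussian likelihood.
    """
    spec = RandomEffectsSpec.coerce(random_effects)
    psi = np.atleast_2d(np.asarray(re_covariance, dtype=float))
    if psi.shape != (spec.q, spec.q):
        raise ValueError(f"re_covariance must be {spec.q}x{spec.q} for subset {spec.which}")
    patterns = _group_patterns(list(cohort))
    sigma2 = float(residual_sd) ** 2
    if sigma2 <= 0:
        raise ValueError("residual_sd must be positive")
    beta = np.array([fixed.amplitude, np.log(fixed.time_constant), fixed.floor])
    if spec.has_b:
        psi_reg = psi + 1e-12 * np.eye(spec.q)
        theta = np.r_[
            beta, _packed_from_psi(psi_reg, "unstructured", floor=1e-12),
            [0.5 * np.log(sigma2)],
        ]
        re_cols = [_RE_ORDER.index(w) for w in spec.which]
        nll = _laplace_nll(theta, _stack_cohort(list(cohort)), re_cols, spec.q,
                           "unstructured")
    else:
        lin_cols = [0 if w == "A" else 1 for w in spec.which]
        nll = 0.0
        for t, Y, _ in patterns:
            X = _decay_design(t, beta[1:2])
            Z = X[:, lin_cols]
            V = Z @ psi @ Z.T + sigma2 * np.eye(t.size)
            cho = linalg.cho_factor(V, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            R = Y - (X @ beta[[0, 2]])[None, :]
            quad = float(np.sum(R * linalg.cho_solve(cho, R.T).T))
            m = Y.shape[0]
            nll += 0.5 * (m * t.size * np.log(2.0 * np.pi) + m * logdet + quad)
    return float(-nll)


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio and information-criterion comparison of two fits.

    ``lrt_stat = 2 (llf_full - llf_reduced)`` is reported as computed
    (it can be negative when the nominally larger model fits worse);
    the chi-square reference uses the parameter-count difference as
    degrees of freedom.
    """

    name_full: str
    name_reduced: str
    lrt_stat: float
    df: int
    p_value: float
    delta_aic: float
    delta_bic: float
    preferred: dict
    nested: bool = True

    def summary(self) -> str:
        note = "" if self.nested else "  [non-nested: LRT is heuristic; prefer AIC/BIC]"
        return (
            f"{self.name_full} vs {self.name_reduced}{note}\n"
            f"  LRT = {self.lrt_stat:.2f}  df = {self.df}  p = {self.p_value:.3g}\n"
            f"  delta AIC = {self.delta_aic:.2f}  delta BIC = {self.delta_bic:.2f}\n"
            f"  preferred: AIC -> {self.preferred['aic']}, BIC -> {self.preferred['bic']}, "
            f"LRT -> {self.preferred['lrt']}"
        )

    def to_dict(self) -> dict:
        return {
            "full": self.name_full,
            "reduced": self.name_reduced,
            "lrt_stat": self.lrt_stat,
            "df": self.df,
            "p_value": self.p_value,
            "delta_aic": self.delta_aic,
            "delta_bic": self.delta_bic,
            "preferred": self.preferred,
            "nested": self.nested,
        }


def compare_models(fit_full, fit_reduced) -> ModelComparison:
    """Compare two fits of the same observations by LRT, AIC and BIC.

    ``fit_full`` should be the model with more parameters.  Comparing an
    NLME with an LME emits a non-nestedness warning — the LRT is then a
    heuristic and AIC/BIC carry the comparison.
    """
    if fit_full.n_obs != fit_reduced.n_obs or (
        fit_full.obs_fingerprint
        and fit_reduced.obs_fingerprint
        and fit_full.obs_fingerprint != fit_reduced.obs_fingerprint
    ):
        raise ValueError("fits must be computed on the identical observation set")
    nested = type(fit_full) is type(fit_reduced)
    if not nested:
        warnings.warn(
            "comparing non-nested model families: the likelihood-ratio test is "
            "heuristic; rely on AIC/BIC",
            stacklevel=2,
        )
    lrt = 2.0 * (fit_full.llf - fit_reduced.llf)
    df = abs(fit_full.n_params - fit_reduced.n_params)
    p = float(stats.chi2.sf(max(lrt, 0.0), df)) if df > 0 else float(lrt <= 0)
    d_aic = fit_full.aic - fit_reduced.aic
    d_bic = fit_full.bic - fit_reduced.bic
    preferred = {
        "aic": fit_full.name if d_aic < 0 else fit_reduced.name,
        "bic": fit_full.name if d_bic < 0 else fit_reduced.name,
        "lrt": fit_full.name if (df > 0 and p < 0.05 and lrt > 0) else fit_reduced.name,
    }
    return ModelComparison(
        name_full=fit_full.name,
        name_reduced=fit_reduced.name,
        lrt_stat=float(lrt),
        df=int(df),
        p_value=p,
        delta_aic=float(d_aic),
        delta_bic=float(d_bic),
        preferred=preferred,
        nested=nested,
    )


def select_random_effects(cohort, alpha: float = 0.05):
    """Choose between random effects on {A, C} and on {A, B, C}.

    Fits both nested specifications and keeps the richer one only when
    the LRT is significant at ``alpha`` AND both AIC and BIC are lower;
    otherwise the simpler {A, C} model is retained.  If one fit fails,
    the surviving specification is returned with a warning.

    Returns ``(spec, comparison, fit)`` where ``fit`` is the retained
    model's results; ``comparison`` is None if a fit failed.
    """
    model = ExponentialDecayModel(cohort)
    simple = rich = None
    try:
        simple = model.fit(random_effects="AC")
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"{{A,C}} fit failed: {exc}", stacklevel=2)
    try:
        rich = model.fit(random_effects="ABC")
    except Exception as exc:
        warnings.warn(f"{{A,B,C}} fit failed: {exc}", stacklevel=2)
    if simple is None and rich is None:
        raise RuntimeError("both candidate random-effects fits failed")
    if simple is None:
        return rich.re_spec, None, rich
    if rich is None:
        return simple.re_spec, None, simple
    comp = compare_models(rich, simple)
    keep_rich = (
        comp.p_value < alpha and comp.delta_aic < 0 and comp.delta_bic < 0
    )
    chosen = rich if keep_rich else simple
    return chosen.re_spec, comp, chosen
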