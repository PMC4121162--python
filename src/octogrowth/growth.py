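"""Candidate size-at-age models, weighted least-squares fitting, AIC model
selection, instantaneous relative growth rates, and bootstrap intervals.

Four candidate models describe mantle weight ``m`` (g) at age ``a`` (days):

* Gompertz   ``m(a) = m_inf * exp(-gamma * exp(-g1 * a))``
* exponential ``m(a) = b0 * exp(c * a)``
* power      ``m(a) = b0 * a**c``
* linear     ``m(a) = b0 + c * a``

The Gompertz curve is parameterised by its asymptote ``m_inf`` (g), shape
``gamma`` (dimensionless) and rate coefficient ``g1`` (day^-1).  Its
inflection sits at weight ``mu = m_inf / e`` and age ``a* = ln(gamma)/g1``;
the instantaneous relative growth rate ``G(a) = d ln m / da =
gamma * g1 * exp(-g1 * a)`` equals ``g1`` exactly at the inflection.

Size-at-age scatter in cephalopods fans out with age (roughly constant
coefficient of variation), so fitting minimises a weighted residual sum of
squares.  The default scheme iteratively reweights with ``w_i = 1/m_hat_i^2``
from the current fit; a fixed data-based ``1/m_i^2`` scheme ("data_sq") and
an unweighted scheme are also available.  Fixed weights are what multimodel
AIC tables and nested-curve comparisons should use, so that every candidate
minimises the same objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GrowthParams",
    "ModelFit",
    "FitError",
    "MODEL_KINDS",
    "predict_mass",
    "relative_growth_rate",
    "fit_model",
    "aic_and_weights",
    "akaike_weights",
    "bootstrap_ci",
]

ModelKind = Literal["gompertz", "exponential", "power", "linear"]
MODEL_KINDS: tuple[str, ...] = ("gompertz", "exponential", "power", "linear")
WeightScheme = Literal["irls_fit_sq", "data_sq", "none"]

#: parameter names per model, in fitting order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "gompertz": ("m_inf", "gamma", "g1"),
    "exponential": ("b0", "c"),
    "power": ("b0", "c"),
    "linear": ("b0", "c"),
}


class FitError(RuntimeError):
    """Raised when a model fit cannot be completed."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one candidate growth model.

    Gompertz uses (``m_inf``, ``gamma``, ``g1``); the simple models use
    (``b0``, ``c``).  Derived quantities for the Gompertz model — the
    inflection weight ``mu = m_inf/e``, the inflection age
    ``ln(gamma)/g1`` and predicted weights at the observed age extremes —
    are exposed as properties/methods so the traditional location-parameter
    presentation (predicted weight at minimum and maximum observed age) can
    be reported without refitting.
    """

    model: str
    m_inf: float | None = None
    gamma: float | None = None
    g1: float | None = None
    b0: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.model == "gompertz":
            if self.m_inf is None or self.gamma is None or self.g1 is None:
                raise ValueError("gompertz requires m_inf, gamma, g1")
            if self.m_inf <= 0 or self.gamma <= 0 or self.g1 <= 0:
                raise ValueError("gompertz parameters must be positive")
        else:
            if self.b0 is None or self.c is None:
                raise ValueError(f"{self.model} requires b0 and c")
            if self.model in ("exponential", "power") and self.b0 <= 0:
                raise ValueError("b0 must be positive for exponential/power")

    @property
    def theta(self) -> np.ndarray:
        if self.model == "gompertz":
            return np.array([self.m_inf, self.gamma, self.g1], dtype=float)
        return np.array([self.b0, self.c], dtype=float)

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.model]

    @property
    def k(self) -> int:
        return len(self.names)

    # Gompertz-specific derived quantities -------------------------------
    @property
    def inflection_weight(self) -> float:
        """mu = m_inf / e, the weight at the curve's inflection (g)."""
        self._require_gompertz()
        return self.m_inf / math.e

    @property
    def inflection_age(self) -> float:
        """a* = ln(gamma) / g1, the age at the inflection (days)."""
        self._require_gompertz()
        return math.log(self.gamma) / self.g1

    def location_parameters(self, a_min: float, a_max: float) -> dict[str, float]:
        """Predicted weights at the observed age extremes (m1, m2)."""
        self._require_gompertz()
        return {
            "m1": float(predict_mass(self, a_min)),
            "m2": float(predict_mass(self, a_max)),
            "a2": float(a_max),
        }

    def _require_gompertz(self) -> None:
        if self.model != "gompertz":
            raise ValueError(f"only defined for the gompertz model, not {self.model}")

    @classmethod
    def from_theta(cls, model: str, theta: Sequence[float]) -> "GrowthParams":
        if model == "gompertz":
            return cls(model=model, m_inf=float(theta[0]), gamma=float(theta[1]), g1=float(theta[2]))
        return cls(model=model, b0=float(theta[0]), c=float(theta[1]))


def _eval(model: str, theta: np.ndarray, age: np.ndarray) -> np.ndarray:
    if model == "gompertz":
        m_inf, gamma, g1 = theta
        return m_inf * np.exp(-gamma * np.exp(-g1 * age))
    if model == "exponential":
        b0, c = theta
        return b0 * np.exp(c * age)
    if model == "power":
        b0, c = theta
        return b0 * np.power(age, c)
    b0, c = theta
    return b0 + c * age


def _jac(model: str, theta: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d m_hat / d theta, shape (n, k)."""
    if model == "gompertz":
        m_inf, gamma, g1 = theta
        e1 = np.exp(-g1 * age)
        core = np.exp(-gamma * e1)
        return np.column_stack([core, -m_inf * e1 * core, m_inf * gamma * age * e1 * core])
    if model == "exponential":
        b0, c = theta
        e = np.exp(c * age)
        return np.column_stack([e, b0 * age * e])
    if model == "power":
        b0, c = theta
        p = np.power(age, c)
        return np.column_stack([p, b0 * p * np.log(age)])
    return np.column_stack([np.ones_like(age), age])


def predict_mass(params: GrowthParams, age) -> np.ndarray | float:
    """Predicted mantle weight (g) at ``age`` (days) under ``params``."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = _eval(params.model, params.theta, a)
    return float(out) if np.isscalar(age) or a.ndim == 0 else out


def relative_growth_rate(params: GrowthParams, age) -> np.ndarray | float:
    """Instantaneous relative growth rate G(a) = d ln m / da (day^-1).

    Defined here for the Gompertz model only:
    ``G(a) = gamma * g1 * exp(-g1 * a)``, which equals ``g1`` at the
    inflection age ``ln(gamma)/g1``.
    """
    if params.model != "gompertz":
        raise ValueError("relative_growth_rate is defined for the gompertz model only")
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    out = params.gamma * params.g1 * np.exp(-params.g1 * a)
    return float(out) if np.isscalar(age) or a.ndim == 0 else out


@dataclass(frozen=True)
class ModelFit:
    """A fitted growth model with its goodness-of-fit bookkeeping.

    ``rss_weighted`` is the weighted residual sum of squares at the optimum,
    ``aic``/``waic`` are populated by :func:`aic_and_weights` relative to a
    candidate set, and ``bootstrap_ci`` by :func:`bootstrap_ci`.
    """

    params: GrowthParams
    n: int
    k: int
    rss_weighted: float
    weighting: str
    converged: bool
    se: dict[str, float]
    aic: float | None = None
    waic: float | None = None
    bootstrap_ci: dict[str, tuple[float, float]] | None = None

    def with_(self, **kw) -> "ModelFit":
        from dataclasses import replace

        return replace(self, **kw)


def _weights(scheme: str, m_obs: np.ndarray, m_hat: np.ndarray | None) -> np.ndarray:
    if scheme == "none":
        return np.ones_like(m_obs)
    if scheme == "data_sq":
        return 1.0 / m_obs**2
    if scheme == "irls_fit_sq":
        ref = m_obs if m_hat is None else np.maximum(m_hat, 1e-12)
        return 1.0 / ref**2
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def _initial_theta(model: str, age: np.ndarray, m: np.ndarray) -> np.ndarray:
    if model == "linear":
        return np.linalg.lstsq(np.column_stack([np.ones_like(age), age]), m, rcond=None)[0]
    logm = np.log(m)
    if model == "exponential":
        b = np.polyfit(age, logm, 1)
        return np.array([math.exp(b[1]), b[0]])
    if model == "power":
        b = np.polyfit(np.log(age), logm, 1)
        return np.array([math.exp(b[1]), b[0]])
    # Gompertz: asymptote above the data; early-age log-slope seeds g1.
    m_inf0 = 1.2 * float(np.max(m))
    order = np.argsort(age)
    lo = order[: max(3, len(age) // 3)]
    slope = np.polyfit(age[lo], logm[lo], 1)[0]
    g10 = max(float(slope), 1e-4)
    gamma0 = min(max(math.log(m_inf0 / max(float(m[order[0]]), 1e-9)), 0.5), 50.0)
    return np.array([m_inf0, gamma0, g10])


# Finite upper bounds keep the Gompertz fit from chasing its exponential
# limit (m_inf, gamma -> inf jointly) forever on data with no asymptote;
# 1e6 g is far beyond any octopus, so real fits never touch the bound.
_BOUNDS = {
    "gompertz": ([1e-9, 1e-9, 1e-9], [1e6, 1e4, 10.0]),
    "exponential": ([1e-12, -np.inf], [np.inf, np.inf]),
    "power": ([1e-12, -np.inf], [np.inf, np.inf]),
    "linear": ([-np.inf, -np.inf], [np.inf, np.inf]),
}


def _wls_solve(
    model: str, age: np.ndarray, m: np.ndarray, w: np.ndarray, theta0: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Minimise sum w_i (m_i - f(a_i; theta))^2 for fixed weights."""
    sw = np.sqrt(w)
    if model == "linear":
        X = np.column_stack([np.ones_like(age), age]) * sw[:, None]
        theta, *_ = np.linalg.lstsq(X, m * sw, rcond=None)
        return theta, True

    def resid(theta: np.ndarray) -> np.ndarray:
        return sw * (_eval(model, theta, age) - m)

    def jac(theta: np.ndarray) -> np.ndarray:
        return sw[:, None] * _jac(model, theta, age)

    res = optimize.least_squares(
        resid,
        theta0,
        jac=jac,
        bounds=_BOUNDS[model],
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
        max_nfev=2000,
    )
    ok = bool(res.success)
    if not ok and res.cost > 0:
        # a near-flat ridge (e.g. Gompertz degenerating towards an
        # exponential, m_inf and gamma unbounded together) can exhaust
        # max_nfev with the objective long since stationary; accept if the
        # scaled gradient is negligible
        grad = res.jac.T @ res.fun
        ok = float(np.max(np.abs(grad * res.x))) < 1e-8 * res.cost * max(len(age), 1)
    return res.x, ok


def fit_model(
    age,
    mass,
    model: str = "gompertz",
    weighting: WeightScheme = "irls_fit_sq",
    theta0: Sequence[float] | None = None,
    max_irls: int = 6,
    n_restarts: int = 5,
    restart_seed: int = 12345,
) -> ModelFit:
    """Fit one candidate model to (age, mantle weight) data by weighted
    least squares.

    Under ``irls_fit_sq`` the weights ``1/m_hat^2`` are refreshed from the
    current fit until the parameters stabilise (constant-CV error model);
    ``data_sq`` freezes ``1/m_obs^2``; ``none`` is ordinary least squares.
    On optimiser failure up to ``n_restarts`` jittered restarts (fixed
    restart seed) are attempted before raising :class:`FitError`.
    """
    age = np.asarray(age, dtype=float)
    m = np.asarray(mass, dtype=float)
    if age.shape != m.shape or age.ndim != 1:
        raise ValueError("age and mass must be 1-D arrays of equal length")
    k = len(PARAM_NAMES[model])
    if len(age) < k + 2:
        raise ValueError(f"need at least {k + 2} observations to fit {model}")
    if np.any(m <= 0) or np.any(age <= 0):
        raise ValueError("ages and weights must be positive")

    t0 = np.asarray(theta0, dtype=float) if theta0 is not None else _initial_theta(model, age, m)

    def run(theta_start: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
        theta = theta_start.copy()
        w = _weights(weighting, m, None)
        ok_all = True
        rounds = max_irls if weighting == "irls_fit_sq" else 1
        for _ in range(rounds):
            theta_new, ok = _wls_solve(model, age, m, w, theta)
            ok_all = ok_all and ok
            if weighting != "irls_fit_sq":
                theta = theta_new
                break
            shift = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-12))
            theta = theta_new
            w = _weights(weighting, m, _eval(model, theta, age))
            if shift < 1e-10:
                break
        return theta, w, ok_all

    rng = np.random.default_rng(restart_seed)
    theta, w, ok = run(t0)
    attempts = 0
    while not ok and attempts < n_restarts:
        jitter = np.exp(rng.normal(0.0, 0.3, size=t0.shape))
        theta, w, ok = run(np.abs(t0) * jitter + 1e-9)
        attempts += 1
    if not ok:
        raise FitError(
            f"{model} fit failed to converge after {n_restarts} jittered restarts "
            f"(n={len(age)}, start={t0.tolist()})"
        )

    m_hat = _eval(model, theta, age)
    rss_w = float(np.sum(w * (m - m_hat) ** 2))

    # asymptotic SEs from the weighted Jacobian at the optimum
    J = np.sqrt(w)[:, None] * _jac(model, theta, age)
    dof = len(age) - k
    se: dict[str, float] = {}
    if dof > 0:
        s2 = rss_w / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = {
                name: float(np.sqrt(max(cov[i, i], 0.0)))
                for i, name in enumerate(PARAM_NAMES[model])
            }
        except np.linalg.LinAlgError:
            se = {name: float("nan") for name in PARAM_NAMES[model]}

    return ModelFit(
        params=GrowthParams.from_theta(model, theta),
        n=len(age),
        k=k,
        rss_weighted=rss_w,
        weighting=weighting,
        converged=ok,
        se=se,
    )


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights exp(-delta_i/2) / sum_j exp(-delta_j/2).

    Computed after subtracting the minimum AIC, so huge AIC gaps underflow
    cleanly to an exact 0 weight instead of producing nan.
    """
    a = np.asarray(aics, dtype=float)
    if a.ndim != 1 or len(a) == 0:
        raise ValueError("aics must be a non-empty 1-D sequence")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def aic_and_weights(fits: Sequence[ModelFit]) -> list[ModelFit]:
    """Populate AIC and Akaike weights across a candidate set.

    Uses the least-squares AIC ``n*ln(RSS_w/n) + 2(k+1)`` (error variance
    counted as a parameter). All fits must share the same data size and
    weighting scheme; Akaike weights are only meaningful within a candidate
    set fitted to identical data under an identical objective.
    """
    if not fits:
        raise ValueError("empty candidate set")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on differing n: {sorted(ns)}")
    schemes = {f.weighting for f in fits}
    if len(schemes) > 1:
        raise ValueError(f"fits use differing weighting schemes: {sorted(schemes)}")
    n = fits[0].n
    aics = [n * math.log(f.rss_weighted / n) + 2 * (f.k + 1) for f in fits]
    w = akaike_weights(aics)
    return [f.with_(aic=aics[i], waic=float(w[i])) for i, f in enumerate(fits)]


def bootstrap_ci(
    age,
    mass,
    model: str = "gompertz",
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    weighting: WeightScheme = "irls_fit_sq",
    point_fit: ModelFit | None = None,
    strict: bool = False,
) -> tuple[dict[str, tuple[float, float]], int]:
    """Case-resampling percentile bootstrap intervals for the fit parameters.

    Resamples (age, weight) pairs with replacement, refits (warm-started at
    the point estimate), and takes percentile intervals per parameter.
    Returns the intervals and the number of failed refits; more than 20%
    failures raises under ``strict``.
    """
    age = np.asarray(age, dtype=float)
    m = np.asarray(mass, dtype=float)
    fit = point_fit or fit_model(age, m, model=model, weighting=weighting)
    rng = np.random.default_rng(seed)
    n = len(age)
    draws: list[np.ndarray] = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            bf = fit_model(
                age[idx],
                m[idx],
                model=model,
                weighting=weighting,
                theta0=fit.params.theta,
                n_restarts=1,
            )
            draws.append(bf.params.theta)
        except (FitError, ValueError, np.linalg.LinAlgError):
            failed += 1
    if failed > 0.2 * n_boot:
        msg = f"{failed}/{n_boot} bootstrap refits failed"
        if strict:
            raise FitError(msg)
        import warnings

        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    if not draws:
        raise FitError("all bootstrap refits failed")
    arr = np.array(draws)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(arr, alpha, axis=0)
    hi = np.quantile(arr, 1.0 - alpha, axis=0)
    ci = {
        name: (float(lo[i]), float(hi[i])) for i, name in enumerate(PARAM_NAMES[model])
    }
    return ci, failed
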