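"""Rate-constant estimation and the derived regressions.

``fit_mechanism`` estimates rate constants (and optionally initial
concentrations) from concentration-vs-time series by Levenberg-Marquardt
least squares on log-transformed parameters, reporting standard errors
from the Jacobian at the optimum and Student-t confidence intervals with
n - p degrees of freedom.  ``arrhenius_fit`` extracts the activation
energy from a temperature series of rate constants, and
``helix_length_fit`` / ``extrapolate_half_life`` implement the
exponential dependence of reduction half-life on outer-helix length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .model import RateConstants, SystemState, simulate

__all__ = [
    "ObservedSeries",
    "FitResult",
    "ArrheniusResult",
    "ExpLengthFit",
    "fit_mechanism",
    "arrhenius_fit",
    "helix_length_fit",
    "extrapolate_half_life",
    "R_GAS",
]

R_GAS = 8.314  # J mol^-1 K^-1

FITTABLE = ("k1", "k2", "k3", "k4", "ss0", "o2_0")
_DEFAULT_INIT = {"k1": 1e-3, "k2": 1e-3, "k3": 1e-3, "k4": 1e-4, "ss0": 1.0, "o2_0": 0.1}


@dataclass
class ObservedSeries:
    """A measured (or synthetic) reduction time course.

    times in minutes (strictly increasing), concentrations in mmol/L.
    ``c_red0`` is the nominal initial reducing-agent concentration and
    ``c_ss0`` the nominal weighed-in protein concentration (defaults to
    the earliest observation when not given).
    """

    times: np.ndarray
    ss_obs: np.ndarray
    sh_obs: np.ndarray | None = None
    source: str = "synthetic"  # NMR | ECD | synthetic
    temperature_c: float | None = None
    c_red0: float = 0.0
    c_ss0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ss_obs = np.asarray(self.ss_obs, dtype=float)
        if self.sh_obs is not None:
            self.sh_obs = np.asarray(self.sh_obs, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.ss_obs.size:
            raise ValueError("times and ss_obs must be 1-D and equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ss_obs < 0) or (self.sh_obs is not None and np.any(self.sh_obs < 0)):
            raise ValueError("observed concentrations must be >= 0")
        if self.source not in ("NMR", "ECD", "synthetic"):
            raise ValueError(f"unknown source tag {self.source!r}")

    @property
    def ss0_nominal(self) -> float:
        return self.c_ss0 if self.c_ss0 is not None else float(self.ss_obs[0])

    def n_residuals(self) -> int:
        return self.times.size * (2 if self.sh_obs is not None else 1)


@dataclass
class FitResult:
    """Parameter estimates with Student-t confidence intervals.

    ``ci_half_widths`` are half-widths of the (1-alpha) interval with
    n - p degrees of freedom; ``relative_sd_percent`` is 100*SE/estimate.
    An unidentifiable parameter carries infinite SE/CI and appears in
    ``unidentifiable``.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    ci_half_widths: dict[str, float]
    relative_sd_percent: dict[str, float]
    sse: float
    n_points: int
    n_params: int
    alpha: float
    residuals: np.ndarray = field(repr=False)
    unidentifiable: tuple[str, ...] = ()
    n_starts: int = 1
    max_start_spread: float = 0.0  # max relative parameter spread across starts

    @property
    def dof(self) -> int:
        return self.n_points - self.n_params

    def rate_constants(self, fixed: dict[str, float]) -> RateConstants:
        vals = {k: self.estimates.get(k, fixed.get(k, 0.0)) for k in ("k1", "k2", "k3", "k4")}
        return RateConstants(**vals)

    def report(self) -> str:
        lines = [
            f"Least-squares fit: {self.n_points} points, {self.n_params} parameter(s), "
            f"SSE = {self.sse:.6g} (mmol/L)^2, alpha = {self.alpha}",
            f"{'parameter':<10}{'estimate':>14}{'std error':>14}"
            f"{'CI half-width':>16}{'rel SD %':>10}",
        ]
        for name, est in self.estimates.items():
            lines.append(
                f"{name:<10}{est:>14.6g}{self.standard_errors[name]:>14.6g}"
                f"{self.ci_half_widths[name]:>16.6g}{self.relative_sd_percent[name]:>10.3g}"
            )
        if self.unidentifiable:
            lines.append(f"unidentifiable: {', '.join(self.unidentifiable)}")
        return "\n".join(lines)

    def to_keyvalue(self) -> dict[str, float | int | str]:
        out: dict[str, float | int | str] = {
            "sse": self.sse,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "alpha": self.alpha,
        }
        for name, est in self.estimates.items():
            out[f"{name}"] = est
            out[f"{name}_se"] = self.standard_errors[name]
            out[f"{name}_ci_half"] = self.ci_half_widths[name]
            out[f"{name}_rel_sd_pct"] = self.relative_sd_percent[name]
        if self.unidentifiable:
            out["unidentifiable"] = ",".join(self.unidentifiable)
        return out


@dataclass(frozen=True)
class ArrheniusResult:
    """Activation energy from ln k vs 1/T ordinary least squares."""

    ea_kj_mol: float
    ln_preexponential: float
    r_squared: float


@dataclass(frozen=True)
class ExpLengthFit:
    """Exponential half-life vs outer-helix-length regression t1/2 = a e^{b n}."""

    a_min: float
    b_per_residue: float
    r_squared: float


def _model_residuals(
    theta: dict[str, float], series: list[ObservedSeries]
) -> np.ndarray:
    params = RateConstants(theta["k1"], theta["k2"], theta["k3"], theta["k4"])
    parts = []
    for s in series:
        ss0 = theta.get("ss0", s.ss0_nominal)
        initial = SystemState(ss=ss0, red=s.c_red0, o2=theta.get("o2_0", 0.0))
        if s.times[0] == 0.0:
            grid = s.times
            course = simulate(params, initial, grid)
            model_ss, model_sh = course.ss, course.sh
        else:
            grid = np.concatenate([[0.0], s.times])
            course = simulate(params, initial, grid)
            model_ss, model_sh = course.ss[1:], course.sh[1:]
        parts.append(model_ss - s.ss_obs)
        if s.sh_obs is not None:
            parts.append(model_sh - s.sh_obs)
    return np.concatenate(parts)


def fit_mechanism(
    series: ObservedSeries | list[ObservedSeries],
    free_params: tuple[str, ...] = ("k1",),
    fixed_values: dict[str, float] | None = None,
    *,
    initial_guess: dict[str, float] | None = None,
    alpha: float = 0.05,
    n_starts: int = 1,
    start_span: float = 100.0,
) -> FitResult:
    """Fit mechanism parameters to one or more observed series.

    Minimizes the unweighted sum of squared concentration residuals by
    Levenberg-Marquardt over log-transformed parameters (positivity is
    structural).  With ``n_starts > 1`` the optimizer is restarted from
    initializations spread over ``[x0/start_span, x0*start_span]`` and the
    best optimum is kept; the relative spread across starts is reported.
    """
    if isinstance(series, ObservedSeries):
        series = [series]
    if not series:
        raise ValueError("at least one observed series is required")
    free = tuple(free_params)
    if not free:
        raise ValueError("free_params must be non-empty")
    for p in free:
        if p not in FITTABLE:
            raise ValueError(f"unknown parameter {p!r}; fittable: {FITTABLE}")

    fixed = {"k1": 0.0, "k2": 0.0, "k3": 0.0, "k4": 0.0, "o2_0": 0.0}
    fixed.update(fixed_values or {})
    n_points = sum(s.n_residuals() for s in series)
    n_params = len(free)
    if n_points <= n_params:
        raise ValueError("need more data points than free parameters")
    for s in series:
        if s.n_residuals() < n_params + 2:
            raise ValueError("each series needs at least n_params + 2 points")

    guess = dict(_DEFAULT_INIT)
    guess["ss0"] = series[0].ss0_nominal or 1.0
    guess.update(initial_guess or {})

    def theta_of(x: np.ndarray) -> dict[str, float]:
        th = dict(fixed)
        th.setdefault("ss0", series[0].ss0_nominal)
        for name, xi in zip(free, x):
            th[name] = math.exp(xi)
        return th

    def resid(x: np.ndarray) -> np.ndarray:
        return _model_residuals(theta_of(x), series)

    x0 = np.log([max(guess[p], 1e-300) for p in free])
    if n_starts > 1:
        offsets = np.linspace(-math.log(start_span), math.log(start_span), n_starts)
    else:
        offsets = np.array([0.0])

    solutions = []
    last_exc: Exception | None = None
    for off in offsets:
        try:
            res = least_squares(resid, x0 + off, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception as exc:  # integrator blow-up from a wild start
            last_exc = exc
            continue
        if res.status <= 0:
            continue
        solutions.append(res)
    if not solutions:
        raise RuntimeError(f"optimization failed to converge from any start: {last_exc}")

    best = min(solutions, key=lambda r: r.cost)
    est_sets = np.exp(np.array([r.x for r in solutions]))
    best_est = np.exp(best.x)
    spread = float(np.max(np.abs(est_sets - best_est) / np.maximum(np.abs(best_est), 1e-300)))

    r = best.fun
    sse = float(r @ r)
    dof = n_points - n_params
    s2 = sse / dof

    # covariance in log space from the Jacobian; rank deficiency => unidentifiable
    J = best.jac
    U, sv, Vt = np.linalg.svd(J, full_matrices=False)
    tol = max(J.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    rank_ok = sv > max(tol, 1e-12)
    unident: list[str] = []
    var_log = np.full(n_params, np.inf)
    if rank_ok.any():
        Vr = Vt[rank_ok].T
        cov_r = Vr @ np.diag(1.0 / sv[rank_ok] ** 2) @ Vr.T * s2
        var_log = np.diag(cov_r).copy()
    if not rank_ok.all():
        null = Vt[~rank_ok]
        for j in range(n_params):
            if np.abs(null[:, j]).max() > 1e-8:
                var_log[j] = np.inf
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)

    estimates, ses, cis, rels = {}, {}, {}, {}
    for j, name in enumerate(free):
        est = float(best_est[j])
        se_log = math.sqrt(var_log[j]) if np.isfinite(var_log[j]) else math.inf
        se = est * se_log  # delta method back to the natural scale
        estimates[name] = est
        ses[name] = se
        cis[name] = tcrit * se
        rels[name] = 100.0 * se / est if est > 0 and math.isfinite(se) else math.inf
        if not math.isfinite(se):
            unident.append(name)
    if unident:
        warnings.warn(
            f"parameter(s) {', '.join(unident)} not identifiable from the data "
            "(flat residual surface); confidence interval reported as infinite",
            RuntimeWarning,
            stacklevel=2,
        )

    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        ci_half_widths=cis,
        relative_sd_percent=rels,
        sse=sse,
        n_points=n_points,
        n_params=n_params,
        alpha=alpha,
        residuals=r,
        unidentifiable=tuple(unident),
        n_starts=len(solutions),
        max_start_spread=spread,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of ordinary least squares y ~ x."""
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ np.array([slope, intercept])
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 and ss_res < 1e-30 else (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return float(slope), float(intercept), r2


def arrhenius_fit(pairs: list[tuple[float, float]]) -> ArrheniusResult:
    """Activation energy from (temperature degC, k1) pairs.

    Ordinary least squares of ln k1 against 1/T (T in kelvin); the slope
    is -Ea/R, reported in kJ/mol.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (temperature, k) pairs")
    T = np.array([t + 273.15 for t, _ in pairs])
    k = np.array([kk for _, kk in pairs], dtype=float)
    if np.any(k <= 0):
        raise ValueError("rate constants must be > 0")
    if np.unique(T).size != T.size:
        raise ValueError("temperatures must be distinct")
    slope, intercept, r2 = _ols(1.0 / T, np.log(k))
    return ArrheniusResult(ea_kj_mol=-slope * R_GAS / 1000.0, ln_preexponential=intercept, r_squared=r2)


def helix_length_fit(points: list[tuple[float, float]]) -> ExpLengthFit:
    """Exponential regression of reduction half-life on outer-helix length.

    Fits ln(t1/2) = ln(a) + b*n by ordinary least squares; R^2 is reported
    in log space, matching how the correlation is assessed.
    """
    if len(points) < 3:
        raise ValueError("need at least three (n, half-life) points")
    n = np.array([p[0] for p in points], dtype=float)
    t = np.array([p[1] for p in points], dtype=float)
    if np.any(t <= 0):
        raise ValueError("half-lives must be > 0")
    slope, intercept, r2 = _ols(n, np.log(t))
    return ExpLengthFit(a_min=math.exp(intercept), b_per_residue=slope, r_squared=r2)


def extrapolate_half_life(fit: ExpLengthFit, n: float) -> float:
    """Predicted half-life (minutes) at outer-helix length ``n``."""
    if n < 0:
        raise ValueError("helix length must be >= 0")
    return fit.a_min * math.exp(fit.b_per_residue * n)
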