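"""Mass-action model of reversible disulfide-bond reduction.

The mechanism couples four elementary steps in a closed vessel:

    SS + Red --k1--> 2SH + Ox        (bimolecular reduction, SN2)
    2SH + O2 --k2--> SS              (bimolecular reoxidation)
    2SH      --k3--> precipitated    (first-order loss to the solid phase)
    gas      --k4--> O2              (zero-order oxygen ingress)

``SS`` is the oxidized protein (intact disulfide), ``2SH`` the reduced
protein with two free thiols, ``Red``/``Ox`` the reducing agent (TCEP or
DTT) and its spent form.  Concentrations are in mmol/L, time in minutes,
so k1 and k2 carry units of L mmol^-1 min^-1 (numerically mM^-1 min^-1),
k3 min^-1 and k4 mmol L^-1 min^-1.

Besides the stiff-capable integrator the module provides the closed-form
solution of the pure second-order reduction (k2=k3=k4=0), the analytic
half-life of the oxidized species, and the conversion fraction used to
express NMR integral ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "SystemState",
    "TimeCourse",
    "HalfLife",
    "SPECIES",
    "rate_equations",
    "simulate",
    "second_order_ss",
    "half_life",
    "conversion_fraction",
]

#: integration tolerances (package-wide defaults)
RTOL = 1e-8
ATOL = 1e-10  # mmol/L
#: negative excursions larger than this are treated as integrator failure
NEG_TOL = 1e-8  # mmol/L

SPECIES = ("ss", "sh", "red", "ox", "o2", "precipitated")


@dataclass(frozen=True)
class RateConstants:
    """The four mechanism rate constants.

    k1, k2 : L mmol^-1 min^-1 (second order); k3 : min^-1 (first order);
    k4 : mmol L^-1 min^-1 (zero order O2 ingress).
    """

    k1: float
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {f.name} must be finite and >= 0, got {v}")


@dataclass
class SystemState:
    """Species concentrations (mmol/L) at one instant."""

    ss: float
    sh: float = 0.0
    red: float = 0.0
    ox: float = 0.0
    o2: float = 0.0
    precipitated: float = 0.0

    def __post_init__(self) -> None:
        for name in SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"concentration {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(**dict(zip(SPECIES, map(float, y))))

    @property
    def total_protein(self) -> float:
        return self.ss + self.sh + self.precipitated

    @property
    def total_reductant(self) -> float:
        return self.red + self.ox


@dataclass
class TimeCourse:
    """Simulated concentrations on a time grid (minutes, first entry 0)."""

    times: np.ndarray
    states: np.ndarray = field(repr=False)  # shape (n_times, 6), columns SPECIES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(SPECIES)):
            raise ValueError("states shape must be (n_times, 6)")

    def __len__(self) -> int:
        return self.times.size

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def ss(self) -> np.ndarray:
        return self.species("ss")

    @property
    def sh(self) -> np.ndarray:
        return self.species("sh")

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_array(self.states[i])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_min": self.times, **{n: self.states[:, j] for j, n in enumerate(SPECIES)}}
        )


@dataclass(frozen=True)
class HalfLife:
    """Half-life of the oxidized species in minutes; ``value`` is None when
    the stoichiometry prevents SS from ever reaching half its initial value."""

    value: float | None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _rhs(y: np.ndarray, k: RateConstants, o2_cap: float | None) -> np.ndarray:
    ss, sh, red, ox, o2, prec = y
    reduction = k.k1 * ss * red
    reoxidation = k.k2 * sh * o2
    precipitation = k.k3 * sh
    ingress = k.k4
    if o2_cap is not None and o2 >= o2_cap:
        ingress = 0.0
    return np.array(
        [
            -reduction + reoxidation,
            reduction - reoxidation - precipitation,
            -reduction,
            reduction,
            -reoxidation + ingress,
            precipitation,
        ]
    )


def rate_equations(state: SystemState, params: RateConstants) -> dict[str, float]:
    """Per-species time derivatives (mmol L^-1 min^-1) of the mechanism.

    Mass action throughout: reduction is second order in (ss, red),
    reoxidation second order in (sh, o2), precipitation first order in sh,
    and oxygen ingress a constant zero-order source.
    """
    dy = _rhs(state.as_array(), params, None)
    return dict(zip(SPECIES, map(float, dy)))


def simulate(
    params: RateConstants,
    initial: SystemState,
    times: np.ndarray,
    *,
    o2_cap: float | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> TimeCourse:
    """Integrate the mechanism on a strictly increasing grid starting at 0.

    Uses a stiff-capable solver (LSODA). Mass conservation (protein and
    reductant pools) is checked to the integration tolerance; negative
    excursions beyond ``NEG_TOL`` raise, smaller ones are clipped to 0.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a 1-D grid")
    if times[0] != 0.0:
        raise ValueError("time grid must start at 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")

    y0 = initial.as_array()
    if times.size == 1:
        return TimeCourse(times=times, states=y0[None, :])

    sol = solve_ivp(
        lambda t, y: _rhs(y, params, o2_cap),
        (0.0, float(times[-1])),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed: {sol.message} (last t={sol.t[-1] if sol.t.size else 0.0}, "
            f"last state={sol.y[:, -1] if sol.t.size else y0})"
        )
    states = sol.y.T.copy()
    states[0] = y0  # exact initial condition
    worst = states.min()
    if worst < -NEG_TOL:
        idx = np.unravel_index(np.argmin(states), states.shape)
        raise RuntimeError(
            f"integration produced {SPECIES[idx[1]]} = {worst:.3e} mmol/L at "
            f"t = {times[idx[0]]:.4g} min; tighten tolerances"
        )
    np.clip(states, 0.0, None, out=states)

    scale = max(initial.total_protein, initial.total_reductant, 1.0)
    protein = states[:, [0, 1, 5]].sum(axis=1)
    reductant = states[:, [2, 3]].sum(axis=1)
    drift = max(
        np.abs(protein - initial.total_protein).max(),
        np.abs(reductant - initial.total_reductant).max(),
    )
    if drift > 1e-6 * scale:
        raise RuntimeError(f"conservation drift {drift:.3e} mmol/L exceeds tolerance")
    return TimeCourse(times=times, states=states)


def second_order_ss(
    times: np.ndarray, k1: float, ss0: float, red0: float
) -> np.ndarray:
    """Closed-form SS(t) for pure irreversible second-order reduction.

    For unequal initial concentrations,
    ``ss(t) = ss0 (red0 - ss0) / (red0 e^{k1 (red0 - ss0) t} - ss0)``;
    the equal-concentration limit is ``ss0 / (1 + k1 ss0 t)``.
    """
    t = np.asarray(times, dtype=float)
    if k1 < 0 or ss0 < 0 or red0 < 0:
        raise ValueError("k1 and concentrations must be >= 0")
    if math.isclose(ss0, red0, rel_tol=1e-12):
        return ss0 / (1.0 + k1 * ss0 * t)
    d = red0 - ss0
    return ss0 * d / (red0 * np.exp(k1 * d * t) - ss0)


def half_life(k1: float, c_ss0: float, c_red0: float) -> HalfLife:
    """Analytic half-life of the oxidized species under second-order kinetics.

    t1/2 = ln(2 - c_ss0/c_red0) / (k1 (c_red0 - c_ss0)).  The same
    expression remains valid with the protein in excess (log argument and
    concentration difference change sign together) and agrees with the
    integrated trajectory's half-crossing time in both regimes.  At or
    beyond a twofold protein excess the SS pool can never reach half its
    initial value (the stoichiometric floor ss0 - red0 is >= ss0/2) and the
    half-life is undefined.  Equal concentrations give the limit
    1/(k1 c_ss0).
    """
    if k1 <= 0 or c_ss0 <= 0 or c_red0 <= 0:
        raise ValueError("k1 and both initial concentrations must be > 0")
    if math.isclose(c_ss0, c_red0, rel_tol=1e-12):
        return HalfLife(1.0 / (k1 * c_ss0))
    if c_ss0 >= 2.0 * c_red0:
        return HalfLife(None)
    return HalfLife(math.log(2.0 - c_ss0 / c_red0) / (k1 * (c_red0 - c_ss0)))


def conversion_fraction(course: TimeCourse) -> np.ndarray:
    """Fraction of soluble protein in the reduced state, sh/(ss+sh), per time.

    The terminal entry is the steady-state conversion.  Time points where
    no soluble protein remains are returned as NaN with a warning.
    """
    ss, sh = course.ss, course.sh
    total = ss + sh
    out = np.full_like(total, np.nan)
    ok = total > 0
    out[ok] = sh[ok] / total[ok]
    if not ok.all():
        warnings.warn(
            f"conversion undefined at {np.count_nonzero(~ok)} time point(s): "
            "no soluble protein",
            RuntimeWarning,
            stacklevel=2,
        )
    return out
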