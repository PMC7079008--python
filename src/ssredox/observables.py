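"""Conversion of raw spectroscopic signals to concentrations and rates.

Near-UV ellipticity traces and NMR integral ratios both report on the
oxidized/reduced partition of the protein; this module maps them onto
the mmol/L scale the kinetic model works in, and computes CPMG
transverse relaxation rates from crosspeak intensity ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EllipticityTrace",
    "IntegralPair",
    "CpmgPoint",
    "ecd_to_concentration",
    "nmr_to_concentrations",
    "cpmg_r2",
]


@dataclass
class EllipticityTrace:
    """Molar ellipticity at a fixed wavelength vs time.

    ``theta_0``/``theta_inf`` are the initial and plateau ellipticities;
    when not supplied they default to the first point and to the mean of a
    final window (``plateau_fraction`` of the trace), since an ellipticity
    trace alone fixes only the shape, not the absolute concentration.
    """

    times: np.ndarray
    theta: np.ndarray
    wavelength_nm: float
    theta_0: float | None = None
    theta_inf: float | None = None
    plateau_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.times.size != self.theta.size or self.times.size < 2:
            raise ValueError("times and theta must be equal length (>= 2)")
        if not 0.0 < self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must be in (0, 1]")

    def endpoints(self) -> tuple[float, float]:
        t0 = self.theta_0 if self.theta_0 is not None else float(self.theta[0])
        if self.theta_inf is not None:
            tinf = self.theta_inf
        else:
            n_tail = max(1, int(round(self.plateau_fraction * self.theta.size)))
            tinf = float(self.theta[-n_tail:].mean())
        return t0, tinf


@dataclass(frozen=True)
class IntegralPair:
    """Trp He1 integrals of the oxidized/reduced forms plus the DSS reference."""

    int_ox: float
    int_red: float
    int_ref: float
    total_protein: float  # mmol/L

    def __post_init__(self) -> None:
        if self.int_ox < 0 or self.int_red < 0:
            raise ValueError("integrals must be >= 0")
        if self.int_ref <= 0:
            raise ValueError("reference integral must be > 0")
        if self.total_protein < 0:
            raise ValueError("total protein concentration must be >= 0")


@dataclass(frozen=True)
class CpmgPoint:
    """One crosspeak intensity ratio from a CPMG relaxation experiment."""

    intensity_i: float
    intensity_ref: float
    t_cpmg: float  # seconds

    def __post_init__(self) -> None:
        if self.intensity_i <= 0 or self.intensity_ref <= 0:
            raise ValueError("intensities must be > 0")
        if self.t_cpmg <= 0:
            raise ValueError("relaxation period must be > 0")


def ecd_to_concentration(trace: EllipticityTrace, ss0: float) -> np.ndarray:
    """Oxidized-protein concentration from an ellipticity trace.

    c(t) = (theta_inf - theta(t)) / (theta_inf - theta_0) * ss0, so the
    trace start maps to ss0 and the plateau to 0.  The mapping is affine
    in theta, hence invariant to offset and rescaling of the raw signal.
    Values outside [0, ss0] (noise overshoot) are clipped with a warning.
    """
    if ss0 <= 0:
        raise ValueError("ss0 must be > 0")
    t0, tinf = trace.endpoints()
    if math.isclose(t0, tinf, rel_tol=1e-12, abs_tol=1e-300):
        raise ValueError("degenerate trace: theta_0 equals theta_inf")
    c = (tinf - trace.theta) / (tinf - t0) * ss0
    n_out = int(np.count_nonzero((c < 0) | (c > ss0)))
    if n_out:
        warnings.warn(
            f"{n_out} converted value(s) outside [0, ss0]; clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        c = np.clip(c, 0.0, ss0)
    return c


def nmr_to_concentrations(pair: IntegralPair) -> tuple[float, float]:
    """(ss, sh) concentrations from oxidized/reduced integrals.

    Both integrals are normalized to the DSS reference (the normalization
    cancels in the ratio but is retained for drift diagnostics); the
    oxidized fraction of total protein is int_ox/(int_ox + int_red), so
    ss + sh equals total protein exactly.
    """
    ox = pair.int_ox / pair.int_ref
    red = pair.int_red / pair.int_ref
    if ox + red <= 0:
        raise ValueError("both integrals are zero: no protein signal")
    ss = pair.total_protein * ox / (ox + red)
    return ss, pair.total_protein - ss


def cpmg_r2(point: CpmgPoint) -> float:
    """Transverse relaxation rate R2 = -ln(I_i/I_ref)/t_CPMG in s^-1.

    An intensity above the reference yields a negative rate; it is kept
    (with a warning) so that noise statistics remain unbiased.
    """
    r2 = -math.log(point.intensity_i / point.intensity_ref) / point.t_cpmg
    if r2 < 0:
        warnings.warn(
            f"negative R2 = {r2:.4g} s^-1 (intensity above reference; noise)",
            RuntimeWarning,
            stacklevel=2,
        )
    return r2
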