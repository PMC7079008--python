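"""Ground-truth-known synthetic data for every pipeline stage.

Two generators: noisy reduction time courses, rendered either as NMR
integral tables or near-UV ellipticity traces (both invertible through
:mod:`ssredox.observables`), and two-state thermal CD spectrum ensembles
with logistic folded-fraction melting curves.  Every generated dataset
carries its generating truth so that recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import RateConstants, SystemState, TimeCourse, simulate
from .estimation import ObservedSeries
from .observables import EllipticityTrace
from .spectra import SpectrumSet

__all__ = [
    "SyntheticDesign",
    "MeltDesign",
    "SyntheticTimeCourse",
    "generate_time_course",
    "generate_melt_ensemble",
    "time_grid",
    "e19_nmr_design",
    "default_melt_design",
]

#: conditions of the reference NMR monitoring experiment this generator
#: emulates by default: 0.113 mmol/L protein, 18-fold TCEP excess, sampling
#: to 3300 min (the time by which the trace had reached steady state)
E19_SS0 = 0.113  # mmol/L
E19_RED_EXCESS = 18.0
E19_K1 = 8.03e-4  # L mmol^-1 min^-1
E19_T_END = 3300.0  # min
E19_N_POINTS = 40
DEFAULT_NOISE = 0.02  # fraction of ss0


def time_grid(
    n_points: int, t_end_min: float, spacing: str = "log", t_min: float = 1.0
) -> np.ndarray:
    """Sampling grid in minutes.

    ``log`` spacing concentrates points in the early reduction phase, the
    usual practice when the initial decay carries most of the rate
    information; ``linear`` covers [0, t_end] uniformly.
    """
    if n_points < 2:
        raise ValueError("need at least two sample points")
    if spacing == "linear":
        return np.linspace(0.0, t_end_min, n_points)
    if spacing == "log":
        if not 0 < t_min < t_end_min:
            raise ValueError("t_min must lie in (0, t_end_min)")
        return np.geomspace(t_min, t_end_min, n_points)
    raise ValueError(f"unknown spacing {spacing!r}")


@dataclass
class SyntheticDesign:
    """Design of one synthetic reduction experiment.

    ``noise_sigma`` is the additive Gaussian noise sd as a fraction of the
    initial SS concentration; a seed is mandatory whenever it is non-zero.
    """

    truth: RateConstants
    initial: SystemState
    times: np.ndarray
    noise_sigma: float = DEFAULT_NOISE
    seed: int | None = None
    forward_model: str = "nmr_integrals"  # nmr_integrals | ecd_trace | both
    theta_0: float = -10.0  # deg cm^2 dmol^-1, ECD forward model
    theta_inf: float = 5.0
    wavelength_nm: float = 287.0
    int_ref: float = 1.0  # DSS reference integral

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sigma > 0")
        if self.forward_model not in ("nmr_integrals", "ecd_trace", "both"):
            raise ValueError(f"unknown forward model {self.forward_model!r}")
        if self.theta_0 == self.theta_inf:
            raise ValueError("theta_0 and theta_inf must differ")


@dataclass
class SyntheticTimeCourse:
    """One generated dataset: the observation series, the raw signal tables
    it was rendered through, and the generating truth."""

    series: ObservedSeries
    course: TimeCourse = field(repr=False)
    truth: dict = field(default_factory=dict)
    integral_table: "np.ndarray | None" = field(default=None, repr=False)  # cols: t, int_ox, int_red, int_dss
    trace: EllipticityTrace | None = None


def _simulate_on(design: SyntheticDesign) -> TimeCourse:
    grid = design.times
    if grid[0] != 0.0:
        full = np.concatenate([[0.0], grid])
        course = simulate(design.truth, design.initial, full)
        return TimeCourse(times=course.times[1:], states=course.states[1:])
    return simulate(design.truth, design.initial, grid)


def generate_time_course(design: SyntheticDesign) -> SyntheticTimeCourse:
    """Simulate the mechanism and render it through the chosen forward model.

    Gaussian noise of sd ``noise_sigma * ss0`` is added to the oxidized
    concentration (clipped at 0: concentrations are non-negative); the raw
    NMR integral table / ellipticity trace are constructed consistently
    with the noisy concentrations, so the observables conversions invert
    them exactly.  Identical seeds give bit-identical output.
    """
    course = _simulate_on(design)
    ss0 = design.initial.ss
    ss_true = course.ss
    soluble = course.ss + course.sh

    if design.noise_sigma > 0:
        rng = np.random.default_rng(design.seed)
        ss_obs = ss_true + rng.normal(0.0, design.noise_sigma * ss0, ss_true.size)
        ss_obs = np.clip(ss_obs, 0.0, None)
    else:
        ss_obs = ss_true.copy()

    integral_table = None
    trace = None
    if design.forward_model in ("nmr_integrals", "both"):
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_ox = np.where(soluble > 0, ss_obs / np.maximum(soluble, 1e-300), 0.0)
        int_ox = design.int_ref * frac_ox
        int_red = design.int_ref * (1.0 - frac_ox)
        integral_table = np.column_stack(
            [course.times, int_ox, int_red, np.full_like(int_ox, design.int_ref)]
        )
    if design.forward_model in ("ecd_trace", "both"):
        theta = design.theta_inf + (design.theta_0 - design.theta_inf) * ss_obs / ss0
        trace = EllipticityTrace(
            times=course.times,
            theta=theta,
            wavelength_nm=design.wavelength_nm,
            theta_0=design.theta_0,
            theta_inf=design.theta_inf,
        )

    sh_obs = np.clip(soluble - ss_obs, 0.0, None)
    series = ObservedSeries(
        times=course.times,
        ss_obs=ss_obs,
        sh_obs=sh_obs if design.forward_model in ("nmr_integrals", "both") else None,
        source="synthetic",
        c_red0=design.initial.red,
        c_ss0=ss0,
    )
    truth = {
        "k1": design.truth.k1,
        "k2": design.truth.k2,
        "k3": design.truth.k3,
        "k4": design.truth.k4,
        "ss0": ss0,
        "red0": design.initial.red,
        "o2_0": design.initial.o2,
        "noise_sigma": design.noise_sigma,
        "seed": design.seed,
        "forward_model": design.forward_model,
    }
    return SyntheticTimeCourse(
        series=series, course=course, truth=truth, integral_table=integral_table, trace=trace
    )


def e19_nmr_design(
    seed: int | None = 0, noise_sigma: float = DEFAULT_NOISE
) -> SyntheticDesign:
    """The reference design: second-order reduction at k1 = 8.03e-4
    L mmol^-1 min^-1, 0.113 mmol/L protein, 18-fold reductant excess,
    40 log-spaced samples to 3300 min, 2% additive noise."""
    return SyntheticDesign(
        truth=RateConstants(k1=E19_K1),
        initial=SystemState(ss=E19_SS0, red=E19_RED_EXCESS * E19_SS0),
        times=time_grid(E19_N_POINTS, E19_T_END, "log"),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _gaussian_bands(wl: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    out = np.zeros_like(wl)
    for center, width, amplitude in bands:
        out += amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


@dataclass
class MeltDesign:
    """Design of a two-state thermal CD ensemble.

    Each spectrum is f(T) * folded_basis + (1 - f(T)) * unfolded_basis plus
    noise, with f a falling logistic in temperature (midpoint ``tm_c``,
    steepness per degC).  Default bases are helix-like (negative 208/222 nm
    bands, positive 193 nm) and coil-like (strong negative near 198 nm).
    """

    wavelengths: np.ndarray = None
    folded_bands: list[tuple[float, float, float]] = None  # (center nm, width nm, amplitude)
    unfolded_bands: list[tuple[float, float, float]] = None
    variants: list[tuple[str, float, float]] = None  # (name, tm_c, steepness)
    temperatures: np.ndarray = None
    noise_sigma: float = 0.0  # fraction of the max |basis| amplitude
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.wavelengths is None:
            self.wavelengths = np.arange(185.0, 261.0, 1.0)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.folded_bands is None:
            self.folded_bands = [(193.0, 9.0, 60.0), (208.0, 9.0, -32.0), (222.0, 10.0, -33.0)]
        if self.unfolded_bands is None:
            self.unfolded_bands = [(198.0, 10.0, -40.0), (218.0, 12.0, 4.0)]
        if self.temperatures is None:
            self.temperatures = np.arange(5.0, 86.0, 5.0)  # 17 temperatures
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.variants is None:
            # 12 variants spanning a realistic range of thermal stabilities
            self.variants = [(f"v{i:02d}", 30.0 + 4.0 * i, 0.12) for i in range(12)]
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sigma > 0")

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            _gaussian_bands(self.wavelengths, self.folded_bands),
            _gaussian_bands(self.wavelengths, self.unfolded_bands),
        )

    def fraction(self, tm_c: float, steepness: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(steepness * (self.temperatures - tm_c)))


def default_melt_design(noise_sigma: float = 0.0, seed: int | None = None) -> MeltDesign:
    """12 variants x 17 temperatures (204 spectra), the ensemble shape of a
    full variant/temperature CD melting study."""
    return MeltDesign(noise_sigma=noise_sigma, seed=seed)


def generate_melt_ensemble(design: MeltDesign) -> tuple[SpectrumSet, "pd.DataFrame"]:
    """Render the two-state ensemble; returns the SpectrumSet and a truth
    table (variant, temperature_c, folded_fraction)."""
    import pandas as pd

    folded, unfolded = design.basis()
    scale = max(np.abs(folded).max(), np.abs(unfolded).max())
    rng = np.random.default_rng(design.seed) if design.noise_sigma > 0 else None

    columns, labels, rows = [], [], []
    for name, tm, steep in design.variants:
        f = design.fraction(tm, steep)
        for T, fi in zip(design.temperatures, f):
            spec = fi * folded + (1.0 - fi) * unfolded
            if rng is not None:
                spec = spec + rng.normal(0.0, design.noise_sigma * scale, spec.size)
            columns.append(spec)
            labels.append((name, float(T)))
            rows.append({"variant": name, "temperature_c": float(T), "folded_fraction": float(fi)})
    data = SpectrumSet(
        wavelengths=design.wavelengths, matrix=np.column_stack(columns), labels=labels
    )
    return data, pd.DataFrame(rows)
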