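"""Headline study routines built from the library primitives.

These are the computations the analysis drivers, the test suite and the
acceptance script all share: the seeded k1-recovery study on the
reference reduction experiment, classification of the three qualitative
redox regimes (reduction-dominated, steady state, reoxidation after
reductant exhaustion), and the folded-fraction recovery study for the
thermal CD deconvolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import ObservedSeries, fit_mechanism
from .model import RateConstants, SystemState, TimeCourse, conversion_fraction, rate_equations, simulate
from .spectra import deconvolve
from .synthetic import MeltDesign, e19_nmr_design, generate_melt_ensemble, generate_time_course

__all__ = [
    "e19_recovery_study",
    "summarize_recovery",
    "classify_regime",
    "regime_parameter_sets",
    "run_regimes",
    "melt_recovery_study",
    "E19_K1_TRUTH",
]

E19_K1_TRUTH = 8.03e-4  # L mmol^-1 min^-1, the reference NMR-derived value


def e19_recovery_study(
    n_replicates: int = 100,
    base_seed: int = 0,
    noise_sigma: float = 0.02,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Seeded replicates of the reference reduction experiment.

    Each replicate simulates the second-order mechanism under the
    reference conditions (0.113 mmol/L protein, 18-fold reductant excess,
    40 log-spaced samples to 3300 min), adds Gaussian noise, refits k1
    alone, and records the estimate, its Student-t CI half-width and
    whether the interval covers the generating value.  The oxidized-state
    series alone enters the fit: the reduced-state channel of the NMR
    forward model is derived from the same integrals and carries no
    independent information.
    """
    rows = []
    for i in range(n_replicates):
        seed = int((base_seed + i) % 2**31)
        rep = generate_time_course(e19_nmr_design(seed=seed, noise_sigma=noise_sigma))
        series = ObservedSeries(
            times=rep.series.times,
            ss_obs=rep.series.ss_obs,
            c_red0=rep.series.c_red0,
            c_ss0=rep.truth["ss0"],
        )
        fit = fit_mechanism(
            series, ("k1",), fixed_values={"ss0": rep.truth["ss0"]}, alpha=alpha
        )
        k1_hat = fit.estimates["k1"]
        ci = fit.ci_half_widths["k1"]
        rows.append(
            {
                "seed": seed,
                "k1_hat": k1_hat,
                "ci_half_width": ci,
                "rel_error": k1_hat / E19_K1_TRUTH - 1.0,
                "covered": abs(k1_hat - E19_K1_TRUTH) <= ci,
            }
        )
    return pd.DataFrame(rows)


def summarize_recovery(df: pd.DataFrame) -> dict[str, float]:
    """Median estimate/bias and nominal-CI coverage of a recovery study."""
    return {
        "k1_median": float(df["k1_hat"].median()),
        "median_rel_bias_pct": float(100.0 * (df["k1_hat"].median() / E19_K1_TRUTH - 1.0)),
        "coverage_pct": float(100.0 * df["covered"].mean()),
        "n_replicates": int(len(df)),
    }


#: |d(ss)/dt| below this fraction of ss0 per minute counts as steady state
REGIME_RATE_TOL = 1e-4


def classify_regime(course: TimeCourse, params: RateConstants, ss0: float) -> str:
    """Label the late-time behaviour of a simulated redox cycle.

    The sign of d(ss)/dt at the final state decides: clearly negative is
    the reduction-dominated stage, clearly positive the reoxidation stage
    after reductant exhaustion, and near-zero the steady state.
    """
    dss = rate_equations(course.state_at(len(course) - 1), params)["ss"]
    if abs(dss) < REGIME_RATE_TOL * ss0:
        return "steady"
    return "reduction" if dss < 0 else "reoxidation"


def regime_parameter_sets() -> dict[str, tuple[RateConstants, SystemState, np.ndarray]]:
    """Parameter sets realizing the three qualitative stages of the cycle.

    reduction: irreversible consumption of SS by excess reductant;
    steady: reoxidation balanced by O2 ingress against an unexhausted
    reductant pool, conversion plateauing below 100%;
    reoxidation: a small reductant pool exhausts while O2 keeps entering,
    so the oxidized species recovers at late time.
    """
    ss0 = 0.113
    return {
        "reduction": (
            RateConstants(k1=1e-2),
            SystemState(ss=1.0, red=2.0),
            np.linspace(0.0, 50.0, 201),
        ),
        "steady": (
            # k4 tuned so that ss_ss = k4/(k1 red) sits near 8% of ss0,
            # the incomplete-conversion plateau regime
            RateConstants(k1=8.03e-4, k2=0.1, k4=1.5e-5),
            SystemState(ss=ss0, red=18 * ss0, o2=0.05),
            np.linspace(0.0, 8000.0, 401),
        ),
        "reoxidation": (
            RateConstants(k1=5e-2, k2=0.05, k4=5e-4),
            SystemState(ss=1.0, red=1.2, o2=0.02),
            np.linspace(0.0, 2000.0, 401),
        ),
    }


def run_regimes() -> pd.DataFrame:
    """Simulate the three regime parameter sets and classify each one."""
    rows = []
    for name, (params, initial, times) in regime_parameter_sets().items():
        course = simulate(params, initial, times)
        conv = conversion_fraction(course)
        rows.append(
            {
                "regime": name,
                "classified": classify_regime(course, params, initial.ss),
                "terminal_conversion": float(conv[-1]),
            }
        )
    return pd.DataFrame(rows)


def melt_recovery_study(
    n_seeds: int = 50,
    noise_sigma: float = 0.02,
    base_seed: int = 0,
    design: MeltDesign | None = None,
) -> pd.DataFrame:
    """Folded-fraction recovery of the convex deconvolution under noise.

    For each seed a two-state ensemble is generated, factorized into two
    components, and the recovered folded weights compared with the
    generating logistic fractions; the per-seed RMS error is returned.
    """
    rows = []
    for i in range(n_seeds):
        seed = int((base_seed + i) % 2**31)
        d = design if design is not None else MeltDesign()
        d = MeltDesign(
            wavelengths=d.wavelengths,
            folded_bands=d.folded_bands,
            unfolded_bands=d.unfolded_bands,
            variants=d.variants,
            temperatures=d.temperatures,
            noise_sigma=noise_sigma,
            seed=seed,
        )
        data, truth = generate_melt_ensemble(d)
        result = deconvolve(data, 2)
        rms = float(
            np.sqrt(np.mean((result.weights[:, 0] - truth["folded_fraction"].to_numpy()) ** 2))
        )
        rows.append({"seed": seed, "rms_error": rms, "sse": result.sse})
    return pd.DataFrame(rows)
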