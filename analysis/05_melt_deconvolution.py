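#!/usr/bin/env python
"""Deconvolve a synthetic thermal CD ensemble into two pure components.

Generates the full study-shaped ensemble — 12 variants x 17 temperatures
(204 far-UV spectra) of two-state melts between a helix-like folded basis
and a coil-like unfolded basis — at 2% noise, factorizes it into two
convex components, and scores the recovered folded fractions against the
generating logistic curves.  A 50-seed replicate study quantifies the
recovery error.  Writes components, weights and the study table under
results/.
"""

import argparse
from pathlib import Path

import numpy as np

from ssredox import io as sio
from ssredox.spectra import deconvolve, folded_fraction
from ssredox.studies import melt_recovery_study
from ssredox.synthetic import default_melt_design, generate_melt_ensemble

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--noise", type=float, default=0.02)
    args = parser.parse_args()

    OUT.mkdir(exist_ok=True)
    design = default_melt_design(noise_sigma=args.noise, seed=args.seed)
    data, truth = generate_melt_ensemble(design)
    sio.write_spectrum_set(data, OUT / "melt_ensemble.csv")

    result = deconvolve(data, 2)
    sio.write_deconv_result(result, data.wavelengths, data.labels,
                            OUT / "melt_components.csv", OUT / "melt_weights.csv")
    df = folded_fraction(result, data.labels)
    df["truth_pct"] = 100.0 * truth["folded_fraction"].to_numpy()
    df.to_csv(OUT / "melt_folded_fraction.csv", index=False)

    rms = float(np.sqrt(np.mean((df["folded_pct"] - df["truth_pct"]) ** 2))) / 100.0
    print(f"ensemble: {data.n_spectra} spectra, factorized in {result.n_iter} "
          f"iterations, SSE = {result.sse:.4g}")
    print(f"folded-fraction RMS error vs generating logistic: {rms:.4f}")

    study = melt_recovery_study(n_seeds=50, noise_sigma=args.noise, base_seed=args.seed)
    study.to_csv(OUT / "melt_recovery_replicates.csv", index=False)
    print(f"50-seed recovery study at {100 * args.noise:.0f}% noise: "
          f"RMS error median {study['rms_error'].median():.4f}, "
          f"max {study['rms_error'].max():.4f}")


if __name__ == "__main__":
    main()
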