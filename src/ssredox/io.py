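"""Delimited-text readers and writers for the package's data formats.

All formats are plain comma-separated text; series files carry their
metadata (source, temperature, nominal concentrations) as ``# key: value``
header lines so a file round-trips to the in-memory object.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import FitResult, ObservedSeries
from .model import SPECIES, TimeCourse
from .spectra import DeconvResult, SpectrumSet

__all__ = [
    "write_time_course",
    "read_time_course",
    "write_observed_series",
    "read_observed_series",
    "write_spectrum_set",
    "read_spectrum_set",
    "write_deconv_result",
    "write_fit_report",
    "write_keyvalue",
    "read_keyvalue",
    "read_descriptor_table",
    "read_csd_table",
    "load_config",
]


def write_time_course(course: TimeCourse, path: str | Path) -> None:
    course.to_frame().to_csv(path, index=False)


def read_time_course(path: str | Path) -> TimeCourse:
    df = pd.read_csv(path)
    return TimeCourse(times=df["time_min"].to_numpy(), states=df[list(SPECIES)].to_numpy())


def write_observed_series(series: ObservedSeries, path: str | Path) -> None:
    meta = {"source": series.source}
    if series.temperature_c is not None:
        meta["temperature_c"] = series.temperature_c
    meta["c_red0"] = series.c_red0
    if series.c_ss0 is not None:
        meta["c_ss0"] = series.c_ss0
    cols = {"time_min": series.times, "ss_mM": series.ss_obs}
    if series.sh_obs is not None:
        cols["sh_mM"] = series.sh_obs
    buf = _io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    pd.DataFrame(cols).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_observed_series(path: str | Path) -> ObservedSeries:
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])))
    return ObservedSeries(
        times=df["time_min"].to_numpy(),
        ss_obs=df["ss_mM"].to_numpy(),
        sh_obs=df["sh_mM"].to_numpy() if "sh_mM" in df else None,
        source=meta.get("source", "synthetic"),
        temperature_c=float(meta["temperature_c"]) if "temperature_c" in meta else None,
        c_red0=float(meta.get("c_red0", 0.0)),
        c_ss0=float(meta["c_ss0"]) if "c_ss0" in meta else None,
    )


def write_spectrum_set(data: SpectrumSet, path: str | Path) -> None:
    cols = {"wavelength_nm": data.wavelengths}
    for j, (variant, temp) in enumerate(data.labels):
        cols[f"{variant}@{temp:g}C"] = data.matrix[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectrum_set(path: str | Path) -> SpectrumSet:
    df = pd.read_csv(path)
    labels = []
    for col in df.columns[1:]:
        variant, _, temp = col.rpartition("@")
        labels.append((variant, float(temp.rstrip("C"))))
    return SpectrumSet(
        wavelengths=df["wavelength_nm"].to_numpy(),
        matrix=df.iloc[:, 1:].to_numpy(),
        labels=labels,
    )


def write_deconv_result(
    result: DeconvResult,
    wavelengths: np.ndarray,
    labels: list[tuple[str, float]],
    components_path: str | Path,
    weights_path: str | Path,
) -> None:
    k = result.components.shape[1]
    comp_cols = {"wavelength_nm": wavelengths}
    names = ["folded"] + [f"component_{i}" for i in range(2, k + 1)]
    if k >= 2:
        names[-1] = "unfolded" if k == 2 else names[-1]
    for i, name in enumerate(names):
        comp_cols[name] = result.components[:, i]
    pd.DataFrame(comp_cols).to_csv(components_path, index=False)
    wdf = pd.DataFrame(
        {
            "variant": [v for v, _ in labels],
            "temperature_c": [t for _, t in labels],
            **{f"w_{name}": result.weights[:, i] for i, name in enumerate(names)},
        }
    )
    wdf.to_csv(weights_path, index=False)


def write_fit_report(result: FitResult, path: str | Path) -> None:
    """Human-readable parameter table plus a machine-readable key=value block."""
    text = result.report() + "\n\n[keyvalue]\n"
    text += "\n".join(f"{k}={v}" for k, v in result.to_keyvalue().items()) + "\n"
    Path(path).write_text(text)


def write_keyvalue(values: dict, path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}={v}\n" for k, v in values.items()))


def read_keyvalue(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Columns: variant, n_outer, rmsd_outer, helicity."""
    df = pd.read_csv(path)
    required = {"variant", "n_outer", "rmsd_outer", "helicity"}
    if not required.issubset(df.columns):
        raise ValueError(f"descriptor table must have columns {sorted(required)}")
    return df


def read_csd_table(path: str | Path) -> dict[str, float]:
    """Columns: residue, atom, csd_ppm -> mapping '<residue>:<atom>' -> csd."""
    df = pd.read_csv(path)
    required = {"residue", "atom", "csd_ppm"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSD table must have columns {sorted(required)}")
    return {
        f"{r.residue}:{r.atom}": float(r.csd_ppm) for r in df.itertuples(index=False)
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
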