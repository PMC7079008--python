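"""Structure-derived scalar descriptors of the outer helix.

The reduction rate of the disulfide scales with how much ordered,
bulky polypeptide shields it.  Three descriptors capture this:
the mean per-residue Halpha chemical-shift deviation (helicity), the
cage score summing nine diagnostic Trp-cage proton CSDs, and the
composite steric factor x = n * RMSD / helicity of the outer
(N-terminal) helical segment.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

__all__ = ["CAGE_PROTONS", "steric_factor", "mean_csd", "csd_cage"]

#: the nine diagnostic cage protons, keyed as "<residue>:<atom>"
CAGE_PROTONS = (
    "W25:HE1",
    "L26:HA",
    "G30:HA2",
    "P31:HB2",
    "R35:HA",
    "P37:HA",
    "P37:HB2",
    "P38:HD1",
    "P38:HD2",
)


def steric_factor(n_outer: int, rmsd_outer: float, helicity: float) -> float:
    """Composite steric descriptor x = n_outer * rmsd_outer / helicity.

    ``n_outer`` is the number of residues N-terminal of the first cysteine,
    ``rmsd_outer`` the ensemble RMSD of that segment (angstrom) and
    ``helicity`` its mean per-residue Halpha CSD (ppm).  By convention
    x = 0 for a variant with no outer segment.
    """
    if n_outer < 0 or rmsd_outer < 0:
        raise ValueError("n_outer and rmsd_outer must be >= 0")
    if n_outer == 0:
        return 0.0
    if helicity <= 0:
        raise ValueError("helicity must be > 0 when the outer segment is non-empty")
    return n_outer * rmsd_outer / helicity


def mean_csd(values: Sequence[float]) -> float:
    """Mean absolute per-residue Halpha chemical-shift deviation (ppm)."""
    if len(values) == 0:
        raise ValueError("need at least one CSD value")
    return sum(abs(v) for v in values) / len(values)


def csd_cage(table: Mapping[str, float]) -> float:
    """Cage score: sum of absolute CSDs over the nine cage protons.

    ``table`` maps "<residue>:<atom>" keys (e.g. ``"W25:HE1"``) to CSDs in
    ppm; every cage proton must be present.
    """
    missing = [p for p in CAGE_PROTONS if p not in table]
    if missing:
        raise ValueError(f"missing cage proton(s): {', '.join(missing)}")
    return sum(abs(table[p]) for p in CAGE_PROTONS)
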