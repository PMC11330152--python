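"""DVH statistics and SABR plan-quality indices.

Dx% values are computed by sorted-voxel linear interpolation rather than a
binned DVH, so there is no hidden bin-width parameter: the masked doses are
sorted descending and the dose is read off a piecewise-linear curve through
the points (cumulative volume fraction i/N, i-th largest dose).  V100%/V50%
are absolute isodose volumes over the whole dose grid (they are not clipped
to the structure — the gradient indices would be meaningless otherwise).
Voxels count wholly in or out of masks; there is no partial-volume
weighting, a documented deviation from TPS small-structure behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BinaryMask, VolumeGrid, equivalent_sphere_diameter_mm

__all__ = [
    "DoseSummary",
    "IndexSet",
    "dose_at_relative_volume",
    "volume_at_dose_level",
    "dose_stats_in_mask",
    "homogeneity_index",
    "conformity_index",
    "gradient_index",
    "gradient_measure",
    "summarize_dose",
    "volume_change_stats",
]


@dataclass(frozen=True)
class DoseSummary:
    """Structure dose statistics (cGy) plus structure size."""

    d_min: float
    d_mean: float
    d_max: float
    d2: float
    d95: float
    d98: float
    v100_cc: float
    v50_cc: float
    volume_cc: float
    eq_sphere_mm: float


@dataclass(frozen=True)
class IndexSet:
    """SABR dose-evaluation indices for one plan/delivery."""

    hi: float
    ci: float
    gi: float
    gm_mm: float


def _masked_doses(dose: VolumeGrid, mask: BinaryMask) -> np.ndarray:
    if not mask.geometry.same_as(dose.geometry):
        raise ValueError("dose and mask geometries differ")
    sel = mask.as_bool()
    if not sel.any():
        raise ValueError("empty mask")
    return dose.values[sel]


def dose_at_relative_volume(dose: VolumeGrid, mask: BinaryMask, x_percent: float) -> float:
    """Dx%: the dose level received by at least x% of the structure volume.

    Sorted descending, each voxel carrying volume fraction 1/N; the dose at
    cumulative fraction x/100 is linearly interpolated between adjacent
    sorted voxels.  D100% is the masked minimum; the x -> 0 limit is the
    maximum.
    """
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    d = np.sort(_masked_doses(dose, mask))[::-1]
    n = d.size
    frac = np.arange(1, n + 1) / n
    return float(np.interp(x_percent / 100.0, frac, d))


def volume_at_dose_level(dose: VolumeGrid, level_cgy: float) -> float:
    """Absolute volume (cc) of the whole grid receiving >= level_cgy."""
    if level_cgy < 0:
        raise ValueError("dose level must be non-negative")
    n = int(np.sum(dose.values >= level_cgy))
    return n * dose.geometry.voxel_volume_mm3 / 1000.0


def dose_stats_in_mask(dose: VolumeGrid, mask: BinaryMask) -> tuple[float, float, float]:
    """(min, mean, max) dose over the masked voxels."""
    d = _masked_doses(dose, mask)
    return float(d.min()), float(d.mean()), float(d.max())


def homogeneity_index(d2: float, d98: float, d_prescribed: float) -> float:
    """HI = (D2% - D98%) * 100 / D_prescribed."""
    if d_prescribed <= 0:
        raise ValueError("prescription must be positive")
    if d2 < d98 - 1e-9:
        raise ValueError("D2% below D98% violates DVH ordering")
    return (d2 - d98) * 100.0 / d_prescribed


def conformity_index(v100_cc: float, structure_volume_cc: float) -> float:
    """CI = V100% / structure volume."""
    if structure_volume_cc <= 0:
        raise ValueError("structure volume must be positive")
    return v100_cc / structure_volume_cc


def gradient_index(v100_cc: float, v50_cc: float) -> float:
    """GI = V100% / V50% (as reported clinically here; <= 1 for nested isodoses)."""
    if v50_cc <= 0:
        raise ValueError("V50% must be positive")
    return v100_cc / v50_cc


def gradient_measure(v50_cc: float, v100_cc: float) -> float:
    """GM (mm): difference of the equivalent-sphere radii of the 50% and
    100% isodose volumes."""
    if v100_cc > v50_cc:
        raise ValueError("V100% cannot exceed V50%")
    if v100_cc < 0:
        raise ValueError("volumes must be non-negative")
    return 0.5 * (
        equivalent_sphere_diameter_mm(v50_cc) - equivalent_sphere_diameter_mm(v100_cc)
    )


def summarize_dose(dose: VolumeGrid, mask: BinaryMask, prescription_cgy: float) -> DoseSummary:
    """Full DVH summary of a dose grid over a structure."""
    dmin, dmean, dmax = dose_stats_in_mask(dose, mask)
    vol = mask.volume_cc
    return DoseSummary(
        d_min=dmin,
        d_mean=dmean,
        d_max=dmax,
        d2=dose_at_relative_volume(dose, mask, 2.0),
        d95=dose_at_relative_volume(dose, mask, 95.0),
        d98=dose_at_relative_volume(dose, mask, 98.0),
        v100_cc=volume_at_dose_level(dose, prescription_cgy),
        v50_cc=volume_at_dose_level(dose, 0.5 * prescription_cgy),
        volume_cc=vol,
        eq_sphere_mm=equivalent_sphere_diameter_mm(vol),
    )


def volume_change_stats(cases: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction mean +/- SD of the percent volume difference of the
    propagated ITV and PTV relative to their planning volumes.

    Expects columns ``fraction``, ``itv_volume_cc``, ``itv_volume_act_cc``,
    ``ptv_volume_cc``, ``ptv_volume_act_cc``; percent difference is
    (V_ACT - V_PCT) / V_PCT * 100.
    """
    df = cases.copy()
    for s in ("itv", "ptv"):
        if (df[f"{s}_volume_cc"] <= 0).any():
            raise ValueError(f"zero planning {s.upper()} volume")
        df[f"{s}_dv_pct"] = (
            (df[f"{s}_volume_act_cc"] - df[f"{s}_volume_cc"]) / df[f"{s}_volume_cc"] * 100.0
        )
    out = df.groupby("fraction")[["itv_dv_pct", "ptv_dv_pct"]].agg(["mean", "std"])
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    return out
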