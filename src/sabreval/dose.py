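"""Per-fraction delivered-dose workflow.

For each treatment fraction: align the planning CT to the daily image
(recorded couch correction), deformably register, compose the total map,
build the adaptive CT (ACT), propagate the target structures (aRS), compute
the per-fraction delivered dose (aRD) with an analytic dose model, warp the
dose back to the planning frame through the inverted total map, and average
the four fractions into the estimated delivered dose.

The analytic plan model (uniform core plus Gaussian penumbra) stands in for
a treatment planning system's dose engine: the analysis layer depends only
on dose *fields*, not on transport physics, so HU-dependent heterogeneity
effects are out of scope.  Dose is warped as a point quantity (no Jacobian
mass weighting), matching the common clinical dose-deformation convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from . import qa as _qa
from .grids import (
    BinaryMask,
    DisplacementField,
    GridGeometry,
    RigidTransform,
    VolumeGrid,
    equivalent_sphere_diameter_mm,
)
from .registration import (
    JacobianStats,
    RegistrationConfig,
    WarpStats,
    apply_rigid,
    bspline_register,
    compose_rigid_dvf,
    displacement_stats,
    invert_dvf,
    jacobian_log_stats,
    warp_image,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlanModel",
    "FractionResult",
    "PatientResult",
    "make_act",
    "propagate_mask",
    "compute_fraction_dose",
    "warp_dose_to_pct",
    "accumulate_mean",
    "evaluate_patient",
]


@dataclass
class PlanModel:
    """Analytic reference plan: uniform dose core of radius ``core_radius_mm``
    centred at the isocenter with a Gaussian penumbra of width
    ``penumbra_sigma_mm``, scaled so the planned PTV D95% equals the
    prescription."""

    prescription_cgy: float = 6000.0
    n_fractions: int = 4
    isocenter: np.ndarray = field(default_factory=lambda: np.zeros(3))
    core_radius_mm: float = 15.0
    penumbra_sigma_mm: float = 5.0
    scale: float = 1.0

    def __post_init__(self):
        if self.prescription_cgy <= 0:
            raise ValueError("prescription must be positive")
        self.isocenter = np.asarray(self.isocenter, dtype=float).reshape(3)

    def dose_at(self, points: np.ndarray) -> np.ndarray:
        """Total-course dose (cGy) at world points, shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        r = np.linalg.norm(pts - self.isocenter, axis=-1)
        excess = np.maximum(r - self.core_radius_mm, 0.0)
        return self.scale * self.prescription_cgy * np.exp(
            -0.5 * (excess / self.penumbra_sigma_mm) ** 2
        )

    def dose_on(self, geometry: GridGeometry) -> VolumeGrid:
        """Total-course planned dose evaluated at the grid's voxel centers."""
        vals = self.dose_at(geometry.voxel_centers())
        return VolumeGrid(geometry, vals, fill=0.0)


@dataclass
class FractionResult:
    """Everything produced for one fraction of one patient."""

    fraction: int
    act: VolumeGrid
    ars_itv: BinaryMask
    ars_ptv: BinaryMask
    ard_fixed: VolumeGrid        # per-fraction dose on the ACT/fixed grid
    ard_on_pct: VolumeGrid       # per-fraction dose warped back, total-course units
    dvf: DisplacementField       # deformable part only
    dvf_total: DisplacementField  # rigid + deformable as one field
    dvf_inverse: DisplacementField
    warp: WarpStats | None
    jacobian: JacobianStats | None
    dsc: float
    surface: _qa.SurfaceDistanceStats | None
    valid: bool = True


@dataclass
class PatientResult:
    patient_id: str
    planned: VolumeGrid
    delivered: VolumeGrid        # mean of the total-course-scaled warped-back doses
    fractions: list[FractionResult]
    records: list[dict]


def make_act(pct: VolumeGrid, setup: RigidTransform, dvf: DisplacementField) -> VolumeGrid:
    """ACT(x) = PCT(total_map(x)), the planning CT warped to the daily frame."""
    total = compose_rigid_dvf(setup, dvf)
    return warp_image(pct, total)


def propagate_mask(mask_on_pct: BinaryMask, total_map: DisplacementField) -> BinaryMask:
    """Propagate a planning structure through the total map (trilinear
    occupancy, thresholded at 0.5).  Warns if the result is empty."""
    out = warp_image(mask_on_pct, total_map)
    if out.values.sum() == 0:
        logger.warning("propagated structure left the field of view (empty mask)")
    return out


def compute_fraction_dose(
    plan: PlanModel,
    fixed_geometry: GridGeometry,
    setup: RigidTransform | None = None,
) -> VolumeGrid:
    """Per-fraction delivered dose on the fixed (treatment-room) grid.

    The dose cloud stays fixed to the plan isocenter in room coordinates; a
    residual setup transform displaces the cloud relative to the anatomy.
    Returns total-course dose divided by the number of fractions.
    """
    pts = fixed_geometry.voxel_centers()
    if setup is not None and not setup.is_identity:
        pts = setup.inverse().apply(pts.reshape(-1, 3)).reshape(pts.shape)
    vals = plan.dose_at(pts) / plan.n_fractions
    return VolumeGrid(fixed_geometry, vals, fill=0.0)


def warp_dose_to_pct(ard_fixed: VolumeGrid, dvf_total_inverse: DisplacementField) -> VolumeGrid:
    """Deform a fixed-frame dose back to the planning frame through the
    inverse of the total map, preserving tissue-element correspondence."""
    return warp_image(ard_fixed, dvf_total_inverse)


def accumulate_mean(doses_on_pct: list[VolumeGrid]) -> VolumeGrid:
    """Voxelwise arithmetic mean of the warped-back fraction doses."""
    if len(doses_on_pct) == 0:
        raise ValueError("no dose grids to accumulate")
    if len(doses_on_pct) != 4:
        logger.info("accumulating %d fraction doses (expected 4)", len(doses_on_pct))
    geom = doses_on_pct[0].geometry
    for d in doses_on_pct[1:]:
        if not d.geometry.same_as(geom):
            raise ValueError("fraction doses must share the planning geometry")
    vals = np.mean([d.values for d in doses_on_pct], axis=0)
    return VolumeGrid(geom, vals, fill=0.0)


def _nan_record(keys):
    return {k: float("nan") for k in keys}


def evaluate_fraction(patient, plan: PlanModel, scenario, reg_cfg: RegistrationConfig):
    """Run the full workflow for one fraction; returns a FractionResult."""
    pct, itv, ptv = patient.pct, patient.itv, patient.ptv
    setup = scenario.setup_error
    fixed = scenario.cbct
    moving = apply_rigid(pct, setup.inverse())
    dvf = bspline_register(fixed, moving, reg_cfg)
    total = compose_rigid_dvf(setup, dvf)
    act = warp_image(pct, total)
    ars_itv = propagate_mask(itv, total)
    ars_ptv = propagate_mask(ptv, total)
    ard = compute_fraction_dose(plan, fixed.geometry)
    inv = invert_dvf(total)
    ard_on_pct = warp_dose_to_pct(
        VolumeGrid(ard.geometry, ard.values * plan.n_fractions, fill=0.0), inv
    )
    valid = ars_ptv.values.any() and ars_itv.values.any()
    if valid:
        warp = displacement_stats(dvf, ars_ptv)
        jac = jacobian_log_stats(total, ars_ptv)
        dsc = _qa.dice(ptv, ars_ptv)
        surf = _qa.surface_distance_stats(ptv, ars_ptv)
    else:
        logger.warning(
            "patient %s fraction %d: empty propagated structure, case flagged",
            patient.patient_id, scenario.fraction_index,
        )
        warp = jac = surf = None
        dsc = float("nan")
    return FractionResult(
        fraction=scenario.fraction_index,
        act=act, ars_itv=ars_itv, ars_ptv=ars_ptv,
        ard_fixed=ard, ard_on_pct=ard_on_pct,
        dvf=dvf, dvf_total=total, dvf_inverse=inv,
        warp=warp, jacobian=jac, dsc=dsc, surface=surf, valid=bool(valid),
    )


def _fraction_record(patient, plan: PlanModel, fr: FractionResult,
                     planned: VolumeGrid) -> dict:
    """One row of the case table (the per-ACT parameter set)."""
    presc = plan.prescription_cgy
    rec = {
        "patient": patient.patient_id,
        "fraction": fr.fraction,
        "lobe": patient.lobe,
        "valid": fr.valid,
    }
    plan_ptv = _metrics.summarize_dose(planned, patient.ptv, presc)
    plan_itv_stats = _metrics.dose_stats_in_mask(planned, patient.itv)
    rec.update(
        itv_volume_cc=patient.itv.volume_cc,
        ptv_volume_cc=plan_ptv.volume_cc,
        eq_sphere_mm=plan_ptv.eq_sphere_mm,
        itv_eq_sphere_mm=equivalent_sphere_diameter_mm(patient.itv.volume_cc),
        planned_min=plan_ptv.d_min, planned_mean=plan_ptv.d_mean, planned_max=plan_ptv.d_max,
        planned_d2=plan_ptv.d2, planned_d95=plan_ptv.d95, planned_d98=plan_ptv.d98,
        planned_v100_cc=plan_ptv.v100_cc, planned_v50_cc=plan_ptv.v50_cc,
        itv_planned_min=plan_itv_stats[0], itv_planned_mean=plan_itv_stats[1],
        itv_planned_max=plan_itv_stats[2],
    )
    hi_plan = _metrics.homogeneity_index(plan_ptv.d2, plan_ptv.d98, presc)
    rec["hi_plan"] = hi_plan

    if not fr.valid:
        for k in ("itv_volume_act_cc", "ptv_volume_act_cc", "delivered_min",
                  "delivered_mean", "delivered_max", "delivered_d2", "delivered_d95",
                  "delivered_d98", "v100_cc", "v50_cc", "dsc", "surf_mean", "surf_sd",
                  "surf_max", "warp_min", "warp_mean", "warp_max", "logjac_min",
                  "logjac_q1", "logjac_median", "logjac_q3", "logjac_max", "logjac_mmr",
                  "logjac_iqr", "hi_del", "dhi", "ci", "gi", "gm_mm", "sub_min",
                  "sub_mean", "sub_max", "itv_del_min", "itv_del_mean", "itv_del_max",
                  "itv_sub_min", "itv_sub_mean", "itv_sub_max", "dmean_pct", "d95"):
            rec[k] = float("nan")
        return rec

    # delivered statistics on the fixed frame (ACT + aRS), total-course units
    dose_total = VolumeGrid(fr.ard_fixed.geometry,
                            fr.ard_fixed.values * plan.n_fractions, fill=0.0)
    deliv = _metrics.summarize_dose(dose_total, fr.ars_ptv, presc)
    itv_del = _metrics.dose_stats_in_mask(dose_total, fr.ars_itv)
    hi_del = _metrics.homogeneity_index(deliv.d2, deliv.d98, presc)
    # subtracted (delivered - planned) in the planning frame over the
    # original structures
    sub = VolumeGrid(planned.geometry, fr.ard_on_pct.values - planned.values, fill=0.0)
    sub_ptv = _metrics.dose_stats_in_mask(sub, patient.ptv)
    sub_itv = _metrics.dose_stats_in_mask(sub, patient.itv)
    rec.update(
        itv_volume_act_cc=fr.ars_itv.volume_cc,
        ptv_volume_act_cc=fr.ars_ptv.volume_cc,
        delivered_min=deliv.d_min, delivered_mean=deliv.d_mean, delivered_max=deliv.d_max,
        delivered_d2=deliv.d2, delivered_d95=deliv.d95, delivered_d98=deliv.d98,
        v100_cc=deliv.v100_cc, v50_cc=deliv.v50_cc,
        dsc=fr.dsc,
        surf_mean=fr.surface.mean, surf_sd=fr.surface.sd, surf_max=fr.surface.max,
        warp_min=fr.warp.min, warp_mean=fr.warp.mean, warp_max=fr.warp.max,
        logjac_min=fr.jacobian.min, logjac_q1=fr.jacobian.q1,
        logjac_median=fr.jacobian.median, logjac_q3=fr.jacobian.q3,
        logjac_max=fr.jacobian.max, logjac_mmr=fr.jacobian.mmr,
        logjac_iqr=fr.jacobian.iqr,
        hi_del=hi_del, dhi=hi_del - hi_plan,
        ci=_metrics.conformity_index(deliv.v100_cc, deliv.volume_cc),
        gi=_metrics.gradient_index(deliv.v100_cc, deliv.v50_cc),
        gm_mm=_metrics.gradient_measure(deliv.v50_cc, deliv.v100_cc),
        sub_min=sub_ptv[0], sub_mean=sub_ptv[1], sub_max=sub_ptv[2],
        itv_del_min=itv_del[0], itv_del_mean=itv_del[1], itv_del_max=itv_del[2],
        itv_sub_min=sub_itv[0], itv_sub_mean=sub_itv[1], itv_sub_max=sub_itv[2],
        dmean_pct=deliv.d_mean / presc * 100.0,
        d95=deliv.d95,
    )
    return rec


def evaluate_patient(patient, plan: PlanModel, fractions, reg_cfg=None) -> PatientResult:
    """Run register -> ACT -> propagate -> dose -> invert -> warp-back ->
    accumulate for one patient's fractions, emitting one case record per
    fraction and the accumulated delivered dose."""
    reg_cfg = reg_cfg or RegistrationConfig()
    planned = plan.dose_on(patient.pct.geometry)
    results, records = [], []
    for sc in fractions:
        fr = evaluate_fraction(patient, plan, sc, reg_cfg)
        results.append(fr)
        records.append(_fraction_record(patient, plan, fr, planned))
    delivered = accumulate_mean([fr.ard_on_pct for fr in results])
    return PatientResult(
        patient_id=patient.patient_id,
        planned=planned,
        delivered=delivered,
        fractions=results,
        records=records,
    )
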