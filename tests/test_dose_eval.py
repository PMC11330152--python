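"""The per-fraction delivered-dose workflow: ACT creation, structure
propagation, dose computation, warp-back and accumulation."""

import numpy as np
import pytest

from sabreval import reference
from sabreval.cohort import (
    CohortConfig,
    generate_fraction,
    generate_patient,
    generate_plan,
)
from sabreval.dose import (
    PlanModel,
    accumulate_mean,
    compute_fraction_dose,
    evaluate_patient,
    make_act,
    propagate_mask,
    warp_dose_to_pct,
)
from sabreval.grids import BinaryMask, DisplacementField, RigidTransform, VolumeGrid
from sabreval.metrics import dose_at_relative_volume
from sabreval.registration import RegistrationConfig, apply_rigid, compose_rigid_dvf

from .conftest import ball_mask, make_geometry


def zero_field(geom):
    return DisplacementField(geom, np.zeros((*geom.shape, 3)))


@pytest.fixture(scope="module")
def fast_cfg():
    return CohortConfig(profile="fast", seed=21)


@pytest.fixture(scope="module")
def patient(fast_cfg):
    return generate_patient(fast_cfg, 30)


@pytest.fixture(scope="module")
def plan(fast_cfg, patient):
    return generate_plan(patient, fast_cfg)


class TestMakeAct:
    def test_identity_maps_reproduce_pct(self, patient):
        act = make_act(patient.pct, RigidTransform(), zero_field(patient.pct.geometry))
        assert np.allclose(act.values, patient.pct.values, atol=1e-9)

    def test_constant_pct_stays_constant(self, geom8):
        pct = VolumeGrid(geom8, np.full(geom8.shape, -500.0), fill=-500.0)
        act = make_act(pct, RigidTransform(translation=(1.0, 2.0, 0.5)),
                       zero_field(geom8))
        assert np.allclose(act.values, -500.0)

    def test_act_is_closer_to_daily_image_than_rigid_only(self, fast_cfg, patient):
        from sabreval.registration import bspline_register

        sc = generate_fraction(patient, fast_cfg, 1, patient_index=30)
        moving = apply_rigid(patient.pct, sc.setup_error.inverse())
        dvf = bspline_register(sc.cbct, moving,
                               RegistrationConfig(passes=(30.0, 15.0), max_iter=10))
        act = make_act(patient.pct, sc.setup_error, dvf)
        rigid_only = make_act(patient.pct, sc.setup_error,
                              zero_field(patient.pct.geometry))
        mse_act = np.mean((act.values - sc.cbct.values) ** 2)
        mse_rigid = np.mean((rigid_only.values - sc.cbct.values) ** 2)
        assert mse_act < mse_rigid


class TestPropagateMask:
    def test_identity_map(self, patient):
        out = propagate_mask(patient.ptv, zero_field(patient.ptv.geometry))
        assert np.array_equal(out.values, patient.ptv.values)

    def test_integer_voxel_translation_preserves_volume(self):
        geom = make_geometry(shape=(20, 20, 20), spacing=(2.0, 2.0, 2.0))
        mask = ball_mask(geom, (0, 0, 0), 8.0)
        shift = np.array([2.0, -4.0, 2.0])  # exactly 1, -2, 1 voxels
        field = DisplacementField(geom, np.broadcast_to(shift, (*geom.shape, 3)).copy())
        out = propagate_mask(mask, field)
        assert out.volume_cc == pytest.approx(mask.volume_cc)
        expected = ball_mask(geom, -shift, 8.0)
        assert np.array_equal(out.values, expected.values)

    def test_empty_result_warns(self, caplog):
        geom = make_geometry(shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0))
        mask = ball_mask(geom, (0, 0, 0), 3.0)
        far = DisplacementField(geom, np.full((*geom.shape, 3), 500.0))
        import logging

        with caplog.at_level(logging.WARNING):
            out = propagate_mask(mask, far)
        assert out.values.sum() == 0
        assert any("empty" in r.message for r in caplog.records)


class TestFractionDose:
    def test_perfect_setup_quarter_of_plan(self, plan, patient):
        geom = patient.pct.geometry
        frac = compute_fraction_dose(plan, geom)
        assert np.allclose(frac.values * 4, plan.dose_on(geom).values, atol=1e-9)

    def test_large_residual_setup_degrades_coverage(self, fast_cfg, patient, plan):
        geom = patient.pct.geometry
        miss = RigidTransform(translation=(20.0, 0.0, 0.0))
        frac = compute_fraction_dose(plan, geom, setup=miss)
        doses = [VolumeGrid(geom, frac.values * 4, fill=0.0)] * 4
        accumulated = accumulate_mean(doses)
        d95 = dose_at_relative_volume(accumulated, patient.ptv, 95.0)
        assert d95 < plan.prescription_cgy

    def test_linearity(self, plan, patient):
        geom = patient.pct.geometry
        frac = compute_fraction_dose(plan, geom)
        doubled = accumulate_mean([VolumeGrid(geom, 2 * frac.values)] * 4)
        single = accumulate_mean([frac] * 4)
        assert np.allclose(doubled.values, 2 * single.values)


class TestWarpBack:
    def test_identity_map_identity_dose(self, plan, patient):
        geom = patient.pct.geometry
        dose = plan.dose_on(geom)
        out = warp_dose_to_pct(dose, zero_field(geom))
        assert np.array_equal(out.values, dose.values)

    def test_translation_closed_form(self, plan, patient):
        geom = patient.pct.geometry
        dose = plan.dose_on(geom)
        c = np.array([4.0, -2.0, 6.0])  # integer multiples of the 5 mm... no:
        c = np.array([5.0, -5.0, 10.0])  # integer voxels at 5 mm spacing
        inv = DisplacementField(geom, np.broadcast_to(-c, (*geom.shape, 3)).copy())
        out = warp_dose_to_pct(dose, inv)
        # warped-back dose at y equals fixed-frame dose at y - c
        expected = plan.dose_at(geom.voxel_centers() - c)
        interior = np.all(np.abs(geom.voxel_centers() - c - geom.origin) >= 0, axis=-1)
        assert np.allclose(out.values[interior], expected[interior], atol=1e-6)

    def test_mean_ptv_dose_conserved_under_translation(self, fast_cfg, patient, plan):
        """Change of variables: for a volume-preserving (translation) map the
        mean dose inside the warped-back PTV matches the mean dose inside the
        propagated PTV on the fixed grid."""
        geom = patient.pct.geometry
        t = np.array([5.0, 0.0, -5.0])  # integer voxels: exact correspondence
        total = DisplacementField(geom, np.broadcast_to(t, (*geom.shape, 3)).copy())
        inv = DisplacementField(geom, np.broadcast_to(-t, (*geom.shape, 3)).copy())
        ard = compute_fraction_dose(plan, geom)
        ars_ptv = propagate_mask(patient.ptv, total)
        back = warp_dose_to_pct(ard, inv)
        mean_fixed = ard.values[ars_ptv.as_bool()].mean()
        mean_pct = back.values[patient.ptv.as_bool()].mean()
        assert mean_pct == pytest.approx(mean_fixed, rel=1e-9)


class TestAccumulate:
    def test_four_identical_grids(self, geom8, rng):
        g = VolumeGrid(geom8, rng.uniform(0, 100, geom8.shape))
        out = accumulate_mean([g] * 4)
        assert np.allclose(out.values, g.values)

    def test_constant_mean(self, geom8):
        grids = [VolumeGrid(geom8, np.full(geom8.shape, v)) for v in (10.0, 20.0, 30.0, 40.0)]
        assert np.allclose(accumulate_mean(grids).values, 25.0)

    def test_permutation_invariance(self, geom8, rng):
        grids = [VolumeGrid(geom8, rng.uniform(0, 10, geom8.shape)) for _ in range(4)]
        a = accumulate_mean(grids)
        b = accumulate_mean(grids[::-1])
        assert np.allclose(a.values, b.values)

    def test_geometry_mismatch_rejected(self, geom8):
        other = make_geometry(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            accumulate_mean([VolumeGrid(geom8, np.zeros(geom8.shape)),
                             VolumeGrid(other, np.zeros(other.shape))])


class TestRigidOnlyScenario:
    def test_delivered_equals_planned_shifted(self, fast_cfg):
        """With a pure (known) setup translation and no deformation, the
        warped-back delivered dose equals the planned dose shifted by the
        setup residual -- here the couch records the full shift, so the
        delivered dose in the patient frame matches the plan."""
        cfg = CohortConfig(profile="fast", seed=77, setup_sigma_mm=0.0,
                           hu_noise_sd=0.0,
                           lobe_amplitude_mm={k: 0.0 for k in reference.LOBES})
        p = generate_patient(cfg, 0)
        plan = generate_plan(p, cfg)
        geom = p.pct.geometry
        from sabreval.registration import invert_dvf

        # integer-voxel shift: trilinear sampling is exact, so the check is sharp
        t = RigidTransform(translation=(5.0, -5.0, 10.0))
        total = compose_rigid_dvf(t, zero_field(geom))
        inv = invert_dvf(total)
        ard = compute_fraction_dose(plan, geom)
        back = warp_dose_to_pct(VolumeGrid(geom, ard.values * 4, fill=0.0), inv)
        # tissue at planning point y sat at room point total^-1(y) = y - t
        expected = plan.dose_at(geom.voxel_centers() - t.translation)
        sel = p.ptv.as_bool()
        assert np.allclose(back.values[sel], expected[sel], atol=1e-6)

        # sub-voxel shift: exactness degrades to trilinear interpolation error
        # in the penumbra, which stays a small fraction of the prescription
        t2 = RigidTransform(translation=(1.4, 1.7, -3.5))
        total2 = compose_rigid_dvf(t2, zero_field(geom))
        back2 = warp_dose_to_pct(VolumeGrid(geom, ard.values * 4, fill=0.0),
                                 invert_dvf(total2))
        expected2 = plan.dose_at(geom.voxel_centers() - t2.translation)
        err = np.abs(back2.values[sel] - expected2[sel])
        assert np.median(err) < 0.01 * plan.prescription_cgy
        assert err.max() < 0.15 * plan.prescription_cgy


class TestEvaluatePatient:
    def test_identity_cohort_null_pipeline(self):
        cfg = CohortConfig(profile="fast", seed=5, setup_sigma_mm=0.0, hu_noise_sd=0.0,
                           lobe_amplitude_mm={k: 0.0 for k in reference.LOBES})
        p = generate_patient(cfg, 0)
        plan = generate_plan(p, cfg)
        fractions = [generate_fraction(p, cfg, f, patient_index=0) for f in (1, 2, 3, 4)]
        result = evaluate_patient(p, plan, fractions,
                                  RegistrationConfig(passes=(30.0, 15.0), max_iter=10))
        assert np.max(np.abs(result.delivered.values - result.planned.values)) < 0.5
        for rec in result.records:
            assert rec["dhi"] == pytest.approx(0.0, abs=1e-9)
            assert rec["dsc"] == 1.0
            assert rec["warp_mean"] == pytest.approx(0.0, abs=1e-9)
            assert rec["logjac_mmr"] == pytest.approx(0.0, abs=1e-9)

    def test_four_records_per_patient(self, fast_cfg, patient, plan):
        fractions = [generate_fraction(patient, fast_cfg, f, patient_index=30)
                     for f in (1, 2, 3, 4)]
        result = evaluate_patient(patient, plan, fractions,
                                  RegistrationConfig(passes=(30.0, 15.0), max_iter=8))
        assert len(result.records) == 4
        for rec in result.records:
            assert rec["planned_d95"] == pytest.approx(6000.0, abs=0.1)
            assert rec["lobe"] == patient.lobe
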