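"""Synthetic phantom cohort: the stand-in for a 72-patient, 288-ACT study.

Patients are schematic thoraces — two low-HU ellipsoidal lungs inside a
soft-tissue body on an air background, with smooth random parenchymal
texture so deformable registration has intensity signal away from edges.
The tumour (ITV) is an ellipsoid seeded at one of five fixed lobe positions;
the PTV is the ITV dilated by an isotropic 5-7 mm margin.  Each fraction
carries a ground-truth smooth B-spline deformation (larger amplitude in the
lower lobes, mirroring diaphragm-driven motion) plus a small rigid setup
error; the daily image is the planning CT warped through that ground truth,
optionally with Gaussian HU noise.

All generators are pure functions of (config, seed): the global seed is
expanded into per-patient / per-fraction substreams with
``numpy.random.SeedSequence`` spawn keys, so outputs are reproducible
independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import reference
from ._bspline import BsplineLattice
from .dose import PlanModel
from .grids import (
    BinaryMask,
    DisplacementField,
    GridGeometry,
    RigidTransform,
    VolumeGrid,
    FILL_AIR_HU,
)
from .metrics import dose_at_relative_volume
from .registration import warp_image

__all__ = [
    "PROFILES",
    "CohortConfig",
    "PhantomPatient",
    "FractionScenario",
    "RegressionTableConfig",
    "generate_patient",
    "generate_fraction",
    "generate_plan",
    "generate_cohort",
    "generate_regression_table",
]

#: grid profiles: desk-scale "fast" and higher-resolution "fine"
PROFILES = {
    "fast": {"shape": (32, 32, 32), "spacing": 5.0},
    "fine": {"shape": (64, 64, 64), "spacing": 2.5},
}

#: default per-lobe cohort composition (patients; four fractions each)
DEFAULT_LOBE_COUNTS = {"LUL": 21, "LLL": 15, "RUL": 16, "RML": 4, "RLL": 16}

#: ground-truth deformation amplitude (mm) at the control points, by lobe;
#: ordered so lower-lobe targets move more than upper-lobe targets
DEFAULT_LOBE_AMPLITUDE_MM = {
    lobe: reference.LOBE_SUMMARY[lobe]["warp_mean"] for lobe in reference.LOBES
}

#: tumour seed positions (mm, world frame centred on the thorax) per lobe
_LOBE_POSITIONS = {
    "LUL": (-38.0, 0.0, 36.0),
    "LLL": (-38.0, 0.0, -30.0),
    "RUL": (38.0, 0.0, 36.0),
    "RML": (38.0, 10.0, 4.0),
    "RLL": (38.0, 0.0, -30.0),
}

_HU_BODY = 40.0
_HU_LUNG = -800.0
_HU_TUMOR = 20.0
_LUNG_TEXTURE_SD_HU = 60.0


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 72
    fractions_per_patient: int = 4
    margin_mm: float = 6.0
    lobe_counts: dict = field(default_factory=lambda: dict(DEFAULT_LOBE_COUNTS))
    lobe_amplitude_mm: dict = field(default_factory=lambda: dict(DEFAULT_LOBE_AMPLITUDE_MM))
    deformation_cp_spacing_mm: float = 30.0
    setup_sigma_mm: float = 1.0
    hu_noise_sd: float = 5.0
    profile: str = "fast"
    prescription_cgy: float = reference.PRESCRIPTION_CGY
    penumbra_sigma_mm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 5.0 <= self.margin_mm <= 7.0:
            raise ValueError("PTV margin must be between 5 and 7 mm")
        if sum(self.lobe_counts.values()) != self.n_patients:
            raise ValueError("lobe counts must sum to n_patients")
        if any(a < 0 for a in self.lobe_amplitude_mm.values()):
            raise ValueError("deformation amplitudes must be non-negative")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def geometry(self) -> GridGeometry:
        p = PROFILES[self.profile]
        shape = np.array(p["shape"])
        spacing = np.full(3, p["spacing"], dtype=float)
        origin = -(shape - 1) / 2.0 * spacing
        return GridGeometry(origin=origin, spacing=spacing, shape=tuple(shape))

    def lobe_of_patient(self, patient_index: int) -> str:
        """Deterministic lobe assignment: patients in config order of lobes."""
        if not 0 <= patient_index < self.n_patients:
            raise ValueError("patient index out of range")
        cum = 0
        for lobe, n in self.lobe_counts.items():
            cum += n
            if patient_index < cum:
                return lobe
        raise AssertionError("unreachable")


@dataclass
class PhantomPatient:
    patient_id: str
    pct: VolumeGrid
    itv: BinaryMask
    ptv: BinaryMask
    lobe: str
    isocenter: np.ndarray


@dataclass
class FractionScenario:
    fraction_index: int
    setup_error: RigidTransform
    true_deformation: DisplacementField
    cbct: VolumeGrid


def _rng_for(config_seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=spawn_key))


def _ellipsoid(centers: np.ndarray, center, radii) -> np.ndarray:
    rel = (centers - np.asarray(center, float)) / np.asarray(radii, float)
    return np.sum(rel**2, axis=-1) <= 1.0


def generate_patient(config: CohortConfig, patient_index: int) -> PhantomPatient:
    """Build one phantom patient (planning CT, ITV, PTV, lobe label)."""
    lobe = config.lobe_of_patient(patient_index)
    rng = _rng_for(config.seed, 1, patient_index)
    geom = config.geometry
    centers = geom.voxel_centers()

    body = _ellipsoid(centers, (0.0, 0.0, 4.0), (70.0, 60.0, 74.0))
    lungs = _ellipsoid(centers, (-38.0, 0.0, 5.0), (26.0, 34.0, 55.0)) | _ellipsoid(
        centers, (38.0, 0.0, 5.0), (26.0, 34.0, 55.0)
    )
    lungs &= body

    pos = np.asarray(_LOBE_POSITIONS[lobe]) + rng.normal(0.0, 2.0, size=3)
    radii = rng.uniform(8.0, 13.0, size=3)
    itv_arr = _ellipsoid(centers, pos, radii)

    hu = np.full(geom.shape, FILL_AIR_HU)
    hu[body] = _HU_BODY
    texture = ndimage.gaussian_filter(rng.standard_normal(geom.shape), sigma=1.5)
    texture *= _LUNG_TEXTURE_SD_HU / texture.std()
    hu[lungs] = _HU_LUNG + texture[lungs]
    hu[itv_arr] = _HU_TUMOR

    itv = BinaryMask(geom, itv_arr.astype(np.uint8))
    # Euclidean dilation on the voxel grid: PTV = points within margin of ITV
    dist = ndimage.distance_transform_edt(~itv_arr, sampling=geom.spacing)
    ptv = BinaryMask(geom, (dist <= config.margin_mm).astype(np.uint8))

    return PhantomPatient(
        patient_id=f"P{patient_index:03d}",
        pct=VolumeGrid(geom, hu, fill=FILL_AIR_HU),
        itv=itv,
        ptv=ptv,
        lobe=lobe,
        isocenter=pos,
    )


def generate_fraction(
    patient: PhantomPatient, config: CohortConfig, fraction_index: int,
    patient_index: int | None = None,
) -> FractionScenario:
    """Ground-truth deformation + setup error + daily image for one fraction."""
    if patient_index is None:
        patient_index = int(patient.patient_id.lstrip("P"))
    rng = _rng_for(config.seed, 2, patient_index, fraction_index)
    geom = patient.pct.geometry

    t = rng.normal(0.0, config.setup_sigma_mm, size=3)
    setup = RigidTransform(translation=t)

    amp = config.lobe_amplitude_mm[patient.lobe]
    lattice = BsplineLattice(geom, config.deformation_cp_spacing_mm)
    coeff = rng.normal(0.0, amp, size=(*lattice.control_shape, 3))
    u = lattice.expand_vector(coeff)
    truth = DisplacementField(geom, u)

    total = DisplacementField(geom, u + t)  # rigid (identity rotation) after deformation
    cbct = warp_image(patient.pct, total)
    if config.hu_noise_sd > 0:
        cbct = VolumeGrid(
            geom, cbct.values + rng.normal(0.0, config.hu_noise_sd, size=geom.shape),
            fill=cbct.fill,
        )
    return FractionScenario(
        fraction_index=fraction_index, setup_error=setup,
        true_deformation=truth, cbct=cbct,
    )


def generate_plan(patient: PhantomPatient, config: CohortConfig) -> PlanModel:
    """Analytic reference plan normalised so planned PTV D95% equals the
    prescription (uniform core of the PTV's equivalent-sphere radius plus
    Gaussian penumbra, centred at the isocenter)."""
    if not patient.ptv.values.any():
        raise ValueError("PTV is empty")
    from .grids import equivalent_sphere_diameter_mm

    core_r = 0.5 * equivalent_sphere_diameter_mm(patient.ptv.volume_cc)
    plan = PlanModel(
        prescription_cgy=config.prescription_cgy,
        n_fractions=config.fractions_per_patient,
        isocenter=patient.isocenter,
        core_radius_mm=core_r,
        penumbra_sigma_mm=config.penumbra_sigma_mm,
        scale=1.0,
    )
    planned = plan.dose_on(patient.pct.geometry)
    d95 = dose_at_relative_volume(planned, patient.ptv, 95.0)
    plan.scale = config.prescription_cgy / d95
    return plan


def generate_cohort(config: CohortConfig) -> Iterator[tuple[PhantomPatient, PlanModel, list[FractionScenario]]]:
    """Yield (patient, plan, fractions) for the whole cohort."""
    for i in range(config.n_patients):
        patient = generate_patient(config, i)
        plan = generate_plan(patient, config)
        fractions = [
            generate_fraction(patient, config, f, patient_index=i)
            for f in range(1, config.fractions_per_patient + 1)
        ]
        yield patient, plan, fractions


# ---------------------------------------------------------------------------
# tabular generator for the statistics layer


@dataclass
class RegressionTableConfig:
    """Generator for case tables following the reference cohort's fitted
    linear model of PTV D95% on (dHI, Dmean%, DSC, Warp_mean).

    Covariates are drawn independently by default (the reference cohort's
    mild collinearity is not emulated); a Gaussian-copula correlation matrix
    can be supplied to exercise VIF > 1.  The residual SD is either given
    explicitly (cGy) or calibrated so the generator's population R-squared
    equals ``r2_target``.
    """

    n_cases: int = 288
    model: reference.RegressionModelSpec = field(default_factory=lambda: reference.FULL_MODEL)
    sigma_eps: float | None = None
    r2_target: float = 0.843
    n_noise_covariates: int = 0
    copula_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma_eps is not None and self.sigma_eps < 0:
            raise ValueError("residual SD must be non-negative")
        if not 0 < self.r2_target < 1:
            raise ValueError("r2_target must be in (0, 1)")

    def marginals(self) -> dict:
        """Frozen scipy distributions of the candidate covariates."""
        t = reference.LOBE_SUMMARY["Total"]
        dsc_mu, dsc_sd = t["dsc_mean"], t["dsc_sd"]
        warp_mu, warp_sd = t["warp_mean"], t["warp_sd"]
        dists = {
            "dhi": stats.gamma(a=2.0, scale=2.5),
            "dmean_pct": stats.norm(loc=100.0, scale=1.63),
            "dsc": stats.truncnorm((0.0 - dsc_mu) / dsc_sd, (1.0 - dsc_mu) / dsc_sd,
                                   loc=dsc_mu, scale=dsc_sd),
            "warp_mean": stats.truncnorm((0.0 - warp_mu) / warp_sd, np.inf,
                                         loc=warp_mu, scale=warp_sd),
        }
        return {k: dists[k] for k in self.model.coefficients}

    def population_lp_variance(self) -> float:
        """Variance of the linear predictor under the generating
        distributions (exact for independent covariates)."""
        marg = self.marginals()
        if self.copula_corr is None:
            return float(sum(
                b**2 * marg[k].var() for k, b in self.model.coefficients.items()
            ))
        # correlated covariates: Monte-Carlo under a fixed internal stream
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(99,)))
        x = self._draw_covariates(rng, 200_000)
        lp = sum(b * x[k] for k, b in self.model.coefficients.items())
        return float(np.var(lp))

    def resolved_sigma_eps(self) -> float:
        """Residual SD: explicit, or calibrated from the population R²:
        sigma² = Var(linear predictor) * (1 - R²) / R²."""
        if self.sigma_eps is not None:
            return self.sigma_eps
        v = self.population_lp_variance()
        return float(np.sqrt(v * (1.0 - self.r2_target) / self.r2_target))

    def _draw_covariates(self, rng: np.random.Generator, n: int) -> dict:
        marg = self.marginals()
        names = list(marg)
        if self.copula_corr is None:
            return {k: marg[k].rvs(size=n, random_state=rng) for k in names}
        corr = np.asarray(self.copula_corr, dtype=float)
        if corr.shape != (len(names), len(names)):
            raise ValueError("copula correlation matrix has wrong shape")
        z = rng.multivariate_normal(np.zeros(len(names)), corr, size=n)
        u = stats.norm.cdf(z)
        return {k: marg[k].ppf(u[:, i]) for i, k in enumerate(names)}


def generate_regression_table(rconfig: RegressionTableConfig) -> pd.DataFrame:
    """Draw a case table: covariates, optional pure-noise candidates, a lobe
    label (per the reference cohort's proportions), and the response
    d95 = intercept + sum B_k x_k + Normal(0, sigma_eps)."""
    rng = np.random.default_rng(np.random.SeedSequence(rconfig.seed, spawn_key=(3,)))
    n = rconfig.n_cases
    x = rconfig._draw_covariates(rng, n)
    df = pd.DataFrame(x)
    for j in range(rconfig.n_noise_covariates):
        df[f"noise{j + 1}"] = rng.standard_normal(n)
    counts = {k: v["n"] for k, v in reference.LOBE_SUMMARY.items() if k != "Total"}
    total = sum(counts.values())
    probs = np.array([c / total for c in counts.values()])
    df["lobe"] = rng.choice(list(counts), size=n, p=probs)
    sigma = rconfig.resolved_sigma_eps()
    lp = rconfig.model.intercept + sum(
        b * df[k].to_numpy() for k, b in rconfig.model.coefficients.items()
    )
    df["d95"] = lp + rng.normal(0.0, sigma, size=n)
    return df
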