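"""Published summary statistics of the clinical lung-SABR cohort that the
synthetic phantoms and regression generators in this package are calibrated
to: 72 NSCLC patients, 60 Gy prescribed to 95% of the PTV in 4 fractions,
288 adaptive-CT cases in total.

These numbers parameterise the generators and serve as arithmetic
consistency checks; they are inputs, not results computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PRESCRIPTION_CGY",
    "N_FRACTIONS",
    "N_PATIENTS",
    "LOBES",
    "LOBE_SUMMARY",
    "RegressionModelSpec",
    "FULL_MODEL",
    "SUBGROUP_MODEL",
    "SUBGROUP_DHI_MAX",
]

PRESCRIPTION_CGY = 6000.0   # 60 Gy to the 95% volume of the PTV
N_FRACTIONS = 4
N_PATIENTS = 72

#: lung lobes: left/right upper, left lower, right middle, right lower
LOBES = ("LUL", "LLL", "RUL", "RML", "RLL")

#: per-lobe case counts and mean +/- SD of PTV D95% (cGy), DSC, and mean PTV
#: displacement (mm) in the reference cohort; "Total" is the 288-case pool.
LOBE_SUMMARY = {
    "LUL": {"n": 84, "d95_mean": 5920.0, "d95_sd": 147.6, "dsc_mean": 0.97, "dsc_sd": 0.04, "warp_mean": 1.57, "warp_sd": 0.83},
    "LLL": {"n": 60, "d95_mean": 5775.1, "d95_sd": 439.4, "dsc_mean": 0.96, "dsc_sd": 0.06, "warp_mean": 1.92, "warp_sd": 1.22},
    "RUL": {"n": 64, "d95_mean": 5889.5, "d95_sd": 120.9, "dsc_mean": 0.97, "dsc_sd": 0.04, "warp_mean": 1.51, "warp_sd": 0.68},
    "RML": {"n": 16, "d95_mean": 5806.5, "d95_sd": 189.7, "dsc_mean": 0.98, "dsc_sd": 0.04, "warp_mean": 2.47, "warp_sd": 1.07},
    "RLL": {"n": 64, "d95_mean": 5800.5, "d95_sd": 349.8, "dsc_mean": 0.96, "dsc_sd": 0.08, "warp_mean": 2.20, "warp_sd": 1.39},
    "Total": {"n": 288, "d95_mean": 5850.2, "d95_sd": 285.5, "dsc_mean": 0.97, "dsc_sd": 0.06, "warp_mean": 1.82, "warp_sd": 1.09},
}


@dataclass(frozen=True)
class RegressionModelSpec:
    """A fitted linear model for PTV D95% (cGy): intercept and per-covariate
    unstandardised coefficients, as reported for the reference cohort."""

    intercept: float
    intercept_se: float
    coefficients: dict = field(default_factory=dict)       # term -> B
    standard_errors: dict = field(default_factory=dict)    # term -> SE(B)
    standardized_betas: dict = field(default_factory=dict)
    adjusted_r2: float = float("nan")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


#: Stepwise model on all 288 cases: D95% ~ dHI + Dmean% + DSC + Warp_mean.
#: dhi is the delivered-minus-planned homogeneity-index difference, dmean_pct
#: the mean delivered PTV dose as % of prescription, warp_mean in mm.
FULL_MODEL = RegressionModelSpec(
    intercept=2032.97,
    intercept_se=572.31,
    coefficients={"dhi": -21.49, "dmean_pct": 33.45, "dsc": 558.55, "warp_mean": -33.71},
    standard_errors={"dhi": 1.08, "dmean_pct": 5.30, "dsc": 149.40, "warp_mean": 9.78},
    standardized_betas={"dhi": -0.648, "dmean_pct": 0.191, "dsc": 0.111, "warp_mean": -0.128},
    adjusted_r2=0.843,
)

#: Refit after excluding the high-dHI cases (dHI > 17): only the dosimetric
#: covariates remain.
SUBGROUP_MODEL = RegressionModelSpec(
    intercept=3924.36,
    intercept_se=240.32,
    coefficients={"dhi": -26.98, "dmean_pct": 19.98},
    standard_errors={"dhi": 0.92, "dmean_pct": 2.31},
    standardized_betas={"dhi": -0.790, "dmean_pct": 0.232},
    adjusted_r2=0.85,
)

#: homogeneity-index-difference cutoff used for the subgroup refit
SUBGROUP_DHI_MAX = 17.0
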