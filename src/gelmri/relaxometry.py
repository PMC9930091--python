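"""Relaxivity calibration and conversion of R1 maps to agent concentration.

A paramagnetic contrast agent raises the longitudinal relaxation rate in
proportion to its concentration,

    R1 = 1/T1 = R1(0) + r1 [CA],

with medium-dependent longitudinal relaxivity r1 (mM^-1 s^-1). Calibration
samples of known concentration fix r1 for each medium (PBS, and each gel
formulation); an R1 map of an unknown sample is then inverted voxel- or
ROI-wise to concentration. All concentrations are per agent molecule; the
74 kDa molecular weight converts between mM and mg/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import MW_GALBUMIN_KDA

__all__ = [
    "RelaxivityCalibration",
    "ConcentrationResult",
    "compute_relaxivity",
    "concentration_from_r1",
    "convert_units",
]


@dataclass
class RelaxivityCalibration:
    """Longitudinal relaxivity of a contrast agent in one medium."""

    medium: str
    r1: float  # mM^-1 s^-1
    r1_0: float  # s^-1, relaxation rate at zero agent
    concentrations_mM: np.ndarray
    t1_s: np.ndarray
    method: str  # "per-sample" | "regression"
    per_sample_r1: np.ndarray | None = None
    r1_sd: float = float("nan")
    intercept: float = float("nan")  # regression intercept (s^-1)
    r_squared: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_mM": self.concentrations_mM,
                "T1_s": self.t1_s,
                "R1_s": 1.0 / self.t1_s,
            }
        )


@dataclass
class ConcentrationResult:
    """Agent concentration derived from R1, in mM and mg/mL."""

    concentration_mM: np.ndarray | float
    concentration_mg_per_ml: np.ndarray | float
    medium: str
    molecular_weight_kda: float
    n_clipped: int = 0  # slightly negative values clipped to zero
    provenance: dict = field(default_factory=dict)


def convert_units(value, molecular_weight_kda: float = MW_GALBUMIN_KDA,
                  to: str = "mM"):
    """Convert between mg/mL and mM for a solute of given molecular weight.

    kDa is kg/mol, so numerically mg/mL = mM x MW(kDa). ``to`` names the
    target unit ("mM" converts from mg/mL, "mg/mL" from mM). Exact inverse
    round trip.
    """
    if molecular_weight_kda <= 0:
        raise ValueError("molecular weight must be positive")
    v = np.asarray(value, dtype=float)
    if to == "mM":
        out = v / molecular_weight_kda
    elif to in ("mg/mL", "mg_per_ml"):
        out = v * molecular_weight_kda
    else:
        raise ValueError("to must be 'mM' or 'mg/mL'")
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def compute_relaxivity(
    concentrations_mM,
    t1_s,
    t1_0_s: float,
    medium: str = "",
    method: str = "regression",
) -> RelaxivityCalibration:
    """Estimate longitudinal relaxivity from a calibration ladder.

    per-sample
        r1_i = (1/T1_i - 1/T1_0) / [CA]_i for each sample; r1 is their mean
        and the dispersion their SD (mirrors the single-sample definition).
    regression (default)
        least-squares slope of R1 against [CA] with free intercept; the
        intercept is reported next to the measured R1_0 as a consistency
        diagnostic. Needs >= 2 distinct concentrations.

    Both estimators agree exactly on noiseless linear data.
    """
    c = np.atleast_1d(np.asarray(concentrations_mM, dtype=float))
    t1 = np.atleast_1d(np.asarray(t1_s, dtype=float))
    if c.shape != t1.shape:
        raise ValueError("concentration and T1 arrays must align")
    if t1_0_s <= 0 or np.any(t1 <= 0):
        raise ValueError("T1 values must be positive")
    if np.unique(c).size != c.size:
        raise ValueError("calibration concentrations must be distinct")
    r1_obs = 1.0 / t1
    r1_0 = 1.0 / t1_0_s

    if method == "per-sample":
        if np.any(c <= 0):
            raise ValueError("per-sample estimator needs strictly positive concentrations")
        per = (r1_obs - r1_0) / c
        r1 = float(per.mean())
        sd = float(per.std(ddof=1)) if per.size > 1 else 0.0
        return RelaxivityCalibration(
            medium=medium, r1=r1, r1_0=r1_0, concentrations_mM=c, t1_s=t1,
            method=method, per_sample_r1=per, r1_sd=sd,
        )
    if method == "regression":
        if c.size < 2:
            raise ValueError("regression needs >= 2 calibration points")
        res = sm.OLS(r1_obs, sm.add_constant(c)).fit()
        intercept, slope = res.params
        return RelaxivityCalibration(
            medium=medium, r1=float(slope), r1_0=r1_0, concentrations_mM=c,
            t1_s=t1, method=method, r1_sd=float(res.bse[1]),
            intercept=float(intercept), r_squared=float(res.rsquared),
        )
    raise ValueError("method must be 'per-sample' or 'regression'")


def concentration_from_r1(
    r1,
    r1_blank: float,
    cal: RelaxivityCalibration,
    clip_tolerance_mM: float = 0.0,
) -> ConcentrationResult:
    """Invert the relaxivity relation: [CA] = (R1 - R1_blank) / r1.

    ``r1`` may be a scalar (ROI mean) or a map. Values in
    [-clip_tolerance_mM, 0) — noise excursions below zero — are clipped to
    zero and counted; values below the tolerance are left negative so
    genuine inconsistencies stay visible.
    """
    if cal.r1 <= 0:
        raise ValueError("calibration relaxivity must be positive")
    r1_arr = np.asarray(r1, dtype=float)
    c = (r1_arr - r1_blank) / cal.r1
    n_clipped = 0
    if clip_tolerance_mM > 0:
        clip = (c < 0) & (c >= -clip_tolerance_mM)
        n_clipped = int(np.count_nonzero(clip))
        c = np.where(clip, 0.0, c)
        if n_clipped:
            warnings.warn(f"clipped {n_clipped} slightly negative concentrations to 0")
    scalar = np.isscalar(r1) or r1_arr.ndim == 0
    c_out = float(c) if scalar else c
    mg = convert_units(c_out, MW_GALBUMIN_KDA, to="mg/mL")
    return ConcentrationResult(
        concentration_mM=c_out,
        concentration_mg_per_ml=mg,
        medium=cal.medium,
        molecular_weight_kda=MW_GALBUMIN_KDA,
        n_clipped=n_clipped,
        provenance={"r1": cal.r1, "r1_blank": r1_blank, "method": cal.method},
    )
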