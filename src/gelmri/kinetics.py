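"""Release kinetics: cumulative release, rate constants, diffusion, mesh size.

Turns ROI concentration and gel-volume time series into apparent and
volume-corrected cumulative release, fits Higuchi-type sqrt-time release-rate
constants, inverts the early-time Fickian slab law for an apparent diffusion
coefficient, and estimates the polymer-network mesh size from rubber
elasticity. Also provides the in vitro / in vivo release comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import (
    ALBUMIN_DIAMETER_NM,
    AVOGADRO,
    BODY_TEMPERATURE_K,
    GAS_CONSTANT,
)

__all__ = [
    "ReleaseSeries",
    "RateFit",
    "MeshResult",
    "DiffusionResult",
    "cumulative_release",
    "sqrt_time_fit",
    "diffusion_from_rate",
    "mesh_size",
    "estimate_plateau",
    "ivivr_table",
]


@dataclass
class ReleaseSeries:
    """Time course of gel concentration, volume and cumulative release.

    Release is expressed in percent of the dose present in the gel at the
    first acquisition time point ``times_h[0]``. The volume-corrected release
    uses the gel mass C(t)*V(t); the apparent release freezes the volume at
    its first-time-point value, so swelling or shrinkage masquerades as
    release/uptake in the apparent curve.
    """

    times_h: np.ndarray
    concentration_mM: np.ndarray
    volume_uL: np.ndarray
    apparent_release_pct: np.ndarray
    corrected_release_pct: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "concentration_mM": self.concentration_mM,
                "volume_uL": self.volume_uL,
                "apparent_release_pct": self.apparent_release_pct,
                "corrected_release_pct": self.corrected_release_pct,
            }
        )


@dataclass
class RateFit:
    """Sqrt-time (Higuchi-type) release-rate regression result."""

    k_pct_per_sqrt_h: float
    intercept_pct: float
    r_squared: float
    window_h: tuple[float, float]
    n_points: int
    slope_se: float = float("nan")
    #: two-series slope comparison (interaction term), when requested
    comparison: dict | None = None


@dataclass
class MeshResult:
    """Rubber-elasticity mesh-size estimate and release-regime verdict."""

    g_prime_pa: float
    temperature_k: float
    mesh_size_nm: float
    solute_diameter_nm: float
    verdict: str  # "diffusive" | "hindered"


@dataclass
class DiffusionResult:
    """Apparent diffusion coefficient from the early-time slab release law."""

    d_m2_s: float
    slab_thickness_m: float
    geometry: str  # "one_sided" | "two_sided"
    prefactor: float
    diffusional_thickness_m: float
    k_pct_per_sqrt_h: float


def cumulative_release(
    concentration_mM,
    volume_uL,
    times_h,
    *,
    label: str = "",
) -> ReleaseSeries:
    """Cumulative release in % of the dose at the first time point.

    The gel's agent mass is C(t)*V(t); release at time t relative to the
    first measurement t1 is

        release(t) = 100 * (1 - C(t) V(t) / (C(t1) V(t1)))    (corrected)
        release(t) = 100 * (1 - C(t) / C(t1))                 (apparent)

    The apparent curve ignores gel swelling/shrinkage (V frozen at V(t1)).
    Both curves are 0 at t1 by construction. Units cancel in the ratios, so
    any consistent concentration and volume units may be supplied.

    Parameters
    ----------
    concentration_mM, volume_uL, times_h
        Equal-length sequences (>= 2 points); times strictly increasing.

    Raises
    ------
    ValueError
        On length mismatch, < 2 points, non-increasing times, or a
        non-positive concentration at the first time point.
    """
    c = np.asarray(concentration_mM, dtype=float)
    v = np.asarray(volume_uL, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if not (c.shape == v.shape == t.shape) or c.ndim != 1:
        raise ValueError("concentration, volume and times must be equal-length 1-D")
    if c.size < 2:
        raise ValueError("need at least 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if c[0] <= 0:
        raise ValueError("reference concentration C(t1) must be positive")
    if np.any(v <= 0):
        raise ValueError("gel volumes must be positive")

    mass0 = c[0] * v[0]
    corrected = 100.0 * (1.0 - c * v / mass0)
    apparent = 100.0 * (1.0 - c / c[0])
    return ReleaseSeries(
        times_h=t,
        concentration_mM=c,
        volume_uL=v,
        apparent_release_pct=apparent,
        corrected_release_pct=corrected,
        label=label,
    )


def sqrt_time_fit(
    series: ReleaseSeries,
    window_h: tuple[float, float] | None = None,
    *,
    use_corrected: bool = True,
    other: ReleaseSeries | None = None,
) -> RateFit:
    """OLS of cumulative release (%) on sqrt(time in hours), free intercept.

    A linear relation between release and sqrt(t) indicates diffusion-
    controlled (Higuchi-type) kinetics; the slope k (% per h^1/2) is the
    release-rate constant. The intercept is left free so an initial burst
    does not bias the slope.

    Parameters
    ----------
    series
        Release time course.
    window_h
        (start, end) in hours; points with start <= t <= end are fitted.
        Defaults to the full observed span.
    use_corrected
        Fit the volume-corrected curve (default) or the apparent one.
    other
        Optional second series; when given, a pooled regression with a
        group x sqrt(t) interaction tests whether the two slopes differ,
        reported in ``RateFit.comparison``.
    """
    t = series.times_h
    y = series.corrected_release_pct if use_corrected else series.apparent_release_pct
    if window_h is None:
        window_h = (float(t[0]), float(t[-1]))
    lo, hi = float(window_h[0]), float(window_h[1])
    if not hi > lo:
        raise ValueError("degenerate fit window")
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points inside the fit window")

    x = np.sqrt(t[sel])
    res = sm.OLS(y[sel], sm.add_constant(x)).fit()
    intercept, slope = res.params
    slope_se = float(res.bse[1])

    comparison = None
    if other is not None:
        yo = other.corrected_release_pct if use_corrected else other.apparent_release_pct
        selo = (other.times_h >= lo) & (other.times_h <= hi)
        xo = np.sqrt(other.times_h[selo])
        xs = np.concatenate([x, xo])
        grp = np.concatenate([np.zeros(x.size), np.ones(xo.size)])
        design = np.column_stack([np.ones(xs.size), xs, grp, xs * grp])
        pooled = sm.OLS(np.concatenate([y[sel], yo[selo]]), design).fit()
        ftest = pooled.f_test(np.array([[0.0, 0.0, 0.0, 1.0]]))
        comparison = {
            "slope_difference": float(pooled.params[3]),
            "f_statistic": float(ftest.fvalue),
            "p_value": float(ftest.pvalue),
            "df": (int(ftest.df_num), int(ftest.df_denom)),
        }

    return RateFit(
        k_pct_per_sqrt_h=float(slope),
        intercept_pct=float(intercept),
        r_squared=float(res.rsquared),
        window_h=(lo, hi),
        n_points=int(sel.sum()),
        slope_se=slope_se,
        comparison=comparison,
    )


def diffusion_from_rate(
    k_pct_per_sqrt_h: float,
    slab_thickness_m: float,
    geometry: str = "one_sided",
    prefactor: float = 4.0,
) -> DiffusionResult:
    """Invert the early-time Fickian slab law for the diffusion coefficient.

    Early-time release from a plane slab follows

        Mt/Minf = P * sqrt(D t / (pi * L_d^2)),

    with prefactor P = 4 and diffusional thickness L_d equal to the full
    slab thickness for two-sided release. A slab of thickness L sealed at
    its base and releasing through one face is the half-problem of a
    symmetric slab of thickness 2L, so L_d = 2L one-sided. Solving for D
    from the fitted slope k (% per h^1/2, i.e. fraction-per-sqrt-second
    slope k/100/60):

        D = pi * L_d^2 * (k/100/60)^2 / P^2
    """
    if k_pct_per_sqrt_h <= 0:
        raise ValueError("rate constant must be positive")
    if slab_thickness_m <= 0:
        raise ValueError("slab thickness must be positive")
    if geometry == "one_sided":
        l_d = 2.0 * slab_thickness_m
    elif geometry == "two_sided":
        l_d = slab_thickness_m
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    # per-sqrt-hour -> per-sqrt-second: divide by sqrt(3600) = 60
    slope_frac_per_sqrt_s = k_pct_per_sqrt_h / 100.0 / 60.0
    d = np.pi * l_d**2 * slope_frac_per_sqrt_s**2 / prefactor**2
    return DiffusionResult(
        d_m2_s=float(d),
        slab_thickness_m=float(slab_thickness_m),
        geometry=geometry,
        prefactor=float(prefactor),
        diffusional_thickness_m=float(l_d),
        k_pct_per_sqrt_h=float(k_pct_per_sqrt_h),
    )


def early_time_slope_pct_per_sqrt_h(
    d_m2_s: float,
    slab_thickness_m: float,
    geometry: str = "one_sided",
    prefactor: float = 4.0,
) -> float:
    """Analytic early-time release slope, % per h^1/2 (inverse of
    :func:`diffusion_from_rate`)."""
    l_d = 2.0 * slab_thickness_m if geometry == "one_sided" else slab_thickness_m
    return 100.0 * prefactor * np.sqrt(d_m2_s / (np.pi * l_d**2)) * 60.0


def mesh_size(
    g_prime_pa: float,
    temperature_k: float = BODY_TEMPERATURE_K,
    solute_diameter_nm: float = ALBUMIN_DIAMETER_NM,
) -> MeshResult:
    """Polymer-network mesh size from rubber elasticity.

    Treating the gel as an affine rubber network, the shear storage modulus
    G' fixes the molar density of elastically effective strands, and the
    mesh size is the side of the cube holding one strand:

        xi = (R T / (G' N_a))^(1/3)

    with R the gas constant and N_a Avogadro's number. The verdict is
    "diffusive" when the solute's hydrodynamic diameter is below xi
    (unhindered Fickian transport through the mesh), else "hindered".
    """
    if g_prime_pa <= 0:
        raise ValueError("storage modulus must be positive")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    xi_m = (GAS_CONSTANT * temperature_k / (g_prime_pa * AVOGADRO)) ** (1.0 / 3.0)
    xi_nm = xi_m * 1e9
    verdict = "diffusive" if solute_diameter_nm < xi_nm else "hindered"
    return MeshResult(
        g_prime_pa=float(g_prime_pa),
        temperature_k=float(temperature_k),
        mesh_size_nm=float(xi_nm),
        solute_diameter_nm=float(solute_diameter_nm),
        verdict=verdict,
    )


def estimate_plateau(trace, tail_fraction: float = 0.2) -> tuple[float, float]:
    """Plateau storage modulus as the mean G' over the trace tail.

    Parameters
    ----------
    trace
        A :class:`~gelmri.phantoms.RheologyTrace` or any object with
        ``times_s`` and ``g_prime_pa`` array attributes.
    tail_fraction
        Fraction (0, 1] of the latest time points to average.

    Returns
    -------
    (mean, sd) of G' over the tail, in Pa.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    g = np.asarray(trace.g_prime_pa, dtype=float)
    if g.size == 0:
        raise ValueError("empty rheology trace")
    n_tail = max(1, int(round(tail_fraction * g.size)))
    tail = g[-n_tail:]
    return float(tail.mean()), float(tail.std(ddof=1)) if n_tail > 1 else 0.0


def ivivr_table(
    in_vitro: ReleaseSeries,
    in_vivo: ReleaseSeries,
    times_h,
) -> pd.DataFrame:
    """In vitro / in vivo release comparison at shared time points.

    Both corrected-release curves are linearly interpolated at the requested
    times; the paired difference (in vivo minus in vitro, percentage points)
    and ratio are reported. Extrapolation outside either observed span is
    refused rather than guessed.
    """
    t = np.asarray(times_h, dtype=float)
    for s in (in_vitro, in_vivo):
        if t.min() < s.times_h[0] or t.max() > s.times_h[-1]:
            raise ValueError(
                "requested times extend outside the observed span of "
                f"series {s.label!r} ([{s.times_h[0]}, {s.times_h[-1]}] h)"
            )
    vitro = np.interp(t, in_vitro.times_h, in_vitro.corrected_release_pct)
    vivo = np.interp(t, in_vivo.times_h, in_vivo.corrected_release_pct)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vitro != 0, vivo / vitro, np.nan)
    return pd.DataFrame(
        {
            "time_h": t,
            "in_vitro_release_pct": vitro,
            "in_vivo_release_pct": vivo,
            "difference_pp": vivo - vitro,
            "ratio_vivo_over_vitro": ratio,
        }
    )
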