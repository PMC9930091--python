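"""Synthetic phantoms with known ground truth for the release pipeline.

Two phantom families emulate the experimental setups end-to-end:

* **tube** — a gel slab (40 uL nominal, slab thickness L = 5.5 mm) at the
  bottom of a PCR tube under a PBS supernatant (160 uL). The contrast agent
  leaves the gel by Fickian diffusion through the top face only (the tube
  base and walls are impermeable); the supernatant is periodically refreshed
  so released agent does not build up in the medium.
* **brain-slice** — a multi-slice grid of tissue with an ellipsoidal gel
  deposit whose volume follows a prescribed trajectory (swelling or
  shrinkage rendered by morphological dilation/erosion of the truth mask),
  with optional short-T1 rim and long-T1 peri-gel shells mimicking the
  tissue reactions seen around injected gels.

Each phantom renders voxel-wise T1 from the ground truth via
1/T1 = 1/T1_blank + r1 * C, generates magnitude Look-Locker series with the
forward model of :mod:`gelmri.t1fit`, and returns a :class:`PhantomTruth`
holding every quantity the analysis pipeline is supposed to recover.
Generation is bit-reproducible under the spec's RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .t1fit import InversionRecoverySeries, forward_look_locker, t1_star_from_t1

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RheologyTrace",
    "simulate_slab_release",
    "generate_tube_phantom",
    "generate_brain_phantom",
    "generate_rheology_trace",
    "tube_spec",
    "brain_spec",
    "invitro_inversion_times",
    "invivo_inversion_times",
]

_CROSS_3D = ndimage.generate_binary_structure(3, 1)  # 6-connected


def invitro_inversion_times(n_images: int = 100, first_ti_s: float = 0.010,
                            tr_img_s: float = 0.025) -> np.ndarray:
    """Inversion-time ladder of the in vitro protocol (100 images, TR 25 ms,
    first inversion time 10 ms)."""
    return first_ti_s + tr_img_s * np.arange(n_images)


def invivo_inversion_times(n_images: int = 28, first_ti_s: float = 0.010,
                           tr_img_s: float = 0.025) -> np.ndarray:
    """Inversion-time ladder of the in vivo protocol (28 images)."""
    return first_ti_s + tr_img_s * np.arange(n_images)


@dataclass
class PhantomSpec:
    """Complete recipe for one synthetic phantom.

    Times are hours since the first acquisition; ``volumes_uL`` prescribes
    the gel volume at each acquisition. For tube geometry the gel is a
    cylinder slab whose cross-section is fixed by ``volumes_uL[0]`` and
    ``slab_thickness_mm`` and whose height tracks the volume; for
    brain-slice geometry the gel is an ellipsoid grown/shrunk to the target
    volume.
    """

    geometry: str  # "tube" | "brain-slice"
    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    times_h: np.ndarray
    volumes_uL: np.ndarray
    slab_thickness_mm: float = 5.5
    t1_blank_gel_s: float = 2.2
    t1_medium_s: float = 2.5  # PBS supernatant (tube) or tissue (brain)
    t1_background_s: float = 1.0
    r1_true: float = 95.5  # mM^-1 s^-1, per contrast-agent molecule
    c0_mM: float = 0.75 / 74.0  # 0.75 mg/mL at 74 kDa
    d_true_m2_s: float = 7.0e-11
    noise_sigma: float = 0.0  # fraction of unit proton density, per average
    noise_model: str = "rician"  # "rician" | "gaussian"
    n_averages: int = 1  # signal averages; effective noise is sigma / sqrt(n)
    inversion_times_s: np.ndarray = field(default_factory=invitro_inversion_times)
    tr_img_s: float = 0.025
    flip_angle_deg: float = 5.0
    seed: int = 0
    # tube-specific
    supernatant_volume_uL: float = 160.0
    refresh_times_h: tuple[float, ...] = ()
    # brain-specific
    gel_semiaxes_mm: tuple[float, float, float] = (1.1, 1.1, 1.0)
    gel_center_offset_vox: tuple[int, int, int] = (0, 0, 0)
    rim_thickness_vox: int = 0
    rim_t1_s: float = 1.2
    peri_thickness_vox: int = 0
    peri_t1_s: float = 2.2
    # optional explicit release trajectory overriding the Fickian slab model
    release_fractions: np.ndarray | None = None

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.volumes_uL = np.asarray(self.volumes_uL, dtype=float)
        if self.geometry not in ("tube", "brain-slice"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.times_h.shape != self.volumes_uL.shape:
            raise ValueError("times and volume trajectory must align")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.volumes_uL <= 0):
            raise ValueError("gel volumes must be positive")
        if self.slab_thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        for name in ("t1_blank_gel_s", "t1_medium_s", "t1_background_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r1_true <= 0:
            raise ValueError("relaxivity must be positive")
        if self.c0_mM < 0:
            raise ValueError("initial concentration must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        self.inversion_times_s = np.asarray(self.inversion_times_s, dtype=float)
        if np.any(np.diff(self.inversion_times_s) <= 0):
            raise ValueError("inversion times must be strictly increasing")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom series.

    ``release`` is the cumulative fractional release rebased to the first
    acquisition (the quantity the pipeline's volume-corrected release should
    recover); ``release_absolute`` counts from the moment of gelation.
    Concentrations are uniform within the gel at each time point (a
    well-mixed gel compartment; the spatial diffusion profile inside the gel
    is deliberately not rendered).
    """

    times_h: np.ndarray
    t1_fields_s: list[np.ndarray]
    concentration_fields_mM: list[np.ndarray]
    gel_masks: list[np.ndarray]
    release: np.ndarray
    release_absolute: np.ndarray
    gel_concentration_mM: np.ndarray
    gel_volume_uL: np.ndarray  # rendered (voxel-quantized) volumes
    gel_mass: np.ndarray  # mM * uL, arbitrary mass units
    supernatant_mass: np.ndarray
    removed_mass: np.ndarray  # cumulative mass discarded at refresh events
    supernatant_concentration_mM: np.ndarray
    seed: int

    def mass_balance_error(self) -> float:
        """Max relative deviation of total agent mass from the initial mass."""
        total = self.gel_mass + self.supernatant_mass + self.removed_mass
        m0 = self.gel_mass[0]
        if m0 == 0:
            return 0.0
        return float(np.max(np.abs(total - m0) / m0))


@dataclass
class RheologyTrace:
    """Oscillatory time sweep of a gelling sample (storage/loss moduli)."""

    times_s: np.ndarray
    g_prime_pa: np.ndarray
    g_double_prime_pa: np.ndarray | None = None
    seed: int | None = None


def simulate_slab_release(
    d_m2_s: float,
    slab_thickness_m: float,
    times_s,
    one_sided: bool = True,
    n_terms: int = 200,
) -> np.ndarray:
    """Exact-series cumulative fractional release Mt/Minf from a plane slab.

    Uses the classical eigenfunction series for desorption from a slab with
    both faces held at zero concentration,

        Mt/Minf = 1 - sum_{n>=0} 8/((2n+1)^2 pi^2) exp(-(2n+1)^2 pi^2 D t / h^2),

    where h is the diffusional thickness. One-sided release (impermeable
    base, release through the top face only) is the half-problem of a
    symmetric slab of thickness 2L, so h = 2L; two-sided uses h = L.
    This series is the brute-force oracle for the early-time sqrt-t
    approximation used in :mod:`gelmri.kinetics`.
    """
    if d_m2_s <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if slab_thickness_m <= 0:
        raise ValueError("slab thickness must be positive")
    if n_terms < 1:
        raise ValueError("need at least one series term")
    t = np.atleast_1d(np.asarray(times_s, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    h = 2.0 * slab_thickness_m if one_sided else slab_thickness_m
    n = np.arange(n_terms)
    lam = (2 * n + 1) ** 2 * np.pi**2  # decay rates scaled by D/h^2
    coef = 8.0 / lam
    expo = np.exp(-lam[None, :] * d_m2_s * t[:, None] / h**2)
    f = 1.0 - expo @ coef
    # t = 0 must give exactly 0 regardless of series truncation
    f[t == 0] = 0.0
    return np.clip(f, 0.0, 1.0)


def _release_curve(spec: PhantomSpec) -> np.ndarray:
    """Absolute cumulative release fraction at the acquisition times."""
    if spec.release_fractions is not None:
        f = np.asarray(spec.release_fractions, dtype=float)
        if f.shape != spec.times_h.shape:
            raise ValueError("release_fractions must align with times_h")
        if np.any(f < 0) or np.any(f > 1) or np.any(np.diff(f) < 0):
            raise ValueError("release fractions must be non-decreasing in [0, 1]")
        return f
    return simulate_slab_release(
        spec.d_true_m2_s,
        spec.slab_thickness_mm * 1e-3,
        spec.times_h * 3600.0,
        one_sided=True,
    )


def _mass_bookkeeping(spec: PhantomSpec, f_abs: np.ndarray, v_rendered: np.ndarray):
    """Track agent mass in gel and supernatant across refresh events.

    Mass units are mM * uL. The gel is treated as well mixed: its
    concentration is gel mass over *rendered* volume, so the imaging
    pipeline (concentration map x segmented volume) can recover the mass
    exactly on noiseless data. Refreshes instantaneously discard the
    supernatant's accumulated mass; the gel's state carries over.
    """
    m0 = spec.c0_mM * v_rendered[0]
    gel_mass = m0 * (1.0 - f_abs)
    released = m0 * f_abs  # cumulative mass having left the gel

    refresh = np.sort(np.asarray(spec.refresh_times_h, dtype=float))
    removed = np.zeros_like(spec.times_h)
    sup_mass = np.zeros_like(spec.times_h)
    # released mass at each refresh time (linear interp between scans)
    rel_at_refresh = np.interp(refresh, spec.times_h, released) if refresh.size else np.array([])
    for i, t in enumerate(spec.times_h):
        past = rel_at_refresh[refresh <= t]
        removed[i] = past[-1] if past.size else 0.0
        sup_mass[i] = released[i] - removed[i]
    c_sup = sup_mass / spec.supernatant_volume_uL
    return gel_mass, sup_mass, removed, c_sup


def _add_noise(signal: np.ndarray, spec: PhantomSpec, rng: np.random.Generator):
    if spec.noise_sigma == 0:
        return signal
    # proton density is 1.0 in phantom units; averaging reduces noise
    sigma = spec.noise_sigma / np.sqrt(spec.n_averages)
    if spec.noise_model == "rician":
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        return np.hypot(re, im)
    noisy = signal + rng.normal(0.0, sigma, signal.shape)
    return np.clip(noisy, 0.0, None)


def _render_series(
    spec: PhantomSpec,
    t1_field: np.ndarray,
    m0_field: np.ndarray,
    rng: np.random.Generator,
    mask: np.ndarray,
    series_id: str,
) -> InversionRecoverySeries:
    """Forward-model one Look-Locker magnitude series from a T1/M0 field."""
    tau = t1_star_from_t1(t1_field, spec.flip_angle_deg, spec.tr_img_s)
    m0_star = m0_field * tau / t1_field
    a = m0_star
    b = m0_field + m0_star
    signal = forward_look_locker(a, b, tau, spec.inversion_times_s)
    signal = _add_noise(signal, spec, rng)
    return InversionRecoverySeries(
        data=signal,
        inversion_times_s=spec.inversion_times_s,
        tr_img_s=spec.tr_img_s,
        flip_angle_deg=spec.flip_angle_deg,
        voxel_size_mm=spec.voxel_size_mm,
        mask=mask,
        series_id=series_id,
    )


def _tube_geometry(spec: PhantomSpec):
    """Cylindrical tube mask and per-slice geometry for the tube phantom."""
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.voxel_size_mm
    # cross-section fixed by the nominal slab: area = V0 / L
    area_mm2 = spec.volumes_uL[0] / spec.slab_thickness_mm
    radius_mm = np.sqrt(area_mm2 / np.pi)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = (np.arange(nx) - cx) * dx
    y = (np.arange(ny) - cy) * dy
    disk = (x[:, None] ** 2 + y[None, :] ** 2) <= radius_mm**2
    if not disk.any():
        raise ValueError("tube cross-section is empty at this resolution")
    tube = np.repeat(disk[:, :, None], nz, axis=2)
    slice_volume_uL = disk.sum() * dx * dy * dz  # 1 mm^3 = 1 uL
    return tube, disk, slice_volume_uL


def generate_tube_phantom(spec: PhantomSpec):
    """Generate the in vitro tube phantom: one Look-Locker series per scan.

    The gel slab sits at the bottom of the tube (low z) and releases agent
    through its top face; the supernatant column above holds the released
    agent until the next refresh event. Voxel T1 follows
    1/T1 = 1/T1_blank + r1 * C in both compartments. Background voxels
    outside the tube carry zero proton density and are excluded from the
    series' analysis mask.

    Returns
    -------
    (series_list, truth)
    """
    if spec.geometry != "tube":
        raise ValueError("spec.geometry must be 'tube'")
    tube, disk, slice_vol = _tube_geometry(spec)
    nz = spec.shape[2]
    dz = spec.voxel_size_mm[2]

    n_slices = np.maximum(1, np.round(spec.volumes_uL / slice_vol).astype(int))
    if np.any(n_slices > nz):
        raise ValueError(
            "volume trajectory exceeds tube capacity "
            f"(needs {int(n_slices.max())} slices, grid has {nz})"
        )
    v_rendered = n_slices * slice_vol

    f_abs = _release_curve(spec)
    gel_mass, sup_mass, removed, c_sup = _mass_bookkeeping(spec, f_abs, v_rendered)
    c_gel = gel_mass / v_rendered
    # release rebased to the first acquisition ("% of initial dose at t1")
    release = 1.0 - gel_mass / gel_mass[0] if gel_mass[0] > 0 else np.zeros_like(gel_mass)

    rng = np.random.default_rng(spec.seed)
    series_list, t1_fields, c_fields, masks = [], [], [], []
    for i, t in enumerate(spec.times_h):
        gel = tube.copy()
        gel[:, :, n_slices[i]:] = False
        sup = tube & ~gel

        c_field = np.zeros(spec.shape)
        c_field[gel] = c_gel[i]
        c_field[sup] = c_sup[i]

        r1_field = np.full(spec.shape, 1.0 / spec.t1_background_s)
        r1_field[gel] = 1.0 / spec.t1_blank_gel_s + spec.r1_true * c_gel[i]
        r1_field[sup] = 1.0 / spec.t1_medium_s + spec.r1_true * c_sup[i]
        t1_field = 1.0 / r1_field

        m0 = np.where(tube, 1.0, 0.0)
        series = _render_series(
            spec, t1_field, m0, rng, mask=tube,
            series_id=f"tube-t{t:g}h",
        )
        series_list.append(series)
        t1_fields.append(t1_field)
        c_fields.append(c_field)
        masks.append(gel)

    truth = PhantomTruth(
        times_h=spec.times_h,
        t1_fields_s=t1_fields,
        concentration_fields_mM=c_fields,
        gel_masks=masks,
        release=release,
        release_absolute=f_abs,
        gel_concentration_mM=c_gel,
        gel_volume_uL=v_rendered,
        gel_mass=gel_mass,
        supernatant_mass=sup_mass,
        removed_mass=removed,
        supernatant_concentration_mM=c_sup,
        seed=spec.seed,
    )
    return series_list, truth


def _morph_to_count(mask: np.ndarray, target: int) -> np.ndarray:
    """Dilate or erode a mask (6-connected cross) to a target voxel count.

    Shape class is preserved: full dilation/erosion passes are applied while
    they fit under the target, then the remainder is taken from the boundary
    ring, nearest-to-centroid first (ties broken by flat index) so the
    result is deterministic.
    """
    mask = mask.copy()
    count = int(mask.sum())
    if count == 0:
        raise ValueError("cannot resize an empty mask")
    centroid = np.array(ndimage.center_of_mass(mask))

    def _rank(idx):
        pts = np.argwhere(idx)
        d2 = ((pts - centroid) ** 2).sum(axis=1)
        flat = np.ravel_multi_index(pts.T, mask.shape)
        order = np.lexsort((flat, d2))
        return pts[order]

    while count != target:
        if count < target:
            ring = ndimage.binary_dilation(mask, _CROSS_3D) & ~mask
            n_ring = int(ring.sum())
            if n_ring == 0:
                raise ValueError("mask cannot grow further inside the grid")
            if count + n_ring <= target:
                mask |= ring
                count += n_ring
            else:
                for p in _rank(ring)[: target - count]:
                    mask[tuple(p)] = True
                count = target
        else:
            core = ndimage.binary_erosion(mask, _CROSS_3D)
            ring = mask & ~core
            n_ring = int(ring.sum())
            if count - n_ring >= target:
                mask = core
                count -= n_ring
            else:
                # remove outermost-first: farthest from centroid
                pts = _rank(ring)[::-1]
                for p in pts[: count - target]:
                    mask[tuple(p)] = False
                count = target
    return mask


def generate_brain_phantom(spec: PhantomSpec):
    """Generate the brain-slice phantom: tissue grid with an ellipsoidal gel.

    The gel volume follows the prescribed trajectory, rendered by
    morphological dilation/erosion of the initial ellipsoid mask. Optional
    rim (shortened T1) and peri-gel (lengthened T1) shells immediately
    outside the gel emulate the tissue reactions observed around injected
    gels. Returns ``(series_list, truth)`` as for tubes.
    """
    if spec.geometry != "brain-slice":
        raise ValueError("spec.geometry must be 'brain-slice'")
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.voxel_size_mm
    voxvol = dx * dy * dz

    off = spec.gel_center_offset_vox
    center = ((nx - 1) / 2.0 + off[0], (ny - 1) / 2.0 + off[1], (nz - 1) / 2.0 + off[2])
    ax, ay, az = spec.gel_semiaxes_mm
    xx = (np.arange(nx) - center[0])[:, None, None] * dx
    yy = (np.arange(ny) - center[1])[None, :, None] * dy
    zz = (np.arange(nz) - center[2])[None, None, :] * dz
    ellipsoid = (xx / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0
    if not ellipsoid.any():
        raise ValueError("gel ellipsoid is empty at this resolution")

    target_counts = np.maximum(1, np.round(spec.volumes_uL / voxvol).astype(int))
    base = _morph_to_count(ellipsoid, int(target_counts[0]))

    masks = []
    current = base
    for tc in target_counts:
        current = _morph_to_count(current, int(tc))
        masks.append(current)
    # the gel must stay inside the grid in-plane (slice-direction contact is
    # normal for a multi-slice acquisition covering the deposit)
    edge = np.zeros(spec.shape, dtype=bool)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    for m in masks:
        if (m & edge).any():
            raise ValueError("gel ellipsoid is not fully inside the grid")

    v_rendered = np.array([int(m.sum()) * voxvol for m in masks])

    f_abs = _release_curve(spec)
    m0_mass = spec.c0_mM * v_rendered[0]
    gel_mass = m0_mass * (1.0 - f_abs)
    c_gel = gel_mass / v_rendered
    release = 1.0 - gel_mass / gel_mass[0] if gel_mass[0] > 0 else np.zeros_like(gel_mass)

    rng = np.random.default_rng(spec.seed)
    series_list, t1_fields, c_fields = [], [], []
    full = np.ones(spec.shape, dtype=bool)
    for i, t in enumerate(spec.times_h):
        gel = masks[i]
        c_field = np.zeros(spec.shape)
        c_field[gel] = c_gel[i]

        r1_field = np.full(spec.shape, 1.0 / spec.t1_medium_s)
        if spec.rim_thickness_vox > 0:
            rim = ndimage.binary_dilation(gel, _CROSS_3D, iterations=spec.rim_thickness_vox) & ~gel
            r1_field[rim] = 1.0 / spec.rim_t1_s
        if spec.peri_thickness_vox > 0:
            inner = ndimage.binary_dilation(
                gel, _CROSS_3D, iterations=spec.rim_thickness_vox
            ) if spec.rim_thickness_vox > 0 else gel
            peri = ndimage.binary_dilation(
                inner, _CROSS_3D, iterations=spec.peri_thickness_vox
            ) & ~inner
            r1_field[peri] = 1.0 / spec.peri_t1_s
        r1_field[gel] = 1.0 / spec.t1_blank_gel_s + spec.r1_true * c_gel[i]
        t1_field = 1.0 / r1_field

        m0 = np.ones(spec.shape)
        series = _render_series(
            spec, t1_field, m0, rng, mask=full, series_id=f"brain-t{t:g}h",
        )
        series_list.append(series)
        t1_fields.append(t1_field)
        c_fields.append(c_field)

    sup = np.zeros_like(spec.times_h)
    truth = PhantomTruth(
        times_h=spec.times_h,
        t1_fields_s=t1_fields,
        concentration_fields_mM=c_fields,
        gel_masks=masks,
        release=release,
        release_absolute=f_abs,
        gel_concentration_mM=c_gel,
        gel_volume_uL=v_rendered,
        gel_mass=gel_mass,
        supernatant_mass=m0_mass * f_abs,  # mass delivered to tissue
        removed_mass=sup,
        supernatant_concentration_mM=sup,
        seed=spec.seed,
    )
    return series_list, truth


def generate_rheology_trace(
    g_inf_pa: float,
    tau_s: float,
    times_s,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
    loss_fraction: float = 0.12,
) -> RheologyTrace:
    """Saturating-exponential gelation curve G'(t) = G_inf (1 - exp(-t/tau)).

    Emulates the in situ rheology of a thermogelling sample: the storage
    modulus rises steeply after the temperature jump and plateaus as the
    network forms. The loss modulus is rendered as a fixed fraction of G'.
    """
    if g_inf_pa <= 0:
        raise ValueError("plateau modulus must be positive")
    if tau_s <= 0:
        raise ValueError("gelation time constant must be positive")
    t = np.asarray(times_s, dtype=float)
    g = g_inf_pa * (1.0 - np.exp(-t / tau_s))
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sd_pa, g.shape)
    return RheologyTrace(
        times_s=t,
        g_prime_pa=g,
        g_double_prime_pa=loss_fraction * np.clip(g, 0.0, None),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Preset specs emulating the study conditions


def tube_spec(formulation: str = "LC", *, noise_sigma: float = 0.0,
              seed: int = 0, **overrides) -> PhantomSpec:
    """In vitro tube phantom preset for the LC (low-concentration, 81% water)
    or HC (high-concentration, 66% water) formulation.

    LC: dimensionally stable near 40 uL, fast release (D ~ 7e-11 m2/s from
    the 10.3 %/h^1/2 rate constant); HC: swells toward ~55 uL by 24 h,
    slower release (D ~ 3.7e-11). Acquisitions at 0-144 h with supernatant
    refreshes 24 h before each daily scan.
    """
    times = np.array([0.0, 2.0, 4.0, 8.0, 16.0, 24.0, 48.0, 96.0, 144.0])
    if formulation.upper() == "LC":
        vols = np.array([39.6, 39.8, 40.0, 40.2, 40.3, 40.4, 40.8, 41.2, 41.5])
        d, r1, t1g = 7.0e-11, 95.5, 2.2
    elif formulation.upper() == "HC":
        vols = np.array([43.5, 45.0, 47.0, 50.0, 53.0, 54.7, 56.5, 58.5, 60.0])
        d, r1, t1g = 3.7e-11, 93.2, 2.0
    else:
        raise ValueError("formulation must be 'LC' or 'HC'")
    defaults = dict(
        geometry="tube",
        shape=(16, 16, 26),
        voxel_size_mm=(0.4, 0.4, 0.5),
        times_h=times,
        volumes_uL=vols,
        slab_thickness_mm=5.5,
        t1_blank_gel_s=t1g,
        t1_medium_s=2.5,
        r1_true=r1,
        c0_mM=0.75 / 74.0,
        d_true_m2_s=d,
        noise_sigma=noise_sigma,
        refresh_times_h=(24.0, 72.0, 120.0),
        n_averages=2,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


def brain_spec(formulation: str = "LC", *, noise_sigma: float = 0.0,
               seed: int = 0, **overrides) -> PhantomSpec:
    """In vivo brain-slice phantom preset (5 uL injected deposit).

    Scans at 0, 2, 7, 14 and 21 days. The LC-like gel swells to ~10.8 uL by
    day 7 and shrinks back to ~5.5 uL; the HC-like gel swells steadily to
    ~21.6 uL. Release in vivo is faster than in vitro, emulated with a
    larger effective diffusivity.
    """
    times = np.array([0.0, 48.0, 168.0, 336.0, 504.0])
    if formulation.upper() == "LC":
        vols = np.array([5.3, 8.5, 10.8, 8.0, 5.5])
        d, r1, t1g = 2.0e-10, 95.5, 2.6
    elif formulation.upper() == "HC":
        vols = np.array([5.3, 9.0, 14.0, 18.0, 21.6])
        d, r1, t1g = 6.0e-11, 93.2, 2.4
    else:
        raise ValueError("formulation must be 'LC' or 'HC'")
    defaults = dict(
        geometry="brain-slice",
        shape=(40, 40, 5),
        voxel_size_mm=(0.15, 0.15, 1.0),
        times_h=times,
        volumes_uL=vols,
        slab_thickness_mm=1.7,  # effective diffusion length of the deposit
        t1_blank_gel_s=t1g,
        t1_medium_s=1.7,  # striatal tissue
        r1_true=r1,
        c0_mM=0.75 / 74.0,
        d_true_m2_s=d,
        noise_sigma=noise_sigma,
        inversion_times_s=invivo_inversion_times(),
        gel_semiaxes_mm=(1.1, 1.1, 1.0),
        n_averages=24,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)
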