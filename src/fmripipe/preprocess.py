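"""Native implementations of the data-transforming processing blocks.

Covers the stages between input concatenation and regression: initial-TR
removal, temporal outlier detection, pre-steady-state detection, slice-time
correction, rigid-body motion estimation, single-step application of
concatenated spatial transforms, multi-echo optimal combination, blurring,
automasking, despiking and percent-signal scaling.

Spatial conventions
-------------------
A rigid transform is parameterized as (roll, pitch, yaw, dS, dL, dP):
rotations in degrees about the world x (L-R), y (P-A) and z (I-S) axes,
applied about the grid center in the order roll→pitch→yaw, followed by
translations of dS mm along +z (superior), dL mm along −x (left) and dP mm
along −y (posterior), in RAS world coordinates.

Motion parameters describe the transform carrying the *reference* into each
volume; correction therefore resamples each volume through the inverse.
All multi-stage chains (motion + EPI→anat + anat→final) are composed and
applied with exactly one interpolation per voxel, which is what keeps the
corrected data from accumulating interpolation smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import CubicSpline
from scipy.stats import norm

from .types import EchoSet, Grid, MotionParams, Volume4D

__all__ = [
    "RigidTransform",
    "OCWeights",
    "remove_initial_volumes",
    "temporal_outlier_fraction",
    "detect_pre_steady_state",
    "slice_time_correct",
    "select_min_outlier_reference",
    "estimate_rigid_motion",
    "apply_rigid",
    "apply_concatenated_transform",
    "gaussian_blur",
    "compute_epi_automask",
    "scale_percent",
    "fit_t2star_and_combine",
    "despike",
    "default_output_grid",
]

#: |residual| > OUTLIER_K * MADN flags a time point as an outlier at a voxel.
OUTLIER_K = float(norm.ppf(1 - 0.001 / 2))  # ≈ 3.2905

KERNELS = ("nearest", "trilinear", "cubic", "wsinc5", "wsinc9")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# rigid transforms


@dataclass
class RigidTransform:
    """Six-parameter rigid-body transform with its world-space affine."""

    params: np.ndarray  # (roll, pitch, yaw) deg, (dS, dL, dP) mm
    center: np.ndarray  # rotation pivot, world mm
    kernel: str = "trilinear"

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float).reshape(6)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown interpolation kernel {self.kernel!r}")

    @property
    def affine(self) -> np.ndarray:
        return rigid_affine(self.params, self.center)


def _rot(axis: int, deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s if axis != 1 else s
    m[j, i] = s if axis != 1 else -s
    return m


def rigid_affine(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    """World→world 4×4 affine for (roll, pitch, yaw, dS, dL, dP)."""
    roll, pitch, yaw, dS, dL, dP = np.asarray(params, dtype=float)
    rot = _rot(2, yaw) @ _rot(1, pitch) @ _rot(0, roll)
    t = np.array([-dL, -dP, dS])  # left = −x, posterior = −y, superior = +z
    aff = np.eye(4)
    aff[:3, :3] = rot
    aff[:3, 3] = np.asarray(center) - rot @ np.asarray(center) + t
    return aff


# ---------------------------------------------------------------------------
# resampling primitives


def _resample_3d(
    data: np.ndarray,
    src_grid: Grid,
    out_grid: Grid,
    world_affine: np.ndarray,
    kernel: str = "trilinear",
) -> np.ndarray:
    """Sample ``data`` (on src_grid) at out_grid voxels mapped through the
    *inverse* of ``world_affine`` (world→world), i.e. pull-back resampling."""
    if kernel not in KERNELS:
        raise ValueError(f"unknown interpolation kernel {kernel!r}")
    # output voxel -> world -> inverse transform -> source voxel
    vox_map = (
        np.linalg.inv(src_grid.affine)
        @ np.linalg.inv(world_affine)
        @ out_grid.affine
    )
    if kernel in ("nearest", "trilinear", "cubic"):
        order = {"nearest": 0, "trilinear": 1, "cubic": 3}[kernel]
        return ndimage.affine_transform(
            data,
            vox_map[:3, :3],
            offset=vox_map[:3, 3],
            output_shape=out_grid.dims,
            order=order,
            mode="constant",
            cval=0.0,
            prefilter=(order > 1),
        )
    half = 5 if kernel == "wsinc5" else 9
    return _wsinc_resample(data, vox_map, out_grid.dims, half)


def _wsinc_resample(data: np.ndarray, vox_map: np.ndarray, out_shape, half: int) -> np.ndarray:
    """Windowed-sinc (Hann window, half-width ``half`` voxels) resampling."""
    idx = np.indices(out_shape).reshape(3, -1).astype(float)
    src = vox_map[:3, :3] @ idx + vox_map[:3, 3:4]
    base = np.floor(src).astype(int)
    frac = src - base
    taps = np.arange(-half + 1, half + 1)  # 2*half taps

    def weights(f):  # (taps, N) separable sinc weights per axis
        x = f[np.newaxis, :] - taps[:, np.newaxis]
        w = np.sinc(x) * (0.5 + 0.5 * np.cos(np.pi * x / half)) * (np.abs(x) < half)
        return w / np.sum(w, axis=0, keepdims=True)

    wx, wy, wz = weights(frac[0]), weights(frac[1]), weights(frac[2])
    padded = np.pad(data, half, mode="constant")
    out = np.zeros(idx.shape[1])
    for i, ti in enumerate(taps):
        xi = base[0] + ti + half
        for j, tj in enumerate(taps):
            yj = base[1] + tj + half
            wij = wx[i] * wy[j]
            # gather a (taps, N) block along z in one shot
            zk = base[2][np.newaxis, :] + taps[:, np.newaxis] + half
            vals = padded[
                np.clip(xi, 0, padded.shape[0] - 1)[np.newaxis, :],
                np.clip(yj, 0, padded.shape[1] - 1)[np.newaxis, :],
                np.clip(zk, 0, padded.shape[2] - 1),
            ]
            out += wij * np.sum(wz * vals, axis=0)
    return out.reshape(out_shape)


def apply_rigid(
    vol_data: np.ndarray, grid: Grid, params: np.ndarray, kernel: str = "trilinear"
) -> np.ndarray:
    """Apply a rigid transform (forward) to one 3D volume on its own grid."""
    aff = rigid_affine(params, grid.center_world())
    return _resample_3d(vol_data, grid, grid, aff, kernel)


# ---------------------------------------------------------------------------
# block operations


def remove_initial_volumes(vol: Volume4D, n: int) -> Volume4D:
    """Drop the first ``n`` time points of each run (pre-steady-state TRs)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return vol
    if any(n >= r for r in vol.run_lengths):
        raise ValueError(
            f"cannot remove {n} volumes from runs of lengths {vol.run_lengths}"
        )
    keep = np.ones(vol.n_volumes, bool)
    for sl in vol.run_slices:
        keep[sl.start : sl.start + n] = False
    out = vol.with_data(
        vol.data[..., keep], run_lengths=[r - n for r in vol.run_lengths]
    )
    out.note(f"remove_initial_volumes n={n}")
    return out


def _legendre_basis(n: int, order: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, n)
    return np.stack(
        [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(order + 1)], axis=1
    )


def _detrend(series: np.ndarray, order: int) -> np.ndarray:
    """Remove a per-run Legendre polynomial trend. series: (T, nvox)."""
    basis = _legendre_basis(series.shape[0], order)
    coef, *_ = np.linalg.lstsq(basis, series, rcond=None)
    return series - basis @ coef


def _detrend_columns(mat: np.ndarray, order: int) -> np.ndarray:
    """Remove a Legendre trend from each row of a (nvox, T) matrix."""
    order = min(order, mat.shape[1] - 1)
    return _detrend(mat.T, order).T


def auto_polort(duration_s: float) -> int:
    """Baseline polynomial order rule: 1 + floor(run duration / 150 s)."""
    return 1 + int(duration_s // 150.0)


def temporal_outlier_fraction(vol: Volume4D, mask: np.ndarray) -> np.ndarray:
    """Per-volume fraction of in-mask voxels that are temporal outliers.

    A time point is an outlier at a voxel when the detrended residual
    exceeds OUTLIER_K·MADN of that voxel's residual series.  Computed per
    run with the run's automatic baseline polynomial order.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.grid.dims:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("empty mask")
    if vol.n_volumes < 5:
        raise ValueError("need at least 5 volumes for outlier detection")
    frac = np.zeros(vol.n_volumes)
    for sl in vol.run_slices:
        series = vol.data[mask][:, sl].T  # (T, nvox)
        order = min(auto_polort(series.shape[0] * vol.tr), series.shape[0] - 1)
        resid = _detrend(series, order)
        madn = 1.4826 * np.median(np.abs(resid), axis=0)
        madn[madn <= 0] = np.inf  # constant voxels can never be outliers
        frac[sl] = np.mean(np.abs(resid) > OUTLIER_K * madn[np.newaxis, :], axis=1)
    return frac


def detect_pre_steady_state(vol: Volume4D, mask: np.ndarray) -> int:
    """Count leading volumes whose in-mask mean exceeds the run's robust level.

    The robust level and spread (MADN) come from the last 80% of volumes;
    the first volumes are flagged while their mean exceeds level + 2·MADN.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    means = vol.data[mask].mean(axis=0)
    tail = means[int(np.ceil(0.2 * means.size)) :]
    center = np.median(tail)
    madn = 1.4826 * np.median(np.abs(tail - center))
    thr = center + 2.0 * max(madn, 1e-12 * max(abs(center), 1.0))
    m = 0
    while m < means.size and means[m] > thr:
        m += 1
    return m


def select_min_outlier_reference(vol: Volume4D, mask: np.ndarray) -> int:
    """MIN_OUTLIER rule: index with the fewest temporal outliers (ties → earliest)."""
    frac = temporal_outlier_fraction(vol, mask)
    return int(np.argmin(frac))


def slice_time_correct(
    vol: Volume4D, method: str = "cubic", align_to: float = 0.0
) -> Volume4D:
    """Resample each slice's series to a common temporal origin.

    ``method`` is ``cubic`` (spline) or ``wsinc5``/``wsinc9`` (windowed
    sinc fractional delay).  Boundary volumes are edge-held.
    """
    if vol.slice_times.size == 0:
        raise ValueError("slice_time_correct requires slice timing metadata")
    if method not in ("cubic", "wsinc5", "wsinc9", "sinc"):
        raise ValueError(f"unknown slice-timing method {method!r}")
    out = np.empty_like(vol.data)
    for sl in vol.run_slices:
        nt = sl.stop - sl.start
        tt = np.arange(nt, dtype=float)
        for z in range(vol.grid.dims[2]):
            # samples live at k*TR + slice_time; we want values at k*TR + align_to
            shift = (align_to - vol.slice_times[z]) / vol.tr
            block = vol.data[:, :, z, sl].reshape(-1, nt)
            if abs(shift) < 1e-12:
                out[:, :, z, sl] = block.reshape(vol.grid.dims[0], vol.grid.dims[1], nt)
                continue
            tq = np.clip(tt + shift, 0.0, nt - 1.0)  # edge-hold
            if method == "cubic":
                res = CubicSpline(tt, block, axis=1)(tq)
            else:
                half = 9 if method in ("wsinc9", "sinc") else 5
                res = _sinc_shift(block, tq, half)
            out[:, :, z, sl] = res.reshape(vol.grid.dims[0], vol.grid.dims[1], nt)
    corrected = vol.with_data(out)
    corrected.slice_times = np.full(vol.grid.dims[2], float(align_to))
    corrected.note(f"slice_time_correct method={method} align_to={align_to}")
    return corrected


def _sinc_shift(block: np.ndarray, tq: np.ndarray, half: int) -> np.ndarray:
    """Windowed-sinc evaluation of row series at fractional indices tq."""
    nt = block.shape[1]
    base = np.floor(tq).astype(int)
    frac = tq - base
    taps = np.arange(-half + 1, half + 1)
    x = frac[np.newaxis, :] - taps[:, np.newaxis]
    w = np.sinc(x) * (0.5 + 0.5 * np.cos(np.pi * x / half)) * (np.abs(x) < half)
    w /= np.sum(w, axis=0, keepdims=True)
    idx = np.clip(base[np.newaxis, :] + taps[:, np.newaxis], 0, nt - 1)
    return np.einsum("vkt->vt", block[:, idx] * w[np.newaxis, :, :])


# ---------------------------------------------------------------------------
# rigid motion estimation


def _ssd_cost(params, moving, ref, grid, kernel="trilinear"):
    # forward view: carry the reference into the volume by T(params) and
    # compare there, so both sides see exactly one interpolation
    aff = rigid_affine(params, grid.center_world())
    res = _resample_3d(ref, grid, grid, aff, kernel)
    return float(np.mean((res - moving) ** 2))


def _downsample_grid(data: np.ndarray, grid: Grid) -> tuple[np.ndarray, Grid]:
    sm = ndimage.gaussian_filter(data, 1.0)
    down = sm[::2, ::2, ::2]
    aff = grid.affine.copy()
    aff[:3, :3] *= 2.0
    return down, Grid(dims=down.shape, affine=aff)


def estimate_rigid_motion(
    vol: Volume4D, ref_index: int = 0, kernel: str = "trilinear"
) -> MotionParams:
    """Estimate 6-parameter rigid motion of each volume relative to a reference.

    Least-squares intensity matching with a 2-level multiresolution search
    and Powell polish; each volume warm-starts from its predecessor.  The
    reference row is exactly zero.
    """
    if vol.n_volumes < 2:
        raise ValueError("need at least 2 volumes to estimate motion")
    ref_full = vol.data[..., ref_index]
    if not np.any(ref_full):
        raise ValueError("reference volume is all zero")
    ref_ds, grid_ds = _downsample_grid(ref_full, vol.grid)
    params = np.zeros((vol.n_volumes, 6))
    prev = np.zeros(6)
    for t in range(vol.n_volumes):
        if t == ref_index:
            prev = np.zeros(6)
            continue
        moving = vol.data[..., t]
        mov_ds, _ = _downsample_grid(moving, vol.grid)
        try:
            # dual start: warm start from the previous volume (motion is
            # usually smooth) and a zero start (guards against jumps)
            starts = [prev.copy()]
            if np.any(np.abs(prev) > 1e-6):
                starts.append(np.zeros(6))
            # head motion is physically bounded; the search window also
            # excludes spurious symmetry solutions (e.g. 180-degree flips)
            bounds = [(-15.0, 15.0)] * 3 + [(-20.0, 20.0)] * 3
            coarse_best = None
            for x0 in starts:
                res = optimize.minimize(
                    _ssd_cost, x0, args=(mov_ds, ref_ds, grid_ds, kernel),
                    method="Powell", bounds=bounds,
                    options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 60},
                )
                if coarse_best is None or res.fun < coarse_best.fun:
                    coarse_best = res
            fine = optimize.minimize(
                _ssd_cost, coarse_best.x, args=(moving, ref_full, vol.grid, kernel),
                method="Powell", bounds=bounds,
                options={"xtol": 1e-6, "ftol": 1e-12, "maxiter": 80},
            )
        except Exception as exc:
            raise RuntimeError(f"motion estimation failed at volume {t}: {exc}") from exc
        if not np.all(np.isfinite(fine.x)):
            raise RuntimeError(f"motion estimation did not converge at volume {t}")
        params[t] = fine.x
        prev = fine.x
    return MotionParams(params=params, reference_index=ref_index)


def apply_concatenated_transform(
    vol: Volume4D,
    per_volume: MotionParams | None,
    epi2anat: np.ndarray | None = None,
    anat2final: np.ndarray | None = None,
    out_grid: Grid | None = None,
    kernel: str = "trilinear",
) -> Volume4D:
    """Resample every volume through the composed map in a single step.

    The composition per volume t is ``anat2final ∘ epi2anat ∘ inv(motion_t)``
    (motion parameters carry reference→volume, so correction inverts them).
    Exactly one interpolation is performed per voxel per volume.
    """
    if per_volume is not None and per_volume.n_volumes != vol.n_volumes:
        raise ValueError("motion parameter count does not match n_volumes")
    out_grid = out_grid or vol.grid
    e2a = np.eye(4) if epi2anat is None else np.asarray(epi2anat, dtype=float)
    a2f = np.eye(4) if anat2final is None else np.asarray(anat2final, dtype=float)
    for name, m in (("epi2anat", e2a), ("anat2final", a2f)):
        if m.shape != (4, 4) or abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError(f"{name} must be an invertible 4x4 affine")
    center = vol.grid.center_world()
    out = np.empty(out_grid.dims + (vol.n_volumes,))
    for t in range(vol.n_volumes):
        motion = (
            np.eye(4)
            if per_volume is None
            else rigid_affine(per_volume.params[t], center)
        )
        world = a2f @ e2a @ np.linalg.inv(motion)
        out[..., t] = _resample_3d(vol.data[..., t], vol.grid, out_grid, world, kernel)
    res = Volume4D(
        grid=out_grid,
        data=out,
        tr=vol.tr,
        slice_times=vol.slice_times.copy() if out_grid.dims[2] == vol.grid.dims[2] else np.empty(0),
        units_tag=vol.units_tag,
        run_lengths=list(vol.run_lengths),
        history=list(vol.history),
    )
    res.note(f"apply_concatenated_transform kernel={kernel}")
    return res


def default_output_grid(vol: Volume4D) -> Grid:
    """Isotropic output grid at the input's minimum voxel dimension,
    truncated to one decimal mm (slightly finer than the input minimum)."""
    dmin = np.floor(min(vol.grid.voxel_size) * 10.0) / 10.0
    extent = np.asarray(vol.grid.dims) * np.asarray(vol.grid.voxel_size)
    dims = tuple(int(np.ceil(e / dmin)) for e in extent)
    # preserve the field of view center
    old_center = vol.grid.center_world()
    aff = np.diag([dmin, dmin, dmin, 1.0])
    aff[:3, :3] = vol.grid.affine[:3, :3] / np.asarray(vol.grid.voxel_size) * dmin
    new_center_vox = (np.asarray(dims) - 1) / 2.0
    aff[:3, 3] = old_center - aff[:3, :3] @ new_center_vox
    return Grid(dims=dims, affine=aff)


# ---------------------------------------------------------------------------
# blur / mask / scale / despike


def gaussian_blur(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Per-volume 3D Gaussian smoothing (σ = FWHM/2.355 per axis, in mm).

    Reflective boundaries conserve total intensity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return vol
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / vs for vs in vol.grid.voxel_size]
    out = np.empty_like(vol.data)
    for t in range(vol.n_volumes):
        out[..., t] = ndimage.gaussian_filter(vol.data[..., t], sigma_vox, mode="reflect")
    res = vol.with_data(out)
    res.note(f"gaussian_blur fwhm={fwhm_mm}mm")
    return res


def _clip_level(img: np.ndarray) -> float:
    """Iterative clip-level threshold of a non-negative mean image."""
    vals = img[img > 0]
    if vals.size == 0:
        raise ValueError("cannot compute clip level of an all-zero volume")
    thr = 0.5 * vals.mean()
    for _ in range(50):
        new = 0.5 * vals[vals > thr].mean() if np.any(vals > thr) else thr
        if abs(new - thr) < 1e-6 * max(thr, 1e-12):
            break
        thr = new
    return float(thr)


def compute_epi_automask(
    vol: Volume4D, anat_mask: np.ndarray | None = None
) -> np.ndarray:
    """Brain mask from the temporal-mean image: clip-level threshold, largest
    connected component, hole fill; intersected with ``anat_mask`` if given.

    The mask is *never* multiplied into the EPI data — callers use it only
    to restrict summary statistics, so artifacts outside the brain remain
    visible in all QC maps.
    """
    mean_img = vol.data.mean(axis=3)
    if not np.any(mean_img):
        raise ValueError("cannot automask an all-zero volume")
    thr = _clip_level(np.abs(mean_img))
    mask = np.abs(mean_img) > thr
    lab, nlab = ndimage.label(mask)
    if nlab == 0:
        raise ValueError("automask produced an empty mask")
    sizes = ndimage.sum(mask, lab, index=np.arange(1, nlab + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    if anat_mask is not None:
        mask = mask & np.asarray(anat_mask, dtype=bool)
    if not mask.any():
        raise ValueError("automask empty after anatomical intersection")
    return mask


def scale_percent(vol: Volume4D, mask: np.ndarray | None = None) -> Volume4D:
    """Scale each run so every voxel's mean is 100 (values capped at 200).

    ``out = min(200, 100·in/mean_t)``; voxels with non-positive temporal
    mean are set to 0 across time.  The mask, when given, only restricts
    which voxels are considered brain for downstream summaries — scaling
    itself is applied to the full field of view.
    """
    out = np.empty_like(vol.data)
    for sl in vol.run_slices:
        block = vol.data[..., sl]
        mean = block.mean(axis=3)
        good = mean > 0
        scaled = np.zeros_like(block)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled[good] = np.minimum(200.0, 100.0 * block[good] / mean[good][..., None])
        out[..., sl] = scaled
    res = vol.with_data(out, units_tag="percent")
    res.note("scale_percent per-run mean->100 cap 200")
    return res


def despike(vol: Volume4D) -> Volume4D:
    """Clip per-voxel detrended excursions beyond 3·MADN (approximate despike)."""
    out = vol.data.copy()
    for sl in vol.run_slices:
        block = out[..., sl]
        flat = block.reshape(-1, block.shape[-1])
        order = min(auto_polort(block.shape[-1] * vol.tr), block.shape[-1] - 1)
        basis = _legendre_basis(block.shape[-1], order)
        coef, *_ = np.linalg.lstsq(basis, flat.T, rcond=None)
        trend = (basis @ coef).T
        resid = flat - trend
        madn = 1.4826 * np.median(np.abs(resid), axis=1, keepdims=True)
        lim = 3.0 * np.where(madn > 0, madn, np.inf)
        out[..., sl] = (trend + np.clip(resid, -lim, lim)).reshape(block.shape)
    res = vol.with_data(out)
    res.note("despike clip at 3*MADN about polynomial trend")
    return res


# ---------------------------------------------------------------------------
# multi-echo optimal combination


@dataclass
class OCWeights:
    """Per-voxel T2*/S0 fits and the echo weights used for optimal combination."""

    t2star: np.ndarray  # ms
    s0: np.ndarray
    weights: np.ndarray  # (..., n_echoes), sums to 1 where valid
    valid: np.ndarray  # bool

    T2S_BOUNDS = (2.0, 300.0)


def fit_t2star_and_combine(
    es: EchoSet, mask: np.ndarray | None = None
) -> tuple[Volume4D, OCWeights]:
    """Optimally combine a multi-echo set into one BOLD-weighted series.

    Per voxel, ``log(mean signal)`` is regressed on TE to give T2* and S0
    (T2* clamped to [2, 300] ms).  Echo weights are
    ``w_i ∝ TE_i · exp(−TE_i / T2*)``, normalized to sum to one; voxels
    with a non-positive mean in any echo fall back to uniform weights.
    """
    if es.n_echoes < 2:
        raise ValueError("optimal combination requires at least 2 echoes")
    tes = np.asarray(es.echo_times)  # ms
    means = np.stack([e.data.mean(axis=3) for e in es.echoes], axis=-1)  # (...,E)
    valid = np.all(means > 0, axis=-1)
    lo, hi = OCWeights.T2S_BOUNDS

    logm = np.log(np.where(means > 0, means, 1.0))
    # least squares of log(S) = log(S0) − TE/T2* over echoes
    x = tes - tes.mean()
    slope = (logm * x).sum(axis=-1) / (x**2).sum()
    intercept = logm.mean(axis=-1) - slope * tes.mean()
    with np.errstate(divide="ignore"):
        t2s = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), hi)
    t2s = np.clip(t2s, lo, hi)
    s0 = np.exp(intercept + tes.mean() / np.where(t2s > 0, t2s, np.inf))

    w = tes[np.newaxis, np.newaxis, np.newaxis, :] * np.exp(
        -tes[np.newaxis, np.newaxis, np.newaxis, :] / t2s[..., np.newaxis]
    )
    w = np.where(valid[..., np.newaxis], w, 1.0)
    w = w / w.sum(axis=-1, keepdims=True)

    combined = np.zeros_like(es.echoes[0].data)
    for i, echo in enumerate(es.echoes):
        combined += w[..., i : i + 1] * echo.data
    first = es.echoes[0]
    out = first.with_data(combined)
    out.note(f"fit_t2star_and_combine echoes={list(tes)}")
    weights = OCWeights(t2star=t2s, s0=s0, weights=w, valid=valid)
    return out, weights
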