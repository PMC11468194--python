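"""The integrated quality-control battery.

Scalar metrics (TSNR summaries, GCOR, censor counts), derived maps (TSNR,
radial correlation, regional/seed correlation), automated checks (left-right
flip, through-plane variance lines), the ROI TSNR/shape table, the basic
review dictionary, the cross-subject review table, and the static HTML
report.

QC maps are deliberately computed over the whole field of view — the brain
mask is reserved for summary statistics only — so artifacts outside the
brain (ghosting, bad coils, misalignment) remain visible instead of being
hidden by masking.
"""

from __future__ import annotations

import base64
import html
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .preprocess import _detrend_columns  # noqa: E402  (backend set first)
from .regress import Warning_  # noqa: E402
from .types import ROILabelVolume, Volume4D

__all__ = [
    "QCRecord",
    "tsnr_map",
    "radial_correlation",
    "gcor",
    "average_roi_correlation_map",
    "seed_correlation_map",
    "lpc_cost",
    "left_right_flip_check",
    "roi_stats_table",
    "variance_line_check",
    "basic_review",
    "review_table",
    "render_apqc_html",
    "DEFAULT_TEMPLATE_SEEDS",
]

#: Template-space seed coordinates (mm) for the shipped resting-state QC
#: maps: default mode (posterior cingulate), visual and auditory cortex.
DEFAULT_TEMPLATE_SEEDS = {
    "DMN": (5.0, -55.0, 26.0),
    "visual": (-4.0, -90.0, 2.0),
    "auditory": (-54.0, -24.0, 10.0),
}


@dataclass
class QCRecord:
    """Scalar QC quantities, derived-map paths and warnings for one subject."""

    scalars: dict = field(default_factory=dict)
    map_paths: dict = field(default_factory=dict)
    warnings: list[Warning_] = field(default_factory=list)
    rating: str = ""  # inert placeholder; the report renders it read-only


# ---------------------------------------------------------------------------
# maps


def tsnr_map(
    vol: Volume4D,
    residuals: Volume4D | None = None,
    mask: np.ndarray | None = None,
    polort: int | str = "auto",
) -> Volume4D:
    """Temporal SNR: mean(baseline-fitted signal) / std(residual), per voxel.

    When GLM residuals are supplied the noise term is their standard
    deviation; otherwise the residual of a per-run polynomial detrend is
    used.  Computed over the whole FOV; any mask only affects summaries
    computed downstream.  Voxels with zero residual spread get TSNR 0.
    """
    if vol.n_volumes < 10:
        raise ValueError("TSNR needs at least 10 volumes")
    mean_img = vol.data.mean(axis=3)
    if residuals is not None:
        noise = residuals.data.std(axis=3)
    else:
        flat = vol.data.reshape(-1, vol.n_volumes)
        resid = np.empty_like(flat)
        for sl in vol.run_slices:
            order = (
                1 + int((sl.stop - sl.start) * vol.tr // 150.0)
                if polort == "auto"
                else int(polort)
            )
            resid[:, sl] = _detrend_columns(flat[:, sl], order)
        noise = resid.std(axis=1).reshape(vol.grid.dims)
    # constant voxels produce numerically-zero residual spread; call them 0
    floor = 1e-10 * (np.abs(mean_img) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(noise > floor, np.abs(mean_img) / noise, 0.0)
    out = vol.with_data(tsnr[..., np.newaxis], units_tag="tsnr", run_lengths=[1])
    out.slice_times = np.empty(0)
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise Pearson r between (V, T) arrays, 0 where either is constant."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    na = np.sqrt(np.sum(a**2, axis=-1))
    nb = np.sqrt(np.sum(b**2, axis=-1))
    denom = na * nb
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, np.sum(a * b, axis=-1) / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def radial_correlation(vol: Volume4D, hwhm_mm: float = 20.0) -> Volume4D:
    """Correlate each voxel with the Gaussian-weighted average of its
    surroundings (default 20 mm half-width at half-max): a detector of
    scanner artifacts and widespread spurious coherence."""
    if vol.n_volumes < 10:
        raise ValueError("radial correlation needs at least 10 volumes")
    sigma_vox = [
        hwhm_mm / np.sqrt(2.0 * np.log(2.0)) / vs for vs in vol.grid.voxel_size
    ]
    neigh = np.empty_like(vol.data)
    for t in range(vol.n_volumes):
        neigh[..., t] = ndimage.gaussian_filter(vol.data[..., t], sigma_vox, mode="nearest")
    r = _safe_corr(
        vol.data.reshape(-1, vol.n_volumes), neigh.reshape(-1, vol.n_volumes)
    ).reshape(vol.grid.dims)
    out = vol.with_data(r[..., np.newaxis], units_tag="correlation", run_lengths=[1])
    out.slice_times = np.empty(0)
    return out


def gcor(vol: Volume4D, mask: np.ndarray) -> float:
    """Global correlation: average of all pairwise temporal correlations.

    Equals ‖mean of the demeaned, unit-norm in-mask series‖²; lies in [0, 1].
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("GCOR needs at least 2 in-mask voxels")
    series = vol.data[mask]  # (V, T)
    series = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(series, axis=1, keepdims=True)
    good = norms[:, 0] > 0
    unit = series[good] / norms[good]
    if unit.shape[0] == 0:
        return 0.0
    mean_vec = unit.mean(axis=0)
    return float(np.clip(np.sum(mean_vec**2), 0.0, 1.0))


def average_roi_correlation_map(
    vol: Volume4D, roi: ROILabelVolume | np.ndarray
) -> Volume4D:
    """Correlate every voxel (whole FOV) with the mean series over all
    nonzero-label voxels of the ROI/mask ("corr_brain"-style map)."""
    region = roi.mask() if isinstance(roi, ROILabelVolume) else np.asarray(roi, bool)
    if not region.any():
        raise ValueError("empty region for average correlation map")
    mean_series = vol.data[region].mean(axis=0)
    r = _safe_corr(
        vol.data.reshape(-1, vol.n_volumes),
        np.broadcast_to(mean_series, (np.prod(vol.grid.dims), vol.n_volumes)),
    ).reshape(vol.grid.dims)
    out = vol.with_data(r[..., np.newaxis], units_tag="correlation", run_lengths=[1])
    out.slice_times = np.empty(0)
    return out


def seed_correlation_map(
    vol: Volume4D, seed_xyz: tuple[float, float, float], censor=None
) -> Volume4D:
    """Correlation of every voxel with the seed voxel's series (seed given in
    world mm); censored volumes are excluded from the correlation."""
    ijk = np.round(vol.grid.world_to_voxel(np.asarray(seed_xyz))).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.asarray(vol.grid.dims)):
        raise ValueError(f"seed {seed_xyz} mm maps outside the field of view")
    keep = censor.keep if censor is not None else np.ones(vol.n_volumes, bool)
    data = vol.data[..., keep]
    seed_series = data[ijk[0], ijk[1], ijk[2]]
    r = _safe_corr(
        data.reshape(-1, keep.sum()),
        np.broadcast_to(seed_series, (np.prod(vol.grid.dims), keep.sum())),
    ).reshape(vol.grid.dims)
    out = vol.with_data(r[..., np.newaxis], units_tag="correlation", run_lengths=[1])
    out.slice_times = np.empty(0)
    return out


# ---------------------------------------------------------------------------
# alignment QC


def lpc_cost(a: np.ndarray, b: np.ndarray, grid: Volume4D | None = None, patch_mm: float = 8.0) -> float:
    """Local Pearson correlation cost between two 3D images.

    The FOV is tiled into ~``patch_mm`` cubes; per patch with nonzero
    variance in both images the Pearson ρ is computed and the cost is
    ``−Σ w·ρ·|ρ| / Σ w`` with w the voxel count.  Identical images → −1,
    contrast-reversed → +1; designed for cross-modality alignment where
    the sign of local contrast may flip.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("lpc_cost requires images on the same grid")
    voxel = grid.grid.voxel_size if isinstance(grid, Volume4D) else (
        grid.voxel_size if grid is not None else (3.0, 3.0, 3.0)
    )
    steps = [max(2, int(round(patch_mm / vs))) for vs in voxel]
    # trim to whole patches and compute all patch correlations in one pass
    trim = [s * (d // s) for s, d in zip(steps, a.shape)]
    if any(t == 0 for t in trim):
        raise ValueError("image smaller than one lpc patch")
    sl = tuple(slice(0, t) for t in trim)

    def blocks(img):
        nb = [t // s for t, s in zip(trim, steps)]
        return img[sl].reshape(
            nb[0], steps[0], nb[1], steps[1], nb[2], steps[2]
        ).transpose(0, 2, 4, 1, 3, 5).reshape(-1, int(np.prod(steps)))

    pa, pb = blocks(a), blocks(b)
    pa = pa - pa.mean(axis=1, keepdims=True)
    pb = pb - pb.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(pa**2, axis=1))
    sb = np.sqrt(np.sum(pb**2, axis=1))
    valid = (sa > 1e-12) & (sb > 1e-12)
    if not valid.any():
        raise ValueError("no patch with sufficient variance for lpc cost")
    rho = np.sum(pa[valid] * pb[valid], axis=1) / (sa[valid] * sb[valid])
    w = float(np.prod(steps))
    return float(-np.sum(w * rho * np.abs(rho)) / (w * valid.sum()))


def _align_cost(params, moving, ref, grid):
    from .preprocess import apply_rigid

    res = apply_rigid(moving, grid, params)
    return lpc_cost(res, ref, grid)


def left_right_flip_check(
    epi_ref: Volume4D, anat: Volume4D
) -> tuple[str, float, float]:
    """Check whether the EPI and anatomical are left-right flipped.

    The anatomical (resampled to the EPI grid) and its x-mirrored copy are
    each rigidly aligned to the EPI reference under the local-Pearson cost;
    the verdict follows the lower (better) cost, or ``inconclusive`` when
    the costs differ by less than 0.02.  Returns (verdict, cost_noflip,
    cost_flip).
    """
    from scipy.optimize import minimize

    from .preprocess import _resample_3d

    epi_img = epi_ref.data[..., 0]
    grid = epi_ref.grid
    anat_res = _resample_3d(anat.data[..., 0], anat.grid, grid, np.eye(4))
    costs = {}
    for tag, img in (("no_flip", anat_res), ("flip", anat_res[::-1].copy())):
        try:
            best = minimize(
                _align_cost, np.zeros(6), args=(img, epi_img, grid),
                method="Powell", options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": 30},
            )
            costs[tag] = float(best.fun)
        except Exception as exc:
            raise RuntimeError(f"flip-check alignment failed ({tag}): {exc}") from exc
    delta = costs["flip"] - costs["no_flip"]
    if abs(delta) < 0.02:
        verdict = "inconclusive"
    else:
        verdict = "no_flip" if delta > 0 else "flip_suspected"
    return verdict, costs["no_flip"], costs["flip"]


# ---------------------------------------------------------------------------
# tables & checks


def roi_stats_table(
    tsnr: Volume4D, roi: ROILabelVolume, labels: list | str = "ALL"
) -> pd.DataFrame:
    """TSNR and shape statistics per ROI.

    Columns: Nvox (ROI voxel count), Nzer (zero-TSNR voxels), Dvox (maximum
    6-connected erosion depth), Tmin/T25%/Tmed/T75%/Tmax over nonzero
    voxels, the deepest voxel's coordinates, and a warning tag (shape warn
    when Nzer > 0 or Dvox ≤ 1; low-TSNR warn when Tmed falls below half the
    global in-ROI median).
    """
    if roi.grid.dims != tsnr.grid.dims:
        raise ValueError("ROI and TSNR grids differ")
    timg = tsnr.data[..., 0]
    if labels == "ALL":
        label_ids = sorted(int(v) for v in np.unique(roi.labels) if v != 0)
    else:
        label_ids = []
        for lab in labels:
            mask = roi.mask(lab)  # raises for unknown labels
            label_ids.append(
                int(lab)
                if not isinstance(lab, str)
                else {v: k for k, v in roi.label_table.items()}[lab]
            )
            del mask
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    all_vals = timg[roi.mask() & (timg != 0)]
    global_med = float(np.median(all_vals)) if all_vals.size else 0.0
    rows = []
    for lid in label_ids:
        mask = roi.labels == lid
        nvox = int(mask.sum())
        vals = timg[mask]
        nzer = int(np.sum(vals == 0))
        depth = np.zeros(roi.grid.dims, dtype=int)
        cur = mask.copy()
        d = 0
        while cur.any():
            d += 1
            depth[cur] = d
            cur = ndimage.binary_erosion(cur, structure=struct)
        dvox = int(depth.max())
        peak_idx = np.unravel_index(int(np.argmax(depth)), depth.shape)
        nz_vals = vals[vals != 0]
        if nz_vals.size:
            tmin, t25, tmed, t75, tmax = np.percentile(nz_vals, [0, 25, 50, 75, 100])
        else:
            tmin = t25 = tmed = t75 = tmax = 0.0
        warn = []
        if nzer > 0 or dvox <= 1:
            warn.append("shape")
        if global_med > 0 and tmed < global_med / 2.0:
            warn.append("low_tsnr")
        rows.append(
            {
                "label": lid,
                "name": roi.label_table.get(lid, str(lid)),
                "Nvox": nvox,
                "Nzer": nzer,
                "Dvox": dvox,
                "Tmin": float(tmin),
                "T25%": float(t25),
                "Tmed": float(tmed),
                "T75%": float(t75),
                "Tmax": float(tmax),
                "depth_voxel": tuple(int(i) for i in peak_idx),
                "warns": ",".join(warn),
            }
        )
    return pd.DataFrame(rows)


def variance_line_check(vol: Volume4D, mask: np.ndarray) -> list[tuple[int, int]]:
    """Flag through-plane (x, y) columns of abnormally high temporal variance.

    Per in-mask column, the mean detrended temporal variance over z is
    compared to the distribution across columns; columns beyond
    median + 4·MADN are reported.  Scale-invariant by construction.
    """
    if vol.grid.dims[2] < 4:
        raise ValueError("variance-line check needs nz >= 4")
    mask = np.asarray(mask, dtype=bool)
    flat = vol.data.reshape(-1, vol.n_volumes)
    resid = _detrend_columns(flat, 2).reshape(vol.data.shape)
    var = resid.var(axis=3)  # (x, y, z)
    col_mask = mask.any(axis=2)
    with np.errstate(invalid="ignore"):
        col_var = np.where(
            mask.sum(axis=2) > 0,
            np.sum(var * mask, axis=2) / np.maximum(mask.sum(axis=2), 1),
            np.nan,
        )
    vals = col_var[col_mask]
    med = np.nanmedian(vals)
    madn = 1.4826 * np.nanmedian(np.abs(vals - med))
    if madn <= 0:
        return []
    thr = med + 4.0 * madn
    hits = np.argwhere(col_mask & (col_var > thr))
    return [tuple(int(v) for v in h) for h in hits]


# ---------------------------------------------------------------------------
# review outputs


def basic_review(qc: QCRecord) -> str:
    """Render the ordered key→value basic-review text from a QC record."""
    lines = []
    width = max((len(k) for k in qc.scalars), default=0)
    for key, value in qc.scalars.items():
        if isinstance(value, float):
            value = f"{value:.6g}"
        lines.append(f"{key:<{width}} : {value}")
    return "\n".join(lines) + "\n"


def review_table(uvars_files: list[str | Path], criteria: list[str] | None = None):
    """Aggregate per-subject uvars files into one table.

    One row per subject, columns the union of keys (missing → blank).
    ``criteria`` strings like ``"censor_frac ge 0.1"`` flag outlier
    subjects; the return is (DataFrame, outlier report list).  Unparseable
    files are listed in the report, not fatal.
    """
    import json

    rows, report = [], []
    for path in uvars_files:
        try:
            with open(path) as fh:
                rec = json.load(fh)
            if not isinstance(rec, dict):
                raise ValueError("uvars is not a dictionary")
            rec.setdefault("_file", str(path))
            rows.append(rec)
        except Exception as exc:
            report.append(f"unparseable uvars file {path}: {exc}")
    df = pd.DataFrame(rows)
    ops = {
        "ge": np.greater_equal,
        "gt": np.greater,
        "le": np.less_equal,
        "lt": np.less,
        "eq": np.equal,
    }
    for crit in criteria or []:
        try:
            key, op, value = crit.split()
            fn, thr = ops[op], float(value)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"bad outlier criterion {crit!r}") from exc
        if key not in df.columns:
            continue
        vals = pd.to_numeric(df[key], errors="coerce")
        for idx in df.index[fn(vals, thr).fillna(False)]:
            subj = df.loc[idx].get("subject_id", df.loc[idx]["_file"])
            report.append(f"{subj}: {key} = {vals[idx]:g} ({crit})")
    return df, report


# ---------------------------------------------------------------------------
# HTML report

_SECTIONS = ("vorig", "ve2a", "mot", "regr", "warns", "radcor", "qsumm")


def _fig_to_b64(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=80, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _montage(map_vol: Volume4D, title: str, threshold: float | None = None):
    """Axial montage; with a threshold, transparent thresholding is applied:
    sub-threshold voxels grow translucent in proportion to |value|/threshold
    and supra-threshold voxels are opaque with a contour outline."""
    img = map_vol.data[..., 0]
    nz = img.shape[2]
    picks = np.linspace(0, nz - 1, min(6, nz)).astype(int)
    fig, axes = plt.subplots(1, len(picks), figsize=(2.2 * len(picks), 2.4))
    axes = np.atleast_1d(axes)
    vmax = np.percentile(np.abs(img), 99.5) or 1.0
    for ax, z in zip(axes, picks):
        sl = img[:, :, z].T
        if threshold is not None:
            alpha = np.clip(np.abs(sl) / threshold, 0.0, 1.0)
            ax.imshow(sl, origin="lower", cmap="coolwarm", vmin=-vmax, vmax=vmax, alpha=alpha)
            if np.any(np.abs(sl) >= threshold):
                ax.contour(np.abs(sl), levels=[threshold], colors="k", linewidths=0.6)
        else:
            ax.imshow(sl, origin="lower", cmap="gray", vmin=-vmax, vmax=vmax)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(f"z={z}", fontsize=7)
    fig.suptitle(title, fontsize=9)
    return fig


def _censor_intervals(keep: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous censored index intervals [start, stop)."""
    out = []
    in_run = False
    for i, k in enumerate(keep):
        if not k and not in_run:
            start, in_run = i, True
        elif k and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(keep)))
    return out


def _motion_figure(qc: QCRecord):
    enorm = np.asarray(qc.scalars.get("_enorm_series", []))
    outl = np.asarray(qc.scalars.get("_outlier_series", []))
    keep = np.asarray(qc.scalars.get("_keep_series", []), dtype=bool)
    fig, axes = plt.subplots(2, 1, figsize=(7, 3.2), sharex=True)
    for ax, series, name, thr_key in (
        (axes[0], enorm, "Enorm (mm)", "censor_enorm_thr"),
        (axes[1], outl, "outlier frac", "censor_outlier_thr"),
    ):
        if series.size:
            ax.plot(series, lw=0.8, color="k")
        thr = qc.scalars.get(thr_key)
        if thr:
            ax.axhline(thr, color="c", lw=1.0)  # censor threshold line
        for a, b in _censor_intervals(keep) if keep.size else []:
            ax.axvspan(a - 0.5, b - 0.5, color="r", alpha=0.3)
        ax.set_ylabel(name, fontsize=8)
    axes[1].set_xlabel("volume index", fontsize=8)
    return fig


def render_apqc_html(qc: QCRecord, out_dir: str | Path, subject_id: str = "subj") -> Path:
    """Write the static single-page QC report.

    Sections: vorig (original data), ve2a (alignment), mot (motion &
    censoring), regr (regression model), warns (sorted by severity),
    radcor (radial correlation), qsumm (scalar summary).  Statistic maps
    use transparent thresholding; motion plots show threshold lines and
    censor bands.  Missing maps render as an "absent" placeholder.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    level_rank = {"severe": 3, "medium": 2, "mild": 1, "none": 0}
    warns = sorted(qc.warnings, key=lambda w: -level_rank.get(w.level, 0))
    keep = np.asarray(qc.scalars.get("_keep_series", []), dtype=bool)
    n_bands = len(_censor_intervals(keep)) if keep.size else 0

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>QC report: {html.escape(subject_id)}</title>",
        "<style>body{font-family:sans-serif;margin:1em}h2{background:#eee;padding:2px}"
        "table{border-collapse:collapse}td,th{border:1px solid #999;padding:2px 6px}"
        ".severe{color:#b00}.medium{color:#c60}.mild{color:#880}</style></head><body>",
        f"<h1>Single-subject QC: {html.escape(subject_id)}</h1>",
        "<nav>" + " | ".join(f"<a href='#{s}'>{s}</a>" for s in _SECTIONS) + "</nav>",
    ]

    def section(sec_id: str, title: str, body: str) -> None:
        parts.append(f"<h2 id='{sec_id}'>{title}</h2>{body}")

    def map_img(key: str, title: str, threshold: float | None = None) -> str:
        vol = qc.map_paths.get(key)
        if vol is None:
            return f"<p><em>{html.escape(title)}: absent</em></p>"
        if isinstance(vol, (str, Path)):
            from .io import read_nifti

            vol = read_nifti(vol)
        fig = _montage(vol, title, threshold)
        return f"<img alt='{html.escape(title)}' src='data:image/png;base64,{_fig_to_b64(fig)}'/>"

    section("vorig", "Original data", map_img("mean_orig", "temporal mean of input EPI"))
    section("ve2a", "EPI/anatomical alignment",
            map_img("anat_edge", "anatomical over EPI")
            + f"<p>left-right flip check: <b>{html.escape(str(qc.scalars.get('flip_verdict', 'n/a')))}</b></p>")
    mot_fig = _motion_figure(qc)
    section(
        "mot",
        "Motion and censoring",
        f"<img alt='motion' data-censor-bands='{n_bands}' "
        f"src='data:image/png;base64,{_fig_to_b64(mot_fig)}'/>"
        f"<p>{qc.scalars.get('n_censored', 0)} volumes censored "
        f"({100 * float(qc.scalars.get('censor_frac', 0.0)):.1f}%).</p>",
    )
    thr = qc.scalars.get("stat_threshold", 3.0)
    section("regr", "Regression model",
            map_img("fstat", "full-model F (transparent thresholding)", threshold=thr)
            + map_img("tsnr", "TSNR after regression"))
    if warns:
        rows = "".join(
            f"<li class='{w.level}'>[{w.level}] {html.escape(w.check)}: {html.escape(w.message)}</li>"
            for w in warns
        )
        section("warns", "Warnings", f"<ul>{rows}</ul>")
    else:
        section("warns", "Warnings", "<p>no warnings</p>")
    section("radcor", "Radial correlation", map_img("radcor", "radial correlation"))
    scal_rows = "".join(
        f"<tr><th>{html.escape(k)}</th><td>{html.escape(f'{v:.6g}' if isinstance(v, float) else str(v))}</td></tr>"
        for k, v in qc.scalars.items()
        if not k.startswith("_")
    )
    rating = "<p>rating: <span id='rating'>(not rated — static report)</span></p>"
    section("qsumm", "Summary quantities", f"<table>{scal_rows}</table>{rating}")
    parts.append("</body></html>")
    out_path = out_dir / f"apqc_{subject_id}.html"
    out_path.write_text("\n".join(parts))
    return out_path
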