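"""Synthetic phantoms and auxiliary inputs with known ground truth.

The generator emulates the features of a single-subject EPI acquisition
that the processing stages act on: an ellipsoidal three-shell "brain" with
tissue-specific S0 and T2* (so multi-echo sets decay correctly with TE),
per-volume rigid head motion injected with the toolkit's own resampler,
slow polynomial drift, task responses built from the regression module's
HRF bases at stated percent amplitudes, cardiac/respiratory sinusoids with
slice-acquisition-dependent phase, optional intensity spikes, an optional
ghost replica at half-FOV offset (for unmasked-QC tests), and Gaussian
noise at a configurable temporal SNR.

Defaults mirror a typical multi-echo resting-state protocol (TR = 2.2 s;
TE = 12.5, 27.6, 42.7 ms) on a grid small enough for fast tests.

Everything is driven by one integer seed; regenerating with the same seed
reproduces the phantom bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .physio import PhysioTrace, write_physio_trace
from .regress import BasisSpec, sample_basis
from .types import EchoSet, Event, Grid, StimClass, TimingSet, Volume4D

__all__ = [
    "PhantomTruth",
    "make_phantom",
    "make_physio_traces",
    "make_task_timing",
    "DEFAULT_ECHO_TIMES_MS",
]

DEFAULT_ECHO_TIMES_MS = (12.5, 27.6, 42.7)

#: tissue shells: fraction of the ellipsoid radius, S0 intensity, T2* (ms)
_TISSUE_SHELLS = (
    ("csf", 0.35, 1400.0, 90.0),
    ("gray", 0.80, 1000.0, 45.0),
    ("white", 1.00, 900.0, 55.0),
)


@dataclass
class PhantomTruth:
    """Everything needed to verify a stage's output against construction."""

    seed: int
    grid_dims: tuple
    tr: float
    n_volumes: int
    echo_times: tuple
    tissue_mask: np.ndarray  # 0 = air, 1..3 = shell index
    brain_mask: np.ndarray
    t2star: np.ndarray  # ms, per voxel (0 outside)
    s0: np.ndarray
    motion: np.ndarray  # (n_volumes, 6) injected rigid parameters
    drift_coefs: np.ndarray
    task_betas: dict  # label -> percent amplitude
    timing: TimingSet | None
    physio: dict
    spikes: list  # (volume index, amplitude multiple of sigma, frac of mask)
    noise_sigma: float
    ghost: float


def _ellipsoid_shells(dims: tuple[int, int, int]) -> np.ndarray:
    """Label volume: 0 air, 1 inner (csf), 2 mid (gray), 3 outer (white)."""
    nx, ny, nz = dims
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    r = np.sqrt((x / 0.8) ** 2 + (y / 0.85) ** 2 + (z / 0.75) ** 2)
    labels = np.zeros(dims, dtype=int)
    for i, (_, frac, _, _) in enumerate(_TISSUE_SHELLS, start=1):
        labels[(r <= frac) & (labels == 0)] = i
    return labels


def _asym_blob(dims: tuple[int, int, int], seed: int) -> np.ndarray:
    """Unit-amplitude Gaussian blob in the left hemisphere, at a
    seed-deterministic normalized location shared across modalities."""
    rng = np.random.default_rng(seed + 77003)
    cx = rng.uniform(-0.55, -0.25)  # left of midline in normalized coords
    cy = rng.uniform(-0.3, 0.3)
    cz = rng.uniform(-0.25, 0.25)
    x, y, z = np.meshgrid(
        *[np.linspace(-1, 1, d) for d in dims], indexing="ij"
    )
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    return np.exp(-r2 / (2.0 * 0.12**2))


def make_phantom(
    dims: tuple[int, int, int] = (32, 32, 20),
    tr: float = 2.2,
    n_volumes: int = 150,
    voxel_mm: float = 3.0,
    echo_times: tuple | None = None,
    seed: int = 0,
    motion_amp_mm: float = 0.0,
    motion_amp_deg: float = 0.0,
    drift_percent: float = 1.0,
    task_timing: TimingSet | None = None,
    task_betas: dict | None = None,
    basis: BasisSpec | None = None,
    physio_cardiac_hz: float = 0.0,
    physio_resp_hz: float = 0.0,
    physio_percent: float = 1.0,
    spikes: list | None = None,
    noise_tsnr: float = 80.0,
    ghost: float = 0.0,
    texture: float = 0.1,
    asymmetry: float = 0.0,
    run_lengths: list[int] | None = None,
):
    """Build a phantom EPI acquisition with full ground truth.

    Returns ``(EchoSet, PhantomTruth)`` when ``echo_times`` has ≥ 2 entries
    and ``(Volume4D, PhantomTruth)`` otherwise (single echo at TE 27.6 ms,
    or at ``echo_times[0]``).  ``noise_tsnr`` sets the Gaussian noise σ as
    (gray-matter baseline)/TSNR; 0 disables noise.  Motion amplitudes are
    the half-ranges of smooth pseudo-random excursions, injected with the
    toolkit's own trilinear resampler.
    """
    if any(d < 4 for d in dims):
        raise ValueError(f"phantom dims too small: {dims}")
    rng = np.random.default_rng(seed)
    tes = tuple(echo_times) if echo_times else (DEFAULT_ECHO_TIMES_MS[1],)
    multi = len(tes) >= 2

    shells = _ellipsoid_shells(dims)
    brain = shells > 0
    s0 = np.zeros(dims)
    t2s = np.zeros(dims)
    for i, (_, _, s0_val, t2_val) in enumerate(_TISSUE_SHELLS, start=1):
        s0[shells == i] = s0_val
        t2s[shells == i] = t2_val
    if texture:
        # smooth multiplicative inhomogeneity: realistic tissue texture, and
        # it anchors rotational registration the bare ellipsoid cannot
        from scipy import ndimage as _ndi

        fieldmap = _ndi.gaussian_filter(rng.standard_normal(dims), 2.0)
        fieldmap /= max(np.abs(fieldmap).max(), 1e-9)
        s0 = s0 * (1.0 + texture * fieldmap)
    if asymmetry:
        # bright left-hemisphere feature, shared with make_anat_phantom at
        # the same seed, so cross-modal laterality checks have an anchor
        s0 = s0 * (1.0 + asymmetry * _asym_blob(dims, seed) * brain)

    nz = dims[2]
    # interleaved slice acquisition order
    order = list(range(0, nz, 2)) + list(range(1, nz, 2))
    slice_times = np.empty(nz)
    slice_times[order] = np.arange(nz) * (tr / nz)
    grid = Grid.isotropic(dims, voxel_mm)
    run_lengths = run_lengths or [n_volumes]
    if sum(run_lengths) != n_volumes:
        raise ValueError("run_lengths must sum to n_volumes")

    # --- temporal modulation common to all echoes (multiplicative, percent)
    frac = np.zeros(dims + (n_volumes,))

    start = 0
    drift_coefs = []
    for n in run_lengths:
        x = np.linspace(-1, 1, n)
        coefs = rng.uniform(-1, 1, size=3) * drift_percent / 100.0
        coefs[0] = 0.0
        drift = sum(
            c * np.polynomial.legendre.Legendre.basis(k)(x) for k, c in enumerate(coefs)
        )
        frac[..., start : start + n] += drift[np.newaxis, np.newaxis, np.newaxis, :]
        drift_coefs.append(coefs)
        start += n

    betas = dict(task_betas or {})
    if task_timing is not None and betas:
        basis = basis or BasisSpec(name="GAM")
        from .regress import event_regressors

        for label, amp in betas.items():
            col, _ = event_regressors(
                task_timing, label, basis, "time", run_lengths=run_lengths, tr=tr
            )
            frac[brain] += (amp / 100.0) * col[:, 0][np.newaxis, :]

    physio_truth = {}
    if physio_cardiac_hz or physio_resp_hz:
        tvol = np.arange(n_volumes) * tr
        zphase = 2.0 * np.pi * rng.random(nz)
        amp = physio_percent / 100.0
        for hz, tag in ((physio_cardiac_hz, "cardiac"), (physio_resp_hz, "resp")):
            if not hz:
                continue
            for z in range(nz):
                t_acq = tvol + slice_times[z]
                wave = amp * np.sin(2.0 * np.pi * hz * t_acq + zphase[z])
                frac[:, :, z, :][brain[:, :, z]] += wave[np.newaxis, :]
            physio_truth[tag] = {"hz": hz, "slice_phase": zphase, "percent": physio_percent}

    spikes = list(spikes or [])

    def build_echo(te_ms: float) -> Volume4D:
        base = np.where(brain, s0 * np.exp(-te_ms / np.where(t2s > 0, t2s, np.inf)), 0.0)
        data = base[..., np.newaxis] * (1.0 + frac)
        gm_level = float(base[shells == 2].mean()) if np.any(shells == 2) else 1.0
        sigma = gm_level / noise_tsnr if noise_tsnr else 0.0
        for t_idx, amp_sigma, mask_frac in spikes:
            vox = np.argwhere(brain)
            take = vox[rng.choice(len(vox), max(1, int(mask_frac * len(vox))), replace=False)]
            bump = amp_sigma * (sigma if sigma else 0.01 * gm_level)
            data[take[:, 0], take[:, 1], take[:, 2], t_idx] += bump
        if ghost:
            shift = dims[1] // 2
            data = data + ghost * np.roll(data, shift, axis=1)
        vol = Volume4D(
            grid=grid, data=data, tr=tr, slice_times=slice_times,
            run_lengths=list(run_lengths),
        )
        if motion_amp_mm or motion_amp_deg:
            from .preprocess import apply_rigid

            moved = vol.data.copy()
            for t in range(n_volumes):
                if np.any(motion[t]):
                    moved[..., t] = apply_rigid(vol.data[..., t], grid, motion[t])
            vol = vol.with_data(moved)
        if sigma:
            vol = vol.with_data(vol.data + rng.normal(0.0, sigma, vol.data.shape))
        vol.note(f"make_phantom seed={seed} te={te_ms}ms")
        return vol

    # smooth pseudo-random motion trajectory (reference volume 0 is zero)
    motion = np.zeros((n_volumes, 6))
    if motion_amp_mm or motion_amp_deg:
        tnorm = np.arange(n_volumes) / max(n_volumes - 1, 1)
        for j in range(6):
            amp = motion_amp_deg if j < 3 else motion_amp_mm
            f1, f2 = rng.uniform(0.5, 2.0, 2)
            ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
            wave = np.sin(2 * np.pi * f1 * tnorm + ph1) + 0.5 * np.sin(
                2 * np.pi * f2 * tnorm + ph2
            )
            wave -= wave[0]  # reference volume has zero parameters
            motion[:, j] = amp * wave / max(np.abs(wave).max(), 1e-9)

    truth = PhantomTruth(
        seed=seed,
        grid_dims=dims,
        tr=tr,
        n_volumes=n_volumes,
        echo_times=tes,
        tissue_mask=shells,
        brain_mask=brain,
        t2star=t2s,
        s0=s0,
        motion=motion,
        drift_coefs=np.array(drift_coefs),
        task_betas=betas,
        timing=task_timing,
        physio=physio_truth,
        spikes=spikes,
        noise_sigma=0.0 if not noise_tsnr else 1.0,
        ghost=ghost,
    )
    if multi:
        echoes = [build_echo(te) for te in tes]
        return EchoSet(echoes=echoes, echo_times=list(tes)), truth
    return build_echo(tes[0]), truth


def make_anat_phantom(
    dims: tuple[int, int, int] = (48, 48, 30),
    voxel_mm: float = 2.0,
    seed: int = 0,
    asymmetry: float = 0.0,
) -> Volume4D:
    """A 3D anatomical companion: same ellipsoid, T1-like contrast.

    ``asymmetry`` adds a bright left-hemisphere feature, which gives the
    left-right flip check something to latch onto.
    """
    shells = _ellipsoid_shells(dims)
    img = np.zeros(dims)
    # T1-like: white bright, gray mid, csf dark (contrast differs from EPI)
    for i, level in ((1, 300.0), (2, 700.0), (3, 1000.0)):
        img[shells == i] = level
    if asymmetry:
        img += asymmetry * 1000.0 * _asym_blob(dims, seed) * (shells > 0)
    return Volume4D(grid=Grid.isotropic(dims, voxel_mm), data=img)


def make_physio_traces(
    duration_s: float,
    rate_hz: float = 50.0,
    cardiac_hz: float = 1.0,
    resp_hz: float = 0.25,
    jitter: float = 0.05,
    amp_mod: float = 0.15,
    seed: int = 0,
) -> tuple[PhysioTrace, PhysioTrace, dict]:
    """Quasi-periodic cardiac and respiratory traces with known peak times.

    Inter-beat intervals are jittered (s.d. ``jitter`` × mean interval) and
    amplitudes slowly modulated.  Returns (cardiac, respiratory, truth)
    where truth holds the exact generated peak times per trace.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    truth: dict = {}

    def quasi_wave(freq: float, sharp: float) -> tuple[np.ndarray, np.ndarray]:
        mean_ibi = 1.0 / freq
        beats = [0.3 * mean_ibi]
        while beats[-1] < duration_s + 2 * mean_ibi:
            beats.append(beats[-1] + mean_ibi * max(0.3, 1.0 + jitter * rng.standard_normal()))
        beats = np.asarray(beats)
        # phase ramps 0..2π between beats; waveform peaks at each beat time
        seg = np.clip(np.searchsorted(beats, t, side="right") - 1, 0, beats.size - 2)
        phase = 2 * np.pi * (t - beats[seg]) / (beats[seg + 1] - beats[seg])
        wave = np.cos(phase) ** 1 if sharp == 1 else np.sign(np.cos(phase)) * np.abs(np.cos(phase)) ** sharp
        am = 1.0 + amp_mod * np.sin(2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi))
        return am * wave, beats[(beats >= 0) & (beats <= duration_s)]

    cwave, cpeaks = quasi_wave(cardiac_hz, sharp=3)  # peaked systolic shape
    rwave, rpeaks = quasi_wave(resp_hz, sharp=1)
    cardiac = PhysioTrace(samples=100.0 + 20.0 * cwave, rate=rate_hz, kind="cardiac")
    resp = PhysioTrace(samples=50.0 + 25.0 * rwave, rate=rate_hz, kind="respiratory")
    truth["cardiac_peaks_s"] = cpeaks
    truth["resp_peaks_s"] = rpeaks
    return cardiac, resp, truth


def make_task_timing(
    n_runs: int = 1,
    run_len_s: float = 300.0,
    classes: dict | None = None,
    min_gap_s: float = 4.0,
    duration_range: tuple[float, float] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> TimingSet:
    """Randomized event timing with a minimum inter-onset gap.

    ``classes`` maps label → total event count (default mirrors a paired
    task/control design: 40 task + 24 control).  When ``out_dir`` is given
    both one-row-per-run timing files and the equivalent events TSV are
    written there.
    """
    classes = classes or {"task": 40, "control": 24}
    rng = np.random.default_rng(seed)
    total = sum(classes.values())
    per_run = [total // n_runs + (1 if r < total % n_runs else 0) for r in range(n_runs)]
    if any(n * min_gap_s > run_len_s - min_gap_s for n in per_run):
        raise ValueError("events do not fit in runs with the requested minimum gap")
    # label sequence, shuffled, then dealt across runs
    pool = [lab for lab, n in classes.items() for _ in range(n)]
    rng.shuffle(pool)
    runs_by_class = {lab: [[] for _ in range(n_runs)] for lab in classes}
    idx = 0
    for r, n_ev in enumerate(per_run):
        # onsets: sorted draw with min-gap enforced by spacing transform
        slack = run_len_s - min_gap_s * (n_ev + 1)
        raw = np.sort(rng.uniform(0, slack, n_ev))
        onsets = raw + min_gap_s * (1 + np.arange(n_ev))
        for onset in onsets:
            lab = pool[idx]
            idx += 1
            dur = (
                float(rng.uniform(*duration_range)) if duration_range else None
            )
            runs_by_class[lab][r].append(Event(onset=float(onset), duration=dur))
    ts = TimingSet(
        stim_classes=[StimClass(label=lab, runs=runs_by_class[lab]) for lab in classes]
    )
    if out_dir is not None:
        from .io import write_stim_timing

        out_dir = Path(out_dir)
        write_stim_timing(ts, out_dir)
        rows = []
        for sc in ts.stim_classes:
            for r, events in enumerate(sc.runs):
                for ev in events:
                    rows.append(
                        {
                            "onset": ev.onset,
                            "duration": 0.0 if ev.duration is None else ev.duration,
                            "trial_type": sc.label,
                            "run": r + 1,
                        }
                    )
        import pandas as pd

        pd.DataFrame(sorted(rows, key=lambda r: (r["run"], r["onset"]))).to_csv(
            out_dir / "events.tsv", sep="\t", index=False
        )
    return ts


def write_phantom_inputs(
    out_dir: str | Path, seed: int = 0, multi_echo: bool = False, **phantom_kw
) -> dict:
    """Write a ready-to-run input directory: EPI NIFTI(s), anatomical,
    physio traces, timing files and a truth JSON.  Returns the manifest."""
    import json

    from .io import write_nifti

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tes = DEFAULT_ECHO_TIMES_MS if multi_echo else None
    phantom_kw.setdefault("asymmetry", 0.8)  # shared with the anatomical
    data, truth = make_phantom(echo_times=tes, seed=seed, **phantom_kw)
    manifest: dict = {"seed": seed, "echo_times_ms": list(tes) if tes else None}
    if multi_echo:
        paths = []
        for i, echo in enumerate(data.echoes):
            p = out_dir / f"epi_echo{i + 1}.nii.gz"
            write_nifti(echo, p)
            paths.append(str(p))
        manifest["epi"] = paths
        ref = data.echoes[0]
    else:
        p = out_dir / "epi.nii.gz"
        write_nifti(data, p)
        manifest["epi"] = [str(p)]
        ref = data
    # anatomical on the same world extent as the EPI (finer voxels), so the
    # normalized-coordinate shapes coincide in world space across modalities
    dims = tuple(phantom_kw.get("dims", (32, 32, 20)))
    epi_vox = float(phantom_kw.get("voxel_mm", 3.0))
    anat = make_anat_phantom(
        dims=tuple(2 * d - 1 for d in dims), voxel_mm=epi_vox / 2.0,
        seed=seed, asymmetry=phantom_kw.get("asymmetry", 0.8),
    )
    write_nifti(anat, out_dir / "anat.nii.gz")
    manifest["anat"] = str(out_dir / "anat.nii.gz")
    dur = ref.n_volumes * ref.tr + 5.0
    cardiac, resp, ptruth = make_physio_traces(dur, seed=seed)
    write_physio_trace(cardiac, out_dir / "cardiac.txt")
    write_physio_trace(resp, out_dir / "resp.txt")
    manifest["physio"] = {"cardiac": str(out_dir / "cardiac.txt"), "resp": str(out_dir / "resp.txt")}
    truth_json = {
        "seed": seed,
        "tr": truth.tr,
        "n_volumes": truth.n_volumes,
        "task_betas": truth.task_betas,
        "n_brain_voxels": int(truth.brain_mask.sum()),
        "cardiac_peaks_s": [float(x) for x in ptruth["cardiac_peaks_s"]],
        "resp_peaks_s": [float(x) for x in ptruth["resp_peaks_s"]],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=2)
    manifest["truth"] = str(out_dir / "truth.json")
    return manifest
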