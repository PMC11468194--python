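"""Slicewise RETROICOR and volumetric RVT nuisance regressors.

Cardiac and respiratory traces recorded during acquisition are turned into
two kinds of regressors:

* RETROICOR: low-order Fourier expansions ``sin(kφ), cos(kφ)`` of the
  cardiac and respiratory phase, sampled at each slice's acquisition time
  (volume onset + slice offset).  Cardiac phase ramps linearly 0→2π
  between successive heartbeat peaks; respiratory phase uses the
  amplitude-histogram transform signed by the trace derivative.  With
  both traces at the default expansion order 2 this gives 8 slicewise
  regressors.
* RVT (respiration volume per time): ``(peak envelope − trough envelope) /
  breathing period`` interpolated to volume times, demeaned, delivered as
  several time-shifted copies (default shifts 0, 5, 10, 15, 20 s → 5
  columns).

Because these regressors carry slicewise information they belong early in
the processing chain, before any spatial transformation mixes slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .types import Volume4D

__all__ = [
    "PhysioTrace",
    "PhysioRegressors",
    "detect_extrema",
    "cardiac_phase",
    "respiratory_phase",
    "retroicor_regressors",
    "rvt_regressors",
    "read_physio_trace",
    "write_physio_trace",
    "DEFAULT_RVT_SHIFTS",
]

#: RVT delays in seconds; 5 shifted copies by convention.
DEFAULT_RVT_SHIFTS = (0.0, 5.0, 10.0, 15.0, 20.0)

_MIN_INTERVAL_S = {"cardiac": 0.3, "respiratory": 1.5}
_SMOOTH_S = 0.25


@dataclass
class PhysioTrace:
    """A sampled physiological recording aligned to the EPI run."""

    samples: np.ndarray
    rate: float  # Hz
    kind: str  # 'cardiac' | 'respiratory'
    start_offset: float = 0.0  # s relative to first retained EPI volume

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind not in ("cardiac", "respiratory"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in run seconds (0 = first retained EPI volume)."""
        return np.arange(self.samples.size) / self.rate + self.start_offset


@dataclass
class PhysioRegressors:
    """RETROICOR (slicewise) and RVT (volumetric) regressor sets."""

    slicewise: np.ndarray  # (n_volumes, n_regressors, n_slices)
    volumetric: np.ndarray  # (n_volumes, n_rvt)
    slicewise_labels: list[str] = field(default_factory=list)
    volumetric_labels: list[str] = field(default_factory=list)

    @property
    def n_slicewise(self) -> int:
        return self.slicewise.shape[1]

    @property
    def n_volumetric(self) -> int:
        return self.volumetric.shape[1]


def _smooth(trace: PhysioTrace) -> np.ndarray:
    w = max(1, int(round(_SMOOTH_S * trace.rate)))
    kernel = np.ones(w) / w
    return np.convolve(trace.samples, kernel, mode="same")


def detect_extrema(trace: PhysioTrace) -> tuple[np.ndarray, np.ndarray]:
    """Peak and trough sample indices, smoothed and strictly alternating.

    The trace is boxcar-smoothed over 0.25 s; peaks must be separated by at
    least 0.3 s (cardiac) or 1.5 s (respiratory).  Adjacent same-type
    extrema are resolved by keeping the more extreme one, so the returned
    sequence alternates peak/trough strictly.
    """
    if trace.duration < 2.0:
        raise ValueError("trace too short for extrema detection (< 2 s)")
    x = _smooth(trace)
    if np.ptp(x) <= 1e-12 * max(1.0, np.abs(x).max()):
        raise ValueError("constant trace: no extrema detectable")
    dist = max(1, int(round(_MIN_INTERVAL_S[trace.kind] * trace.rate)))
    prom = 0.1 * np.ptp(x)
    peaks, _ = signal.find_peaks(x, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-x, distance=dist, prominence=prom)
    if peaks.size == 0 or troughs.size == 0:
        raise ValueError("no extrema detected in trace")

    events = sorted([(int(i), "p") for i in peaks] + [(int(i), "t") for i in troughs])
    cleaned: list[tuple[int, str]] = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx = cleaned[-1][0]
            better = (x[idx] > x[prev_idx]) if kind == "p" else (x[idx] < x[prev_idx])
            if better:
                cleaned[-1] = (idx, kind)
            continue
        cleaned.append((idx, kind))
    out_p = np.array([i for i, k in cleaned if k == "p"], dtype=int)
    out_t = np.array([i for i, k in cleaned if k == "t"], dtype=int)
    return out_p, out_t


def cardiac_phase(trace: PhysioTrace, query_times: np.ndarray) -> np.ndarray:
    """Phase in [0, 2π): linear ramp between successive peaks (φ=0 at a peak)."""
    peaks, _ = detect_extrema(trace)
    if peaks.size < 2:
        raise ValueError("need at least 2 cardiac peaks for phase estimation")
    pt = trace.times[peaks]
    # extend with one synthetic beat on each side (edge period) for coverage
    pt = np.concatenate([[pt[0] - (pt[1] - pt[0])], pt, [pt[-1] + (pt[-1] - pt[-2])]])
    q = np.asarray(query_times, dtype=float)
    seg = np.clip(np.searchsorted(pt, q, side="right") - 1, 0, pt.size - 2)
    t0, t1 = pt[seg], pt[seg + 1]
    return 2.0 * np.pi * (q - t0) / (t1 - t0)


def respiratory_phase(trace: PhysioTrace, query_times: np.ndarray) -> np.ndarray:
    """Amplitude-histogram respiratory phase, signed by the derivative.

    φ(t) = ±π·P(b ≤ b(t)) where b is the smoothed amplitude above its
    minimum and P its empirical CDF; the sign follows dx/dt (inhalation
    positive).
    """
    x = _smooth(trace)
    b = x - x.min()
    order = np.argsort(b, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, b.size + 1)
    cdf = ranks / b.size
    dx = np.gradient(x)
    phase = np.pi * cdf * np.sign(np.where(dx == 0, 1.0, dx))
    q = np.asarray(query_times, dtype=float)
    return np.interp(q, trace.times, phase)


def _check_coverage(trace: PhysioTrace, vol: Volume4D) -> None:
    run_dur = vol.n_volumes * vol.tr
    if trace.start_offset > 0 or trace.times[-1] < run_dur - vol.tr:
        raise ValueError(
            f"{trace.kind} trace ({trace.times[0]:.1f}..{trace.times[-1]:.1f}s) "
            f"does not cover the run (0..{run_dur:.1f}s)"
        )


def retroicor_regressors(
    cardiac: PhysioTrace | None,
    resp: PhysioTrace | None,
    vol: Volume4D,
    orders: int = 2,
) -> PhysioRegressors:
    """Slicewise RETROICOR regressors sampled at slice acquisition times.

    For each present trace and harmonic k = 1..orders, ``sin(kφ)`` and
    ``cos(kφ)`` are evaluated at ``volume_onset + slice_time`` for every
    slice.  Both traces at orders=2 → 8 slicewise regressors.
    """
    if vol.slice_times.size == 0:
        raise ValueError("RETROICOR requires slice timing metadata on the volume")
    if cardiac is None and resp is None:
        raise ValueError("at least one physiological trace required")
    nz = vol.grid.dims[2]
    nt = vol.n_volumes
    vol_onsets = np.arange(nt) * vol.tr
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for trace, tag in ((cardiac, "card"), (resp, "resp")):
        if trace is None:
            continue
        _check_coverage(trace, vol)
        phase_at = cardiac_phase if trace.kind == "cardiac" else respiratory_phase
        # (nt, nz) acquisition times
        tq = vol_onsets[:, np.newaxis] + vol.slice_times[np.newaxis, :]
        phi = phase_at(trace, tq.ravel()).reshape(nt, nz)
        for k in range(1, orders + 1):
            cols.append(np.sin(k * phi))
            labels.append(f"{tag}_sin{k}")
            cols.append(np.cos(k * phi))
            labels.append(f"{tag}_cos{k}")
    slicewise = np.stack(cols, axis=1)  # (nt, n_reg, nz)
    return PhysioRegressors(
        slicewise=slicewise,
        volumetric=np.empty((nt, 0)),
        slicewise_labels=labels,
    )


def rvt_regressors(
    resp: PhysioTrace,
    vol: Volume4D,
    shifts_s: tuple[float, ...] = DEFAULT_RVT_SHIFTS,
) -> np.ndarray:
    """Respiration-volume-per-time columns: demeaned, time-shifted copies.

    RVT(t) = (peak envelope − trough envelope) / breathing period,
    interpolated to volume onsets.  Each requested shift delays the series
    (edge-held) by that many seconds.  Defaults give 5 columns.
    """
    _check_coverage(resp, vol)
    peaks, troughs = detect_extrema(resp)
    if peaks.size < 2 or troughs.size < 2:
        raise ValueError("too few respiratory extrema for RVT")
    x = _smooth(resp)
    t = resp.times
    vol_times = np.arange(vol.n_volumes) * vol.tr
    env_p = np.interp(t, t[peaks], x[peaks])
    env_t = np.interp(t, t[troughs], x[troughs])
    mid = 0.5 * (t[peaks][:-1] + t[peaks][1:])
    periods = np.diff(t[peaks])
    period = np.interp(t, mid, periods) if mid.size else np.full_like(t, periods.mean())
    rvt = (env_p - env_t) / np.maximum(period, 1e-6)
    cols = []
    for s in shifts_s:
        cols.append(np.interp(np.clip(vol_times - s, t[0], t[-1]), t, rvt))
    mat = np.stack(cols, axis=1)
    return mat - mat.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# trace files: 1-column samples with a small '#'-comment header


def write_physio_trace(trace: PhysioTrace, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# kind = {trace.kind}\n")
        fh.write(f"# rate = {trace.rate:g}\n")
        fh.write(f"# start = {trace.start_offset:g}\n")
        for v in trace.samples:
            fh.write(f"{v:.10g}\n")


def read_physio_trace(path: str | Path) -> PhysioTrace:
    path = Path(path)
    meta = {"kind": None, "rate": None, "start": 0.0}
    samples = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if "=" in stripped:
                    key, _, val = stripped.lstrip("# ").partition("=")
                    key = key.strip()
                    if key in meta:
                        meta[key] = val.strip()
                continue
            samples.append(float(stripped.split()[0]))
    if meta["kind"] is None or meta["rate"] is None:
        raise ValueError(f"{path}: trace header must declare kind and rate")
    return PhysioTrace(
        samples=np.asarray(samples),
        rate=float(meta["rate"]),
        kind=str(meta["kind"]),
        start_offset=float(meta["start"]),
    )
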