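"""Domain types shared across the toolkit.

Conventions (asserted in tests):

* world space is RAS, in mm; voxel indices are 0-based; time index is 0-based
* motion parameter column order is (roll, pitch, yaw, dS, dL, dP), rotations
  in degrees and displacements in mm, matching the conventional 6-column
  motion file layout
* a ``Volume4D`` always carries its run structure: ``run_lengths`` partitions
  the time axis so per-run stages (scaling, baselines, motion demeaning)
  know where run boundaries fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid",
    "Volume4D",
    "EchoSet",
    "MotionParams",
    "CensorSeries",
    "TimingSet",
    "StimClass",
    "Event",
    "ROILabelVolume",
    "UNITS_TAGS",
]

#: Allowed values of :attr:`Volume4D.units_tag`.
UNITS_TAGS = ("raw", "percent", "correlation", "tsnr", "statistic")


@dataclass
class Grid:
    """Spatial geometry of a volume: dimensions, spacing and voxel→world map."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel-index -> world-mm (RAS)

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"grid dims must be three positive integers, got {self.dims}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def orientation_code(self) -> str:
        """Three-letter axis code, e.g. ``RAS``."""
        import nibabel as nib

        return "".join(nib.orientations.aff2axcodes(self.affine))

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        out = (inv[:3, :3] @ xyz.T).T + inv[:3, 3]
        return out.squeeze()

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]
        return out.squeeze()

    def center_world(self) -> np.ndarray:
        """World coordinates of the grid center (rotation pivot)."""
        c_ijk = (np.asarray(self.dims, dtype=float) - 1.0) / 2.0
        return np.asarray(self.voxel_to_world(c_ijk), dtype=float)

    @classmethod
    def isotropic(cls, dims: tuple[int, int, int], voxel_mm: float | tuple = 3.0) -> "Grid":
        """A simple RAS grid centered on the origin."""
        vs = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
        aff = np.diag([vs[0], vs[1], vs[2], 1.0])
        aff[:3, 3] = -vs * (np.asarray(dims) - 1) / 2.0
        return cls(dims=tuple(dims), affine=aff)

    def __eq__(self, other) -> bool:  # geometric, not identity, equality
        return (
            isinstance(other, Grid)
            and self.dims == other.dims
            and np.allclose(self.affine, other.affine, atol=1e-5)
        )


@dataclass
class Volume4D:
    """A 3D+time image: the object every processing stage transforms.

    ``data`` is indexed ``(x, y, z, t)``; 3D images are stored with a
    singleton time axis.  ``slice_times`` (seconds, one per z-slice, each in
    ``[0, tr)``) is empty when slice timing is unknown or not applicable.
    """

    grid: Grid
    data: np.ndarray
    tr: float = 1.0
    slice_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    units_tag: str = "raw"
    run_lengths: list[int] = field(default_factory=list)
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"data must be 3D or 4D, got shape {self.data.shape}")
        if self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid dims {self.grid.dims}"
            )
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        self.slice_times = np.asarray(self.slice_times, dtype=float)
        if self.slice_times.size:
            if self.slice_times.size != self.grid.dims[2]:
                raise ValueError("slice_times length must equal nz")
            if np.any(self.slice_times < 0) or np.any(self.slice_times >= self.tr):
                raise ValueError("slice_times must lie in [0, TR)")
        if self.units_tag not in UNITS_TAGS:
            raise ValueError(f"unknown units_tag {self.units_tag!r}")
        if not self.run_lengths:
            self.run_lengths = [self.n_volumes]
        if sum(self.run_lengths) != self.n_volumes:
            raise ValueError("run_lengths must sum to n_volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def run_slices(self) -> list[slice]:
        """Per-run slices into the time axis."""
        out, start = [], 0
        for n in self.run_lengths:
            out.append(slice(start, start + n))
            start += n
        return out

    def with_data(self, data: np.ndarray, **overrides) -> "Volume4D":
        """Copy carrying grid/TR/slice-time metadata, with new voxel data."""
        kw = dict(
            grid=self.grid,
            data=data,
            tr=self.tr,
            slice_times=self.slice_times.copy(),
            units_tag=self.units_tag,
            run_lengths=list(self.run_lengths),
            history=list(self.history),
        )
        data_arr = np.asarray(data)
        if data_arr.ndim == 3 or data_arr.shape[3] != self.n_volumes:
            kw["run_lengths"] = []
        kw.update(overrides)
        return Volume4D(**kw)

    def note(self, entry: str) -> "Volume4D":
        self.history.append(entry)
        return self


@dataclass
class EchoSet:
    """Multi-echo acquisition: one Volume4D per echo, on an identical grid."""

    echoes: list[Volume4D]
    echo_times: list[float]  # ms, strictly increasing

    def __post_init__(self) -> None:
        if len(self.echoes) < 1:
            raise ValueError("EchoSet requires at least one echo")
        if len(self.echo_times) != len(self.echoes):
            raise ValueError("one echo time per echo required")
        self.echo_times = [float(t) for t in self.echo_times]
        if any(t <= 0 for t in self.echo_times):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(self.echo_times, self.echo_times[1:])):
            raise ValueError("echo times must be strictly increasing")
        first = self.echoes[0]
        for e in self.echoes[1:]:
            if e.grid.dims != first.grid.dims or e.n_volumes != first.n_volumes:
                raise ValueError("all echoes must share dims and n_volumes")
            if abs(e.tr - first.tr) > 1e-9:
                raise ValueError("all echoes must share TR")

    @property
    def n_echoes(self) -> int:
        return len(self.echoes)


@dataclass
class MotionParams:
    """Per-volume rigid-body estimates: (roll, pitch, yaw) deg, (dS, dL, dP) mm."""

    params: np.ndarray  # (n_volumes, 6)
    reference_index: int = 0

    COLUMNS = ("roll", "pitch", "yaw", "dS", "dL", "dP")

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError("motion parameters must have 6 columns")
        if not (0 <= self.reference_index < len(self.params)):
            raise ValueError("reference_index out of range")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class CensorSeries:
    """Keep/censor state per volume plus the metrics that produced it."""

    keep: np.ndarray  # bool, per volume
    enorm: np.ndarray
    outlier_frac: np.ndarray
    thresholds: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.enorm = np.asarray(self.enorm, dtype=float)
        self.outlier_frac = np.asarray(self.outlier_frac, dtype=float)
        n = self.keep.size
        if self.enorm.size != n or self.outlier_frac.size != n:
            raise ValueError("censor component lengths differ")
        if np.any(self.outlier_frac < 0) or np.any(self.outlier_frac > 1):
            raise ValueError("outlier fractions must lie in [0, 1]")

    @property
    def n_volumes(self) -> int:
        return self.keep.size

    @property
    def n_censored(self) -> int:
        return int(np.sum(~self.keep))

    @property
    def censor_fraction(self) -> float:
        return self.n_censored / self.n_volumes if self.n_volumes else 0.0

    @classmethod
    def all_kept(cls, n: int) -> "CensorSeries":
        return cls(np.ones(n, bool), np.zeros(n), np.zeros(n))


@dataclass
class Event:
    """One stimulus event: onset (s from run start), optional duration (s),
    optional amplitude modulators."""

    onset: float
    duration: float | None = None
    modulators: list[float] = field(default_factory=list)


@dataclass
class StimClass:
    label: str
    runs: list[list[Event]]  # one event list per run (possibly empty)

    @property
    def n_events(self) -> int:
        return sum(len(r) for r in self.runs)

    @property
    def all_events(self) -> list[Event]:
        return [e for r in self.runs for e in r]


@dataclass
class TimingSet:
    """Stimulus timing for all classes, organized per run."""

    stim_classes: list[StimClass]

    def __post_init__(self) -> None:
        for sc in self.stim_classes:
            for run in sc.runs:
                onsets = [e.onset for e in run]
                if any(o < 0 for o in onsets):
                    raise ValueError(f"negative onset in class {sc.label!r}")
                if any(b < a for a, b in zip(onsets, onsets[1:])):
                    raise ValueError(f"onsets must be non-decreasing in class {sc.label!r}")
                if any(e.duration is not None and e.duration < 0 for e in run):
                    raise ValueError(f"negative duration in class {sc.label!r}")

    @property
    def labels(self) -> list[str]:
        return [sc.label for sc in self.stim_classes]

    def get(self, label: str) -> StimClass:
        for sc in self.stim_classes:
            if sc.label == label:
                return sc
        raise KeyError(f"unknown stimulus class {label!r}")


@dataclass
class ROILabelVolume:
    """Integer-labelled parcellation on a grid, with a label→name table."""

    grid: Grid
    labels: np.ndarray  # non-negative ints, shape = dims
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.dims:
            raise ValueError("label volume shape must match grid dims")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            # auto-name rather than fail: keeps programmatic atlases light
            for v in sorted(missing):
                self.label_table[v] = f"roi_{v}"

    def mask(self, label: int | str | None = None) -> np.ndarray:
        """Boolean mask of one ROI (by id or name) or of all nonzero labels."""
        if label is None:
            return self.labels > 0
        if isinstance(label, str):
            inv = {v: k for k, v in self.label_table.items()}
            if label not in inv:
                raise KeyError(f"unknown ROI name {label!r}")
            label = inv[label]
        if int(label) not in self.label_table:
            raise KeyError(f"unknown ROI label {label}")
        return self.labels == int(label)
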