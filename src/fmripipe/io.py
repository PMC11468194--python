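"""Readers and writers for every external format the toolkit touches.

Supported formats: NIFTI-1 images (via nibabel), whitespace-delimited
column files with ``#`` comments (motion, censor and regressor series),
one-row-per-run stimulus timing files with optional married
duration/amplitude tokens, BIDS-style events tables (TSV), and flat JSON
dictionaries for the review-variables ("uvars") file.

Every writer stamps an accumulating provenance note (command + version +
timestamp) so each file records how it was produced.
"""

from __future__ import annotations

import datetime
import json
import re
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._version import __version__
from .types import Event, Grid, StimClass, TimingSet, Volume4D

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_column_file",
    "write_column_file",
    "read_stim_timing",
    "write_stim_timing",
    "read_events_tsv",
    "write_uvars",
    "read_uvars",
    "provenance_note",
]

_META_EXT_CODE = 6  # NIFTI "comment" extension; carries our JSON sidecar


def provenance_note(action: str, timestamp: str | None = None) -> str:
    """One history line: what was done, by which version, when."""
    if timestamp is None:
        timestamp = datetime.datetime.now().isoformat(timespec="seconds")
    return f"[fmripipe {__version__} @ {timestamp}] {action}"


def read_nifti(path: str | Path) -> Volume4D:
    """Load a 3D or 4D NIFTI-1 image as a :class:`Volume4D`.

    3D inputs become ``n_volumes = 1``.  TR is read from the header time
    step; a zero/absent TR on 4D data is replaced by 1.0 s with a warning
    so the pipeline stays runnable while surfacing the problem.  Data are
    returned in native scaling (scl_slope/inter applied by nibabel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIFTI file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # bad magic / not a NIFTI container
        raise ValueError(f"could not read {path} as NIFTI: {exc}") from exc
    if img.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D image, got {img.ndim}D")
    data = np.asanyarray(img.dataobj, dtype=float)
    hdr = img.header
    grid = Grid(dims=tuple(int(d) for d in data.shape[:3]), affine=np.asarray(img.affine))

    slice_times = np.empty(0)
    tr = 1.0
    if data.ndim == 4:
        zooms = hdr.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            warnings.warn(
                f"{path}: 4D image with zero/absent TR in header; using TR=1.0 s",
                stacklevel=2,
            )
            tr = 1.0

    units_tag = "raw"
    run_lengths: list[int] = []
    meta = _read_meta_extension(img)
    if meta:
        tr = float(meta.get("tr", tr))
        units_tag = meta.get("units_tag", units_tag)
        slice_times = np.asarray(meta.get("slice_times", []), dtype=float)
        run_lengths = list(meta.get("run_lengths", []))
    else:
        # fall back to NIFTI slice-timing fields when encoded
        try:
            st = hdr.get_slice_times()
            slice_times = np.asarray(st, dtype=float)
        except Exception:
            slice_times = np.empty(0)

    hist = list(meta.get("history", [])) if meta else []
    vol = Volume4D(
        grid=grid,
        data=data,
        tr=tr,
        slice_times=slice_times,
        units_tag=units_tag,
        run_lengths=run_lengths,
        history=hist,
    )
    return vol


def write_nifti(vol: Volume4D, path: str | Path, timestamp: str | None = None) -> None:
    """Write a :class:`Volume4D` as NIFTI-1, preserving affine, TR and units.

    ``units_tag`` goes in the header description field; slice times, run
    structure and accumulated history travel in a JSON header extension so
    a round-trip through :func:`read_nifti` is lossless while the file
    stays readable by standard tools.
    """
    path = Path(path)
    data = vol.data
    if data.shape[3] == 1:
        data = data[..., 0]  # single volume written 3D-compatible
    img = nib.Nifti1Image(data.astype(np.float32), vol.grid.affine)
    hdr = img.header
    if data.ndim == 4:
        hdr.set_zooms(tuple(vol.grid.voxel_size) + (vol.tr,))
        hdr.set_xyzt_units(xyz="mm", t="sec")
    else:
        hdr.set_xyzt_units(xyz="mm")
    hdr["descrip"] = f"units={vol.units_tag}".encode()[:79]
    meta = {
        "tr": vol.tr,
        "units_tag": vol.units_tag,
        "slice_times": [float(t) for t in vol.slice_times],
        "run_lengths": list(vol.run_lengths),
        "history": list(vol.history) + [provenance_note(f"write_nifti {path.name}", timestamp)],
    }
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension(_META_EXT_CODE, json.dumps(meta).encode())
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    img.to_filename(str(path))


def _read_meta_extension(img) -> dict:
    for ext in getattr(img.header, "extensions", []):
        if ext.get_code() == _META_EXT_CODE:
            raw = ext.get_content()
            if isinstance(raw, bytes):
                raw = raw.decode(errors="replace")
            try:
                parsed = json.loads(raw)
            except (json.JSONDecodeError, TypeError):
                continue
            if isinstance(parsed, dict) and "tr" in parsed:
                return parsed
    return {}


# ---------------------------------------------------------------------------
# plain-text column files ("1D" files: motion, censor, regressors)


def read_column_file(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited numeric text file (rows = time points).

    ``#``-prefixed comment lines are ignored.  Always returns a 2D array.
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = stripped.split()
            try:
                vals = [float(t) for t in toks]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token in {stripped!r}") from exc
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(vals)} values, expected {ncol})"
                )
            rows.append(vals)
    return np.asarray(rows, dtype=float).reshape(len(rows), ncol or 0)


def write_column_file(
    data: np.ndarray,
    path: str | Path,
    labels: list[str] | None = None,
    header_lines: list[str] | None = None,
    timestamp: str | None = None,
) -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 1 and data.shape[1] > 1 and labels is None:
        data = data.T
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {provenance_note(f'write_column_file {path.name}', timestamp)}\n")
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        if labels:
            fh.write("# columns: " + " ".join(labels) + "\n")
        for row in data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# stimulus timing

_TOKEN_RE = re.compile(
    r"""^(?P<onset>-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)
        (?P<amps>(?:\*-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)*)
        (?::(?P<dur>\d+(?:\.\d+)?(?:[eE][-+]?\d+)?))?$""",
    re.VERBOSE,
)


def _parse_timing_token(tok: str, where: str) -> Event:
    m = _TOKEN_RE.match(tok)
    if not m:
        raise ValueError(f"{where}: malformed timing token {tok!r}")
    onset = float(m.group("onset"))
    if onset < 0:
        raise ValueError(f"{where}: negative onset in token {tok!r}")
    dur = float(m.group("dur")) if m.group("dur") is not None else None
    amps = [float(a) for a in m.group("amps").split("*") if a] if m.group("amps") else []
    return Event(onset=onset, duration=dur, modulators=amps)


def read_stim_timing(paths: list[str | Path], labels: list[str]) -> TimingSet:
    """Read one-row-per-run stimulus timing files, one file per class.

    Token grammar: ``onset``, ``onset:dur``, ``onset*amp``,
    ``onset*amp1*amp2:dur``.  A row consisting of ``*`` alone (or ``-1``)
    records an empty run while preserving the run count.
    """
    if len(paths) != len(labels):
        raise ValueError("one label per timing file required")
    classes = []
    for path, label in zip(paths, labels):
        path = Path(path)
        runs: list[list[Event]] = []
        with open(path) as fh:
            for rowno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                toks = stripped.split()
                if toks in (["*"], ["-1"]):
                    runs.append([])
                    continue
                events = [
                    _parse_timing_token(t, f"{path} row {rowno}")
                    for t in toks
                    if t != "*"  # trailing pad markers tolerated
                ]
                runs.append(events)
        classes.append(StimClass(label=label, runs=runs))
    return TimingSet(stim_classes=classes)


def write_stim_timing(ts: TimingSet, directory: str | Path) -> list[Path]:
    """Write one timing file per class; inverse of :func:`read_stim_timing`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for sc in ts.stim_classes:
        path = directory / f"stim_times.{sc.label}.txt"
        with open(path, "w") as fh:
            for run in sc.runs:
                if not run:
                    fh.write("*\n")
                    continue
                toks = []
                for ev in run:
                    tok = f"{ev.onset:.10g}"
                    for a in ev.modulators:
                        tok += f"*{a:.10g}"
                    if ev.duration is not None:
                        tok += f":{ev.duration:.10g}"
                    toks.append(tok)
                fh.write(" ".join(toks) + "\n")
        out.append(path)
    return out


def read_events_tsv(
    path: str | Path, class_column: str = "trial_type", run_column: str | None = None
) -> TimingSet:
    """Read a BIDS-style events table (onset/duration columns required).

    One stimulus class is created per distinct value of ``class_column``;
    when ``run_column`` is given, events are split into runs by its value,
    otherwise a single run is assumed.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", class_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if run_column is not None and run_column not in df.columns:
        raise ValueError(f"{path}: missing run column {run_column!r}")
    run_values = sorted(df[run_column].unique()) if run_column else [None]
    mod_cols = [
        c
        for c in df.columns
        if c not in ("onset", "duration", class_column, run_column)
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    classes = []
    for label in sorted(df[class_column].astype(str).unique()):
        runs = []
        sub_c = df[df[class_column].astype(str) == label]
        for rv in run_values:
            sub = sub_c if rv is None else sub_c[sub_c[run_column] == rv]
            sub = sub.sort_values("onset")
            events = [
                Event(
                    onset=float(r.onset),
                    duration=float(r.duration),
                    modulators=[float(getattr(r, c)) for c in mod_cols if pd.notna(getattr(r, c))],
                )
                for r in sub.itertuples()
            ]
            runs.append(events)
        classes.append(StimClass(label=label, runs=runs))
    return TimingSet(stim_classes=classes)


# ---------------------------------------------------------------------------
# uvars (review-variables dictionary)


def write_uvars(record: dict, path: str | Path) -> None:
    """Write the flat review-variables dictionary as sorted-key JSON."""
    for key, value in record.items():
        if isinstance(value, (dict, list, tuple, set)):
            raise TypeError(f"uvars value for {key!r} must be scalar/string, got {type(value)}")
        if value is not None and not isinstance(value, (int, float, str, bool, np.number)):
            raise TypeError(f"uvars value for {key!r} is not JSON-serializable")
    clean = {
        k: (v.item() if isinstance(v, np.number) else v) for k, v in sorted(record.items())
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_uvars(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
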