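"""Pipeline compiler: block+option specifications → validated execution
plans → commented runnable scripts → executed results directories.

A processing specification is hierarchical: the user orders the major
processing *blocks* (tshift, volreg, blur, ...) and attaches options whose
name prefix identifies the owning block (``blur_size`` → blur).  Compiling
a spec resolves every parameter (user value or default, with the origin
recorded), inserts the automatic stages that always run (setup, tcat,
outcount, QC_review) and any implicit stages the inputs demand (multi-echo
input forces a combine stage), and rejects unknown blocks, unknown options
and options addressed to absent blocks.

The compiled plan renders to a *proc script*: a commented, runnable Python
script that calls this library stage by stage, embeds the generating
command verbatim and prints every resolved parameter value — the analysis
is fully specified by the script alone, and rendering the same spec twice
(fixed-timestamp mode) is byte-identical.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._version import __version__

__all__ = [
    "PipelineSpec",
    "Stage",
    "ExecutionPlan",
    "ProcScript",
    "assemble_plan",
    "render_script",
    "compare_specs",
    "run_plan",
    "read_spec_file",
    "PACKAGED_EXAMPLES",
]

AUTOMATIC_BLOCKS = ("setup", "tcat", "outcount", "QC_review")
DEFAULT_BLOCKS = ("tshift", "volreg", "blur", "mask", "scale", "regress")
OPTIONAL_BLOCKS = ("align", "combine", "despike", "empty", "ricor", "tlrc")
KNOWN_BLOCKS = set(AUTOMATIC_BLOCKS) | set(DEFAULT_BLOCKS) | set(OPTIONAL_BLOCKS)

#: canonical execution order (despike before ricor; both before tshift)
_CANONICAL_ORDER = [
    "setup", "tcat", "outcount", "despike", "ricor", "tshift", "align",
    "tlrc", "volreg", "combine", "blur", "mask", "scale", "regress",
    "QC_review",
]

#: option name -> (owning block, default value)
OPTION_REGISTRY: dict[str, tuple[str, object]] = {
    "tcat_remove_first_trs": ("tcat", 0),
    "tshift_align_to": ("tshift", 0.0),
    "tshift_interp": ("tshift", "cubic"),
    "despike_clip": ("despike", 3.0),
    "ricor_orders": ("ricor", 2),
    "ricor_rvt_shifts": ("ricor", [0.0, 5.0, 10.0, 15.0, 20.0]),
    "align_affine_mtx": ("align", None),
    "tlrc_affine_mtx": ("tlrc", None),
    "volreg_align_to": ("volreg", "MIN_OUTLIER"),
    "volreg_warp_dxyz": ("volreg", None),
    "volreg_final_interp": ("volreg", "trilinear"),
    "combine_method": ("combine", "OC"),
    "blur_size": ("blur", 4.0),
    "mask_epi_anat": ("mask", "no"),
    "scale_max": ("scale", 200.0),
    "regress_polort": ("regress", "auto"),
    "regress_censor_motion": ("regress", 0.3),
    "regress_censor_outliers": ("regress", 0.05),
    "regress_apply_mot_types": ("regress", ["demean", "deriv"]),
    "regress_motion_per_run": ("regress", "no"),
    "regress_bandpass": ("regress", None),
    "regress_basis": ("regress", "GAM"),
    "regress_basis_dur": ("regress", 1.0),
    "regress_stim_types": ("regress", "time"),
    "regress_reml": ("regress", "no"),
    "regress_glt": ("regress", []),
    "outlier_presteady": ("outcount", "check"),
    "qc_check_flip": ("QC_review", "yes"),
    "qc_stat_threshold": ("QC_review", 3.0),
}

_UNSUPPORTED_OPTIONS = {
    "blip_forward_dset": "blip (B0 distortion) correction not supported",
    "blip_reverse_dset": "blip (B0 distortion) correction not supported",
}


@dataclass
class PipelineSpec:
    """The user-facing processing specification."""

    subject_id: str = "subj"
    blocks: list[str] = field(default_factory=lambda: list(DEFAULT_BLOCKS))
    options: dict = field(default_factory=dict)
    epi_paths: list[str] = field(default_factory=list)  # one per run (single echo)
    echo_paths: list[str] = field(default_factory=list)  # one per echo (one run)
    echo_times: list[float] = field(default_factory=list)  # ms
    anat_path: str | None = None
    cardiac_path: str | None = None
    resp_path: str | None = None
    roi_path: str | None = None
    stim_files: list[str] = field(default_factory=list)
    stim_labels: list[str] = field(default_factory=list)

    @property
    def is_multi_echo(self) -> bool:
        return len(self.echo_paths) >= 2


@dataclass
class Stage:
    name: str
    params: dict  # option -> {"value": ..., "origin": "user"|"default"}
    implicit: bool = False

    def value(self, opt: str):
        return self.params[opt]["value"]


@dataclass
class ExecutionPlan:
    spec: PipelineSpec
    stages: list[Stage]

    def stage(self, name: str) -> Stage | None:
        for s in self.stages:
            if s.name == name:
                return s
        return None

    @property
    def block_names(self) -> list[str]:
        return [s.name for s in self.stages]


@dataclass
class ProcScript:
    text: str
    generating_command: str
    version: str = __version__


def assemble_plan(spec: PipelineSpec) -> ExecutionPlan:
    """Compile a spec into a validated, fully-resolved execution plan.

    Automatic stages are always present; a combine stage is inserted for
    multi-echo input even when not requested.  Every user option must be
    consumed by exactly one stage; surf/blip requests fail loudly.
    """
    if not spec.blocks:
        raise ValueError("block list is empty")
    for blk in spec.blocks:
        if blk.startswith("surf"):
            raise ValueError("surface-based processing ('surf' block) is not supported")
        if blk not in KNOWN_BLOCKS:
            raise ValueError(f"unknown processing block {blk!r}")
        if blk in AUTOMATIC_BLOCKS:
            raise ValueError(f"block {blk!r} is automatic and may not be listed")
    for opt in spec.options:
        if opt in _UNSUPPORTED_OPTIONS:
            raise ValueError(_UNSUPPORTED_OPTIONS[opt])

    wanted = set(spec.blocks) | set(AUTOMATIC_BLOCKS)
    implicit: set[str] = set()
    if spec.is_multi_echo and "combine" not in wanted:
        wanted.add("combine")
        implicit.add("combine")

    # resolve options: each belongs to exactly one present stage
    by_block: dict[str, dict] = {b: {} for b in wanted}
    for opt, val in spec.options.items():
        if opt not in OPTION_REGISTRY:
            raise ValueError(f"unknown option {opt!r}")
        block, _ = OPTION_REGISTRY[opt]
        if block not in wanted:
            raise ValueError(
                f"option {opt!r} targets block {block!r}, which is not in the pipeline"
            )
        by_block[block][opt] = {"value": val, "origin": "user"}
    for opt, (block, default) in OPTION_REGISTRY.items():
        if block in wanted and opt not in by_block[block]:
            by_block[block][opt] = {"value": default, "origin": "default"}

    stages = [
        Stage(name=b, params=by_block[b], implicit=b in implicit)
        for b in _CANONICAL_ORDER
        if b in wanted
    ]
    return ExecutionPlan(spec=spec, stages=stages)


def render_script(
    plan: ExecutionPlan,
    generating_command: str,
    timestamp: str | None = None,
) -> ProcScript:
    """Render the commented, runnable proc script for a compiled plan.

    The script re-enters this library stage by stage; the generating
    command appears verbatim in the header and every resolved parameter —
    defaults included — is printed next to its stage, so the actual values
    used are always directly visible.  ``timestamp=None`` renders in fixed
    mode so identical specs render to identical bytes.
    """
    ts = timestamp if timestamp is not None else "(fixed-timestamp render)"
    spec = plan.spec
    lines = [
        "#!/usr/bin/env python",
        '"""Single-subject processing script (auto-generated).',
        "",
        "Runnable provenance record: executing this script reproduces the",
        "full analysis; every stage and resolved parameter is listed below.",
        '"""',
        f"# toolkit version : {__version__}",
        f"# rendered        : {ts}",
        "# generating command (verbatim):",
    ]
    for cmd_line in generating_command.splitlines() or [""]:
        lines.append(f"#   {cmd_line}")
    lines += [
        "",
        "import sys",
        "",
        "from fmripipe.pipeline import PipelineSpec, assemble_plan, run_plan",
        "",
        "spec = PipelineSpec(",
        f"    subject_id={spec.subject_id!r},",
        f"    blocks={spec.blocks!r},",
        f"    options={spec.options!r},",
        f"    epi_paths={spec.epi_paths!r},",
        f"    echo_paths={spec.echo_paths!r},",
        f"    echo_times={spec.echo_times!r},",
        f"    anat_path={spec.anat_path!r},",
        f"    cardiac_path={spec.cardiac_path!r},",
        f"    resp_path={spec.resp_path!r},",
        f"    roi_path={spec.roi_path!r},",
        f"    stim_files={spec.stim_files!r},",
        f"    stim_labels={spec.stim_labels!r},",
        ")",
        "",
        "# processing stages, in execution order:",
    ]
    for stage in plan.stages:
        tag = " (implicit)" if stage.implicit else ""
        lines.append("")
        lines.append("# " + "=" * 66)
        lines.append(f"# ===== block: {stage.name}{tag}")
        if stage.params:
            for opt in sorted(stage.params):
                p = stage.params[opt]
                lines.append(f"#   {opt} = {p['value']!r}   [{p['origin']}]")
        else:
            lines.append("#   (no parameters)")
    lines += [
        "",
        "plan = assemble_plan(spec)",
        "out_dir = sys.argv[1] if len(sys.argv) > 1 else "
        f"{spec.subject_id + '.results'!r}",
        "run_plan(plan, out_dir)",
        "",
    ]
    return ProcScript(text="\n".join(lines), generating_command=generating_command)


def compare_specs(a: PipelineSpec, b: PipelineSpec) -> dict:
    """Diff two specifications after default resolution.

    Returns three sections: options set only in a, only in b, and shared
    options whose resolved values differ.  An empty report means the two
    specs compile to equivalent plans.
    """
    plan_a, plan_b = assemble_plan(a), assemble_plan(b)

    def resolved(plan: ExecutionPlan) -> dict:
        out = {}
        for st in plan.stages:
            for opt, p in st.params.items():
                out[opt] = p["value"]
        for fld in (
            "blocks", "epi_paths", "echo_paths", "echo_times", "anat_path",
            "cardiac_path", "resp_path", "roi_path", "stim_files", "stim_labels",
        ):
            out[f"<{fld}>"] = getattr(plan.spec, fld)
        return out

    ra, rb = resolved(plan_a), resolved(plan_b)
    only_a = {k: v for k, v in ra.items() if k not in rb}
    only_b = {k: v for k, v in rb.items() if k not in ra}
    different = {
        k: (ra[k], rb[k]) for k in sorted(set(ra) & set(rb)) if ra[k] != rb[k]
    }
    return {"only_in_a": only_a, "only_in_b": only_b, "different": different}


# ---------------------------------------------------------------------------
# spec files


def read_spec_file(path: str | Path) -> PipelineSpec:
    """Parse a flat key/value spec file (repeated keys append to lists)."""
    path = Path(path)
    multi: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            key, *vals = stripped.split()
            multi.setdefault(key, []).extend(vals)

    def pop_one(key, default=None):
        vals = multi.pop(key, None)
        return vals[0] if vals else default

    def to_num(v):
        try:
            f = float(v)
            return int(f) if f == int(f) and "." not in v and "e" not in v.lower() else f
        except ValueError:
            return v

    spec = PipelineSpec(
        subject_id=pop_one("subj_id", "subj"),
        blocks=multi.pop("blocks", list(DEFAULT_BLOCKS)),
        epi_paths=multi.pop("dsets", []),
        echo_paths=multi.pop("dsets_me_run", []),
        echo_times=[float(v) for v in multi.pop("echo_times", [])],
        anat_path=pop_one("copy_anat"),
        cardiac_path=pop_one("ricor_cardiac"),
        resp_path=pop_one("ricor_resp"),
        roi_path=pop_one("roi_import"),
        stim_files=multi.pop("regress_stim_times", []),
        stim_labels=multi.pop("regress_stim_labels", []),
    )
    options = {}
    for key, vals in multi.items():
        parsed = [to_num(v) for v in vals]
        default = OPTION_REGISTRY.get(key, (None, None))[1]
        options[key] = parsed if isinstance(default, list) or len(parsed) > 1 else parsed[0]
    spec.options = options
    return spec


PACKAGED_EXAMPLES: dict[str, str] = {
    "task_basic": """\
# task-based single-echo processing with duration modulation
subj_id sub01
blocks tshift volreg blur mask scale regress
dsets epi.nii.gz
copy_anat anat.nii.gz
tcat_remove_first_trs 4
blur_size 6
regress_stim_times stim_times.task.txt stim_times.control.txt
regress_stim_labels task control
regress_basis dmUBLOCK
regress_censor_motion 0.3
regress_censor_outliers 0.05
""",
    "rest_ricor": """\
# resting state with physiological regressors and motion derivatives
subj_id sub02
blocks despike ricor tshift volreg blur mask scale regress
dsets epi.nii.gz
copy_anat anat.nii.gz
ricor_cardiac cardiac.txt
ricor_resp resp.txt
regress_censor_motion 0.2
regress_censor_outliers 0.05
regress_apply_mot_types demean deriv
""",
    "rest_me": """\
# multi-echo resting state with optimal combination
subj_id sub03
blocks tshift volreg combine blur mask scale regress
dsets_me_run epi_echo1.nii.gz epi_echo2.nii.gz epi_echo3.nii.gz
echo_times 12.5 27.6 42.7
combine_method OC
regress_censor_motion 0.2
""",
}


# ---------------------------------------------------------------------------
# execution


def run_plan(
    plan: ExecutionPlan, out_dir: str | Path, overwrite: bool = False
) -> dict:
    """Execute a compiled plan, producing a ``<subject>.results`` directory.

    The directory receives copies of the inputs, one ``pb<k>`` dataset per
    data-transforming stage, motion/censor/regressor column files, stats
    and errts outputs, the uvars JSON, the QC directory and a log file.
    A stage failure aborts with the stage name; prior outputs are kept.
    """
    from . import io as fio
    from . import physio as fphysio
    from . import preprocess as pre
    from . import qc as fqc
    from . import regress as reg
    from .types import CensorSeries, EchoSet, Volume4D

    spec = plan.spec
    out_dir = Path(out_dir)
    if out_dir.name != f"{spec.subject_id}.results":
        out_dir = out_dir / f"{spec.subject_id}.results"
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"results directory {out_dir} exists and is not empty (use overwrite)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    qc_dir = out_dir / f"QC_{spec.subject_id}"
    log_lines: list[str] = []
    manifest: dict = {"subject_id": spec.subject_id, "version": __version__, "stages": {}}

    def log(msg: str) -> None:
        log_lines.append(msg)

    # mutable pipeline state
    state: dict = {
        "echoes": None,  # list[Volume4D] (single-echo: length 1)
        "mask": None,
        "motion": None,
        "censor": None,
        "outlier_frac": None,
        "presteady": 0,
        "ref_index": 0,
        "epi2anat": None,
        "anat2final": None,
        "anat": None,
        "glm": None,
        "ledger": None,
        "warnings": [],
        "physio_df": 0,
        "pb_counter": 0,
    }

    def write_pb(block: str, vols: list[Volume4D]) -> list[str]:
        k = state["pb_counter"]
        state["pb_counter"] += 1
        paths = []
        for i, v in enumerate(vols):
            suffix = f".e{i + 1}" if len(vols) > 1 else ""
            p = out_dir / f"pb{k:02d}.{spec.subject_id}{suffix}.{block}.nii.gz"
            fio.write_nifti(v, p)
            paths.append(str(p.relative_to(out_dir)))
        return paths

    def auto_mask():
        if state["mask"] is None:
            state["mask"] = pre.compute_epi_automask(state["echoes"][0])
        return state["mask"]

    stage_runners = {}

    def runner(name):
        def deco(fn):
            stage_runners[name] = fn
            return fn
        return deco

    @runner("setup")
    def _setup(stage: Stage):
        copied = []
        for p in list(spec.epi_paths) + list(spec.echo_paths) + list(spec.stim_files):
            if p and Path(p).exists():
                shutil.copy(p, out_dir / Path(p).name)
                copied.append(Path(p).name)
        for p in (spec.anat_path, spec.cardiac_path, spec.resp_path, spec.roi_path):
            if p and Path(p).exists():
                shutil.copy(p, out_dir / Path(p).name)
                copied.append(Path(p).name)
        if spec.anat_path:
            state["anat"] = fio.read_nifti(spec.anat_path)
        manifest["stages"]["setup"] = {"copied_inputs": copied}

    @runner("tcat")
    def _tcat(stage: Stage):
        n_rm = int(stage.value("tcat_remove_first_trs"))
        if spec.is_multi_echo:
            raw = [fio.read_nifti(p) for p in spec.echo_paths]
        elif spec.epi_paths:
            runs = [fio.read_nifti(p) for p in spec.epi_paths]
            first = runs[0]
            data = np.concatenate([r.data for r in runs], axis=3)
            raw = [
                Volume4D(
                    grid=first.grid, data=data, tr=first.tr,
                    slice_times=first.slice_times,
                    run_lengths=[r.n_volumes for r in runs],
                )
            ]
        else:
            raise ValueError("no EPI inputs specified")
        state["echoes"] = [pre.remove_initial_volumes(v, n_rm) for v in raw]
        paths = write_pb("tcat", state["echoes"])
        manifest["stages"]["tcat"] = {"removed_first_trs": n_rm, "outputs": paths}
        log(f"tcat: {state['echoes'][0].n_volumes} volumes retained "
            f"({n_rm} removed per run)")

    @runner("outcount")
    def _outcount(stage: Stage):
        vol = state["echoes"][0]
        mask = auto_mask()
        frac = pre.temporal_outlier_fraction(vol, mask)
        state["outlier_frac"] = frac
        state["presteady"] = pre.detect_pre_steady_state(vol, mask)
        state["ref_index"] = int(np.argmin(frac))
        fio.write_column_file(frac[:, None], out_dir / "outcount.1D",
                              labels=["outlier_frac"])
        manifest["stages"]["outcount"] = {
            "pre_steady_state": state["presteady"],
            "min_outlier_index": state["ref_index"],
            "outputs": ["outcount.1D"],
        }
        log(f"outcount: pre-steady-state volumes flagged = {state['presteady']}")

    @runner("despike")
    def _despike(stage: Stage):
        state["echoes"] = [pre.despike(v) for v in state["echoes"]]
        paths = write_pb("despike", state["echoes"])
        manifest["stages"]["despike"] = {"outputs": paths}

    @runner("ricor")
    def _ricor(stage: Stage):
        vol = state["echoes"][0]
        cardiac = fphysio.read_physio_trace(spec.cardiac_path) if spec.cardiac_path else None
        resp = fphysio.read_physio_trace(spec.resp_path) if spec.resp_path else None
        if cardiac is None and resp is None:
            raise ValueError("ricor block requires cardiac and/or respiratory traces")
        orders = int(stage.value("ricor_orders"))
        regs = fphysio.retroicor_regressors(cardiac, resp, vol, orders=orders)
        rvt = (
            fphysio.rvt_regressors(resp, vol, tuple(stage.value("ricor_rvt_shifts")))
            if resp is not None
            else np.empty((vol.n_volumes, 0))
        )
        nt = vol.n_volumes
        order_bl = pre.auto_polort(nt * vol.tr)
        basis = pre._legendre_basis(nt, order_bl)
        n_nuis = regs.slicewise.shape[1] + rvt.shape[1]
        for v in state["echoes"]:
            for z in range(v.grid.dims[2]):
                xz = np.concatenate([basis, regs.slicewise[:, :, z], rvt], axis=1)
                y = v.data[:, :, z, :].reshape(-1, nt).T
                coef, *_ = np.linalg.lstsq(xz, y, rcond=None)
                nuis = xz[:, basis.shape[1]:] @ coef[basis.shape[1]:]
                v.data[:, :, z, :] -= nuis.T.reshape(v.grid.dims[0], v.grid.dims[1], nt)
        state["physio_df"] = n_nuis
        fio.write_column_file(rvt, out_dir / "rvt.1D")
        paths = write_pb("ricor", state["echoes"])
        manifest["stages"]["ricor"] = {
            "n_slicewise": regs.slicewise.shape[1],
            "n_rvt": rvt.shape[1],
            "outputs": paths,
        }
        log(f"ricor: removed {regs.slicewise.shape[1]} slicewise + {rvt.shape[1]} RVT regressors")

    @runner("tshift")
    def _tshift(stage: Stage):
        method = str(stage.value("tshift_interp"))
        align_to = float(stage.value("tshift_align_to"))
        state["echoes"] = [
            pre.slice_time_correct(v, method=method, align_to=align_to)
            for v in state["echoes"]
        ]
        paths = write_pb("tshift", state["echoes"])
        manifest["stages"]["tshift"] = {"outputs": paths}

    @runner("align")
    def _align(stage: Stage):
        mtx = stage.value("align_affine_mtx")
        state["epi2anat"] = (
            fio.read_column_file(mtx).reshape(4, 4) if mtx else np.eye(4)
        )
        manifest["stages"]["align"] = {"supplied_affine": bool(mtx)}

    @runner("tlrc")
    def _tlrc(stage: Stage):
        mtx = stage.value("tlrc_affine_mtx")
        state["anat2final"] = (
            fio.read_column_file(mtx).reshape(4, 4) if mtx else np.eye(4)
        )
        manifest["stages"]["tlrc"] = {"supplied_affine": bool(mtx)}

    @runner("volreg")
    def _volreg(stage: Stage):
        base = stage.value("volreg_align_to")
        ref = state["ref_index"] if base == "MIN_OUTLIER" else int(base)
        kernel = str(stage.value("volreg_final_interp"))
        mp = pre.estimate_rigid_motion(state["echoes"][0], ref_index=ref)
        state["motion"] = mp
        dxyz = stage.value("volreg_warp_dxyz")
        out_grid = None
        if dxyz is not None:
            from .types import Grid

            vol = state["echoes"][0]
            extent = np.asarray(vol.grid.dims) * np.asarray(vol.grid.voxel_size)
            dims = tuple(int(np.ceil(e / float(dxyz))) for e in extent)
            g = Grid.isotropic(dims, float(dxyz))
            out_grid = g
        state["echoes"] = [
            pre.apply_concatenated_transform(
                v, mp, state["epi2anat"], state["anat2final"], out_grid, kernel
            )
            for v in state["echoes"]
        ]
        state["mask"] = None  # grid may have changed; recompute on demand
        # unscaled temporal mean of the registered run, kept for
        # contrast-based QC (flip check): averaging beats single-frame noise
        vr = state["echoes"][0]
        state["vr_base"] = vr.with_data(
            vr.data.mean(axis=3)[..., np.newaxis], run_lengths=[1]
        )
        fio.write_column_file(
            mp.params, out_dir / "motion.1D", labels=list(mp.COLUMNS)
        )
        paths = write_pb("volreg", state["echoes"])
        manifest["stages"]["volreg"] = {
            "reference_index": ref, "outputs": paths + ["motion.1D"],
        }
        log(f"volreg: reference volume {ref}")

    @runner("combine")
    def _combine(stage: Stage):
        method = str(stage.value("combine_method"))
        if method != "OC":
            raise ValueError(f"unsupported combine method {method!r} (only 'OC')")
        if len(state["echoes"]) < 2:
            raise ValueError("combine stage requires multi-echo input")
        es = EchoSet(echoes=state["echoes"], echo_times=list(spec.echo_times))
        combined, weights = pre.fit_t2star_and_combine(es)
        state["echoes"] = [combined]
        state["t2star"] = weights
        paths = write_pb("combine", state["echoes"])
        manifest["stages"]["combine"] = {"method": method, "outputs": paths}

    @runner("blur")
    def _blur(stage: Stage):
        size = float(stage.value("blur_size"))
        state["echoes"] = [pre.gaussian_blur(v, size) for v in state["echoes"]]
        paths = write_pb("blur", state["echoes"])
        manifest["stages"]["blur"] = {"fwhm_mm": size, "outputs": paths}

    @runner("mask")
    def _mask(stage: Stage):
        anat_mask = None
        if str(stage.value("mask_epi_anat")) == "yes" and state["anat"] is not None:
            res = pre._resample_3d(
                state["anat"].data[..., 0], state["anat"].grid,
                state["echoes"][0].grid, np.eye(4),
            )
            anat_mask = res > pre._clip_level(np.abs(res))
        state["mask"] = pre.compute_epi_automask(state["echoes"][0], anat_mask)
        mvol = Volume4D(grid=state["echoes"][0].grid, data=state["mask"].astype(float))
        fio.write_nifti(mvol, out_dir / f"mask_epi.{spec.subject_id}.nii.gz")
        manifest["stages"]["mask"] = {
            "n_mask_voxels": int(state["mask"].sum()),
            "outputs": [f"mask_epi.{spec.subject_id}.nii.gz"],
        }

    @runner("scale")
    def _scale(stage: Stage):
        state["echoes"] = [pre.scale_percent(v) for v in state["echoes"]]
        paths = write_pb("scale", state["echoes"])
        manifest["stages"]["scale"] = {"outputs": paths}

    @runner("regress")
    def _regress(stage: Stage):
        vol = state["echoes"][0]
        nt = vol.n_volumes
        run_lengths = list(vol.run_lengths)
        mask = auto_mask()
        mp = state["motion"]
        enorm = (
            reg.enorm_series(mp, run_lengths) if mp is not None else np.zeros(nt)
        )
        ofrac = (
            state["outlier_frac"]
            if state["outlier_frac"] is not None
            else np.zeros(nt)
        )
        mthr = stage.value("regress_censor_motion")
        othr = stage.value("regress_censor_outliers")
        censor = reg.build_censor(
            enorm, ofrac,
            None if mthr in (None, "none") else float(mthr),
            None if othr in (None, "none") else float(othr),
        )
        parts = []
        base_cols, base_labels = reg.baseline_regressors(
            run_lengths, vol.tr, stage.value("regress_polort")
        )
        parts.append((base_cols, base_labels, "baseline"))
        if mp is not None:
            mot_types = tuple(stage.value("regress_apply_mot_types"))
            per_run = str(stage.value("regress_motion_per_run")) == "yes"
            mcols, mlabels = reg.motion_regressors(mp, mot_types, per_run, run_lengths)
            parts.append((mcols, mlabels, "motion"))
        band = stage.value("regress_bandpass")
        predicted_loss = None
        if band:
            fbot, ftop = (float(x) for x in band)
            bcols, blabels, predicted_loss = reg.bandpass_regressors(
                nt, vol.tr, fbot, ftop, run_lengths
            )
            parts.append((bcols, blabels, "bandpass"))
        ts = None
        if spec.stim_files:
            ts = fio.read_stim_timing(spec.stim_files, spec.stim_labels)
            basis = reg.BasisSpec(
                name=str(stage.value("regress_basis")),
                duration=float(stage.value("regress_basis_dur")),
            )
            for label in spec.stim_labels:
                scols, slabels = reg.event_regressors(
                    ts, label, basis, str(stage.value("regress_stim_types")),
                    run_lengths=run_lengths, tr=vol.tr,
                )
                parts.append((scols, slabels, f"stim:{label}"))
        X = reg.assemble_design(parts, censor=censor, run_lengths=run_lengths)
        whiten = "ar1" if str(stage.value("regress_reml")) == "yes" else "none"
        glm = reg.fit_glm(vol, X, whiten=whiten, mask=mask)
        for spec_str in stage.value("regress_glt") or []:
            label, _, body = str(spec_str).partition("=")
            weights = {}
            for item in body.split(","):
                col, _, w = item.partition(":")
                weights[col.strip()] = float(w)
            reg.linear_test(glm, weights, label.strip())
        state["glm"] = glm
        state["censor"] = censor
        state["ledger"] = reg.compute_df_ledger(X)
        if state["physio_df"]:
            led = state["ledger"]
            led.df_used["physio"] = led.df_used.get("physio", 0) + state["physio_df"]
            led.df_remaining -= state["physio_df"]
        state["warnings"] = reg.design_warnings(
            X, ts, presteady_flag=max(
                0, state["presteady"] - int(plan.stage("tcat").value("tcat_remove_first_trs"))
            ), tr=vol.tr,
        )
        fio.write_column_file(
            X.columns, out_dir / "X.xmat.1D", labels=X.labels,
            header_lines=[f"categories: {' '.join(X.categories)}"],
        )
        fio.write_column_file(censor.keep.astype(int)[:, None], out_dir / "censor.1D")
        fio.write_nifti(
            Volume4D(grid=vol.grid, data=glm.fstat[..., np.newaxis],
                     units_tag="statistic"),
            out_dir / f"stats_F.{spec.subject_id}.nii.gz",
        )
        fio.write_nifti(glm.errts, out_dir / f"errts.{spec.subject_id}.nii.gz")
        if band:
            manifest["stages"].setdefault("regress", {})["bandpass_predicted_df_loss"] = predicted_loss
        manifest["stages"].setdefault("regress", {}).update(
            {
                "n_censored": censor.n_censored,
                "df_remaining": state["ledger"].df_remaining,
                "whiten": whiten,
                "outputs": ["X.xmat.1D", "censor.1D",
                            f"stats_F.{spec.subject_id}.nii.gz",
                            f"errts.{spec.subject_id}.nii.gz"],
            }
        )
        log(f"regress: censored {censor.n_censored}/{nt}; "
            f"df remaining {state['ledger'].df_remaining}")

    @runner("QC_review")
    def _qc_review(stage: Stage):
        vol = state["echoes"][0]
        mask = auto_mask()
        glm = state["glm"]
        censor = state["censor"] or CensorSeries.all_kept(vol.n_volumes)
        resid = glm.errts if glm is not None else None
        tsnr = fqc.tsnr_map(vol, residuals=resid)
        g = fqc.gcor(resid if resid is not None else vol, mask)
        radcor = fqc.radial_correlation(vol)
        corr_brain = fqc.average_roi_correlation_map(
            resid if resid is not None else vol, mask
        )
        # two central, left-right offset seeds (no template space declared)
        center = vol.grid.center_world()
        off = vol.grid.voxel_size[0] * vol.grid.dims[0] / 5.0
        seeds = {"seed_left": center + np.array([-off, 0, 0]),
                 "seed_right": center + np.array([off, 0, 0])}
        seed_maps = {
            name: fqc.seed_correlation_map(
                resid if resid is not None else vol, tuple(xyz), censor
            )
            for name, xyz in seeds.items()
        }
        flip_verdict = "not_checked"
        if state["anat"] is not None and str(stage.value("qc_check_flip")) == "yes":
            ref3d = state.get("vr_base") or vol.with_data(
                vol.data[..., [state["ref_index"]]], run_lengths=[1]
            )
            flip_verdict, *_ = fqc.left_right_flip_check(ref3d, state["anat"])
        var_lines = fqc.variance_line_check(vol, mask)
        if var_lines:
            state["warnings"].append(
                reg.Warning_("variance_lines", "medium",
                             f"{len(var_lines)} high-variance through-plane column(s)")
            )
        ledger = state["ledger"]
        record = fqc.QCRecord(warnings=state["warnings"])
        record.scalars = {
            "subject_id": spec.subject_id,
            "tr": vol.tr,
            "n_volumes": vol.n_volumes,
            "n_runs": len(vol.run_lengths),
            "n_censored": censor.n_censored,
            "censor_frac": censor.censor_fraction,
            "censor_enorm_thr": censor.thresholds[0],
            "censor_outlier_thr": censor.thresholds[1],
            "max_enorm": float(np.max(censor.enorm)) if censor.enorm.size else 0.0,
            "tsnr_mean": float(tsnr.data[..., 0][mask].mean()),
            "gcor": g,
            "df_remaining": ledger.df_remaining if ledger else vol.n_volumes,
            "flip_verdict": flip_verdict,
            "pre_steady_state": state["presteady"],
            "n_variance_lines": len(var_lines),
            "stat_threshold": float(stage.value("qc_stat_threshold")),
            "_enorm_series": list(censor.enorm),
            "_outlier_series": list(censor.outlier_frac),
            "_keep_series": list(int(k) for k in censor.keep),
        }
        qc_dir.mkdir(parents=True, exist_ok=True)
        for name, m in (
            ("tsnr", tsnr), ("radcor", radcor), ("corr_brain", corr_brain),
            *seed_maps.items(),
        ):
            p = qc_dir / f"{name}.{spec.subject_id}.nii.gz"
            fio.write_nifti(m, p)
            record.map_paths[name] = m
        mean_orig = vol.with_data(vol.data.mean(axis=3)[..., np.newaxis],
                                  run_lengths=[1])
        mean_orig.slice_times = np.empty(0)
        record.map_paths["mean_orig"] = mean_orig
        if glm is not None:
            record.map_paths["fstat"] = vol.with_data(
                glm.fstat[..., np.newaxis], units_tag="statistic", run_lengths=[1]
            )
            record.map_paths["fstat"].slice_times = np.empty(0)
        html_path = fqc.render_apqc_html(record, qc_dir, spec.subject_id)
        uvars = {k: v for k, v in record.scalars.items() if not k.startswith("_")}
        uvars["qc_html"] = str(Path(html_path).relative_to(out_dir))
        fio.write_uvars(uvars, out_dir / "out.ss_review_uvars.json")
        (out_dir / "out.ss_review_basic.txt").write_text(fqc.basic_review(record))
        manifest["stages"]["QC_review"] = {
            "outputs": ["out.ss_review_uvars.json", "out.ss_review_basic.txt",
                        str(Path(html_path).relative_to(out_dir))],
        }
        state["qc_record"] = record
        log(f"QC_review: gcor={g:.4f} tsnr_mean={record.scalars['tsnr_mean']:.1f}")

    for stage in plan.stages:
        try:
            fn = stage_runners.get(stage.name)
            if fn is None:  # 'empty' placeholder block
                manifest["stages"][stage.name] = {"outputs": []}
                continue
            fn(stage)
        except Exception as exc:
            (out_dir / "output.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"stage {stage.name!r} failed: {exc}") from exc

    (out_dir / "output.log").write_text("\n".join(log_lines) + "\n")
    manifest["results_dir"] = str(out_dir)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
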