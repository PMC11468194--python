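# fmripipe

Single-subject FMRI processing with explicit provenance: a block-based
pipeline compiler, native implementations of the standard preprocessing
stages through GLM regression, physiological-noise regressors, an
integrated quality-control battery, and a synthetic phantom generator
that makes the whole chain testable offline.

## Who this is for

Researchers and methods developers who want a complete, inspectable
single-subject EPI processing stream — from raw 4D NIFTI through motion
correction, nuisance modeling and a static QC report — in plain
scientific Python, where every stage is an ordinary function with a
testable contract and every analysis is reproducible from a short
specification plus the package version.

## The processing model

A pipeline is specified hierarchically: an ordered list of processing
**blocks** (`tshift`, `volreg`, `blur`, `mask`, `scale`, `regress`, plus
optional `despike`, `ricor`, `align`, `tlrc`, `combine`) with options
whose name prefix identifies the owning block (`blur_size` → blur).
Compiling a specification inserts the automatic stages (`setup`, `tcat`,
`outcount`, `QC_review`), resolves every parameter (recording whether it
came from the user or a default), and renders a commented, runnable
*proc script* that embeds the generating command verbatim — the analysis
is fully documented by its own artifact.

Scientifically, the core commitments are:

- **Rigid-body motion correction** estimates six parameters per volume
  (roll, pitch, yaw in degrees; dS, dL, dP in mm) by intensity matching,
  and applies all spatial transforms (motion ∘ EPI→anat ∘ anat→final) as
  **one concatenated resampling**, so interpolation smoothing is paid
  once, not per stage.
- **Censoring** uses the Euclidean norm of the motion-parameter first
  difference, `Enorm_t = ‖p_t − p_{t−1}‖₂` (≈ mm), censoring *both*
  volumes flanking a suprathreshold difference (default threshold
  0.3 mm), plus an outlier-fraction criterion (default 0.05).
- **Regression is a single model**: baseline polynomials, motion
  regressors and derivatives, physiological regressors, bandpass
  sinusoids and stimulus responses (BLOCK/dmUBLOCK/GAM/SPMG1/TENT bases,
  with duration and amplitude modulation) are solved together with
  censored rows deleted — never as a chained sequence of filters.
- **Degrees of freedom are ledgered.** Bandpassing to a pass band
  `[fbot, ftop]` costs a fraction `DFloss = 1 − 2·TR·(ftop − fbot)` of
  the time series DFs — 60% for the standard 0.1 Hz band at TR = 2 s,
  80% at TR = 1 s — and the ledger partitions every DF across censoring,
  baseline, motion, physio, bandpass and stimulus categories before you
  spend them.
- **Scaling** puts each voxel in percent-of-mean units: run mean → 100,
  capped at 200, so effect estimates read directly as BOLD percent
  signal change.
- **QC is computed unmasked**: TSNR, radial correlation, GCOR
  (`‖mean of unit-norm series‖²` = mean pairwise correlation), seed and
  region correlation maps, a left-right flip check (local Pearson
  correlation cost on the image and its mirror), variance-line and
  collinearity warnings — all over the whole field of view, with the
  brain mask reserved for summary statistics, so artifacts outside the
  brain stay visible.

Multi-echo input is combined by the optimal-combination rule: per voxel
a log-linear fit of mean signal against TE gives T2\*, and echoes are
averaged with weights `w_i ∝ TE_i·exp(−TE_i/T2*)`.

## Worked example

Generate a synthetic subject (known ground truth), run a resting-state
style pipeline with physiological regressors, and read the review
dictionary:

```python
import json
from fmripipe.synth import write_phantom_inputs
from fmripipe.pipeline import PipelineSpec, assemble_plan, run_plan

inputs = write_phantom_inputs("inputs", seed=1, n_volumes=60, dims=(24, 24, 14),
                              noise_tsnr=80, motion_amp_mm=0.5, motion_amp_deg=0.3)
spec = PipelineSpec(
    subject_id="demo",
    blocks=["ricor", "tshift", "volreg", "blur", "mask", "scale", "regress"],
    options={"tcat_remove_first_trs": 2, "blur_size": 6.0,
             "regress_censor_motion": 0.3, "regress_censor_outliers": 0.05},
    epi_paths=inputs["epi"],
    anat_path=inputs["anat"],
    cardiac_path=inputs["physio"]["cardiac"],
    resp_path=inputs["physio"]["resp"],
)
run_plan(assemble_plan(spec), ".")
uvars = json.load(open("demo.results/out.ss_review_uvars.json"))
```

This prints (seed 1):

```
           tr : 2.2
    n_volumes : 58
   n_censored : 0
  censor_frac : 0.0
    max_enorm : 0.22044881523335175
    tsnr_mean : 298.187818315183
         gcor : 0.23033355959826302
 df_remaining : 31
 flip_verdict : no_flip
```

Reading: the two pre-steady-state volumes were removed (60 → 58); the
injected ≤0.5 mm motion never crossed the 0.3 mm Enorm threshold, so
nothing was censored; the RETROICOR stage consumed 8 slicewise + 5 RVT
regressors and, with baseline and 12 motion regressors, 31 of 58 DFs
remain (the QC report warns that this is getting thin for such a short
run); the GCOR of ≈0.23 correctly flags the phantom's unmodeled
quadratic drift as a global nuisance signal; and the EPI and anatomical
are not left-right flipped relative to each other. The
`demo.results/` directory holds one `pb*.nii.gz` intermediate per
data-transforming stage, motion/censor/outlier column files, the design
matrix, `stats_F`/`errts` volumes, and `QC_demo/apqc_demo.html` — a
static report with motion/censor plots, transparently-thresholded stat
maps and the warning list.

The same workflow is available from a shell: `fmripipe simulate`,
`fmripipe build` (spec file → commented proc script), `fmripipe run`,
`fmripipe compare` (diff two specs after default resolution) and
`fmripipe show-example`.

## Scope

Volumetric, single-subject processing only. Nonlinear template warping,
B0/blip distortion correction, surface-based analysis, multi-echo ICA
denoising beyond optimal combination, and interactive report features
are out of scope; affine anatomical↔template transforms are accepted as
user-supplied matrices. See `docs/methods.md` for the model details,
parameter conventions and known limitations.
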