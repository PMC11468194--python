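# Methods

This note documents the models, conventions and numerical choices behind
fmripipe, in the order data flows through a pipeline. Everything stated
here is exercised by the test suite; nothing reports an empirical result
the tests or `scripts/acceptance.py` do not themselves compute.

## Coordinate and data conventions

World space is RAS in mm; voxel and time indices are 0-based. A
`Volume4D` carries its grid (4×4 voxel→world affine), TR in seconds,
per-slice acquisition offsets in `[0, TR)`, a units tag
(`raw`/`percent`/`correlation`/`tsnr`/`statistic`) that only defined
operations may change, and the run structure (`run_lengths`), which
per-run stages (scaling, baselines, motion demeaning, Enorm) consult.
Motion parameter files are six columns in the order
(roll, pitch, yaw, dS, dL, dP) — rotations in degrees about the world
x/y/z axes applied in that order about the grid center, then
translations of dS mm along +z (superior), dL along −x (left), dP along
−y (posterior). Every written NIFTI/1D/JSON file carries an
accumulating history note (action, package version, timestamp); slice
times, run structure and history travel in a NIFTI header extension so
files round-trip losslessly while remaining readable by standard tools.

A 4D NIFTI with a zero or absent TR is read with TR := 1.0 s and a
warning: the pipeline stays runnable and the problem is surfaced rather
than hidden.

## Pipeline compilation

Blocks are drawn from a fixed registry; `setup`, `tcat`, `outcount` and
`QC_review` are automatic, `tshift volreg blur mask scale regress` is
the default user list, and the canonical execution order is

    setup, tcat, outcount, [despike], [ricor], tshift, [align], [tlrc],
    volreg, [combine], blur, mask, scale, regress, QC_review.

`despike` runs before `ricor` (both before `tshift`): the slicewise
physiological model assumes un-resampled slices, and despiking first
keeps spikes from leaking into the physiological fit. Multi-echo input
inserts an implicit `combine` stage after `volreg` (the optimal-
combination weights need registered echoes; the method needs no mask,
so `mask` stays in its usual place). Surface processing and blip/B0
correction are rejected with explicit errors, not silently ignored.
Option conservation is enforced: every user option must be consumed by
exactly one present stage.

The rendered proc script is a runnable Python program calling the
library stage by stage — the two-stage command→script design without
shelling out. It embeds the generating command verbatim, prints every
resolved parameter with its origin (`[user]`/`[default]`), and renders
byte-identically for the same spec in fixed-timestamp mode. Spec
comparison resolves defaults first, so an explicitly-set default
compares equal to an omitted one.

## Preprocessing stages

**Temporal outliers.** Per run, each voxel's series is detrended with
the run's baseline polynomial (order rule below); MADN =
1.4826·median|residual|; a time point is an outlier where
|residual| > k·MADN with k = Φ⁻¹(1 − 0.001/2) ≈ 3.2905. The per-volume
outlier fraction is the in-mask mean of this indicator. The
MIN_OUTLIER registration reference is the argmin of this fraction
(earliest index on ties).

**Pre-steady-state check.** Per-volume in-mask means are compared
against the median of the last 80% of volumes; leading volumes
exceeding median + 2·MADN are flagged. The flag is passed into the
model warnings when it exceeds the number of removed initial TRs.

**Slice-timing correction** resamples each slice's series from
`k·TR + slice_time` to `k·TR + align_to` (default 0) with a cubic
spline or a windowed-sinc fractional-delay filter (Hann window,
half-width 5 or 9 samples), edge-held at the run boundaries. On a
sinusoid with a TR/2 slice offset the sinc kernel's mid-series phase
error is below one degree.

**Rigid motion estimation.** Parameters are defined as the transform
carrying the *reference into each volume*; correction applies the
inverse. The cost is the mean squared intensity difference after
resampling the reference forward by the candidate transform — the
forward formulation matters: resampling the (already once-interpolated)
moving volume back instead biases the optimum toward under-rotation,
because the doubly-interpolated image can never match a sharp
reference. Optimization is two-level (Gaussian-smoothed, 2× decimated
coarse pass, then full resolution), Powell, warm-started from the
previous volume with a zero-start fallback, and bounded to ±15° / ±20 mm
— physically generous for within-run head motion, and it excludes the
spurious 180° symmetry minima of near-ellipsoidal heads.

**Single-step resampling.** All spatial maps for a volume
(anat→final ∘ EPI→anat ∘ inverse-motion) are composed and applied in
one `scipy.ndimage` resampling (nearest/trilinear/cubic) or one
windowed-sinc gather (wsinc5/wsinc9, Hann window). One caveat worth
stating precisely: "one-step resampling smooths less than sequential
resampling" is exact when the chain composes to a whole-voxel shift
(one-step is then lossless) and true on average over random rigid
chains, but it is *not* a per-instance inequality for the delta-image
peak — two trilinear kernels at quarter-voxel offsets compose to a
peakier kernel than the one-step half-voxel kernel. The tests assert
the exact case and the expectation, not the false universal.

**Blur** is a per-volume 3D Gaussian with σ = FWHM/(2√(2 ln 2)) per
axis in mm, reflective boundaries (total intensity conserved to
machine precision). **Automask** thresholds the temporal mean at an
iteratively-computed clip level, keeps the largest 6-connected
component and fills holes; with `mask_epi_anat`, it is intersected with
the anatomical mask. The mask is never multiplied into the data — it
only restricts summary statistics, so QC maps remain whole-FOV.
**Scale** maps each run to `min(200, 100·x/mean)` per voxel (mean ≤ 0 →
0), setting the `percent` units tag; the operation is idempotent.
**Despike** (offered as an approximate stage) clips detrended
excursions at 3·MADN about the polynomial trend.

**Optimal combination.** Per voxel, `log(mean signal)` is regressed on
TE (ms); T2\* = −1/slope clamped to [2, 300] ms; voxels with a
non-positive mean in any echo fall back to uniform weights. Weights
`w_i = TE_i·exp(−TE_i/T2*)`, normalized to sum to 1, average the
echoes; identical echoes pass through unchanged, and the combination's
contrast-to-noise on the phantom is never worse than the best single
echo at matched noise.

The default output grid rule (when a resolution is requested without a
value) is isotropic at the input's minimum voxel dimension truncated to
one decimal mm.

## Physiological regressors

Cardiac phase ramps linearly 0→2π between detected heartbeat peaks
(φ = 0 at a peak), extended one synthetic beat beyond each end.
Respiratory phase uses the amplitude-histogram transform —
φ = ±π·P(b ≤ b(t)) with b the smoothed amplitude above its minimum and
the sign from the derivative. Extrema detection smooths with a 0.25 s
boxcar, requires 0.3 s (cardiac) / 1.5 s (respiratory) between peaks,
and enforces strict peak/trough alternation by keeping the more extreme
of adjacent same-type candidates. RETROICOR regressors are
sin(kφ), cos(kφ) for k = 1..2 per trace, evaluated at each slice's
acquisition time — 8 slicewise regressors with both traces at the
defaults. RVT is (peak envelope − trough envelope)/period interpolated
to volume onsets, demeaned, delivered at shifts {0, 5, 10, 15, 20} s —
5 volumetric columns. The shift set and the histogram phase variant
are conventions of this implementation (chosen to realize the standard
counts), not facts about any particular acquisition. In the pipeline,
the `ricor` stage projects these regressors out slicewise (protecting
the polynomial baseline) on the un-resampled data, and books their 13
DFs in the ledger's physio category.

## Regression

**Bases.** BLOCK(d) is a width-d boxcar convolved with the impulse
response h(t) = (t/4)⁴·e^{4−t} (peak 1 at 4 s), scaled so the
1-s-duration response peaks at exactly 1; dmUBLOCK applies the same
scaling with per-event durations, so a 1 s event has unit magnitude and
longer events saturate upward — the duration-modulation unit
convention. GAM(p, q) = (t/(p·q))^p·e^{p−t/q} with defaults
p = 8.6, q = 0.547 (peak 1 at p·q ≈ 4.7 s). TENT(b, c, n) gives n
triangular knots (partition of unity) over [b, c]; CSPLIN is accepted
as an alias. Stimulus types: `time` (summed responses), `AM1`
(modulator-scaled), `AM2` (unmodulated column plus one
mean-centered-modulator column each; centering uses the within-class
event mean), `IM` (one column per event). Events past the run end are
dropped with a warning.

**Bandpass-in-model.** Per run of length N, sine+cosine columns at DFT
frequencies k/(N·TR) strictly outside the keep band (boundaries belong
to the keep band; Nyquist contributes cosine only; the constant belongs
to the baseline). Projecting these out equals FFT band rejection to
1e-8 RMS on an uncensored run — filtering and regression are the same
operation here, which is what makes the DF cost exact and auditable.
The closed form DFloss = 1 − 2·TR·(ftop − fbot) is returned alongside
the columns (0.60 at TR = 2 s, ftop = 0.1 Hz; 0.80 at TR = 1 s).

**Baselines** are per-run Legendre polynomials, orders 0..polort with
the automatic rule polort = 1 + ⌊run_duration/150 s⌋, QR-orthogonalized
on the run's sample grid (sampled Legendre polynomials are not
discretely orthogonal; the QR preserves each order's span, keeps order
0 constant, and normalizes to unit maximum). **Motion regressors** are
per-run demeaned parameters and/or backward first differences (first
volume of each run 0), optionally block-diagonal per run. **ROI
principal components** erode the ROI by one voxel, then take the top-k
temporal singular vectors of the demeaned voxel×time matrix (unit
norm; padded only to rank, with a warning).

**Censoring** combines Enorm > threshold (censoring volumes t−1 and t:
the difference implicates both) and outlier fraction > threshold
(censoring t only); Enorm mixes degrees and mm unscaled, on raw (not
demeaned) parameters. Censored rows are deleted from the solve; the
censor series is retained for reporting and plots.

**Solver.** OLS over the whole field of view; residual df =
kept rows − columns. `ar1` mode estimates one pooled lag-1 residual
autocorrelation (runs handled separately, in-mask voxels), prewhitens
rows with (1, −ρ) (first row of each run scaled by √(1−ρ²)) and refits
— a two-pass generalized-least-squares treatment of serial correlation;
a deliberate simplification of full ARMA(1,1) restricted-likelihood
fitting, adequate for the phantom's AR structure and flagged here as an
approximation. Slicewise physiological columns, when present in a
design, are substituted per slice so each slice is solved with its own
regressors. Rank deficiency fails with the names of the dependent
columns (QR pivoting). The errts residual volume zero-fills censored
time points. General linear tests take label→weight maps (one row → t,
several rows → F).

**DF ledger and warnings.** The ledger partitions
n_total = n_censored + Σ per-category columns + remaining, warning at
<30% remaining (medium) and ≤0 (severe/error-level). Model warnings:
stimulus collinearity (max |pairwise r| > 0.4 medium, > 0.7 severe),
overall censor fraction > 0.1 (medium), more than half of a class's
events overlapping censored volumes within a 15 s response window
(severe), pre-steady-state passthrough, and the ledger flags. The
censor-fraction and collinearity thresholds are this package's own
choices.

## Quality control

TSNR = |baseline-fitted mean| / residual SD (GLM residuals when
available, else polynomial-detrend residuals), 0 for constant voxels.
Radial correlation correlates each voxel with the Gaussian-weighted
neighborhood average (HWHM 20 mm default; σ = HWHM/√(2 ln 2));
edge voxels are somewhat self-inflated by the boundary handling of the
neighborhood average. GCOR is ‖mean of demeaned unit-norm series‖²,
exactly the mean of the full pairwise correlation matrix (verified
against brute force). Seed maps exclude censored volumes; without a
declared template space, two central left-right-offset seeds are used
(with a template, shipped DMN/visual/auditory coordinates apply).
All maps are computed unmasked.

The local-Pearson alignment cost tiles the FOV into ~8 mm cubes and
returns −Σ w·ρ·|ρ|/Σ w over patches with nonzero variance (w = patch
voxel count): identical images → −1, contrast-reversed → +1. This is a
documented variant of the named cross-modal cost, validated by the
flip-check property (20/20 constructed pairs) rather than numeric
equality with any external implementation. The flip check rigidly
aligns the anatomical and its x-mirror to the (unscaled, temporally
averaged) EPI under this cost; |Δcost| < 0.02 is inconclusive — the
verdict a perfectly symmetric head must produce.

The ROI table reports Nvox, Nzer (zero-TSNR voxels), Dvox (maximum
6-connected erosion depth), TSNR min/quartiles/max over nonzero voxels
and the deepest voxel, with shape (Nzer > 0 or Dvox ≤ 1) and low-TSNR
(median < half the global median) warnings. Variance lines flag
through-plane (x,y) columns whose mean detrended variance exceeds
median + 4·MADN across columns (scale-invariant). The review
dictionary (uvars JSON), basic-review text and cross-subject review
table (union of keys, blank for missing, criterion strings like
`censor_frac ge 0.1` for outlier flagging) aggregate the scalars.

The HTML report is fully static: sections vorig/ve2a/mot/regr/warns/
radcor/qsumm, inline PNG images, censor threshold lines and red censor
bands on the motion plots (the band count is recorded in the image
metadata), warnings sorted by severity, and a rating placeholder
rendered inert. Statistic maps use transparent thresholding with a
transfer function linear in |stat|/threshold below threshold and an
opaque contour above — the linearity is this package's choice.

## Synthetic phantoms

The generator emulates what the stages act on: a three-shell ellipsoid
(inner CSF-like S0 1400/T2* 90 ms, gray 1000/45, white 900/55) with a
smooth multiplicative texture field (default ±10%; it also anchors
rotational registration, which a bare ellipsoid under-constrains), an
optional seed-deterministic left-hemisphere bright feature shared with
the anatomical companion (defined in normalized coordinates, so the
pair must share a world extent — `write_phantom_inputs` builds the
anatomical accordingly), per-echo signal S0·exp(−TE/T2*), interleaved
slice timing, per-run Legendre drift (default ±1%, orders 1–2), task
responses injected through the package's own basis functions at stated
percent amplitudes, slice-phase-locked physiological sinusoids, an
optional half-FOV ghost replica, spikes, smooth injected rigid motion
(applied with the package's own resampler), and white Gaussian noise at
a target gray-matter TSNR (default 80). Defaults mirror a typical
multi-echo resting protocol: TR = 2.2 s, TE = 12.5/27.6/42.7 ms,
32×32×20 voxels at 3 mm, 150 volumes — large enough for registration
stability, small enough for fast tests. Timing sets default to a
40 + 24 two-class event design; physiological traces are quasi-periodic
with jittered inter-beat intervals and slow amplitude modulation, and
return their exact peak times.

What the phantom does *not* emulate — and hence what passing tests do
not establish about real data: anatomical texture beyond a smooth
field, EPI geometric distortion and signal dropout, k-space/ghosting
physics beyond an additive replica, non-rigid motion, spin-history
effects, colored (non-AR) noise, and realistic hemodynamic variability.
Recovery results on the phantom are oracle checks of the
implementation, not validation against acquisition physics.

## Problem sizes and tolerances

Tests run phantoms of 8³–32×32×20 voxels and 20–200 volumes; the
end-to-end pipeline check uses a 20×20×12 subject with 40 volumes, and
the acceptance script a 16×16×10 run of 50 volumes — sizes chosen so
the whole suite completes in about a minute while leaving each
property's signal comfortably above its tolerance. Key tolerances:
motion recovery median ≤ 0.1 mm / 0.2° on injected ±5 mm/±5°
transforms (observed ~1e-8 on the self-consistent oracle);
bandpass-vs-FFT equivalence ≤ 1e-8 RMS; GCOR vs brute force ≤ 1e-12;
percent-beta recovery |bias| < 0.05 points at TSNR 100; NIFTI
round-trip ≤ 1e-6 relative on data and 1e-5 mm on affines.
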