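# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cmequant`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic scenes

The generator renders one capsule-shaped cell (cylinder with
hemispherical caps, default 12 µm long, 1.75 µm radius — a geometry
whose surface area 2πrL ≈ 132 µm² matches the average cell the counting
calculations assume) at 0.1 µm/px, one frame per second for 60 frames,
matching the acquisition cadence the analyses are designed for.

Endocytic events follow a piecewise-linear intensity profile: a linear
rise over `rise_s` (default 10 s, the time scale of actin/fimbrin
assembly) to a peak of `peak_molecules` (default 830, the calibration
anchor) and a linear fall over `fall_s` (default 10 s).  Linear
rise/fall is the simplest shape with a unique peak and well-defined
half-peak times; it is not a mechanistic claim about assembly kinetics.
Spots are rendered as 2-D Gaussians of SD 1.3 px (sub-diffraction at
this pixel size), stationary until the peak — scission — and performing
a 2-D random walk with RMS step `diffusion_step_px` afterwards.  Event
anchors are rejection-sampled inside the eroded cell mask with a ≥10 px
mutual separation so that ground-truth identity is unambiguous.

The background has a cytoplasmic level inside the cell and a medium
level outside, *blurred by the same PSF* — a hard intensity step at the
cell boundary is an optical impossibility and, if rendered, produces
boundary artifacts that no real detector faces.  Photobleaching
multiplies the whole frame by e^(−λt); an optional multiplicative
illumination field and additive Gaussian (EMCCD-like) camera noise are
applied last.  Poisson noise is not modelled.  Identical parameters and
seed give bit-identical stacks.

What the generator does **not** emulate: z-defocus (scenes are 2-D,
standing for sum projections), yeast autofluorescence texture, vesicle
motion in z, spot shape changes during invagination, and multiple cells
per field.  Recovery results on these scenes therefore demonstrate the
correctness of the algorithms, not their performance on raw microscope
data.

FM4-64 traces rise saturating (τ = fast_phase/5, reaching exactly 1 at
the end of the fast phase, default 60 s) and then grow linearly at
k/100 per minute.  Eisosome area-fraction series decay as
plateau + (f₀−plateau)e^(−kt), normalized to 1 at t = 0.  Aspiration
series grow the tongue linearly with pressure, crossing l = Rp exactly
at ΔP\* = 2σ(1−Rp/Rc)/Rp.  Survival times are geometric (per-interval
death probability), censored past the last interval.

## Patch detection, linking, measurement, filtering

Detection applies a Laplacian-of-Gaussian filter at the spot scale
(σ = 1.3 px) per frame and takes local maxima above `threshold_sd`
(default 5) times a robust MAD-based noise estimate of the response.
Ridge-like maxima — responses of the cell boundary rather than of
diffraction-limited spots — are rejected by the ratio of principal
curvatures of the response (threshold 10, the standard keypoint
edge-rejection test).  Centers are refined to sub-pixel precision by
center of mass of the median-subtracted intensity in a 7-px window;
on synthetic spots this is accurate to well under 0.5 px.

Linking is frame-to-frame minimum-cost assignment (Hungarian algorithm)
with a displacement gate of 3 px and gap closing over 1 missed frame:
endocytic patches are near-stationary until scission, so a tight gate
prevents identity switches and the short gap tolerates single-frame
detection dropouts.

Intensity is measured as the sum over a circular 7-px-diameter disc
(37 pixels) centered on the rounded track position.  The local
background is the value, at the center, of the frame median-filtered
with a 9-px *radius* (ImageJ convention; a 9-px-wide window would sit
inside the spot's own tail and overestimate the background).  The
corrected intensity subtracts background × 37.  Frames whose ROI would
leave the image are excluded and flagged.

The quality filter keeps tracks that last ≥ 5 s and whose 3-frame
moving-average intensity has an interior, positive maximum with both
endpoints at or below 70% of it.  The endpoint condition is what
"an increase followed by a decrease" means operationally: tracks are
truncated at the detection limit, so endpoints are not zero, but a
genuine assembly/disassembly cycle leaves them well below the peak,
whereas static artifacts whose intensity merely wiggles (e.g. residual
boundary responses) do not.  Filtering is idempotent.

On synthetic scenes with 20 events the detector+filter recovers exactly
20 tracks, both noiseless and at realistic noise (SD 4 a.u. against an
830 a.u. peak).

Known systematic: the 7-px disc captures ≈97% of a σ = 1.3 px Gaussian,
and the local median retains a small spot-tail contribution, so measured
track intensities are a few percent below the rendered photon totals.
Molecule calibration is unaffected (it is anchored on the same
measurement), but see "Ratiometric counting" below.

## Temporal super-resolution alignment

Traces carry no absolute clock, so each is first coarse-centered on its
sample argmax.  The aligner then iterates: (1) for each trace, find the
offset on a grid of step `sub_dt_s` (default 0.1 s, range ±10 s) that
minimizes the mean-square difference between the linearly interpolated,
shifted trace and the reference over their overlap; (2) recompute the
reference as the pointwise mean of the realigned traces (the initial
reference is the first trace).  Iteration stops when the largest offset
change is below `sub_dt_s` (or after 50 iterations); the grid is then
shifted so the lightly smoothed (3-point) mean peaks at t = 0.
Exhaustive grid search is robust and cheap at this problem size; the
3-point smoothing prevents a single noisy sample from defining t = 0.

Pointwise statistics use the per-time-point number of overlapping
traces n(t); the 95% CI is the normal approximation 1.96·SD/√n.  Traces
that lose all overlap with the reference are dropped with a warning.

Planted offsets uniform in ±2 s are recovered (after removing the
arbitrary global time origin) to ≤ 0.1 s RMS on noiseless traces and
≤ 0.3 s at SNR 10 with 50 traces — the sub-frame ("super-resolution")
regime, since the sampling interval is 1 s.

Calibration divides by the control ensemble's peak intensity and
multiplies by the 830-molecule anchor.  Speed is the frame-to-frame
displacement magnitude over the interval; ensemble speeds are averaged
on the same grid using the same offsets.  Assembly and disassembly
durations are measured between the peak and the half-peak crossings
(linear interpolation), reported as undefined on a side that never
drops below half-peak.

## Ratiometric counting

The number of concurrent endocytic events in a cell is

    n = (total patch-attributable fluorescence) / A_event

where A_event is the time-average of the single-event corrected
intensity over its lifetime (time-mean of the aligned ensemble).  The
patch-attributable total is computed as: whole-image sum of
(image − medium level) minus (cytoplasm level × outline area).  Summing
the whole image rather than the outline interior is deliberate —
blurring conserves photons, so the PSF skirt that leaks across the cell
boundary is recaptured, while an interior-only sum loses it.  The medium
level is the median outside the dilated mask; the cytoplasm level is the
median of spot-masked pixels in the eroded interior (erosion keeps the
blur-affected boundary band out of the estimate).  The density is n over
the cell length; turnover rates follow as events/min = n·60/τ and
area/min = events/min·πd² (a vesicle of diameter d carries a sphere's
worth of membrane).

Planted counts are recovered to ≈1% without background and within 5%
with uniform cytoplasm.  When A_event is taken from the tracking
ensemble rather than given, the count inherits the ROI capture
systematic described above (A_event is a few percent low, so n is a few
percent high); this cancels in *comparisons* across conditions analysed
identically, which is how such densities are used.

## FM4-64 exocytosis rates

Whole-cell fluorescence is summed over a per-frame threshold mask
(Otsu of the first frame unless a threshold is given).  The trace is
normalized to 1 at the end of the fast staining phase (fixed 1 min by
default; in auto mode, the first time the smoothed derivative falls
below 10% of its initial maximum).  The rate k is the OLS slope of the
normalized trace over a window measured from the anchor, ×100 → %/min,
with the OLS standard error.  k is invariant to the camera gain by
construction.  True rates of 2–6 %/min with noise SD 0.01 are recovered
within 2·SE in ≥90% of seeds (a 2·SE interval is nominally 95%).

## Eisosomes

Density: cytosolic signal is removed with a fixed threshold (when not
known, the 95th percentile of a user-marked cytosol region), the
z-stack is sum-projected, and the remaining intensity inside the
outline is divided by the spherical surface area 4πR² (protoplasts are
spheres; walled cells would use the capsule formula).  The quantity is
intensive: cells with equal per-area membrane signal give equal density
regardless of radius.

Disassembly kinetics: the above-threshold area per frame of a top-plane
time lapse, normalized to the first frame, is fit by least squares to
plateau + (1−plateau)e^(−kt).  The plateau is fixed at 0 by default
(complete disassembly); the free-plateau mode exists because moderate
shocks disassemble only part of the eisosome pool.  Rates of
0.05–0.3 /min at noise SD 0.02 are recovered with <10% median relative
error.

## Biophysics conventions

All internal computation is SI (Pa, N/m, m); report units are mN/m,
MPa, µm².  Report rounding is fixed so printed comparisons are
deterministic: fold changes to one decimal, percent changes to integer
percent, areas to three significant figures.  The default cell radius
(1.75 µm) is the value at which a 12 µm capsule has the 132 µm²
reference area; it is exposed as a parameter.  The eisosome reservoir
counts the hemi-cylinder membrane πd/2 per unit furrow length minus the
flat footprint d, i.e. (π/2−1)·d·ρ ≈ 4.6% of the membrane for
ρ = 1.6 µm/µm² and d = 50 nm ("about 5%"); partial disassembly scales
linearly.

The tongue-length criterion for aspiration (σ evaluated at the pressure
where l = Rp) is interpolated linearly between pressure steps; a series
that never reaches l = Rp is reported as "not reached" (`None`) rather
than extrapolated.

## Survival statistics

The product-limit estimator and Greenwood variance are computed
directly: S(t) = Π(1 − dᵢ/nᵢ) over death times, Var = S²·Σ dᵢ/[nᵢ(nᵢ−dᵢ)],
with deaths processed before censorings at tied times.  The two-group
logrank test (χ², 1 df) is delegated to lifelines; lifelines'
Kaplan–Meier fitter also serves as an independent cross-check of our
estimator in the tests.  With no deaths in either group the logrank
statistic is defined as 0 (p = 1).

## Numerical and degenerate-input conventions

- Corrected images are clipped at 0 (intensities are photon counts).
- The bleach fit runs in log space when the trace is strictly positive
  and falls back to nonlinear least squares otherwise; a fitted
  negative rate is clamped to 0 with a warning.
- Blank frames in FM segmentation contribute 0 and are flagged.
- A capsule must satisfy L ≥ 2r; an aspiration geometry must satisfy
  Rp < Rc; generators reject negative rates, levels and probabilities.
- Problem sizes used in the tests (60-frame single-cell movies, 20
  events, 50-trace ensembles, 50–100-seed recovery loops) keep the full
  suite fast while leaving every estimator's sampling error well below
  the tolerances being checked.

## Limitations

- No 3-D (z-resolved) tracking; z-stacks are sum-projected first.
- No track splitting/merging; overlapping endocytic events closer than
  the linking gate would be mis-linked.
- No automated segmentation of bright-field cells; outlines are
  supplied (a capsule helper exists for synthetic scenes).
- The FM4-64 rate cannot distinguish exocytosis from non-vesicular
  lipid transfer; the measured quantity is membrane-area addition.
- Single-exponential bleach and decay models; multi-component
  photophysics is out of scope.
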