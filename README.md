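# cmequant

Quantitative-microscopy analysis of how fission yeast (*S. pombe*) adapts
endocytosis, exocytosis, and eisosomes to changes in plasma-membrane
tension.  The package is aimed at cell biophysicists who quantify
clathrin-mediated endocytosis (CME) from fluorescence time-lapse movies
and who measure membrane tension and membrane-area fluxes in walled
cells and protoplasts.

## What it computes

- **Endocytic patch tracking** — Laplacian-of-Gaussian spot detection,
  assignment-based linking, intensity measurement in a circular 7-px
  ROI with local-median background correction, photobleaching
  correction, and quality filtering (tracks ≥ 5 s showing an increase
  followed by a decrease in intensity).
- **Temporal super-resolution averaging** — single-event intensity
  traces sampled at 1 s are aligned with sub-frame offsets δᵢ by
  iteratively minimizing the mean-square difference to a running
  reference, then averaged into an ensemble N(t) ± 95% CI with the peak
  (vesicle scission) at t = 0.  Intensities are converted to molecule
  numbers with a calibration anchoring the control-strain ensemble peak
  to 830 fimbrin molecules.
- **Ratiometric event counting** — the number of concurrent endocytic
  events per cell is the background-corrected whole-cell fluorescence
  divided by the time-averaged intensity of one event, A_event; the
  linear density is that count over the cell length, and the membrane
  turnover follows from the event lifetime and vesicle size
  (events/min = n·60/τ, area/min = events/min·πd²).
- **Exocytosis rate from FM4-64** — with the dye kept in the medium the
  normalized whole-cell fluorescence grows linearly after the fast
  surface-staining phase; the OLS slope over the first 5/10/15 min
  (k₀₋₅, k₀₋₁₀, k₀₋₁₅) is the % of membrane surface area exocytosed per
  minute.
- **Eisosome quantification** — membrane-bound Pil1p density
  (thresholded z-sum over 4πR²) and the post-shock decay of the area
  fraction covered by eisosomes, fit to plateau + (1−plateau)·e^(−kt).
- **Biophysics** — membrane tension from micropipette aspiration,
  σ = ΔP·Rp/[2(1−Rp/Rc)] at the pressure where the tongue length
  reaches Rp; osmotic pressure ΔP = RT·ΔC ≈ 2.45×10⁶·ΔC Pa/M; capsule
  surface area 2πrL; the eisosome membrane reservoir
  (π/2−1)·d·ρ; and the post-shock membrane-area budget.
- **Survival statistics** — Kaplan–Meier curves with Greenwood standard
  errors and two-group logrank tests for repeated-shock survival.
- **Synthetic data** — every analysis stage is validated against a
  generator that renders patch movies (rise-then-fall spots, cytoplasm,
  bleaching, uneven illumination, camera noise) and traces with known
  ground truth.

## Worked example

Simulate a 60-frame movie of one 12 µm cell with 20 endocytic events
and run the full analysis (simulate → bleach-correct → track → align →
count):

```
$ cmequant pipeline --seed 0 --out demo/
{
 "n_tracks_detected": 35,
 "n_tracks_kept": 20,
 "peak_molecules": 830.0,
 "assembly_s": 5.22,
 "disassembly_s": 5.13,
 "n_events": 7.29,
 "density_per_um": 0.61,
 "true_density_per_um": 0.56,
 "cell_area_um2": 131.9
}
```

All 20 planted events pass the quality filter (the extra raw detections
are short or shapeless fragments that the filter rejects).  The
ensemble peak is calibrated to 830 molecules; the half-peak assembly
and disassembly times (≈5 s each) reflect the generator's 10 s linear
rise and fall.  The ratiometric count recovers about 7 concurrent
events (0.61/µm against a planted time-average of 0.56/µm; the small
excess is the ROI capture fraction, see `docs/methods.md`).

The membrane-area budget of the post-shock response, from the printed
steady-state rates (endocytosis 2 %/min reduced by 25%, exocytosis
6.2 %/min increased by 10%, for 10 min):

```
$ cmequant budget --endo-rate 2 --endo-reduction 0.25 \
      --exo-rate 6.2 --exo-increase 0.1 --duration 10
{
 "endo_gain_pct_rounded": 5,
 "exo_gain_pct_rounded": 6,
 "total_gain_pct_rounded": 11
}
```

i.e. a 5% + 6% = 11% net gain in protoplast surface area.

Other subcommands: `simulate`, `track`, `align`, `density`, `exo`,
`eisosome`, `tension`, `survive`.  Stages exchange TIFF/CSV/JSON files,
so any stage can be re-run in isolation; the same functionality is
available as a library (`import cmequant`).

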