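# Methods

## Scope and model

`sptkit` analyzes 2D single-particle trajectories of intracellular
vesicles (positions in μm, uniform sampling, default 1 frame/s) and
classifies motion into two modes:

* **Brownian diffusion** — thermal random motion with mean-square
  displacement `MSD(τ) = 4Dτ + ε`;
* **Flow (directed) motion** — motor-driven transport superposed on
  diffusion, `MSD(τ) = 4Dτ + (vτ)² + ε`.

`D` (μm²/s) is the diffusion coefficient, `v` the drift speed (reported
in μm/min; all internal computation is in μm and s, the factor 60 is
applied only at reporting boundaries), and `ε ≥ 0` a constant offset
caused by localization error (`ε = 4σ²` for i.i.d. Gaussian error of
s.d. σ per coordinate).

## MSD estimation and model fitting

The time-averaged MSD uses all overlapping frame pairs at each lag —
the standard single-particle-tracking estimator. Long lags average few
pairs and are statistically weak, so curves are truncated at lags
`k ≤ floor(f·N)` with `f = 0.1` by default (a 300-frame track keeps
lags 1–30 s); the minimum usable track is `ceil(1/f) + 1 = 11` frames.

Both model forms are linear in `(4D, v², ε)`, so the nonnegativity-
constrained fits are solved exactly by nonnegative least squares; no
iterative optimizer or starting values are involved. Fits are
unweighted by default, with an option to weight lags by their pair
counts. Model selection uses the nested-model F-test
`F = (RSS_brownian − RSS_flow)/(RSS_flow/(n−3))` at level 0.05, ties
and degenerate (all-zero) curves resolving to Brownian by parsimony.

**Known limitation.** Time-averaged MSD values at different lags of one
track are strongly correlated, which the F-test ignores; on single
pure-Brownian tracks it over-calls flow (order 40% at 300 frames) while
flow tracks are recognized almost perfectly. Classification of single
tracks therefore leans on the segmentation/asphericity route below; the
MSD fits are most reliable on ensemble-averaged curves.

Per-track estimator bias: the `ε ≥ 0` constraint clips negative
intercept estimates and thereby biases per-track `D̂` downward by a few
percent at desk-scale track lengths, and `v̂ = sqrt(v̂²)` is concave, so
averages of per-track fits are not unbiased. Ensemble-MSD fits (pooling
pairs across tracks before fitting) remove both effects to well below
the Monte-Carlo error and are what the parameter-recovery checks use.

## Gyration tensor and asphericity

The gyration tensor `T_ij = ⟨x_i x_j⟩ − ⟨x_i⟩⟨x_j⟩` (population
normalization, averages over the track's frames) summarizes a track's
shape; with eigenvalues `λ₁ ≥ λ₂` the asphericity in 2D is
`α = (λ₁−λ₂)²/(λ₁+λ₂)²` ∈ [0, 1]: 0 for isotropic/confined shapes, 1
for a perfect line. The general-d form divides the pairwise
eigenvalue-difference sum by `(d−1)(Σλ)²`. A zero tensor (all points
identical) is flagged degenerate and assigned α = 0.

Two ensemble estimators exist and differ: the *ratio of means*
`⟨(λ₁−λ₂)²⟩/⟨(λ₁+λ₂)²⟩` converges for ideal 2D Brownian walks to the
closed form `2(d+2)/(5d+4) = 4/7 ≈ 0.571`, the reference value used to
recognize diffusive ensembles; the *mean of per-track ratios* converges
elsewhere and is used only for single-track classification (`α_sp`).
Both are exposed; `ensemble_asphericity` implements ratio-of-means.

Because an individual Brownian walk can look elongated by chance, the
single-track threshold is calibrated by Monte Carlo: for each track
length, `n_sims` pure Brownian walks (unit steps — α is
scale-invariant) are simulated fully vectorized with a closed-form 2×2
eigen-decomposition, and the tail probability `P(α_sp ≥ α_thr)` is the
empirical false-positive rate. At `α_thr = 0.8` this falls in the
3–8% range over 10–300-frame tracks (largest for the shortest tracks).
Distributions are stored as fixed-width histograms (bin 0.01) so the
tail is also recomputable as a bin sum; direct sample counting is the
primary estimate to avoid bin-edge effects. Default length grid
10–300 frames, default `n_sims = 10⁴` (10⁵ runs in under a minute if
wanted).

## Segmentation into motion domains

Per ensemble (one experimental condition):

1. **Partition** each track into consecutive non-overlapping segments of
   `m = 3` frames; remainder frames join the last segment so labels tile
   the track. A segment's speed components are the means of its
   finite-difference velocities (which telescope to
   `(last − first)/span`).
2. **Thresholds**: `v_x^thr, v_y^thr` = 0.70 × the ensemble means of the
   absolute segment-speed components. An alternative statistic (mean of
   per-segment maxima of |v_x|, |v_y|) is available behind
   `statistic="mean_of_max"`; the default is the reading that yields one
   threshold pair directly from the component distributions.
3. **Grouping**: maximal runs of consecutive segments uniformly above or
   uniformly below threshold. "Above" means |v_x| ≥ v_x^thr OR
   |v_y| ≥ v_y^thr by default (an axis-aligned drift must not be
   missed); AND is available.
4. **Classification**: an above-threshold run of ≥ 2 segments becomes a
   flow-motion domain iff its local asphericity `α_L` (computed on the
   run's positions) exceeds `α_thr = 0.8`; isolated above-threshold
   segments and failed runs are absorbed into diffusion. Adjacent
   same-kind domains merge, and each final domain's `α_L` is recorded on
   its merged span. Degenerate spans are labeled diffusion.

Consequences asserted as invariants: every frame gets exactly one
label; no flow domain is shorter than `2m` frames; relabeling is
deterministic; uniform coordinate scaling scales speeds and thresholds
identically and leaves labels unchanged.

Population summaries report both weightings — fraction of tracked time
per kind, and fraction of tracks whose dominant-by-time kind is each
kind — because either convention is found in practice; outputs label
which is which. Thresholds are an ensemble property, so each segmented
track records the thresholds it was classified with.

**Detection power at realistic parameters.** At 1 frame/s the reported
drift scale `v ≈ 0.45 μm/min` moves a particle 0.0075 μm per frame,
several-fold less than a diffusive step `sqrt(2·D·dt) ≈ 0.027 μm` at
`D = 3.7×10⁻⁴ μm²/s`, and less than the localization-noise velocity.
Per-segment speeds are then noise-dominated, above-threshold runs
fragment, and short flow bouts are genuinely undetectable locally;
flow becomes recognizable only over long persistent runs where the
accumulated displacement outgrows the diffusive spread. Synthetic
benchmarks that probe the segmentation machinery therefore use stronger
drift (a few μm/min), while demo conditions at the reported magnitudes
show the qualitative ordering (directed-transport ensembles carry more
flow-labeled time than diffusive ones) rather than large absolute flow
fractions.

## Synthetic data

The generator emulates the study conditions: 2–5 min tracks at
1 frame/s, alternating Brownian domains (D ~ 10⁻⁴–10⁻³ μm²/s) and flow
domains (v ~ 0.3–0.45 μm/min, drift superposed on Brownian jitter with
the same D), with i.i.d. Gaussian localization error added to stored
positions only (measurement error does not propagate into the true
path — this is exactly what makes the fitted ε a positive offset).
Per-frame ground-truth labels are retained. The localization s.d. is
not published for the emulated instrument; the default σ = 0.02 μm is a
synthetic convention chosen so that ε = 4σ² = 1.6×10⁻³ μm² is small
against 4Dτ at τ = 1 s for the upper D scale. Flow headings are
constant within a track by default (transport along one microtubule), a
per-run re-draw is available. Stop-and-go ensembles draw geometric
domain durations with means set so the expected flow-time fraction hits
a target.

What the generator does *not* emulate: confined/anomalous diffusion
(actin-caging phases), 3D motion projected to 2D, detection/linking
artifacts (blinking, gap closing, misassignment), heterogeneous
per-spot noise. Passing tests on these synthetics therefore validate
the estimators and the segmentation logic, not robustness to tracking
errors.

## Colocalization

Pixel mode: Manders `M1 = (above-threshold red intensity inside the
green mask)/(above-threshold red intensity everywhere)`; an automatic
Costes-style threshold pair (regression of green on red, threshold
walked down until the below-threshold correlation ≤ 0) is available as
a pre-step, with a fixed user threshold the default. Object mode: a
red spot is colocalized when its centroid lies within `max_dist` of any
green centroid (k-d tree lookup); default 0.5 μm, a diffraction-scale
spot radius, is a convention — the matching rule is not standardized.
Zero-signal inputs return an explicit undefined result with counts
rather than 0/0.

## Physico-chemical conversions

Stokes–Einstein `R_H = k_B T/(6πηD)` and Smoluchowski `ζ = uη/ε` with
SI units internally (k_B from CODATA via scipy), nm/mV at reporting
boundaries. Defaults: T = 298.15 K, η = 8.9×10⁻⁴ Pa·s,
ε = 6.93×10⁻¹⁰ F/m (water at 25 °C).

## Numerical choices and degenerate inputs

* 2×2 eigenvalues: `numpy.linalg.eigvalsh` for single tracks, the
  closed form `trace/2 ± sqrt(((T_xx−T_yy)/2)² + T_xy²)` vectorized for
  calibration batches (both paths cross-checked in tests); tiny negative
  round-off eigenvalues are clipped at 0.
* λ₁ = λ₂ ties need no tie-break — α is symmetric in the eigenvalues.
* Tracks too short for an analysis raise explicit errors naming the
  minimum length; empty input files warn and return empty lists.
* Gap policy on import: tracks are split at missing frames by default;
  `bridge` interpolates single missing frames (mirroring upstream
  gap-closing) and splits at larger gaps.
* Per-track seeds are spawned from the master seed via
  `numpy.random.SeedSequence`, so ensembles are reproducible and
  streamable (10⁵ tracks never need to be resident at once).
* Desk-scale default sizes: calibration 10⁴ walks per length over a
  10-point grid (seconds of runtime), recovery checks 8 replicate
  ensembles × 200 tracks × 300 frames.
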