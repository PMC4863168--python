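# sptkit

Single-particle-tracking motion analysis for live-cell imaging of
intracellular cargo (e.g. lipoplex-loaded vesicles): given 2D
trajectories exported from a tracker such as TrackMate, `sptkit`
quantifies how particles move — free Brownian diffusion versus
motor-driven directed ("flow") transport — and how much of a labeled
cargo ends up inside a second-channel compartment.

It is aimed at microscopists and quantitative cell biologists who have
tracks (μm coordinates, uniform frame interval) and want per-track
motion parameters, per-frame motion-domain labels, and population-level
summaries, with every stage testable against simulated ground truth.

## What it computes

**MSD model fitting.** The time-averaged mean-square displacement
(overlapping pairs, lags restricted to 10% of the track length) is
fitted to

* Brownian: `MSD(τ) = 4Dτ + ε`
* Flow: `MSD(τ) = 4Dτ + (vτ)² + ε`

with `D, v², ε ≥ 0` (exact nonnegative least squares — both forms are
linear in the parameters) and an F-test choosing between the nested
models. `ε` is the localization-error offset; `v` is reported in μm/min.

**Asphericity.** The gyration tensor
`T_ij = ⟨x_i x_j⟩ − ⟨x_i⟩⟨x_j⟩` gives the track-shape asphericity
`α = (λ₁−λ₂)²/(λ₁+λ₂)² ∈ [0,1]` (0 = confined/isotropic, 1 = a straight
line). Ideal 2D Brownian ensembles give the ratio-of-means value
`4/7 ≈ 0.57`; the single-track threshold `α_thr = 0.8` is calibrated by
Monte Carlo so that a pure Brownian track exceeds it only ~3–8% of the
time, depending on track length.

**Segmentation.** Tracks are cut into 3-frame segments; segments whose
mean speed components exceed 70% of the ensemble mean absolute speeds
are candidates; runs of ≥ 2 consecutive candidate segments whose local
asphericity exceeds `α_thr` become flow-motion domains, everything else
is diffusion. Ensembles are summarized as diffusion/flow fractions
(time-weighted and dominant-track-weighted).

**Colocalization.** Manders `M1 = colocalized red / total red` on
intensity image + mask, and object-based percent of red spots within a
distance cutoff of any green spot.

**Conversions.** Stokes–Einstein `R_H = k_B T/(6πηD)` and Smoluchowski
`ζ = uη/ε`.

A synthetic-trajectory generator (Brownian / drift / stop-and-go
mixtures with localization noise and per-frame ground-truth labels)
makes the whole pipeline testable without any microscopy data.

## Worked example

```python
import numpy as np
import sptkit as sk

# simulate a 5-min stop-and-go track: diffusion, a directed run, diffusion
track = sk.simulate_stop_and_go(
    [sk.MotionDomainSpec("brownian", 120, D=1.0e-3),
     sk.MotionDomainSpec("flow", 60, D=3.7e-4, v=3.0, heading=0.6),
     sk.MotionDomainSpec("brownian", 120, D=1.0e-3)],
    seed=7)

fit = sk.select_model(sk.compute_msd(track.to_trajectory()))
print(fit.model, round(fit.D, 5), round(fit.v, 3))
# flow 0.00102 1.332

print(round(sk.asphericity(track.positions), 3))
# 0.44
```

The MSD fit recognizes the directed contribution (model `flow`) with
`D ≈ 1.0×10⁻³ μm²/s` (the dominant Brownian domains' value) and an
effective whole-track `v ≈ 1.3 μm/min` — the 3 μm/min run is active
only one-third of the time. The whole-track asphericity 0.44 stays
below the Brownian reference 0.57 even though a third of the track is
directed: global shape statistics dilute embedded runs, which is
exactly why the local segmentation stage exists.

Ensemble segmentation and population fractions, via the CLI:

```bash
sptkit run --out-dir out --seed 1
```

simulates two 60-track conditions at the experimentally observed
magnitudes (a diffusion-dominant one at `D = 1.0×10⁻³ μm²/s` and a
directed-transport one at `D = 3.7×10⁻⁴ μm²/s`, both with
`v = 0.45 μm/min`), runs calibration, MSD fits and segmentation, writes
`tracks_*.csv`, `msd_fits.csv`, `segmented_*.csv`, `population.csv` and
`calibration.json` under `out/`, and prints the fraction table, e.g.

```
"DD-like":  {"time_flow": 0.055, "tracks_flow": 0.0, ...}
"LFN-like": {"time_flow": 0.032, "tracks_flow": 0.0, ...}
```

(the directed condition carries more flow-labeled time; absolute
fractions are small because at 0.45 μm/min a particle drifts far less
per frame than it diffuses — see `docs/methods.md` on detection power).
Other subcommands: `simulate`, `msd`, `calibrate`, `segment`, `coloc`,
`report` (e.g. `sptkit report --d 2.45e-11` → `R_H = 10.02 nm`).

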