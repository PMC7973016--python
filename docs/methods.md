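# Methods

This note records the models, conventions and numerical choices behind
`apdisp`, in the order the analysis runs.

## Synthetic data model

**Why synthetic.**  Optical-mapping recordings of fibrillation-prone
hearts are rarely deposited, so the package ships a generator whose
outputs carry exact ground truth: the per-pixel APD field, the
activation delays, the supra-threshold dispersion fraction (computed by
the generator's own brute-force oracle, an implementation deliberately
independent of the analysis module), and spiral-core locations.  Every
recovery test in the suite measures the analysis chain against this
truth.

**Action-potential template.**  Each pixel's trace is a train of
identical analytic action potentials: a tanh upstroke with time
constant 0.4 ms (10–90% rise < 2 ms, matching fast cardiac phase 0 at
1 kHz sampling), a plateau lasting 25% of the APD, and a raised-cosine
repolarization whose duration is solved in closed form so the waveform
crosses `1 − L/100` of its amplitude exactly APD milliseconds after the
upstroke midpoint.  The raised cosine reaches the resting level in
finite time (≈1.19 × APD for L = 90), so successive beats at a
physiological cycle length leave the next beat's baseline clean; an
infinite exponential tail instead biases the per-beat amplitude
reference by several ms on long-APD pixels at a 100 ms cycle length.
No ionic model is involved — the template exists to make the ground
truth exact, not to be biophysically detailed.

**APD fields.**  Islands of elevated APD are painted onto a uniform
baseline (default 50 ms, a typical murine optical APD90 scale).
Island centers follow the three point-process archetypes matching the
theoretical dispersion taxonomy: jittered regular lattice (uniform;
jitter 10% of spacing), homogeneous Poisson (random), Matérn cluster
process (clustered; 5 parents, 10 px cluster radius, optionally biased
to the tissue border).  Island geometry defaults — 25 islands of radius
6 px, elevation 25 ms — are synthetic conventions chosen once to put
the supra-10 ms dispersion fraction in the ~10% regime characteristic
of fibrillation-prone tissue.  The elevation must exceed twice the
binarization threshold for a two-level field, since a step of height Δ
can contribute at most Δ/2 to a windowed standard deviation.
Serpiginous (snake-like) islands are built by dilating a self-avoiding
random walk; ovoid islands are discs.

**Pacing, propagation, noise.**  Default pacing is a 100 ms cycle
(10 Hz) with activation delayed by a plane wave at 0.3 mm/ms — a
typical ventricular conduction speed — over the 0.095 mm pixel pitch.
Noise is additive Gaussian (sd relative to unit AP amplitude) plus a
0.5 Hz sinusoidal baseline drift with random per-pixel phase and an
optional linear photobleaching ramp; these are the dominant separable
artifacts of dye imaging.  Motion artifact is not modeled
(mechanically arrested preparations are assumed).

**Spiral movies.**  Reentry test inputs are analytic:
`cos(2πft + Σᵢ χᵢ θᵢ + 2πr/λ)` with polar angle θᵢ about core *i* of
chirality χᵢ = ±1 and wavelength λ = 60 px.  Cores sit at half-pixel
offsets so the singular point falls between samples.  Two opposite
cores give a figure-of-eight with zero net charge.  The rotation
frequency must stay below one quarter of Nyquist.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no curved or anisotropic wavefronts, no
spatially correlated noise, no motion, no fractionated electrograms,
no APD restitution or alternans, and two-valued APD fields rather than
continuous gradients.  Recovery numbers on real recordings will be
worse than the synthetic bounds.

## APD measurement

Preprocessing order: per-pixel linear detrend, temporal moving average
(default 5 ms), mask-restricted spatial mean filter (default 3 px),
then per-pixel normalization to [0, 1] over the recording.  The
detrend line is fitted to each pixel's **below-median samples** only:
an ordinary least-squares line through a short paced recording is
pulled by the large AP deflections and tilts the baseline enough to
push the repolarization tail above threshold.  Flat pixels are dropped
from the mask rather than raising.

Activation is the upward 0.5-amplitude crossing with a 30 ms
refractory lockout — more robust at 1 kHz sampling than max dV/dt.
APD_L runs from the interpolated upstroke midpoint to the first
interpolated downward crossing of `1 − L/100` of the beat's local
baseline-to-peak amplitude; the per-beat amplitude reference tolerates
residual drift and makes the measurement exactly invariant to affine
rescaling of the trace.  Beats whose repolarization is not reached
before the next activation are discarded.  The default aggregate is
the median across complete beats (robust to one corrupted beat); a
single-beat policy is available.  The default level is APD90, the
common optical-mapping convention; 50–90 are supported and maps depend
on the choice.

Conduction velocity comes from a least-squares plane fit of activation
time over a centered window (default 5 px); speed is the inverse
gradient magnitude, invalid where the fit residual exceeds 2 ms RMS or
the gradient is degenerate (simultaneous activation).

Measured recovery at the default acquisition scale (100 × 100 px,
1 kHz, 10 Hz pacing; see `scripts/acceptance.py`): noise-free maximum
per-pixel error ≈ 0.13 ms (sub-frame interpolation of the analytic
template); at Gaussian noise of 10% of AP amplitude, mean absolute
error ≈ 2 ms with the default filters.

## Dispersion and islands

Dispersion is the **population** (divide-by-n) standard deviation of
the valid APDs in a sliding centered window, default 10 × 10 px — a
fixed-size descriptive summary, not a sample estimate.  Even windows
place the extra row/column at the bottom/right so results are
bit-reproducible.  A pixel is valid only when ≥ 50% of its full window
area holds valid APDs, which suppresses the border-inflation artifact
of partially filled edge windows.  The `max_minus_min` statistic
implements the high-gradient definition (largest long-vs-short APD
difference within the window) under identical masking.

Binarization is strictly `> threshold` (default 10 ms, the dispersion
level above which reentry becomes likely in fibrillation-prone
tissue).  The area fraction divides by the tissue mask restricted to
pixels where the statistic was computable.  Islands are 8-connected
components; elongation is the second-moment major/minor axis ratio,
and the ovoid/serpiginous cut (elongation > 3 or solidity < 0.6 ⇒
serpiginous) is an explicit package convention — the shape taxonomy is
verbal in origin and carries no published metric.

Group statistics are mean ± SEM with a two-sided one-sample t-test;
zero-variance groups report a degenerate test (t = 0, p = 1 when the
common value equals the null) with a warning.

## Pattern classification

The uniform/random/clustered taxonomy is operationalized on island
centroids (point-process view) plus Moran's *I* on the continuous map:

* **Quadrat VMR** — the region is tiled with quadrats of twice the
  dispersion window (20 px): larger than the island scale, so clumping
  concentrates counts, while still leaving 25 cells on a 100 × 100
  map.  Results are sensitive to this choice; it is configurable.
  Quadrats < 50% inside the region are dropped.  The reported
  VMR uses the population variance of counts; the significance test
  uses the exact Pearson index of dispersion
  `Σ(x − x̄)²/x̄ = VMR · Q`, whose null expectation with the total
  count fixed is exactly Q − 1, referred to χ²(Q − 1).  (The scaled
  alternative `VMR · (Q − 1)` is biased low by a factor (Q − 1)/Q and
  measurably inflates false regularity calls at these counts.)
* **Clark–Evans R** — observed over expected (`0.5/√density`) mean
  nearest-neighbor distance; an optional guard-region correction drops
  border points from the numerator.  Donnelly's full correction is out
  of scope.
* **Decision rule** — clustered iff the one-sided upper χ² test
  rejects at α (default 0.05) *and* R < 1; uniform iff the lower test
  rejects *and* R > 1; random iff neither rejects; conflicting signals
  or fewer than 5 islands ⇒ indeterminate.  All inputs are recorded in
  the report.

Calibration, measured over seeded replicates at the defaults
(25 points on 100 × 100): uniform and clustered generator patterns are
recovered in ≈ 100% of replicates; the random pattern in ≈ 92–94% —
the residual being exactly the two-sided type-I rate of the quadrat
test (nominal 2α = 10%, conservative in practice because the count
distribution is discrete at mean 1 per quadrat).  A consequence worth
noting: the end-to-end pipeline classifies *extracted* binary islands,
and clustered fields often merge into < 5 components after
binarization, returning indeterminate; the statistics are most
informative on the generating centers or on maps with many separated
islands, while Moran's *I* of the continuous dispersion map (≈ 1 for
clustered fields) remains discriminative regardless.

## Phase and singularities

Phase is the analytic-signal angle of the mean-subtracted, linearly
detrended trace (Hilbert transform).  The transform is unreliable near
the record ends over a zone that scales with the oscillation period,
so 5% of frames (minimum 2) are trimmed from each end and the offset
recorded.  A state-space embedding alternative is not implemented.

Singularities are detected per frame by topological charge: wrapped
phase differences summed counterclockwise around each 2 × 2 plaquette
equal ±2π exactly when the loop encloses a singularity (sign =
chirality).  Detections land on the half-integer plaquette grid, hence
within half a pixel of an analytic core.  The SPD map counts
singularity visits in a smoothing window tied to the 10 × 10
dispersion window, per second of recording.  The highest-SPD window is
compared against the nearest fully-valid non-overlapping window of the
same size (ties broken row-then-column) — "neighboring" has no
published definition, so this convention is explicit.

Dominant frequency uses a Hann-window periodogram of the linearly
detrended trace within a band (default 1–40 Hz, covering murine AF/VF
rates); DF is exact to one frequency bin for band-interior tones, and
the peak-power fraction is reported as a confidence proxy.

## Determinism and problem sizes

Every stochastic step draws from `numpy.random.default_rng` seeded
explicitly; identical configuration and seed reproduce byte-identical
metric files (fixed `%.10g` formatting).  The test suite and the
acceptance script run movies of 100 × 100 px with 4–8 beats
(0.4–0.9 s) and 150–200-frame spiral movies — sizes chosen so the full
chain, including brute-force oracles, completes on a laptop-class
single core in well under a minute per scenario while exercising the
full acquisition geometry.

## Known limitations

* The two-level synthetic APD fields make supra-threshold area
  fractions crisply defined; real fields with smooth gradients will
  sit closer to the threshold and recover less exactly.
* Spatial smoothing (default 3 px) biases APD at island borders by
  mixing traces across the step; quantification configs that need
  unbiased edges should disable it, as the zero-noise tests do.
* The classifier's minimum of 5 islands makes it conservative on
  heavily merged binary maps (see above).
* No rotor trajectory linking across frames, no 3D/panoramic geometry,
  no ratiometric or calcium-signal support.
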