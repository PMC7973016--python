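# apdisp

Spatial dispersion of action potential duration (APD) — the standard
deviation of APD across neighboring pixels — marks cardiac tissue prone
to reentrant arrhythmias such as atrial and ventricular fibrillation.
`apdisp` turns voltage-dye optical-mapping movies into per-pixel APD
maps, windowed std(APD) dispersion maps, binarized supra-threshold area
quantification with island morphometry, phase-singularity statistics,
and a quantitative classification of the dispersion pattern as
**uniform**, **random** or **clustered**.  It is written for
electrophysiology labs analysing MiCAM-style acquisitions (1,000
frames/s, 100 × 100 px, ≈0.095 mm/pixel) and for methodologists who
need a fully synthetic, ground-truth-exact test bed for dispersion
analysis.

## What it computes

For a movie $V(t, y, x)$ the chain is:

1. **APD mapping** — per pixel, beats are detected at the
   50%-amplitude upstroke crossing (30 ms refractory lockout) and
   $\mathrm{APD}_L$ is the time from that crossing to the first
   downward crossing of $1 - L/100$ of the beat's baseline-to-peak
   amplitude (default $L = 90$, linear sub-frame interpolation, median
   over beats).
2. **Dispersion mapping** — a sliding $w \times w$ window (default
   $w = 10$) yields either the population standard deviation
   $\sigma(\mathrm{APD})$ or the range $\max - \min$ (the high-gradient
   definition) of the valid APDs around each pixel.
3. **Binarization and quantification** — pixels with dispersion
   strictly above a threshold (default 10 ms) form the binary map;
   the supra-threshold **area fraction** is their percentage of the
   computable tissue.  8-connected islands get area (mm²), elongation,
   solidity and an ovoid/serpiginous shape label.
4. **Pattern classification** — island centroids are tested with the
   quadrat variance-to-mean ratio (Pearson index of dispersion against
   $\chi^2_{Q-1}$) and the Clark–Evans nearest-neighbor index $R$;
   Moran's *I* measures autocorrelation of the continuous map.
   Clustered = VMR significantly > 1 and $R < 1$; uniform = VMR
   significantly < 1 and $R > 1$; random = no rejection; conflicting
   signals are reported as indeterminate.
5. **Phase analysis** (fibrillation recordings) — Hilbert-transform
   phase maps, topological-charge detection of phase singularities on
   2 × 2 plaquettes, singularity-point-density (SPD) maps, dominant
   frequency maps, and comparison of the highest-SPD region against a
   neighboring 10 × 10 window of the APD map.

Because real recordings of this kind are rarely shareable, the
`synthetic` module generates paced movies from an analytic
action-potential template over ground-truth APD fields (islands placed
by jittered-lattice, Poisson or Matérn-cluster point processes) and
analytic spiral-wave movies with known singularity cores — every
downstream number can be checked against exact truth.

## Conventions

Arrays are indexed `[frame, row, col]`, origin top-left, 0-based; masks
are boolean `[row, col]` with `True` = tissue.  Even windows center
with the extra row/column at the bottom/right.  Binary-map PNG renders
are green (≤ threshold), yellow (> threshold), black (background).
Reported APD maps depend on the configured repolarization level; the
default is APD90.

## Worked example

```python
import numpy as np
import apdisp as ap

field = ap.generate_apd_field("clustered", grid=(100, 100), seed=7)
movie, truth = ap.synthesize_movie(field, pacing=(100.0, 4),
                                   noise=(0.05, 0.02), seed=7)
cfg = ap.SignalConfig(spatial_filter_px=1, temporal_filter_ms=5.0)
apd = ap.compute_apd_map(movie, cfg)
disp = ap.dispersion_map(apd, window_px=10)
binary = ap.binarize(disp, threshold_ms=10.0)
frac = ap.area_fraction(binary, movie.mask)
islands = ap.extract_islands(binary, movie.meta.pixel_pitch_mm)
report = ap.classify_pattern(field.centers, region=movie.mask, dmap=disp)

print(f"mean APD: {np.mean(apd.values[apd.valid]):.1f} ms at APD{apd.level_pct:.0f}")
print(f"supra-threshold area: {frac:.1f}% "
      f"(generator oracle {truth.true_area_fraction_pct:.1f}%)")
print(f"islands: {len(islands)}; largest "
      f"{max(i.area_mm2 for i in islands.islands):.2f} mm^2; "
      f"shapes {sorted({i.shape_label for i in islands.islands})}")
print(f"pattern: {report.label} (VMR {report.vmr:.2f}, p={report.vmr_p:.1e}; "
      f"R={report.clark_evans_r:.2f}; Moran's I {report.morans_i:.2f})")
```

prints:

```
mean APD: 55.2 ms at APD90
supra-threshold area: 14.9% (generator oracle 14.9%)
islands: 4; largest 4.72 mm^2; shapes ['ovoid', 'serpiginous']
pattern: clustered (VMR 3.12, p=2.5e-07; R=0.43; Moran's I 0.98)
```

i.e. on a noisy 10 Hz-paced movie the pipeline recovers the generator's
supra-10 ms area fraction to 0.1 percentage points, finds the
high-dispersion islands (both compact and snake-like shapes present),
and the spatial statistics of the island centers identify the clustered
arrangement decisively.  Note that classifying from *extracted* binary
islands instead of the generating centers needs at least 5 components;
merged archipelagos below that return `indeterminate`.

A `apdisp` console script exposes the same steps as subcommands
(`simulate`, `apd`, `dispersion`, `patterns`, `phase`, `run`,
`summarize`); `apdisp run --config cfg.yaml --out out/` executes the
whole chain and writes maps (CSV/PNG), an island table, the pattern
report and a tidy metrics CSV, deterministically for a given seed.

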