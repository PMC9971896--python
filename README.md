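# puffkit

Analysis of Ca²⁺ puffs — brief, localized Ca²⁺ release events produced by
small clusters of IP₃ receptors — in high-speed TIRF image streams, together
with puncta colocalization analysis for two-channel receptor-labelling
images. The package is aimed at labs that record Cal520 (or similar
indicator) movies at ~200 frames/s around a photolysis flash and need a
reproducible, scriptable replacement for the usual chain of interactive
tools (event detection, kinetic measurement, site counting, JACoP-style
colocalization), plus a ground-truth simulator to validate every stage.

## What it computes

**Event detection.** Each pixel trace is normalized to its pre-flash
baseline (F/F₀), expressed in units of its baseline standard deviation, and
spatially blurred (σ = 2 px). Voxels brighter than a threshold are grouped
into 26-connected components over (t, y, x); each component is one puff. The
event is localized with sub-pixel precision by fitting an isotropic 2D
Gaussian to the *unsmoothed* F/F₀ image at the peak frame, and an F/F₀
trace is read from a 1.76 × 1.76 μm ROI centred on the centroid.

**Kinetics.** Per event: amplitude (baseline-to-peak ΔF/F₀), rise time
(20% → 100% of peak), decay time (100% → 20%), and duration (time above
half-maximal amplitude), all with linearly interpolated crossing times.
Events with a sustained plateau near peak ("square" events) are flagged and
excluded from kinetic means. Per cell: event frequency, latency from the
flash, and the recording interval.

**Site clustering.** Event centroids are grouped into stable release sites
when they fall within 1 μm (6.25 px at 0.16 μm/px) of a site's running
centroid — a greedy, sorted, centroid-updating pass. A single-linkage
("chain") variant is included because it reproduces a known failure mode:
densely packed centroids link across large distances and the site count is
underestimated.

**Colocalization.** LoG spot detection (estimated punctum size 600 nm) with
quality and size filters, point-intensity mapping between registered
channels, Manders split coefficients M1/M2 on thresholded images, pixel-wise
Pearson r, and Costes block-randomization significance (100 iterations,
5-px blocks).

**Statistics.** Bead-normalized expression (10,000 × F_sample/F_beads),
unpaired Student's t, Pearson correlation, and the Cochran–Armitage χ² test
for trend.

**Simulator.** Seeded synthetic movies (default 19.2 × 19.2 μm at
0.16 μm/px, 5-ms frames, flash at 2 s) with immobile sites emitting
linear-rise/exponential-decay transients of known amplitude, plus
two-channel puncta pairs with controllable colocalized fraction and
intensity correlation — full ground truth for recovery testing.

## Worked example

```python
from puffkit.synthetic import SimMovieConfig, simulate_movie
from puffkit.pipeline import analyze_movie

cfg = SimMovieConfig(n_frames=4000, n_sites=10, seed=1)
stack, truth = simulate_movie(cfg)
res = analyze_movie(stack, ground_truth=truth)
print(res.recovery)
print(res.summary)
```

prints (seed 1):

```
{'n_truth_events': 37, 'n_detected_events': 37, 'n_matched': 37,
 'recall': 1.0, 'precision': 1.0,
 'centroid_error_px_mean': 0.022, 'centroid_error_px_max': 0.068,
 'amplitude_rel_bias_mean': 0.001,
 'n_true_sites': 10, 'n_sites_centroid_update': 10, 'n_sites_chain': 10}
CellSummary(n_events=37, frequency_hz=2.15, latency_s=0.815,
            recording_interval_s=17.18, mean_amplitude_dFF0=0.296,
            mean_rise_ms=20.0, mean_decay_ms=64.2, mean_duration_ms=40.3,
            n_square_excluded=0)
```

All 37 injected events are recovered with no false positives, centroids are
localized to well under a tenth of a pixel, and the measured mean amplitude
(≈ 0.30 ΔF/F₀) equals the injected mean amplitude (1.0) times the analytic
attenuation of averaging the 0.4-μm Gaussian event profile over the 11 × 11 px
trace ROI. The rise (≈ 20 ms) and decay (≈ 64 ms) means match the configured
waveform closed forms: 0.8 × 25 ms rise and 40 ms × ln 5 decay.

The same workflow runs from the shell:

```
puffkit simulate-movie --seed 1 --out sim/
puffkit puffs sim/movie.tif --ground-truth sim/ground_truth.json --out run/
puffkit coloc channel_a.tif channel_b.tif --out coloc/
```

Each run directory receives the resolved config, a log, and a version stamp.

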