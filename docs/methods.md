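# Methods

## Signal model and the synthetic generator

The simulator renders a movie as

    F(x, y, t) = B · G(t) · (1 + Σᵢ aᵢ sᵢ(t) exp(−((x−xᵢ)² + (y−yᵢ)²) / 2σ²)) + ε

where B is the camera baseline, G(t) an optional global ramp starting at the
flash (modelling a slow cytosolic Ca²⁺ rise), the sum runs over events at
immobile sites (xᵢ, yᵢ), and ε is additive Gaussian noise. Events are
*multiplicative* on the baseline, so the injected amplitude aᵢ is directly a
ΔF/F₀ value and comparable without conversion to what the pipeline measures.
The event time course sᵢ(t) is a linear rise to 1 over `rise_ms`, an
optional plateau (`plateau_ms`, used only for "square" events), and an
exponential decay with constant `decay_tau_ms`. This is the minimal waveform
with well-defined values for all four kinetic metrics; no claim is made that
real puffs rise linearly.

Default acquisition geometry matches the experiments the analysis is built
for: 120 × 120 px at 0.16 μm/px (a 19.2 μm square), 5-ms frames, flash at
frame 400 (2 s), with 2 saturated flash-artifact frames. Default event
parameters — amplitude lognormal with mean 1.0 ΔF/F₀ and CV 0.3, rise 25 ms,
decay τ 40 ms, spatial σ 0.4 μm, sites ≥ 2.5 μm apart, 0.2 events s⁻¹ per
site after the flash — give transients whose measured rise/decay/duration
fall in the tens-of-milliseconds range typical of puffs. The spatial σ is a
configuration knob, not a measured quantity: puff microdomains (clusters
spanning a few hundred nm) are below the diffraction-limited spread of the
indicator signal, and no within-study value exists to copy.

Two deliberate bookkeeping rules keep ground truth aligned with what is
measurable. Event start times are a Poisson process per site with a dead
time (default 0.5 s): two overlapping transients at one site form a single
suprathreshold cluster that no threshold segmentation can split, so
overlapping draws are not injected (they would be a statement about the
generator, not the detector). And an event is only recorded if its
above-20% window (rise + plateau + τ·ln 5) fits inside the stack, so every
truth event has measurable kinetics.

What the generator does *not* emulate: photobleaching, Poisson/EMCCD noise
statistics, mobile events, diffusive Ca²⁺ waves, or optical aberrations.
Passing recovery tests therefore demonstrates the correctness of the
analysis chain under its stated assumptions, not robustness to every
property of real recordings.

The puncta generator places Gaussian spots with a minimum separation (dart
throwing; an unsatisfiable packing raises an error). `round(f · n_spots)`
positions are shared between channels; paired intensities of shared spots
come from a bivariate normal with the requested correlation, clipped at
zero, with the same marginal used for unshared spots.

## Preprocessing: the two-stack discipline

Detection and measurement use different representations of the same movie:

* **Measurement stack** — F/F₀, each pixel divided by its mean over the
  pre-flash baseline window (default 390 frames). Traces, amplitudes and
  kinetics are read here, unsmoothed, because blurring and SD scaling
  distort amplitudes.
* **Detection stack** — (F/F₀ − 1) divided by each pixel's baseline SD of
  F/F₀, then Gaussian-blurred (σ = 2 px) frame by frame. Subtracting the
  baseline mean puts the resting level at zero so that "voxels brighter than
  a threshold" is meaningful; dividing by the per-pixel SD equalizes
  sensitivity across pixels of different brightness.

SD normalization is per pixel. Pixels with zero baseline SD (possible only
in noiseless synthetic data) fall back to the field median SD; an all-zero
SD map is an error. If fewer pre-flash frames exist than requested, all of
them are used, with a warning.

Background subtraction takes either a scalar or a cell-free region whose
mean is subtracted per frame (robust to illumination drift); single images
destined for puncta analysis can instead be rolling-ball corrected
(default radius 50 px). Flash-artifact frames (default 2) are removed
*before* normalization, and the removed original indices are carried along
so every reported time is in acquisition time.

Slow baseline drift is removed, when enabled, by a zero-phase (forward–
backward) order-2 Butterworth high-pass along time with cutoff 0.01 × Nyquist
(1 Hz at 200 fps), after which the pre-flash mean is added back so baselines
stay near 1. At these settings a sinusoid at a tenth of the cutoff is
attenuated to a few percent while a 50-ms transient keeps ≈ 95% of its
amplitude. Order and cutoff are configurable because drift time courses vary.

## Detection threshold units

The detector binarizes the detection stack at a strict `>` threshold
expressed in baseline-SD units. Note a subtlety of those units: after the
per-pixel SD division the *unblurred* noise floor is 1 by construction, and
the σ = 2 blur reduces it to ≈ 1/(2σ√π) ≈ 0.14. Interactive tools built on
the same normalization are commonly run with small nominal thresholds
(0.25 is a widely used value) and rely on manual curation of the resulting
candidates; an unattended pipeline cannot, so the default configuration uses
3.0 baseline-SD units — about 21 blurred-noise SDs — which on the synthetic
conditions above yields zero false clusters while sitting far below event
peaks (an amplitude-1 event is ≈ 30 units after blur). The threshold remains
a per-dataset analysis parameter, as it is in interactive practice.

Components smaller than 4 voxels are discarded (`min_voxels`), replacing the
by-eye rejection of flicker noise with a deterministic gate. Temporal
segmentation falls out of 3D 26-connectivity: two events at one site are
distinct when separated by at least one sub-threshold frame. A consequence
worth knowing: event counts are *not* strictly monotone in the threshold for
arbitrary inputs (a bimodal component can split into two as the threshold
rises); for isolated unimodal events monotonicity holds and is tested.

## Localization and traces

The component's brightest voxel seeds an isotropic 2D Gaussian + offset
least-squares fit on a 9 × 9 px patch of the measurement stack at the peak
frame. A failed or out-of-patch fit falls back to the intensity-weighted
centre of mass (flagged); a patch clipped below 3 × 3 px marks the event
unlocalizable and it is dropped. The trace ROI side (1.76 μm) is converted
to the nearest odd pixel count (11 px at 0.16 μm/px) so the centroid pixel
is central.

## Kinetics

Baseline is the mean of up to 20 frames immediately before the event start
(never reaching back past the flash) — a *local* baseline, so events riding
on residual drift are measured correctly. The peak is the maximum sample in
the detected window; crossings of the 20% and 50% levels are linearly
interpolated, giving sub-frame resolution (metrics are reported in ms from
5-ms samples). A decay that never returns to 20% within the trace is
right-censored: flagged, excluded from means, still counted.

The square-event rule quantifies what is normally a by-eye exclusion: an
event is square when it spends more than `plateau_min_ms` (50 ms) at or
above baseline + 0.9 × amplitude. Both knobs are exposed; with the default
waveforms an ordinary puff dwells ≈ 7 ms above that level and a plateau
event > 100 ms, so the rule separates them cleanly. Square events stay in
frequency counts but leave kinetic means, because plateau noise makes their
discrete peak time — and hence rise time — arbitrary.

Cell summaries: latency is flash-to-first-event using peak time (start time
selectable by config; the convention is not universal). The recording
interval runs from the first event's peak to the end of the recording or to
the moment a global fluorescence rise obscures events — supplied explicitly
or auto-estimated as the first time the field-median F/F₀ exceeds 1.5.

## Site clustering

Points are sorted lexicographically (x, then y) for determinism, then
assigned greedily: a point joins the nearest existing site whose *running
centroid* is within 1 μm (ties by site index), and that centroid is updated
to the member mean; otherwise it seeds a new site. Joining at exactly the
radius (a measure-zero case) counts as within. The partition is
order-dependent in principle — the canonical sort fixes the output — and
members are not guaranteed to lie within the radius of the final centroid.

The chain (single-linkage) variant connects any two points within the radius
and takes connected components. It can never produce more sites than the
centroid-update rule and, on dense centroid fields, collapses distinct sites
into one — the documented failure mode the centroid-update rule exists to
avoid. Both partitions are always computed and written, with the
centroid-update one used for site assignment by default.

## Colocalization

LoG detection uses σ = d/(2√2) with d the estimated punctum diameter
(600 nm default). The image mean is subtracted before filtering because the
truncated discrete LoG kernel does not sum exactly to zero and would
otherwise leak a constant-offset response. Local maxima of the
scale-normalized response (−σ²∇²G∗I) above zero are refined by separable
quadratic interpolation (capped at ±0.5 px); quality is the response at the
maximum; the diameter estimate is 2√2 σ_fit from an isotropic Gaussian fit
to the raw image (falling back to the filter scale). Filters are strict:
quality > cutoff, diameter < 600 nm. Quality cutoffs are inherently
per-image (they depend on labelling density and background) and are taken as
parameters.

Manders coefficients use explicit numeric thresholds — reproducibility over
interactive thresholding — with M1 the fraction of channel-A suprathreshold
intensity at pixels where both channels exceed their thresholds, over the
total A suprathreshold intensity (restricting the numerator to the A mask
keeps M ∈ [0, 1] by construction), and M2 the converse. Costes
randomization centre-crops both images to a whole number of 5 × 5 px blocks,
permutes channel B's blocks 100 times, and reports the fraction of
randomizations whose Pearson r does not exceed the observed r (ties count
toward the fraction); p > 0.95 indicates significant colocalization at the
5% level. The permutation stream is seeded, so p is bit-reproducible.

## Statistics

Expression is normalized as 10,000 × F_sample/F_beads against reference-bead
fluorescence recorded under identical settings. Group comparison is the
classical equal-variance Student's t (Welch by flag). The trend test is
Cochran–Armitage with unit-spaced scores (configurable):
χ² = U²/Var(U) with U = Σsⱼn₁ⱼ − R₁Σsⱼcⱼ/N and the (N−1) finite-population
variance, 1 df. It is verified in the tests against an independent
linear-by-linear association implementation.

## Numerical choices and problem sizes

All stacks are processed in float64. Crossing times, Costes p values and
site partitions are deterministic given seeds and the canonical sort.
Degenerate inputs fail loudly and specifically: zero-baseline pixels are
named, empty background regions, oversized rolling-ball radii, out-of-range
flash windows, zero-variance t tests and zero-margin trend tables all raise.

Recovery tests run on a 120 × 120 px, 4000-frame movie (20 s at 200 fps,
10 sites, ~35 events) — large enough that recall/precision of 0.95 are
meaningful and the full pipeline completes in well under a minute — and on
an 80 × 80 px, 1500-frame movie for the shared fixtures. The site-clustering
recovery uses 100 seeded draws of 200 jittered events around 10 true sites.
These sizes are the package's validation conditions, scaled for a desk run;
nothing in the implementation depends on them.

## Known limitations

* Threshold-cluster segmentation cannot split overlapping same-site events;
  frequency is underestimated at high event rates (the simulator's dead time
  makes this explicit rather than hiding it).
* The Gaussian-fit centroid assumes an isotropic spot; strongly elongated
  events fall back to centre-of-mass accuracy.
* Chain-linkage site counts are provided for comparison only and should not
  be used for inference — that is the point of including them.
* The square-event rule is a deterministic stand-in for expert judgement;
  its two parameters should be checked against a sample of traces for any
  new indicator or acquisition rate.
* No drift correction or bleaching correction is applied; movies are assumed
  mechanically stable over tens of seconds.
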