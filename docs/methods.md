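# Methods

`ablatemap` quantifies the spatial footprint of focal high-frequency
irreversible electroporation (H-FIRE) in cortex from dual-channel
two-photon movies: a green calcium indicator (GCaMP6f) reports neuronal
activity and injury, and a red astrocytic dye (SR-101) reports membrane
permeabilization when it appears in neurons. This note documents the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic benchmark does and does not establish.

## Experimental model

The emulated experiment: a recording starts with a 60 s baseline, then a
surface electrode delivers 180 trains of 25 bipolar microsecond pulses at
1 Hz (250 kHz carrier, 150 V — electrical values are carried as metadata
only). Two neuronal response phenotypes follow:

* **Sustained / near field.** Neurons within ~200 um of the electrode
  centre show a fast, large calcium rise that stays elevated for the rest
  of the recording (irreversible membrane damage); these same cells take
  up the red dye. Their fluorescence peaks a few seconds after stimulus
  onset (population mean 5.9 s, SD 1.8 s in the generator defaults), and
  individual cells are first recruited by different trains — none by the
  first train, most by the fourth.
* **Transient / far field.** Beyond the zone, a delayed calcium wave
  produces reversible transients whose onset latency grows linearly with
  distance; the inverse slope is the wave propagation speed.

## Analysis pipeline

### Soma segmentation

The reference image is the pixel-wise mean of the last 20 s of the green
channel, min-max normalized to [0, 1] (an exactly constant average maps
to zeros). It is reflect-padded onto a grid of overlapping 238 x 238
tiles (overlap 32 px, about two soma diameters, so a soma border-cleared
in one tile is interior to a neighbor). Per tile:

1. **Adaptive Wiener filter**, 3 x 3 neighborhood. Local mean mu and
   variance sigma^2 are computed over the border-truncated neighborhood
   (normalizing by the in-image pixel count, so constant images pass
   through unchanged); the output is
   `mu + (sigma^2 - nu^2)/sigma^2 * (a - mu)`, clamped to `mu` wherever
   `sigma^2 <= nu^2`. The noise variance nu^2 defaults to the mean of all
   local variances.
2. **Gaussian smoothing**, sigma 0.5 px, sampled kernel of side
   `2*ceil(2*sigma)+1`, reflective (edge-mirroring) borders.
3. **CLAHE** contrast enhancement, 8 x 8 tile grid, clip limit 0.01
   (unstated in the protocol; these are the common defaults).
4. **Binarization.** Tiles with mean intensity >= 0.1 (the boundary case
   is assigned to this branch) use a local-mean threshold over a window
   of two soma diameters: foreground iff
   `I > local_mean * (1 + margin)`, `margin = 0.5 - 50 * sensitivity`
   with sensitivity 0.006. The mapping from the dimensionless sensitivity
   to the margin is an implementation constant calibrated once on
   noiseless synthetic fixtures. Darker tiles use Otsu's global threshold
   over a 256-bin histogram.
5. **Cleanup.** Border-touching components are removed, holes filled,
   the mask opened with a disk of radius 1 px, and components smaller
   than `pi*(soma_radius_px/2)^2` dropped.
6. **Watershed.** Markers are connected components of
   `distance transform > 0.5 * per-component maximum`; the watershed
   floods the negated distance transform within the mask. The 0.5 marker
   level splits disks whose centres are further apart than ~1.7 radii.
7. **Circularity filter.** Objects with `4*pi*A/P^2 < 0.4` are removed
   (neurites, vessel fragments). The perimeter is the Crofton estimate;
   naive pixel-edge counting systematically understates disk circularity.
   Circularity is clipped at 1.

Detections are mapped to global 0-based (row, col) coordinates;
detections whose centroid falls in the padding are dropped, and centroids
closer than the dedup radius are merged keeping the larger ROI. The
dedup radius defaults to one soma diameter (2 x `soma_radius_px`):
tile-overlap duplicates of the same soma land within ~2 px of each other,
while genuinely adjacent somata are at least a diameter apart — a larger
fixed radius was observed to delete real neighbors. Per-cell traces are
the mean raw intensity over each mask, per frame and channel.

### Trace analysis

Raw traces are smoothed with a 3-point Gaussian window (offsets
{-1,0,+1}, sigma 0.65, normalized; approximately [0.239, 0.522, 0.239])
using reflective ends, then converted to dF/F = (F_t - F0)/F0 with F0 the
mean smoothed fluorescence over the final 9.5 s before stimulus onset
(onset frame = `floor(onset_s * frame_rate)`). An event is called when
any post-stimulus dF/F sample strictly exceeds 15 baseline standard
deviations, with the SD taken over the baseline window of the dF/F series
itself — the threshold is deliberately extreme and essentially never
fires on pure noise. Time-to-peak is the latency from stimulus onset to
the post-stimulus argmax. The first responding train is the earliest
1 Hz train in whose one-second window the dF/F first crosses threshold.

### Plateau detection

Abrupt changes in RMS level are located by exactly minimizing, over all
segmentations, the summed zero-mean RMS log-cost

    chi(x_m..x_n) = (n-m+1) * log( (1/(n-m+1)) * sum_r x_r^2 )

plus a per-changepoint penalty (PELT pruning; lossless for this cost
because merging two segments never costs less than their sum, by
concavity of the log). Numerical decisions:

* the mean square inside the log is floored at 1e-12, which makes an
  all-zero stretch's cost invariant under splitting, so the penalty alone
  decides there;
* the default penalty is the dimensionless BIC-style `2*log(T)`. A
  penalty proportional to the signal's noise *variance* would be
  inconsistent with this cost: the log-cost responds additively, not
  multiplicatively, to rescaling (multiplying the trace by c adds
  `2*log(c)` per sample to every segmentation equally), so a
  variance-scaled penalty of order 1e-4 on dF/F traces would shatter
  every trace. With `2*log(T)`, stationary white noise stays unsplit and
  an order-of-magnitude variance step is located to within a few frames.

The runs between consecutive changepoints (including both trace ends) are
candidate plateaus. A candidate is a plateau iff it is **strictly longer
than 1500 frames** and its signed mean dF/F **strictly exceeds one third
of the trace maximum**. The frame count is normative (1500 frames is
48.5 s at the default 30.9375 Hz frame rate, 150 s at the reduced 10 Hz
benchmark rate).

### Spatial analysis

Distances are Euclidean centroid-to-electrode-centre distances times the
pixel size. A cell is **sustained** iff it has a plateau OR its dF/F five
minutes after stimulus onset (mean over a 5 s window centred there,
clipped to the recording) still exceeds the event threshold — the two
signatures of irreversible damage are combined disjunctively because
either alone marks a cell the experiment would call damaged. The
**ablation radius** is estimated by step-fitting the distance-sorted
sustained indicator: every cut position is scored by its
misclassification count and the estimate is the distance midpoint at the
best cut; a cell-level bootstrap (default 200 resamples) provides a
spread, which blows up when the spatial structure is destroyed (the
estimator's instability diagnostic). The far-field latency-vs-distance
relation is an ordinary least-squares line over responders beyond the
estimated radius; its inverse slope is the wave speed. The per-train
histogram counts cells by first responding train; ties in the argmax
break toward the smallest index. Red uptake is evaluated on the
green-derived ROIs: a neuron is double-labeled iff its red dF/F (against
its own pre-stimulus red baseline) exceeds the event threshold over the
final seconds of the recording, and the cumulative double-labeled count
uses each cell's first sustained crossing.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes and
provides exact ground truth. Somata are Gaussian-tapered disks (flat top
of radius `soma_radius` = 6 um, edge sigma 1 px) placed uniformly outside
the electrode disk without overlap (bounded retries; failure raises a
"field too crowded" error). Geometry lives in pixels; micrometres enter
only via `pixel_size`.

Per-cell kinetics (a dimensionless relative change k(t) multiplying the
resting soma brightness):

* **sustained-near** — the dF/F peak time is drawn from a truncated
  Normal(5.9 s, 1.8 s^2) *measured from stimulus onset* (truncated below
  at the earliest recruitable train plus one frame, so every peak is
  causal), matching how the latency is measured: from the onset of the
  pulsed fields, not from each cell's recruiting train. The recruiting
  train is then drawn from the recruitment pmf conditioned on firing
  before the peak; the fluorescence rises from the recruiting train as a
  fast + slow double-exponential reaching the peak exactly at the drawn
  time, then relaxes to a plateau at 0.8 of peak ("remains elevated"
  is qualitative; 0.8 keeps the plateau above the one-third amplitude
  rule) held to the end of the movie.
* **transient-far** — onset delay `(d - 200 um) / wave_speed` after
  stimulus onset; a difference-of-exponentials pulse (rise 0.2 s, decay
  0.6 s) whose amplitude decays as `exp(-(d - 200)/200 um)`.
* **silent** — a 5% fraction, baseline only.

The recruitment pmf is triangular over trains 2-8 with mode 4 (train 1
never recruits), weights (1, 2, 3, 2.1, 1.3, 0.6, 0.2): the descent is
steep enough that the modal train is resolvable from a few hundred cells,
which is the property the benchmark asserts.

The red channel holds static astrocyte blobs plus, for every
sustained-near cell, a linear uptake ramp from its recruitment time
saturating 180 s later (the experiment gives only a qualitative "3.5
minutes" milestone). Noise is Poisson shot noise (gain
`photons_per_count` = 4) plus Gaussian read noise (SD 2 counts), both
per pixel and reproducible from the scene seed; identical (config, seed)
pairs give bit-identical movies and ground truth.

Free parameters the experiment does not constrain, fixed once and
documented: wave speed 15 um/s (glial calcium waves propagate at roughly
10-30 um/s), far-field amplitude decay length 200 um, near/far peak
relative amplitudes 1.5/1.2, background 20 counts, resting soma
brightness 30 counts. `simulate_traces` generates soma-averaged traces
directly (the same kinetics plus Gaussian noise whose SD equals the
shot + read noise of a soma-sized pixel average) for population-scale
experiments where segmentation is not under test.

**What the benchmark does not show.** The generator has no motion
artifacts, vasculature, neuropil contamination, focal drift,
photobleaching, or spontaneous activity; backgrounds are flat and noise
is white. Passing recovery tests therefore demonstrates the correctness
of the pipeline's logic under its stated assumptions, not robustness to
real-tissue nuisance structure. Real recordings will need the
segmentation sensitivity constant and the changepoint penalty re-examined.

## Benchmark problem sizes

Recovery experiments run at a reduced scale chosen so every timing
relationship the analysis depends on is preserved: 256 px (single-scene,
full pipeline) or 512 px (radius recovery, trace level) fields at
2 um/px, 10 Hz frame rate, 6 simulated minutes, ~200 neurons. At 10 Hz
the 9.5 s baseline spans 95 frames, the 1 Hz train windows span 10
frames, and the post-recruitment sustained segment (~297 s, ~2970 frames)
comfortably exceeds the 1500-frame plateau rule, while a full-rate
30.9375 Hz movie of the same field would be ~3 GB per channel. The
radius-recovery experiment uses the 512 px field so distances span
~0-720 um around the 200 um step.

## Known limitations

* The adaptive-threshold sensitivity mapping is a calibrated constant;
  MATLAB's `imbinarize` sensitivity scale is not public, so only the
  qualitative behaviour (higher sensitivity, more foreground) is matched.
* The step-fit radius estimator assumes a single transition; overlapping
  sustained/transient populations yield a midpoint between error-minimal
  cuts, with the bootstrap CI as the honest uncertainty statement.
* Changepoint detection is exact but O(T)-per-frame after pruning;
  hour-long recordings at resonant rates may want a coarser penalty or
  decimation.
* With fewer than ~10 cells, or a single response class, the radius is
  reported as undefined rather than extrapolated.
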