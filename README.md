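# ablatemap

Analysis of focal electroporation ablation in cortex from two-photon
calcium imaging — soma segmentation, dF/F event detection, plateau
detection and distance-dependent response classification — plus a
synthetic two-channel movie generator with ground truth for every stage.

## The problem

High-frequency irreversible electroporation (H-FIRE) delivered through a
surface microelectrode ablates tissue non-thermally, and the open
question for neural applications is *how focal* the damage is. Dual-color
two-photon imaging answers it optically: a green calcium indicator
(GCaMP6f) reports activity and injury, and a red astrocytic dye (SR-101),
normally excluded from healthy neurons, reports membrane
permeabilization when it appears in neuronal somata. After a 60 s
baseline, 180 pulse trains at 1 Hz produce two neuronal phenotypes:

* **near field** — within a radius *r* of the electrode, calcium rises
  within seconds and stays elevated (irreversible damage), and the red
  dye enters the cells;
* **far field** — beyond *r*, a delayed calcium wave produces reversible
  transients whose peak latency grows linearly with distance *d*
  (slope = 1 / wave speed).

`ablatemap` turns a two-channel movie into per-cell response records and
a population summary: the ablation radius *r̂* (step-fit of the
distance-sorted sustained indicator), the near-field mean time-to-peak,
the far-field latency-vs-distance line, the per-train recruitment
histogram, and the double-labeled (red-uptake) count.

The core trace statistic is dF/F = (F_t − F₀)/F₀ against a 9.5 s
pre-stimulus baseline; events are threshold crossings at 15 baseline SD,
and *sustained* cells are identified by RMS-changepoint segmentation
(segment cost χ(x_m..x_n) = (n−m+1)·log(mean x²), exact penalized
minimization) followed by a duration/amplitude plateau rule (> 1500
frames and mean > ⅓ of the trace maximum). The segmentation stage
reproduces a tiled watershed pipeline: Wiener → Gaussian → CLAHE →
adaptive/Otsu binarization → morphology → distance-transform watershed →
circularity ≥ 0.4, with tile-overlap deduplication. Full details and
defaults are in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a synthetic session, analyze it, and render the figures:

```bash
ablatemap simulate --seed 1 --out scene/ --frame-rate 10 --duration 360
ablatemap analyze --movie scene/ --out results/
ablatemap report --results results/ --out figures/
```

The same from Python:

```python
import ablatemap as am

cfg = am.SceneConfig(frame_rate=10.0, duration=360.0, n_neurons=200, seed=5)
scene = am.generate_scene(cfg)
movie = am.render_movie(scene)
geometry = am.ElectrodeGeometry(cfg.centre_px, cfg.electrode_radius,
                                cfg.pixel_size)
records, summary, labelmap, dff = am.analyze_movie(movie, geometry,
                                                   scene.protocol)
print(f"cells: {summary.n_cells}, responders: {summary.n_responders}")
print(f"near-field time-to-peak: {summary.near_ttp_mean:.2f} "
      f"+/- {summary.near_ttp_sd:.2f} s (n = {summary.n_near})")
print(f"ablation radius: {summary.ablation_radius:.0f} um, "
      f"wave speed: {summary.wave_speed:.1f} um/s")
print(f"peak recruitment train: {summary.peak_train}")
```

which prints (seed 5):

```
cells: 253, responders: 182
near-field time-to-peak: 5.97 +/- 1.68 s (n = 91)
ablation radius: 198 um, wave speed: 14.9 um/s
peak recruitment train: 3
```

Read: 253 somata were segmented from the time-averaged image (200 real,
the rest noise ROIs that never cross the event threshold); of the 182
responders, the 91 inside the estimated 198 um sustained zone peaked
5.97 ± 1.68 s after stimulus onset (the generator draws them at
5.9 ± 1.8 s), and the far-field latency slope inverts to 14.9 um/s
against a configured wave speed of 15 um/s. The full-population
histogram peaks at train 3 here because far-field cells with short wave
delays fall into the earliest train windows; the recruitment pmf itself
(sustained cells only) has its mode at train 4.

`analyze` writes `records.csv` (one row per cell), `summary.json`
(validated against the shipped schema, with a provenance block),
`labels.tif` and `traces.csv`.

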