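"""End-to-end analysis: movie -> per-cell records -> population summary."""

from __future__ import annotations

import numpy as np

from .movie import Movie
from .protocol import StimulusProtocol
from . import plateau as plt_mod
from . import spatial
from . import traces as tr
from .segmentation import (LabelMap, SegmentationParams, extract_traces,
                           reference_image, segment)
from .spatial import (CellResponseRecord, ElectrodeGeometry, PopulationSummary,
                      estimate_ablation_radius, fit_peak_time_vs_distance,
                      train_response_histogram, red_uptake_analysis)

__all__ = ["analyze_movie", "records_from_traces", "summarize"]


def records_from_traces(raw: np.ndarray, centroids: np.ndarray,
                        geometry: ElectrodeGeometry,
                        protocol: StimulusProtocol, frame_rate: float,
                        k_sd: float = tr.DEFAULT_K_SD,
                        min_len: int = plt_mod.DEFAULT_MIN_LEN,
                        amp_fraction: float = plt_mod.DEFAULT_AMP_FRACTION,
                        ) -> tuple[list[CellResponseRecord], np.ndarray]:
    """Per-cell response records from raw green traces.

    ``raw`` is ``(n_cells, T)``; ``centroids`` aligns row-wise. Returns the
    records and the dF/F array. Plateau detection runs only on cells with
    a detected event (silent traces cannot be sustained).
    """
    n_cells, T = raw.shape
    duration = T / frame_rate
    eval_5min_ok = duration >= protocol.stimulus_onset + spatial.FIVE_MIN
    records: list[CellResponseRecord] = []
    dffs = np.empty_like(raw, dtype=float)
    for i in range(n_cells):
        dff, base = tr.compute_dff(raw[i], frame_rate, protocol.stimulus_onset)
        dffs[i] = dff
        event = tr.detect_event(dff, base, frame_rate, protocol.stimulus_onset,
                                k_sd)
        ttp = first = None
        sustained = False
        plateau_ivs: list[tuple[int, int]] = []
        dff5 = None
        if eval_5min_ok:
            dff5 = spatial.dff_at_time(dff, frame_rate,
                                       protocol.stimulus_onset + spatial.FIVE_MIN)
        if event.detected:
            ttp = tr.time_to_peak(event, frame_rate, protocol.stimulus_onset)
            first = tr.first_responding_train(dff, base, protocol, frame_rate,
                                              k_sd)
            flag, call = plt_mod.has_plateau(dff, min_len=min_len,
                                             amp_fraction=amp_fraction)
            plateau_ivs = [(iv.start, iv.stop) for iv in call.plateaus()]
            sustained = spatial.classify_sustained(flag, dff5, base, k_sd)
        records.append(CellResponseRecord(
            cell_id=i + 1,
            distance=spatial.cell_distance(tuple(centroids[i]), geometry),
            responded=event.detected, time_to_peak=ttp, sustained=sustained,
            dff_at_5min=dff5, plateau_intervals=plateau_ivs, first_train=first,
        ))
    return records, dffs


def summarize(records: list[CellResponseRecord],
              protocol: StimulusProtocol) -> PopulationSummary:
    """Aggregate per-cell records into the population summary."""
    n_resp = sum(r.responded for r in records)
    radius = ci = None
    try:
        est = estimate_ablation_radius(records)
        radius, ci = est.radius_, est.ci_
    except ValueError:
        pass
    near_mean = near_sd = None
    n_near = 0
    if radius is not None:
        near_ttp = [r.time_to_peak for r in records
                    if r.responded and r.time_to_peak is not None
                    and r.distance <= radius]
        n_near = len(near_ttp)
        if n_near:
            near_mean = float(np.mean(near_ttp))
            near_sd = float(np.std(near_ttp, ddof=1)) if n_near > 1 else 0.0
    slope = intercept = speed = None
    if radius is not None:
        try:
            fit = fit_peak_time_vs_distance(records, radius)
            slope, intercept = fit.slope_, fit.intercept_
            speed = float(fit.wave_speed_)
        except ValueError:
            pass
    counts, peak_train = train_response_histogram(records, protocol.n_trains)
    return PopulationSummary(
        n_cells=len(records), n_responders=n_resp,
        near_ttp_mean=near_mean, near_ttp_sd=near_sd, n_near=n_near,
        ablation_radius=radius, ablation_radius_ci=ci,
        far_slope=slope, far_intercept=intercept, wave_speed=speed,
        train_counts=[int(c) for c in counts], peak_train=peak_train,
        n_double_labeled=sum(r.red_uptake for r in records),
    )


def analyze_movie(movie: Movie, geometry: ElectrodeGeometry,
                  protocol: StimulusProtocol | None = None,
                  seg_params: SegmentationParams | None = None,
                  labelmap: LabelMap | None = None,
                  k_sd: float = tr.DEFAULT_K_SD,
                  ) -> tuple[list[CellResponseRecord], PopulationSummary,
                             LabelMap, np.ndarray]:
    """Full pipeline on a two-channel movie.

    Segments the time-averaged green reference image (unless a label map
    is supplied), extracts per-cell traces, derives dF/F, events, peak
    latencies, plateaus, 5-min persistence and red uptake, and aggregates
    the population summary. Returns
    ``(records, summary, labelmap, dff array)``.
    """
    if protocol is None:
        protocol = StimulusProtocol()
    if seg_params is None:
        seg_params = SegmentationParams()
    if labelmap is None:
        ref = reference_image(movie, seg_params.averaging_window)
        labelmap = segment(ref, seg_params)
    raw = extract_traces(movie, labelmap, "green")
    centroids = labelmap.centroids()
    records, dffs = records_from_traces(raw, centroids, geometry, protocol,
                                        movie.frame_rate, k_sd)
    if movie.red is not None and labelmap.n_cells:
        red_raw = extract_traces(movie, labelmap, "red")
        red_dff = np.empty_like(red_raw)
        red_bases = []
        for i in range(red_raw.shape[0]):
            rdff, rbase = tr.compute_dff(red_raw[i], movie.frame_rate,
                                         protocol.stimulus_onset)
            red_dff[i] = rdff
            red_bases.append(rbase)
        flags, _ = red_uptake_analysis(red_dff, red_bases, movie.frame_rate,
                                       protocol, k_sd)
        for rec, f in zip(records, flags):
            rec.red_uptake = bool(f)
    summary = summarize(records, protocol)
    return records, summary, labelmap, dffs
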