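"""Synthetic two-channel calcium-imaging movies with ground truth.

Emulates the phenomenology of focal high-frequency electroporation in
cortex seen through a two-photon microscope: a near-electrode population
whose calcium rises fast and stays elevated (irreversible damage, plus
uptake of the normally astrocyte-only red dye), a far population showing a
delayed, transient calcium wave whose onset latency grows linearly with
distance, and silent cells. The generator produces both rendered movies
(for testing segmentation) and per-cell raw fluorescence traces (for
testing trace analysis at population scale), together with machine-
readable ground truth.

Geometry is kept in pixels internally; micrometres enter only through
``pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .movie import Movie
from .protocol import StimulusProtocol

__all__ = [
    "SceneConfig",
    "GroundTruthCell",
    "SyntheticScene",
    "generate_scene",
    "cell_kinetics",
    "render_movie",
    "simulate_traces",
]

# Classes a generated cell can belong to.
SUSTAINED_NEAR = "sustained-near"
TRANSIENT_FAR = "transient-far"
SILENT = "silent"

# Sustained-rise shape: fast + slow exponential components (weights sum to 1)
# expressed on the normalized rise interval [0, 1].
_RISE_TAUS = (0.1, 0.5)
_RISE_WEIGHTS = (0.5, 0.5)
_PLATEAU_TAU = 5.0  # s, relaxation from peak down to the plateau level


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic imaging session.

    Defaults encode the recording conditions of the emulated experiment:
    resonant scanning at 30.9375 Hz, stimulation starting after a 60 s
    baseline (see :class:`~ablatemap.protocol.StimulusProtocol`), sustained
    near-field responses peaking ``near_peak_mean`` = 5.9 s (SD 1.8 s)
    after stimulus onset, and a 200 um ablation radius. Quantities the
    experiment does not constrain (wave speed, transient amplitudes, noise
    levels) are free parameters; see docs/methods.md for the rationale
    behind each default.
    """

    field_height: int = 256
    field_width: int = 256
    pixel_size: float = 2.0  # um / px
    frame_rate: float = 30.9375  # Hz
    duration: float = 360.0  # s
    n_neurons: int = 200
    soma_radius: float = 6.0  # um
    electrode_center: tuple[float, float] | None = None  # (row, col) px; None -> centre
    electrode_radius: float = 25.0  # um
    ablation_radius: float = 200.0  # um
    near_peak_mean: float = 5.9  # s from stimulus onset
    near_peak_sd: float = 1.8  # s
    # P(recruiting train = k) for k = 1..len(weights); train 1 never recruits.
    # Triangular over trains 2-8 with mode 4 and a descent steep enough that
    # the mode is resolvable from a few hundred cells.
    recruitment_weights: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 2.1, 1.3, 0.6, 0.2)
    wave_speed: float = 15.0  # um/s, far-field onset delay slope
    gcamp_rise_tau: float = 0.2  # s, transient kernel
    gcamp_decay_tau: float = 0.6  # s
    transient_amplitude_decay_length: float = 200.0  # um
    near_peak_dff: float = 1.5  # peak relative change of near cells
    far_peak_dff: float = 1.2  # far-cell peak relative change at the zone edge
    plateau_fraction: float = 0.8  # sustained level as a fraction of peak
    silent_fraction: float = 0.05
    n_astrocytes: int = 15
    astrocyte_radius: float = 8.0  # um
    background: float = 20.0  # green background, counts
    cell_baseline: float = 30.0  # resting soma brightness over background, counts
    red_background: float = 5.0
    astrocyte_brightness: float = 40.0
    red_uptake_amplitude: float = 12.0  # asymptotic neuronal red gain, counts
    red_ramp_duration: float = 180.0  # s from recruitment to full uptake
    photons_per_count: float = 4.0  # shot-noise gain; 0 disables shot noise
    read_noise_sd: float = 2.0  # counts; 0 disables read noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size", "frame_rate", "duration", "soma_radius",
            "ablation_radius", "near_peak_mean", "near_peak_sd", "wave_speed",
            "gcamp_rise_tau", "gcamp_decay_tau",
            "transient_amplitude_decay_length", "astrocyte_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.electrode_radius < 0:
            raise ValueError("electrode_radius must be nonnegative")
        if not 0 <= self.silent_fraction < 1:
            raise ValueError("silent_fraction must be in [0, 1)")
        w = np.asarray(self.recruitment_weights, dtype=float)
        if w.ndim != 1 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("recruitment_weights must be nonnegative with positive sum")

    @property
    def recruitment_pmf(self) -> np.ndarray:
        """Normalized recruitment probabilities over trains ``1..len(weights)``."""
        w = np.asarray(self.recruitment_weights, dtype=float)
        return w / w.sum()

    @property
    def centre_px(self) -> tuple[float, float]:
        if self.electrode_center is not None:
            return self.electrode_center
        return (self.field_height / 2.0, self.field_width / 2.0)

    @property
    def soma_radius_px(self) -> float:
        return self.soma_radius / self.pixel_size

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class GroundTruthCell:
    """True state of one generated neuron."""

    id: int
    centroid: tuple[float, float]  # (row, col) px
    distance_to_electrode: float  # um, centroid to electrode centre
    cls: str  # sustained-near | transient-far | silent
    recruitment_train: int | None  # 1-based, responsive cells only
    true_onset: float | None  # s, start of the fluorescence rise
    true_peak_time: float | None  # s, time of the dF/F maximum
    red_uptake: bool


@dataclass
class SyntheticScene:
    """A generated scene: configuration, ground truth and true masks."""

    config: SceneConfig
    protocol: StimulusProtocol
    cells: list[GroundTruthCell]
    astrocytes: np.ndarray  # (n, 2) float px
    label_image: np.ndarray  # uint16, 0 background, k = cell id k

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cells_of_class(self, cls: str) -> list[GroundTruthCell]:
        return [c for c in self.cells if c.cls == cls]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float) -> float:
    """Rejection-sample N(mean, sd^2) conditioned on x >= lower."""
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    # Pathological truncation (lower far above the mean): fall back to the bound.
    return float(lower)


def _place_points(rng: np.random.Generator, n: int, config: SceneConfig,
                  radius_px: float, existing: np.ndarray | None = None,
                  min_sep: float | None = None) -> np.ndarray:
    """Uniformly place ``n`` non-overlapping points outside the electrode disk."""
    margin = float(np.ceil(radius_px)) + 2.0
    lo_r, hi_r = margin, config.field_height - margin
    lo_c, hi_c = margin, config.field_width - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("field too small for the requested soma radius")
    sep = (2.0 * radius_px + 2.0) if min_sep is None else min_sep
    cr, cc = config.centre_px
    elec_px = config.electrode_radius / config.pixel_size
    pts: list[tuple[float, float]] = []
    others = existing if existing is not None else np.empty((0, 2))
    max_tries = 1000 * max(n, 1)
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} objects after {max_tries} attempts: "
                "field too crowded"
            )
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if np.hypot(r - cr, c - cc) < elec_px + radius_px:
            continue
        all_pts = np.vstack([others, np.asarray(pts).reshape(-1, 2)])
        if all_pts.size and np.min(np.hypot(all_pts[:, 0] - r, all_pts[:, 1] - c)) < sep:
            continue
        pts.append((r, c))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def generate_scene(config: SceneConfig,
                   protocol: StimulusProtocol | None = None) -> SyntheticScene:
    """Generate ground truth for one synthetic imaging session.

    Somata are placed uniformly outside the electrode disk without
    overlap. Cells within ``ablation_radius`` of the electrode centre (and
    not silent) become sustained-near responders: their dF/F peak time is
    drawn from a truncated Normal(``near_peak_mean``, ``near_peak_sd``^2)
    measured from stimulus onset, and their recruiting train is drawn from
    the recruitment pmf restricted to trains that fire before the peak.
    Cells beyond the radius become transient-far responders with onset
    delay ``(d - ablation_radius) / wave_speed``.

    Raises
    ------
    RuntimeError
        If non-overlapping placement fails after bounded retries.
    """
    if protocol is None:
        protocol = StimulusProtocol()
    rng = np.random.default_rng(config.seed)
    r_px = config.soma_radius_px
    pos = _place_points(rng, config.n_neurons, config, r_px)
    pmf = config.recruitment_pmf
    trains = np.arange(1, len(pmf) + 1)
    # Earliest recruitable train bounds the peak-time draw from below
    # (plus one frame period, so every peak is causal).
    recruitable = trains[pmf > 0]
    if recruitable.size == 0 and config.n_neurons > 0:
        raise ValueError("recruitment pmf has no positive mass")
    frame = 1.0 / config.frame_rate
    earliest_offset = (
        float(recruitable.min() - 1) / protocol.train_rate if recruitable.size else 0.0
    )

    cells: list[GroundTruthCell] = []
    transient_peak_lag = _transient_peak_lag(config)
    for i in range(config.n_neurons):
        r, c = pos[i]
        d_um = float(np.hypot(r - config.centre_px[0], c - config.centre_px[1])
                     * config.pixel_size)
        if rng.random() < config.silent_fraction:
            cells.append(GroundTruthCell(i + 1, (r, c), d_um, SILENT,
                                         None, None, None, False))
            continue
        if d_um <= config.ablation_radius:
            peak_delay = _truncated_normal(
                rng, config.near_peak_mean, config.near_peak_sd,
                lower=earliest_offset + 2 * frame,
            )
            peak_t = protocol.stimulus_onset + peak_delay
            # Recruiting train must fire at least two frames before the peak.
            offsets = (trains - 1) / protocol.train_rate
            ok = (pmf > 0) & (offsets <= peak_delay - 2 * frame)
            if not ok.any():
                ok = trains == recruitable.min()
            p = pmf * ok
            k = int(rng.choice(trains, p=p / p.sum()))
            onset = protocol.train_time(k)
            cells.append(GroundTruthCell(i + 1, (r, c), d_um, SUSTAINED_NEAR,
                                         k, onset, peak_t, True))
        else:
            onset = (protocol.stimulus_onset
                     + (d_um - config.ablation_radius) / config.wave_speed)
            k = _train_containing(onset, protocol)
            cells.append(GroundTruthCell(i + 1, (r, c), d_um, TRANSIENT_FAR,
                                         k, onset, onset + transient_peak_lag,
                                         False))

    astro = (
        _place_points(rng, config.n_astrocytes, config,
                      config.astrocyte_radius / config.pixel_size, existing=pos)
        if config.n_astrocytes else np.empty((0, 2))
    )
    label = _paint_labels(config, pos)
    return SyntheticScene(config, protocol, cells, astro, label)


def _train_containing(t: float, protocol: StimulusProtocol) -> int | None:
    """1-based train whose window [t_k, t_{k+1}) contains time ``t``."""
    if t < protocol.stimulus_onset or t >= protocol.stimulus_end:
        return None
    return int((t - protocol.stimulus_onset) * protocol.train_rate) + 1


def _transient_peak_lag(config: SceneConfig) -> float:
    """Peak offset of the difference-of-exponentials transient kernel."""
    tr, td = config.gcamp_rise_tau, config.gcamp_decay_tau
    return tr * td / (td - tr) * np.log(td / tr)


def _paint_labels(config: SceneConfig, pos: np.ndarray) -> np.ndarray:
    label = np.zeros((config.field_height, config.field_width), dtype=np.uint16)
    rr, cc = np.mgrid[: config.field_height, : config.field_width]
    r_px = config.soma_radius_px
    for i, (r, c) in enumerate(pos):
        lo_r = max(int(r - r_px - 2), 0)
        hi_r = min(int(r + r_px + 3), config.field_height)
        lo_c = max(int(c - r_px - 2), 0)
        hi_c = min(int(c + r_px + 3), config.field_width)
        d = np.hypot(rr[lo_r:hi_r, lo_c:hi_c] - r, cc[lo_r:hi_r, lo_c:hi_c] - c)
        label[lo_r:hi_r, lo_c:hi_c][d <= r_px] = i + 1
    return label


def cell_kinetics(cell: GroundTruthCell, protocol: StimulusProtocol,
                  config: SceneConfig) -> np.ndarray:
    """Noiseless relative fluorescence change ``k(t)`` of one cell.

    The rendered soma intensity is ``cell_baseline * (1 + k(t))``, so
    ``k`` is the cell's true dF/F up to the background dilution of the
    measured trace.

    * sustained-near: double-exponential rise (fast + slow component) from
      the recruiting train to the peak at ``true_peak_time``, then
      relaxation to ``plateau_fraction`` of the peak, held to the end;
    * transient-far: difference-of-exponentials pulse at ``true_onset``
      with amplitude decaying exponentially in distance beyond the zone;
    * silent: zeros.
    """
    t = config.times()
    k = np.zeros_like(t)
    if cell.cls == SILENT:
        return k
    if cell.cls == SUSTAINED_NEAR:
        rec, peak = cell.true_onset, cell.true_peak_time
        span = max(peak - rec, 2.0 / config.frame_rate)
        amp = config.near_peak_dff
        u = (t - rec) / span
        rising = (t >= rec) & (t <= peak)
        g = np.zeros_like(t)
        norm = sum(w * (1 - np.exp(-1.0 / tau))
                   for w, tau in zip(_RISE_WEIGHTS, _RISE_TAUS))
        for w, tau in zip(_RISE_WEIGHTS, _RISE_TAUS):
            g[rising] += w * (1 - np.exp(-u[rising] / tau))
        k[rising] = amp * g[rising] / norm
        after = t > peak
        plateau = config.plateau_fraction * amp
        k[after] = plateau + (amp - plateau) * np.exp(-(t[after] - peak) / _PLATEAU_TAU)
        return k
    # transient-far
    o = cell.true_onset
    tr, td = config.gcamp_rise_tau, config.gcamp_decay_tau
    amp = config.far_peak_dff * np.exp(
        -(cell.distance_to_electrode - config.ablation_radius)
        / config.transient_amplitude_decay_length
    )
    dt = t - o
    live = dt >= 0
    kern = np.exp(-dt[live] / td) - np.exp(-dt[live] / tr)
    peak_val = (np.exp(-_transient_peak_lag(config) / td)
                - np.exp(-_transient_peak_lag(config) / tr))
    k[live] = amp * kern / peak_val
    return k


def _soma_profile(config: SceneConfig, r: float, c: float,
                  radius_px: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-tapered disk: flat top of ``radius_px``, edge sigma 1 px.

    Returns flat (rows, cols, weights) arrays restricted to the field.
    """
    lo_r = max(int(np.floor(r - radius_px - 4)), 0)
    hi_r = min(int(np.ceil(r + radius_px + 5)), config.field_height)
    lo_c = max(int(np.floor(c - radius_px - 4)), 0)
    hi_c = min(int(np.ceil(c + radius_px + 5)), config.field_width)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    d = np.hypot(rr - r, cc - c)
    w = np.exp(-0.5 * np.clip(d - radius_px, 0, None) ** 2)
    keep = w > 1e-4
    return rr[keep].ravel(), cc[keep].ravel(), w[keep].ravel()


def render_movie(scene: SyntheticScene, noise: bool | None = None) -> Movie:
    """Render a scene into a two-channel movie.

    Green = background + sum of soma profiles x kinetics, with Poisson
    shot noise (gain ``photons_per_count``) and Gaussian read noise.
    Red = static astrocyte blobs plus a linear uptake ramp, starting at
    each red-uptake cell's recruitment and saturating ``red_ramp_duration``
    seconds later. Deterministic given ``config.seed``.

    Set ``noise=False`` to disable both noise sources regardless of config.
    """
    cfg = scene.config
    T = cfg.n_frames
    t = cfg.times()
    green = np.full((T, cfg.field_height, cfg.field_width), cfg.background,
                    dtype=np.float32)
    red_static = np.full((cfg.field_height, cfg.field_width), cfg.red_background,
                         dtype=np.float32)
    a_px = cfg.astrocyte_radius / cfg.pixel_size
    for r, c in scene.astrocytes:
        rows, cols, w = _soma_profile(cfg, r, c, a_px)
        red_static[rows, cols] += cfg.astrocyte_brightness * w.astype(np.float32)
    red = np.broadcast_to(red_static, (T,) + red_static.shape).copy()

    r_px = cfg.soma_radius_px
    for cell in scene.cells:
        rows, cols, w = _soma_profile(cfg, *cell.centroid, r_px)
        k = cell_kinetics(cell, scene.protocol, cfg)
        f = (cfg.cell_baseline * (1.0 + k)).astype(np.float32)
        green[:, rows, cols] += f[:, None] * w[None, :].astype(np.float32)
        if cell.red_uptake and cell.true_onset is not None:
            ramp = np.clip((t - cell.true_onset) / cfg.red_ramp_duration, 0, 1)
            red[:, rows, cols] += (
                (cfg.red_uptake_amplitude * ramp).astype(np.float32)[:, None]
                * w[None, :].astype(np.float32)
            )

    if noise is None:
        noise = cfg.photons_per_count > 0 or cfg.read_noise_sd > 0
    if noise:
        rng = np.random.default_rng([cfg.seed, 7])
        for stack in (green, red):
            for lo in range(0, T, 128):  # chunked to bound peak memory
                hi = min(lo + 128, T)
                block = stack[lo:hi]
                if cfg.photons_per_count > 0:
                    block[:] = (
                        rng.poisson(block * cfg.photons_per_count)
                        / cfg.photons_per_count
                    ).astype(np.float32)
                if cfg.read_noise_sd > 0:
                    block += rng.normal(
                        0, cfg.read_noise_sd, block.shape
                    ).astype(np.float32)
    return Movie(green=green, red=red, frame_rate=cfg.frame_rate,
                 pixel_size=cfg.pixel_size,
                 meta={"seed": cfg.seed, "synthetic": True})


def simulate_traces(scene: SyntheticScene, noise: bool = True) -> np.ndarray:
    """Per-cell raw fluorescence traces without rendering a movie.

    Returns an ``(n_cells, T)`` array of soma-averaged fluorescence
    matching what :func:`~ablatemap.segmentation.extract_traces` would
    measure on a rendered movie with the true masks: ``background +
    cell_baseline * (1 + k(t))`` plus Gaussian noise whose SD is the
    shot + read noise of a soma-sized pixel average. Used for
    population-scale experiments where segmentation is not under test.
    """
    cfg = scene.config
    rng = np.random.default_rng([cfg.seed, 11])
    n_px = max(np.pi * cfg.soma_radius_px**2, 1.0)
    out = np.empty((scene.n_cells, cfg.n_frames))
    for i, cell in enumerate(scene.cells):
        f = cfg.background + cfg.cell_baseline * (
            1.0 + cell_kinetics(cell, scene.protocol, cfg)
        )
        if noise:
            shot_var = f / cfg.photons_per_count if cfg.photons_per_count > 0 else 0.0
            sd = np.sqrt((shot_var + cfg.read_noise_sd**2) / n_px)
            f = f + rng.normal(0, 1, f.shape) * sd
        out[i] = f
    return out


def noiseless(config: SceneConfig) -> SceneConfig:
    """Copy of ``config`` with both noise sources disabled."""
    return replace(config, photons_per_count=0.0, read_noise_sd=0.0)
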