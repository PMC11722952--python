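"""Population-level spatial analyses around the stimulating electrode.

Maps each segmented cell to its distance from the electrode centre,
classifies sustained versus transient responders, estimates the radius of
the sustained (ablation) zone by step-fitting the distance-sorted
sustained indicator, fits peak latency versus distance in the far field
(whose inverse slope is the calcium-wave speed), builds the per-train
recruitment histogram, and quantifies red-channel (membrane
permeabilization) dye uptake on the green-derived ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .protocol import StimulusProtocol
from .traces import BaselineStats, DEFAULT_K_SD

__all__ = [
    "ElectrodeGeometry",
    "CellResponseRecord",
    "PopulationSummary",
    "cell_distance",
    "dff_at_time",
    "classify_sustained",
    "estimate_ablation_radius",
    "AblationRadiusEstimator",
    "fit_peak_time_vs_distance",
    "PeakTimeDistanceFit",
    "train_response_histogram",
    "red_uptake_analysis",
]

FIVE_MIN = 300.0  # s, evaluation time for persistent fluorescence
FIVE_MIN_WINDOW = 5.0  # s, averaging window centred on the evaluation time


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Stimulating electrode position and size."""

    center: tuple[float, float]  # (row, col) px
    radius: float  # um
    pixel_size: float  # um / px

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("electrode radius must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class CellResponseRecord:
    """Derived per-cell quantities feeding the population summary."""

    cell_id: int
    distance: float  # um, centroid to electrode centre
    responded: bool
    time_to_peak: float | None  # s from stimulus onset
    sustained: bool
    dff_at_5min: float | None
    plateau_intervals: list[tuple[int, int]] = field(default_factory=list)
    first_train: int | None = None
    red_uptake: bool = False


@dataclass
class PopulationSummary:
    """Headline numbers of one analyzed recording."""

    n_cells: int
    n_responders: int
    near_ttp_mean: float | None  # s, cells inside the estimated radius
    near_ttp_sd: float | None
    n_near: int
    ablation_radius: float | None  # um
    ablation_radius_ci: tuple[float, float] | None  # bootstrap 95%
    far_slope: float | None  # s / um
    far_intercept: float | None  # s
    wave_speed: float | None  # um / s
    train_counts: list[int] = field(default_factory=list)
    peak_train: int | None = None
    n_double_labeled: int = 0


def cell_distance(centroid: tuple[float, float],
                  geometry: ElectrodeGeometry) -> float:
    """Euclidean centroid-to-electrode-centre distance in micrometres."""
    dr = centroid[0] - geometry.center[0]
    dc = centroid[1] - geometry.center[1]
    return float(np.hypot(dr, dc) * geometry.pixel_size)


def dff_at_time(dff: np.ndarray, frame_rate: float, at: float,
                window: float = FIVE_MIN_WINDOW) -> float:
    """Mean dF/F over a window centred at time ``at`` (clipped to the trace)."""
    dff = np.asarray(dff, dtype=float)
    lo = max(int(np.floor((at - window / 2) * frame_rate)), 0)
    hi = min(int(np.ceil((at + window / 2) * frame_rate)), dff.size)
    if hi <= lo:
        raise ValueError(f"evaluation time {at} s outside the recording")
    return float(dff[lo:hi].mean())


def classify_sustained(has_plateau: bool, dff_at_5min: float | None,
                       baseline: BaselineStats,
                       k_sd: float = DEFAULT_K_SD) -> bool:
    """Sustained iff a plateau was called OR the 5-min dF/F stays above threshold.

    The two signatures of irreversible damage — a long high-amplitude
    plateau and fluorescence still elevated five minutes after stimulus
    onset — are combined disjunctively.
    """
    if has_plateau:
        return True
    if dff_at_5min is None:
        return False
    return dff_at_5min > k_sd * baseline.sd_dff


class AblationRadiusEstimator(BaseEstimator):
    """Step-fit of the distance-sorted sustained indicator.

    Cells are sorted by distance; every cut position is scored by its
    misclassification count (non-sustained inside + sustained outside),
    and the estimate is the distance midpoint at the best cut. A
    bootstrap over cells gives a spread estimate (``ci_``); a wide CI
    flags an unstable step (e.g. shuffled labels).
    """

    def __init__(self, n_bootstrap: int = 200, random_state: int = 0):
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    @staticmethod
    def _step_fit(d: np.ndarray, s: np.ndarray) -> float:
        order = np.argsort(d)
        d, s = d[order], s[order].astype(int)
        n = d.size
        # errors(i): cut between i-1 and i -> first i cells called sustained
        inside_wrong = np.concatenate([[0], np.cumsum(1 - s)])
        outside_wrong = s.sum() - np.concatenate([[0], np.cumsum(s)])
        errors = inside_wrong + outside_wrong
        i = int(np.argmin(errors))
        if i == 0:
            return float(d[0] / 2.0)
        if i == n:
            return float(d[-1])
        return float((d[i - 1] + d[i]) / 2.0)

    def fit(self, distances: np.ndarray, sustained: np.ndarray
            ) -> "AblationRadiusEstimator":
        d = np.asarray(distances, dtype=float)
        s = np.asarray(sustained, dtype=bool)
        if d.size != s.size:
            raise ValueError("distances and sustained flags must align")
        if d.size < 10:
            raise ValueError("need at least 10 cells for a radius estimate")
        if s.all() or not s.any():
            raise ValueError(
                "radius undefined: population contains a single response class"
            )
        self.radius_ = self._step_fit(d, s)
        rng = np.random.default_rng(self.random_state)
        boot = []
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, d.size, d.size)
            if s[idx].all() or not s[idx].any():
                continue
            boot.append(self._step_fit(d[idx], s[idx]))
        if boot:
            self.bootstrap_ = np.asarray(boot)
            self.ci_ = (float(np.percentile(boot, 2.5)),
                        float(np.percentile(boot, 97.5)))
        else:
            self.bootstrap_ = np.empty(0)
            self.ci_ = (np.nan, np.nan)
        return self

    def predict(self, distances: np.ndarray) -> np.ndarray:
        """Predicted sustained flag: inside the fitted radius."""
        return np.asarray(distances, dtype=float) <= self.radius_


def estimate_ablation_radius(records: list[CellResponseRecord],
                             n_bootstrap: int = 200,
                             random_state: int = 0) -> AblationRadiusEstimator:
    """Fit the step estimator on a list of per-cell records."""
    d = np.asarray([r.distance for r in records])
    s = np.asarray([r.sustained for r in records])
    return AblationRadiusEstimator(n_bootstrap, random_state).fit(d, s)


class PeakTimeDistanceFit(BaseEstimator):
    """Least-squares line of peak latency on distance, far field only.

    ``fit`` expects distances (um) and times-to-peak (s) of responders
    beyond the sustained zone. ``wave_speed_`` is ``1 / slope_`` when the
    slope is positive.
    """

    def fit(self, distances: np.ndarray, times: np.ndarray
            ) -> "PeakTimeDistanceFit":
        d = np.asarray(distances, dtype=float)
        t = np.asarray(times, dtype=float)
        if d.size < 3:
            raise ValueError("need at least 3 far-field responders")
        if np.ptp(d) == 0:
            raise ValueError("degenerate distance spread; line fit undefined")
        res = sps.linregress(d, t)
        self.slope_ = float(res.slope)  # s / um
        self.intercept_ = float(res.intercept)  # s
        self.stderr_ = float(res.stderr)
        self.rvalue_ = float(res.rvalue)
        self.wave_speed_ = 1.0 / res.slope if res.slope > 0 else np.nan
        return self

    def predict(self, distances: np.ndarray) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(distances, dtype=float)


def fit_peak_time_vs_distance(records: list[CellResponseRecord],
                              radius: float) -> PeakTimeDistanceFit:
    """Fit latency-vs-distance on responders beyond ``radius``."""
    far = [r for r in records
           if r.responded and r.time_to_peak is not None and r.distance > radius]
    d = np.asarray([r.distance for r in far])
    t = np.asarray([r.time_to_peak for r in far])
    return PeakTimeDistanceFit().fit(d, t)


def train_response_histogram(records: list[CellResponseRecord],
                             n_trains: int) -> tuple[np.ndarray, int | None]:
    """New-responder counts per train and the (1-based) argmax train.

    ``counts[k-1]`` is the number of cells whose first threshold crossing
    fell in train ``k``'s window. Ties break toward the smallest index;
    with no responders the argmax is None.
    """
    counts = np.zeros(n_trains, dtype=int)
    for r in records:
        if r.first_train is not None and 1 <= r.first_train <= n_trains:
            counts[r.first_train - 1] += 1
    if counts.sum() == 0:
        return counts, None
    return counts, int(np.argmax(counts)) + 1


def red_uptake_analysis(red_dff: np.ndarray,
                        red_baselines: list[BaselineStats],
                        frame_rate: float,
                        protocol: StimulusProtocol,
                        k_sd: float = DEFAULT_K_SD,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Red-dye uptake on neuronal (green-derived) ROIs.

    ``red_dff`` is ``(n_cells, T)`` of red-channel dF/F against each
    cell's pre-stimulus red baseline. A cell is double-labeled iff its
    red dF/F exceeds the event threshold at the end of the recording.
    Returns ``(uptake flags, cumulative double-labeled count per frame)``;
    the cumulative count uses each cell's first sustained crossing.
    """
    red_dff = np.atleast_2d(np.asarray(red_dff, dtype=float))
    n_cells, T = red_dff.shape
    if n_cells != len(red_baselines):
        raise ValueError("one baseline per red trace is required")
    flags = np.zeros(n_cells, dtype=bool)
    first_cross = np.full(n_cells, -1, dtype=int)
    for i in range(n_cells):
        thr = k_sd * red_baselines[i].sd_dff
        # Evaluate uptake on the final seconds, where the ramp has settled.
        tail = red_dff[i, max(T - int(5 * frame_rate), 0):]
        flags[i] = bool(tail.mean() > thr)
        if flags[i]:
            above = np.flatnonzero(red_dff[i] > thr)
            first_cross[i] = int(above[0]) if above.size else T - 1
    cumulative = np.zeros(T, dtype=int)
    for i in np.flatnonzero(flags):
        cumulative[first_cross[i]:] += 1
    return flags, cumulative
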