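"""Plateau detection on dF/F traces via RMS-level changepoints.

A changepoint is a frame at which the root-mean-square level of the trace
changes abruptly. Each candidate segment x_m..x_n is scored with the
zero-mean RMS log-cost

    chi(x_m..x_n) = (n - m + 1) * log( (1/(n - m + 1)) * sum x_r^2 )

and a segmentation is chosen by exactly minimizing total cost plus a
per-changepoint penalty (pruned exact dynamic programming, PELT; the
pruning is lossless for this cost because merging two segments never
costs less than their sum). The stretches between consecutive
changepoints are candidate plateaus; a candidate is a plateau iff it is
strictly longer than ``min_len`` frames (default 1500) AND its mean
amplitude strictly exceeds ``amp_fraction`` (default 1/3) of the signal
maximum.

Zero-energy segments would make the log diverge; the mean square is
floored at ``EPS`` = 1e-12, which leaves the cost of an all-zero stretch
invariant under splitting (so the penalty alone decides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "EPS",
    "ChangepointModel",
    "Interval",
    "PlateauCall",
    "segment_cost",
    "default_penalty",
    "find_changepoints",
    "call_plateaus",
    "has_plateau",
    "RmsChangepointDetector",
]

EPS = 1e-12

DEFAULT_MIN_LEN = 1500  # frames; the frame count is normative
DEFAULT_AMP_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class ChangepointModel:
    """Changepoint search configuration (RMS cost only)."""

    cost: str = "rms"
    penalty: float | None = None  # None -> 2 * log(T)
    max_changepoints: int | None = None

    def __post_init__(self) -> None:
        if self.cost != "rms":
            raise ValueError("only the 'rms' cost is implemented")
        if self.penalty is not None and self.penalty < 0:
            raise ValueError("penalty must be nonnegative")


@dataclass(frozen=True)
class Interval:
    """Half-open candidate interval [start, stop) with its mean level."""

    start: int
    stop: int
    mean_amplitude: float

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class PlateauCall:
    """Candidate intervals of one trace with their plateau flags."""

    intervals: list[Interval]
    flags: list[bool]
    min_len: int = DEFAULT_MIN_LEN
    amp_fraction: float = DEFAULT_AMP_FRACTION

    @property
    def any_plateau(self) -> bool:
        return any(self.flags)

    def plateaus(self) -> list[Interval]:
        return [iv for iv, f in zip(self.intervals, self.flags) if f]


def segment_cost(signal: np.ndarray, m: int, n: int) -> float:
    """RMS log-cost of the inclusive segment ``signal[m..n]``.

    ``(n - m + 1) * log(mean of squares)``, with the mean square floored
    at EPS. Raises on an empty segment.
    """
    x = np.asarray(signal, dtype=float)
    if not 0 <= m <= n < x.size:
        raise ValueError(f"invalid segment [{m}, {n}] for length {x.size}")
    k = n - m + 1
    return k * np.log(max(np.sum(x[m:n + 1] ** 2) / k, EPS))


def default_penalty(n: int) -> float:
    """BIC-style per-changepoint penalty, 2*log(T)."""
    return 2.0 * np.log(max(n, 2))


def find_changepoints(signal: np.ndarray,
                      model: ChangepointModel | None = None,
                      penalty: float | None = None) -> list[int]:
    """Exact penalized minimization of the summed RMS log-cost.

    Returns strictly increasing changepoint indices: each index is the
    first frame of a new segment, so ``k`` changepoints split ``[0, T)``
    into ``k + 1`` half-open runs. An empty list (no changepoints) is a
    valid result.
    """
    if model is None:
        model = ChangepointModel(penalty=penalty)
    elif penalty is not None:
        raise ValueError("pass the penalty via the model or the argument, not both")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("find_changepoints requires a 1-D signal of length >= 2")
    T = x.size
    beta = model.penalty if model.penalty is not None else default_penalty(T)
    cps = _pelt(x, beta)
    if model.max_changepoints is not None and len(cps) > model.max_changepoints:
        cps = _constrained_dp(x, beta, model.max_changepoints)
    return cps


def _seg_cost_vec(cum2: np.ndarray, starts: np.ndarray, stop: int) -> np.ndarray:
    """Vectorized cost of half-open segments [starts, stop)."""
    n = stop - starts
    meansq = np.maximum((cum2[stop] - cum2[starts]) / n, EPS)
    return n * np.log(meansq)


def _pelt(x: np.ndarray, beta: float) -> list[int]:
    T = x.size
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    F = np.empty(T + 1)
    F[0] = -beta
    last = np.zeros(T + 1, dtype=np.int64)
    cand = np.array([0], dtype=np.int64)
    for t in range(1, T + 1):
        vals = F[cand] + _seg_cost_vec(cum2, cand, t) + beta
        best = int(np.argmin(vals))
        F[t] = vals[best]
        last[t] = cand[best]
        # Lossless pruning: a start that cannot beat the optimum now never will.
        keep = F[cand] + _seg_cost_vec(cum2, cand, t) <= F[t]
        cand = np.append(cand[keep], t)
    cps: list[int] = []
    t = T
    while t > 0:
        s = int(last[t])
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def _constrained_dp(x: np.ndarray, beta: float, kmax: int) -> list[int]:
    """Exact DP limited to at most ``kmax`` changepoints (O(K T^2))."""
    T = x.size
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    starts = np.arange(T)
    cost0 = np.array([_seg_cost_vec(cum2, np.array([0]), t + 1)[0]
                      for t in range(T)])
    D = cost0.copy()  # D[t] = best cost of x[0..t] with k changepoints
    back: list[np.ndarray] = []
    best_total = D[-1]
    best_k = 0
    backs_at_best: list[np.ndarray] = []
    for k in range(1, kmax + 1):
        Dn = np.full(T, np.inf)
        bk = np.zeros(T, dtype=np.int64)
        for t in range(k, T):
            s = np.arange(k, t + 1)  # changepoint position: new segment [s, t]
            vals = D[s - 1] + _seg_cost_vec(cum2, s, t + 1)
            i = int(np.argmin(vals))
            Dn[t] = vals[i]
            bk[t] = s[i]
        D = Dn
        back.append(bk)
        total = D[-1] + beta * k
        if total < best_total:
            best_total, best_k = total, k
            backs_at_best = [b.copy() for b in back]
    cps: list[int] = []
    t = T - 1
    for k in range(best_k, 0, -1):
        s = int(backs_at_best[k - 1][t])
        cps.append(s)
        t = s - 1
    return sorted(cps)


def call_plateaus(signal: np.ndarray, changepoints: list[int],
                  min_len: int = DEFAULT_MIN_LEN,
                  amp_fraction: float = DEFAULT_AMP_FRACTION) -> PlateauCall:
    """Apply the duration/amplitude plateau rule to candidate intervals.

    Candidates are the half-open runs between consecutive changepoints,
    including ``[0, cp_1)`` and ``[cp_k, T)``. A candidate is a plateau
    iff its length is strictly greater than ``min_len`` frames and its
    mean amplitude strictly exceeds ``amp_fraction`` times the maximum of
    the full signal.
    """
    x = np.asarray(signal, dtype=float)
    cps = sorted(int(c) for c in changepoints)
    if any(c <= 0 or c >= x.size for c in cps):
        raise ValueError("changepoints must lie strictly inside (0, T)")
    bounds = [0] + cps + [x.size]
    sig_max = float(x.max()) if x.size else 0.0
    intervals, flags = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        mean_amp = float(x[a:b].mean())
        intervals.append(Interval(a, b, mean_amp))
        flags.append((b - a) > min_len and mean_amp > amp_fraction * sig_max)
    return PlateauCall(intervals, flags, min_len, amp_fraction)


def has_plateau(dff: np.ndarray, penalty: float | None = None,
                min_len: int = DEFAULT_MIN_LEN,
                amp_fraction: float = DEFAULT_AMP_FRACTION,
                ) -> tuple[bool, PlateauCall]:
    """Changepoint segmentation followed by the plateau rule.

    Returns ``(any plateau, full PlateauCall)`` for one dF/F trace.
    """
    x = np.asarray(dff, dtype=float)
    cps = find_changepoints(x, penalty=penalty)
    call = call_plateaus(x, cps, min_len, amp_fraction)
    return call.any_plateau, call


class RmsChangepointDetector(BaseEstimator):
    """Scikit-learn style estimator for RMS-level changepoints.

    ``fit(x)`` stores ``changepoints_`` (sorted indices), ``n_segments_``
    and ``cost_`` (total penalized cost of the chosen segmentation).
    ``transform(x)`` maps each frame to its segment index.
    """

    def __init__(self, penalty: float | None = None,
                 max_changepoints: int | None = None):
        self.penalty = penalty
        self.max_changepoints = max_changepoints

    def fit(self, X: np.ndarray, y=None) -> "RmsChangepointDetector":
        x = np.asarray(X, dtype=float).ravel()
        model = ChangepointModel(penalty=self.penalty,
                                 max_changepoints=self.max_changepoints)
        cps = find_changepoints(x, model)
        self.changepoints_ = cps
        self.n_segments_ = len(cps) + 1
        bounds = [0] + cps + [x.size]
        beta = (self.penalty if self.penalty is not None
                else default_penalty(x.size))
        self.cost_ = sum(segment_cost(x, a, b - 1)
                         for a, b in zip(bounds[:-1], bounds[1:])) \
            + beta * len(cps)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        out = np.zeros(x.size, dtype=int)
        for i, c in enumerate(self.changepoints_, start=1):
            out[c:] = i
        return out
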