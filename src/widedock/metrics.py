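"""Search-trace analytics: proximity frequencies, sensitivity, timing.

The central statistic is the Average Sum of proximity relative
Frequencies (ASoF).  For ``n`` walkers, the relative frequency of walker
``i``'s head passing near the history of walker ``j`` at step ``t`` is a
proximity indicator divided by ``t``; summing over the other walkers
gives ``SoF_it`` (a real number in [0, n] -- it can exceed 1 when a head
is near several other walkers at once), and averaging over walkers gives
``ASoF_t``.

Two readings of the relative frequency are provided.  The default,
*instantaneous*, scores the walkers near the head at step ``t`` divided
by ``t`` -- this reproduces the canonical three-walker illustration
(ASoF progression 0, 0.167, 0.222, 0.333 at t = 1..4).  The
*cumulative* reading divides the running count of near events up to
``t`` by ``t`` and is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .engine import TraceRecord
from .objectives import InvalidArgumentError, WideDockError

FrMode = Literal["instantaneous", "cumulative"]

#: Default spatial proximity radius for trace analytics (Angstrom).
DEFAULT_RADIUS = 5.0


class UndefinedMetricError(WideDockError, ArithmeticError):
    """A windowed metric has no defining events (e.g. zero acceptances)."""


# ---------------------------------------------------------------------------
# Proximity events and ASoF
# ---------------------------------------------------------------------------

@dataclass
class ProximityEvents:
    """Per step and walker: which *other* walkers' history is nearby.

    ``events[(i, t)]`` is the set of walkers ``j != i`` with at least one
    history point recorded before step ``t`` within the proximity radius
    of walker ``i``'s head at ``t``.  Steps are 1-based (step 0 is the
    starting position, which has no preceding history).
    """

    n: int
    events: dict[tuple[int, int], frozenset[int]] = field(default_factory=dict)

    def add(self, i: int, t: int, near: Iterable[int]) -> None:
        near = frozenset(near)
        if i in near:
            raise InvalidArgumentError("a walker cannot be near itself")
        if t < 1:
            raise InvalidArgumentError("event steps are >= 1")
        self.events[(i, t)] = near

    def near(self, i: int, t: int) -> frozenset[int]:
        return self.events.get((i, t), frozenset())


def sof(events: ProximityEvents, i: int, t: int,
        mode: FrMode = "instantaneous") -> float:
    """Sum of proximity relative frequencies of walker ``i`` at step ``t``.

    Instantaneous: (number of distinct other walkers near the head at
    ``t``) / ``t``.  Cumulative: (number of near events over steps
    1..``t``) / ``t``.  ``t`` must be nonzero.
    """
    if t < 1:
        raise InvalidArgumentError("t must be >= 1")
    if mode == "instantaneous":
        return len(events.near(i, t)) / t
    if mode == "cumulative":
        return sum(len(events.near(i, tau)) for tau in range(1, t + 1)) / t
    raise InvalidArgumentError(f"unknown Fr mode: {mode!r}")


def asof(events: ProximityEvents, t: int,
         mode: FrMode = "instantaneous") -> float:
    """Average SoF over all walkers at step ``t``."""
    if events.n < 1:
        raise InvalidArgumentError("need at least one walker")
    return sum(sof(events, i, t, mode) for i in range(events.n)) / events.n


def asof_series(events: ProximityEvents, t_max: int,
                mode: FrMode = "instantaneous") -> np.ndarray:
    return np.array([asof(events, t, mode) for t in range(1, t_max + 1)])


def events_from_traces(histories: Sequence[np.ndarray],
                       radius: float = DEFAULT_RADIUS) -> ProximityEvents:
    """Extract proximity events from per-walker head trajectories.

    ``histories[i]`` is the ordered array of walker ``i``'s visited
    points (row 0 = start); proximity uses the spatial (first three)
    coordinates only.  Walker ``j`` is near walker ``i`` at step ``t``
    when any of ``j``'s points recorded before ``t`` lies within
    ``radius`` of ``i``'s head at ``t``.
    """
    n = len(histories)
    ev = ProximityEvents(n=n)
    if n < 2:
        return ev
    spatial = [np.atleast_2d(np.asarray(h, float))[:, :3] for h in histories]
    trees = [cKDTree(s) for s in spatial]
    for i in range(n):
        heads = spatial[i]
        t_len = heads.shape[0]
        near_lists = [trees[j].query_ball_point(heads, radius)
                      if j != i else None for j in range(n)]
        for t in range(1, t_len):
            near = set()
            for j in range(n):
                if j == i:
                    continue
                idxs = near_lists[j][t]
                limit = min(t, spatial[j].shape[0])
                if any(k < limit for k in idxs):
                    near.add(j)
            if near:
                ev.add(i, t, near)
    return ev


def frame_means(series: np.ndarray, frame_len: int) -> np.ndarray:
    """Mean of a per-step series over consecutive frames of ``frame_len``."""
    if frame_len < 1:
        raise InvalidArgumentError("frame_len must be >= 1")
    series = np.asarray(series, float)
    n_frames = int(np.ceil(series.size / frame_len))
    return np.array([series[f * frame_len:(f + 1) * frame_len].mean()
                     for f in range(n_frames)])


# ---------------------------------------------------------------------------
# Decision analytics
# ---------------------------------------------------------------------------

def g_sensitivity(trace: Iterable[TraceRecord]) -> float:
    """Fraction of buffered acceptances won at the global stage.

    ``(#G-pass) / (#G-pass + #I-pass)`` over the window; default-accepts
    do not count as buffered acceptances.  Raises
    :class:`UndefinedMetricError` when the window holds no G or I pass.
    """
    g = i = 0
    for rec in trace:
        if rec.outcome == "G":
            g += 1
        elif rec.outcome == "I":
            i += 1
    if g + i == 0:
        raise UndefinedMetricError("no buffered acceptances in window")
    return g / (g + i)


def decision_cost(trace: Iterable[TraceRecord]) -> int:
    """Total pairwise checks spent on the passed tests in the window."""
    return sum(rec.p1 + rec.p2 for rec in trace if rec.accepted)


def _windows_of_passes(trace: Sequence[TraceRecord], passes_per_window: int,
                       counted: tuple[str, ...]) -> list[list[TraceRecord]]:
    windows: list[list[TraceRecord]] = []
    current: list[TraceRecord] = []
    n_passes = 0
    for rec in trace:
        current.append(rec)
        if rec.outcome in counted:
            n_passes += 1
            if n_passes == passes_per_window:
                windows.append(current)
                current = []
                n_passes = 0
    if current and n_passes:
        windows.append(current)
    return windows


def g_sensitivity_series(trace: Sequence[TraceRecord],
                         passes_per_window: int = 7500) -> np.ndarray:
    """G sensitivity over consecutive windows of G/I passes."""
    wins = _windows_of_passes(trace, passes_per_window, ("G", "I"))
    return np.array([g_sensitivity(w) for w in wins])


def decision_cost_series(trace: Sequence[TraceRecord],
                         passes_per_window: int = 7500) -> np.ndarray:
    """Sum of checks per consecutive window of passed tests."""
    wins = _windows_of_passes(trace, passes_per_window, ("G", "I", "D"))
    return np.array([decision_cost(w) for w in wins])


def checks_per_accept(trace: Iterable[TraceRecord]) -> float:
    """Mean pairwise checks spent per accepted proposal."""
    recs = [r for r in trace if r.accepted]
    if not recs:
        raise UndefinedMetricError("no acceptances in window")
    return sum(r.p1 + r.p2 for r in recs) / len(recs)


# ---------------------------------------------------------------------------
# Pose quality and acceleration
# ---------------------------------------------------------------------------

def rmsd_success(pose_atoms: np.ndarray, reference_atoms: np.ndarray,
                 threshold: float = 2.0) -> tuple[float, bool]:
    """Heavy-atom RMSD without superposition, and the 2-Angstrom verdict.

    The docking frame is fixed (receptor coordinates), so no alignment is
    performed; a prediction is successful when RMSD < ``threshold``.
    """
    a = np.atleast_2d(np.asarray(pose_atoms, float))
    b = np.atleast_2d(np.asarray(reference_atoms, float))
    if a.shape != b.shape:
        raise InvalidArgumentError("atom count/shape mismatch")
    rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    return rmsd, rmsd < threshold


@dataclass(frozen=True)
class TimingBreakdown:
    """Search time, overhead time and their sum (any consistent unit)."""

    search: float
    overhead: float

    def __post_init__(self) -> None:
        if self.search <= 0 or self.overhead < 0:
            raise InvalidArgumentError("times must be positive")

    @property
    def overall(self) -> float:
        return self.search + self.overhead


def acceleration(timing_ref: TimingBreakdown, timing_new: TimingBreakdown,
                 base: int = 1) -> tuple[float, float, float]:
    """Speed-up ratios of a new tool against a reference.

    Returns ``(a_Ts, a_To, normalized a_To)``: the search-time ratio, the
    overall-time ratio, and the overall ratio credited with the step base
    ``B`` in {1, 2, 4} (a run exploring B-fold the steps counts as B
    runs' worth of work): ``normalized a_To = a_To * B``.
    """
    if base not in (1, 2, 4):
        raise InvalidArgumentError("base must be 1, 2 or 4")
    if timing_new.search <= 0 or timing_new.overall <= 0:
        raise InvalidArgumentError("new timings must be positive")
    a_ts = timing_ref.search / timing_new.search
    a_to = timing_ref.overall / timing_new.overall
    return a_ts, a_to, a_to * base


def asof_sensitivity_correlation(histories: Sequence[np.ndarray],
                                 trace: Sequence[TraceRecord],
                                 radius: float = DEFAULT_RADIUS,
                                 frame_len: int = 1000) -> float:
    """Pearson correlation between frame-wise ASoF and G sensitivity.

    The statistic linking walker proximity to global-stage success:
    both series are computed per frame and correlated over the frames
    where the sensitivity is defined.  Raises
    :class:`UndefinedMetricError` with fewer than three such frames.
    """
    table = metrics_table(histories, trace, radius=radius,
                          frame_len=frame_len)
    valid = table.dropna(subset=["g_sensitivity"])
    if len(valid) < 3:
        raise UndefinedMetricError(
            "need at least three frames with defined sensitivity")
    r = float(np.corrcoef(valid["asof"], valid["g_sensitivity"])[0, 1])
    return r


# ---------------------------------------------------------------------------
# Frame table
# ---------------------------------------------------------------------------

def metrics_table(histories: Sequence[np.ndarray],
                  trace: Sequence[TraceRecord],
                  radius: float = DEFAULT_RADIUS,
                  frame_len: int = 1000) -> pd.DataFrame:
    """Per-frame table of asof, g_sensitivity and decision_cost.

    Frames partition steps into consecutive blocks of ``frame_len``.
    ``g_sensitivity`` is NaN in frames without a buffered acceptance.
    """
    events = events_from_traces(histories, radius)
    t_max = max((np.atleast_2d(h).shape[0] - 1 for h in histories),
                default=0)
    series = asof_series(events, t_max) if t_max else np.array([])
    asof_frames = frame_means(series, frame_len) if series.size else []
    n_frames = len(asof_frames)
    rows = []
    for f in range(n_frames):
        lo, hi = f * frame_len + 1, (f + 1) * frame_len
        window = [r for r in trace if lo <= r.step <= hi]
        try:
            sens = g_sensitivity(window)
        except UndefinedMetricError:
            sens = float("nan")
        rows.append({"frame": f + 1, "asof": asof_frames[f],
                     "g_sensitivity": sens,
                     "decision_cost": decision_cost(window)})
    return pd.DataFrame(rows, columns=["frame", "asof", "g_sensitivity",
                                       "decision_cost"])
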