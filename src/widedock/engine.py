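"""Multi-walker modified Monte Carlo search with hybrid-buffer gating.

Each walker loops: mutate the current point, evaluate it, run the
two-stage significance check, and only if accepted spend the expensive
steps -- an "essential" local optimization, a Metropolis test on the
optimized score, and (on acceptance) a second local optimization whose
end point is archived in the shared octree and collected as a candidate
pose.  Every visited point is pushed to the walker's circular buffer and
recorded in the trace.

Walkers are scheduled by a deterministic cooperative round-robin in
fixed-size step slices ("time frames", 1000 steps each by default), so a
given configuration and seed always reproduce the identical trace and
poses regardless of host parallelism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .buffers import CircularBuffer, HistoryArchive
from .objectives import (DofLayout, InvalidArgumentError, Objective,
                         SearchPoint, normalize_angles)
from .significance import CheckConfig, CheckOutcome, hybrid_check

logger = logging.getLogger("widedock")

#: Steps per scheduling slice / analytics time frame.
FRAME_STEPS = 1000
#: Iteration cap shared by the essential and the post-acceptance
#: local optimizations.
BFGS_MAX_ITERS = 300

CheckMode = Literal["hybrid", "individual", "none"]


def max_steps(movable_atoms: int, rotatable_bonds: int,
              multiplier: int = 1) -> int:
    """Per-walker step budget S.

    The budget grows with ligand size and flexibility:
    ``S = multiplier * (70 * (movable_atoms + 10 * rotatable_bonds) + 500)``
    -- a fixed, configurable surrogate for the (unpublished) heuristic of
    the original tools.  ``multiplier`` in {1, 2, 4} scales the whole
    budget, so S(x4) = 4 * S(x1) for any ligand.
    """
    if movable_atoms < 0 or rotatable_bonds < 0:
        raise InvalidArgumentError("atom/bond counts must be >= 0")
    if multiplier not in (1, 2, 4):
        raise InvalidArgumentError("multiplier must be 1, 2 or 4")
    return multiplier * (70 * (movable_atoms + 10 * rotatable_bonds) + 500)


@dataclass
class SearchConfig:
    """All tunables of one search run."""

    objective: Objective
    exhaustiveness: int = 8
    seed: int = 0
    step_multiplier: int = 1
    check: CheckConfig | None = None
    check_mode: CheckMode = "hybrid"
    temperature: float = 1.2
    bfgs_max_iters: int = BFGS_MAX_ITERS
    # stop-point gradient tolerance: deliberately coarse, emulating the
    # fidelity of iteration-capped optimization on rugged surfaces (end
    # points carry small residual gradients rather than exact zeros)
    bfgs_gtol: float = 1e-3
    amplitude_translation: float = 2.0      # Angstrom
    amplitude_angle: float = 0.5            # radians
    num_modes: int = 9
    max_steps: int | None = None
    frame_steps: int = FRAME_STEPS
    mode_distance: float = 2.0              # Angstrom, pose clustering

    def __post_init__(self) -> None:
        if self.exhaustiveness < 1:
            raise InvalidArgumentError("exhaustiveness must be >= 1")
        if self.step_multiplier not in (1, 2, 4):
            raise InvalidArgumentError("step_multiplier must be 1, 2 or 4")
        if self.temperature <= 0:
            raise InvalidArgumentError("temperature must be > 0")
        if self.check is None:
            self.check = CheckConfig.from_dim(self.objective.dim)

    def resolved_max_steps(self) -> int:
        if self.max_steps is not None:
            return self.max_steps
        tree = getattr(self.objective, "tree", None)
        if tree is not None:
            movable = int(np.count_nonzero(tree.heavy_mask))
            return max_steps(movable, tree.n_rotatable_bonds,
                             self.step_multiplier)
        return max_steps(0, 0, self.step_multiplier)


@dataclass(frozen=True)
class TraceRecord:
    """One proposal: which walker, which step, how it was decided."""

    walker: int
    step: int
    outcome: str            # 'G', 'I', 'D' or 'R'
    p1: int
    p2: int
    is_end_point: bool
    score: float

    @property
    def accepted(self) -> bool:
        return self.outcome != "R"


_STAGE_CODE = {"global": "G", "individual": "I",
               "default-accept": "D", "rejected": "R"}


@dataclass
class Pose:
    """A predicted conformation/placement, ranked by score."""

    point: SearchPoint
    score: float
    rank: int = 0


@dataclass
class WalkerState:
    """Mutable per-walker search state."""

    walker_id: int
    rng: np.random.Generator
    current: SearchPoint
    buffer: CircularBuffer
    s: int = 0
    finished: bool = False
    minima: list[SearchPoint] = field(default_factory=list)
    history: list[np.ndarray] = field(default_factory=list)
    trace: list[TraceRecord] = field(default_factory=list)


@dataclass
class SearchResult:
    poses: list[Pose]
    trace: list[TraceRecord]
    histories: list[np.ndarray]     # per walker: (steps+1, N) visited heads
    archive: HistoryArchive
    config: SearchConfig


# ---------------------------------------------------------------------------
# Elementary moves
# ---------------------------------------------------------------------------

def mutate(coords: np.ndarray, rng: np.random.Generator, objective: Objective,
           amplitude_translation: float = 2.0,
           amplitude_angle: float = 0.5) -> np.ndarray:
    """Propose a neighbor: perturb the translation block, the rotation
    block, or one randomly chosen torsion (uniform choice among blocks).

    Translations are Gaussian with sigma ``amplitude_translation`` and
    clamped to the box; the rotation block is composed with a small
    random rotation (Gaussian angle about a uniform axis); torsions get a
    Gaussian angular increment.  Extra non-angular dimensions of
    landscape objectives are treated like torsion blocks with the
    translation amplitude.  Angles are normalized afterwards.
    """
    layout = objective.layout
    out = np.array(coords, float, copy=True)
    n_extra = layout.dim - 3 if not layout.rotation_block else 0
    blocks = 1 + (1 if layout.rotation_block else 0) + layout.n_torsions + \
        max(n_extra, 0)
    choice = int(rng.integers(blocks)) if blocks > 1 else 0
    if layout.dim < 3:
        choice = 0
    if choice == 0:
        k = min(3, layout.dim)
        out[:k] += rng.normal(0.0, amplitude_translation, size=k)
    elif layout.rotation_block and choice == 1:
        axis = rng.normal(size=3)
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        angle = rng.normal(0.0, amplitude_angle)
        composed = Rotation.from_rotvec(axis * angle) * \
            Rotation.from_rotvec(out[3:6])
        out[3:6] = composed.as_rotvec()
    else:
        offset = choice - (2 if layout.rotation_block else 1)
        if layout.rotation_block:
            dim = 6 + offset
            out[dim] += rng.normal(0.0, amplitude_angle)
        else:
            dim = 3 + offset
            out[dim] += rng.normal(0.0, amplitude_translation)
    lo, hi = objective.bounds[:, 0], objective.bounds[:, 1]
    k = min(3, layout.dim)
    out[:k] = np.clip(out[:k], lo[:k], hi[:k])
    if not layout.rotation_block and layout.dim > 3:
        out[3:] = np.clip(out[3:], lo[3:], hi[3:])
    return normalize_angles(out, layout)


def _bfgs_descend(fun, x0: np.ndarray, f0: float, g0: np.ndarray,
                  max_iters: int, gtol: float) -> tuple[np.ndarray, float,
                                                        np.ndarray]:
    """Inverse-Hessian BFGS with Armijo backtracking.

    A lean quasi-Newton loop (the search spends most of its time here, so
    per-call overhead matters).  Monotone by construction: every accepted
    step satisfies the Armijo decrease condition.
    """
    n = x0.size
    x, f, g = x0, f0, g0
    H = np.eye(n)
    first = True
    for _ in range(max_iters):
        if float(np.max(np.abs(g))) <= gtol:
            break
        p = -H @ g
        gp = float(g @ p)
        if gp >= 0.0:                      # H lost positive-definiteness
            H = np.eye(n)
            p = -g
            gp = float(g @ p)
            if gp >= 0.0:
                break
        alpha = 1.0
        for _ in range(30):
            xn = x + alpha * p
            fn, gn = fun(xn)
            if fn <= f + 1e-4 * alpha * gp:
                break
            alpha *= 0.5
        else:
            break                          # no acceptable step
        if alpha == 1.0:
            # expand while the longer step keeps improving: flat regions
            # need steps far beyond the unit quasi-Newton step, matching
            # the extrapolation phase of a Wolfe line search
            for _ in range(40):
                a2 = alpha * 2.0
                x2 = x + a2 * p
                f2, g2 = fun(x2)
                if f2 <= f + 1e-4 * a2 * gp and f2 < fn:
                    alpha, xn, fn, gn = a2, x2, f2, g2
                else:
                    break
        s = xn - x
        y = gn - g
        x, f, g = xn, float(fn), np.asarray(gn, float)
        sy = float(s @ y)
        if sy > 1e-12:
            if first:                      # scale H0 to the local curvature
                H *= sy / float(y @ y)
                first = False
            rho = 1.0 / sy
            Hy = H @ y
            H = (H - rho * (np.outer(s, Hy) + np.outer(Hy, s))
                 + (rho + rho * rho * float(y @ Hy)) * np.outer(s, s))
    return x, f, g


def local_optimize(point: SearchPoint, objective: Objective,
                   max_iters: int = BFGS_MAX_ITERS,
                   gtol: float = 1e-6) -> SearchPoint:
    """Quasi-Newton (BFGS) descent from ``point``; at most ``max_iters``
    iterations.  The returned end point carries its score and gradient
    and never scores worse than the input."""
    point.require_evaluated()
    x, f, g = _bfgs_descend(objective.evaluate, point.coords,
                            float(point.score), point.gradient,
                            max_iters, gtol)
    if f <= point.score:
        coords = normalize_angles(x, objective.layout)
        return objective.evaluate_point(coords)
    return point


def metropolis_accept(delta: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: always accept downhill moves, accept uphill
    moves with probability exp(-delta / temperature)."""
    if temperature <= 0:
        raise InvalidArgumentError("temperature must be > 0")
    if delta <= 0:
        return True
    return bool(rng.random() < math.exp(-delta / temperature))


# ---------------------------------------------------------------------------
# Walker loop
# ---------------------------------------------------------------------------

def init_walker(walker_id: int, rng: np.random.Generator,
                cfg: SearchConfig) -> WalkerState:
    obj = cfg.objective
    start = obj.evaluate_point(obj.random_point(rng))
    # the starting point is not pre-pushed into the buffer: the first
    # proposal of a cold walker is accepted by default (no history yet)
    state = WalkerState(walker_id=walker_id, rng=rng, current=start,
                        buffer=CircularBuffer(cfg.check.q))
    state.history.append(start.coords.copy())
    return state


def walker_step(state: WalkerState, archive: HistoryArchive | None,
                cfg: SearchConfig) -> TraceRecord:
    """One Monte Carlo proposal of one walker (one unit of ``s``)."""
    obj = cfg.objective
    cand_coords = mutate(state.current.coords, state.rng, obj,
                         cfg.amplitude_translation, cfg.amplitude_angle)
    cand = obj.evaluate_point(cand_coords)

    if cfg.check_mode == "none":
        outcome = CheckOutcome(True, "default-accept", 0, 0)
    else:
        global_archive = archive if cfg.check_mode == "hybrid" else None
        outcome = hybrid_check(cand, global_archive, state.buffer, cfg.check)

    state.buffer.push(cand)
    head = cand
    is_end = False
    if outcome.accepted:
        optimized = local_optimize(cand, obj, cfg.bfgs_max_iters,
                                   gtol=cfg.bfgs_gtol)
        state.buffer.push(optimized)
        head = optimized
        delta = optimized.score - state.current.score
        if metropolis_accept(delta, cfg.temperature, state.rng):
            end = local_optimize(optimized, obj, cfg.bfgs_max_iters,
                                 gtol=cfg.bfgs_gtol)
            state.buffer.push(end)
            if archive is not None:
                archive.add_end_point(end)
            state.minima.append(end)
            state.current = end
            head = end
            is_end = True
    else:
        # an insignificant proposal skips optimization, but the Monte
        # Carlo move itself still stands or falls by Metropolis on the
        # raw score -- the check saves optimizations, not moves
        delta = cand.score - state.current.score
        if metropolis_accept(delta, cfg.temperature, state.rng):
            state.current = cand

    state.s += 1
    state.history.append(head.coords.copy())
    rec = TraceRecord(walker=state.walker_id, step=state.s,
                      outcome=_STAGE_CODE[outcome.stage],
                      p1=outcome.p1, p2=outcome.p2,
                      is_end_point=is_end, score=float(cand.score))
    state.trace.append(rec)
    return rec


def run_walker(state: WalkerState, archive: HistoryArchive | None,
               cfg: SearchConfig,
               steps: int | None = None) -> tuple[list[SearchPoint],
                                                  list[TraceRecord]]:
    """Run one walker for ``steps`` proposals (default: the full budget).

    Returns the walker's collected minima and its trace records.
    """
    total = cfg.resolved_max_steps() if steps is None else steps
    while state.s < total:
        walker_step(state, archive, cfg)
    state.finished = True
    return state.minima, state.trace


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def cluster_poses(minima: list[SearchPoint], objective: Objective,
                  mode_distance: float, num_modes: int) -> list[Pose]:
    """Greedy best-first clustering of minima into modes.

    Minima are visited in non-decreasing score order; one joins an
    existing mode if its pose distance (ligand RMSD for docking
    objectives) to the mode representative is below ``mode_distance``,
    otherwise it founds a new mode.  Modes are ranked by score.
    """
    poses: list[Pose] = []
    for pt in sorted(minima, key=lambda p: p.score):
        for pose in poses:
            if objective.pose_distance(pt.coords, pose.point.coords) \
                    < mode_distance:
                break
        else:
            poses.append(Pose(point=pt, score=float(pt.score)))
            if len(poses) >= num_modes:
                break
    for rank, pose in enumerate(poses, start=1):
        pose.rank = rank
    return poses


def run_search(cfg: SearchConfig) -> SearchResult:
    """Run E walkers against one shared archive; deterministic.

    Walkers hold independent seeded random streams (spawned from
    ``cfg.seed``) and are interleaved round-robin in slices of
    ``cfg.frame_steps`` steps, the same granularity used by the trace
    analytics.  All walkers' minima are merged, clustered into modes and
    ranked by score.
    """
    obj = cfg.objective
    archive = HistoryArchive(obj.bounds[:3, 0], obj.bounds[:3, 1],
                             layout=obj.layout)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.exhaustiveness)
    walkers = [init_walker(i, np.random.default_rng(ss), cfg)
               for i, ss in enumerate(streams)]
    total = cfg.resolved_max_steps()

    frame = 0
    while any(w.s < total for w in walkers):
        frame += 1
        for w in walkers:
            budget = min(cfg.frame_steps, total - w.s)
            for _ in range(budget):
                walker_step(w, archive, cfg)
            if w.s >= total:
                w.finished = True
        best = min((m.score for w in walkers for m in w.minima),
                   default=float("nan"))
        logger.info("frame %d: active walkers %d, best score %.4f, "
                    "archived end points %d", frame,
                    sum(not w.finished for w in walkers), best, len(archive))

    minima = [m for w in walkers for m in w.minima]
    poses = cluster_poses(minima, obj, cfg.mode_distance, cfg.num_modes)
    trace: list[TraceRecord] = []
    for w in walkers:
        trace.extend(w.trace)
    trace.sort(key=lambda r: (r.step, r.walker))
    histories = [np.array(w.history) for w in walkers]
    return SearchResult(poses=poses, trace=trace, histories=histories,
                        archive=archive, config=cfg)
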