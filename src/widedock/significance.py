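"""Two-stage first-order-consistency significance check.

A proposed point only deserves (expensive) local optimization if it lies
in an energy well not explored before.  The first-order test compares
the proposal's gradient with the gradient at a nearby history point: if
for *every* design variable the two partial derivatives have opposite
signs or one of them is zero, no previously explored descent path leads
through the proposal -- it is *significant*.

The hybrid check runs the test in two stages: first against up to ``P1``
high-quality end points from the shared global archive (within spatial
cutoff ``R``, nearest first in full-N distance), then -- if the global
stage neither accepted nor had enough near points to decide -- against
the walker's own circular buffer.  The individual budget is
``p2 = P - p1`` where ``p1`` is the number of global checks actually
performed (not ``P - P1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .buffers import CircularBuffer, HistoryArchive
from .objectives import InvalidArgumentError, SearchPoint

#: Default multipliers on N for (max total checks, buffer capacity,
#: max global checks): P = 4N, Q = 5N, P1 = 1N.
DEFAULT_MULTIPLIERS = (4, 5, 1)
#: Default spatial proximity cutoff for the global stage (Angstrom).
DEFAULT_RADIUS = 5.0

Stage = Literal["global", "individual", "default-accept", "rejected"]


@dataclass(frozen=True)
class CheckConfig:
    """Tunables of the two-stage check, all derived from N by default.

    ``n``: degrees of freedom; ``p``: max total checks; ``q``: circular
    buffer capacity; ``p1``: max checks against the global archive;
    ``r``: spatial proximity cutoff in Angstrom.
    """

    n: int
    p: int
    q: int
    p1: int
    r: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if min(self.n, self.p, self.q, self.p1) <= 0 or self.r <= 0:
            raise InvalidArgumentError("check parameters must be positive")
        if not (self.p1 <= self.p <= self.q):
            raise InvalidArgumentError(
                f"need p1 <= p <= q, got p1={self.p1}, p={self.p}, q={self.q}")

    @classmethod
    def from_dim(cls, n: int,
                 multipliers: tuple[int, int, int] = DEFAULT_MULTIPLIERS,
                 r: float = DEFAULT_RADIUS) -> "CheckConfig":
        p_mult, q_mult, p1_mult = multipliers
        return cls(n=n, p=p_mult * n, q=q_mult * n, p1=p1_mult * n, r=r)


def derive_check_config(rotatable_bonds: int,
                        multipliers: tuple[int, int, int] = DEFAULT_MULTIPLIERS,
                        r: float = DEFAULT_RADIUS) -> CheckConfig:
    """Check configuration for a ligand: ``N = 6 + rotatable bonds``.

    With the default multipliers (4, 5, 1) a 4-bond ligand gets N=10,
    P=40 checks among the latest Q=50, and at most P1=10 global checks.
    """
    if rotatable_bonds < 0:
        raise InvalidArgumentError("rotatable_bonds must be >= 0")
    return CheckConfig.from_dim(6 + rotatable_bonds, multipliers, r)


@dataclass(frozen=True)
class CheckOutcome:
    """Result of one hybrid check.

    ``p1``/``p2`` are the counts of global/individual pairwise tests
    actually performed; ``p1 <= P1`` and ``p1 + p2 <= P`` always hold.
    """

    accepted: bool
    stage: Stage
    p1: int
    p2: int

    @property
    def checks(self) -> int:
        return self.p1 + self.p2


def pairwise_significant(candidate: SearchPoint,
                         history_point: SearchPoint) -> bool:
    """First-order consistency between a proposal and one history point.

    True iff for every design variable the product of the two partial
    derivatives is <= 0 (opposite signs, or at least one exactly zero):
    the proposal then lies in an energy well the history point's descent
    cannot have explored.  A proposal with an exactly zero gradient (a
    stationary point) passes against any history.
    """
    candidate.require_evaluated()
    history_point.require_evaluated()
    gc, gh = candidate.gradient, history_point.gradient
    if gc.shape != gh.shape:
        raise InvalidArgumentError("gradient dimension mismatch")
    return bool(np.all(gc * gh <= 0.0))


def hybrid_check(candidate: SearchPoint, archive: HistoryArchive | None,
                 circular: CircularBuffer, cfg: CheckConfig) -> CheckOutcome:
    """Decide whether ``candidate`` deserves local optimization.

    Global stage: test up to ``cfg.p1`` archived end points within
    spatial radius ``cfg.r``, nearest first in full-N distance; the first
    pairwise pass accepts at stage ``"global"``.  If the global stage did
    not decide (all tested failed, or fewer than ``p1`` near points were
    available), the individual stage tests the nearest ``cfg.p - p1``
    points of the walker's own buffer.  If no history point at all was
    available the candidate is accepted by default (the search could
    never start otherwise).
    """
    candidate.require_evaluated()
    gc = candidate.gradient

    def first_pass(points: list[SearchPoint]) -> tuple[int, int]:
        """(#tested, 1-based index of the first pass or 0)."""
        if not points:
            return 0, 0
        grads = np.array([p.gradient for p in points])
        passes = np.all(gc[None, :] * grads <= 0.0, axis=1)
        hit = int(np.argmax(passes)) + 1 if passes.any() else 0
        return (hit if hit else len(points)), hit

    p1 = hit1 = 0
    if archive is not None:
        p1, hit1 = first_pass(archive.query(candidate.coords, cfg.r)[:cfg.p1])
        if hit1:
            return CheckOutcome(True, "global", p1, 0)
    layout = getattr(archive, "layout", None)
    p2, hit2 = first_pass(circular.nearest(candidate.coords, cfg.p - p1,
                                           layout))
    if hit2:
        return CheckOutcome(True, "individual", p1, p2)
    if p1 == 0 and p2 == 0:
        return CheckOutcome(True, "default-accept", 0, 0)
    return CheckOutcome(False, "rejected", p1, p2)
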