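"""Objective functions over ligand conformational space.

A conformation is a point in an ``N``-dimensional design space:

* dims 0-2   -- translation of the ligand root centroid (Angstrom),
* dims 3-5   -- rigid-body rotation about the root centroid, stored as a
  rotation vector (axis * angle, radians),
* dims 6..N  -- one torsion angle (radians) per rotatable bond.

``N = 6 + number of rotatable bonds``.  Synthetic landscapes use the same
point type but declare their own dimensionality and treat every dimension
as a plain box-bounded coordinate (no angular wrapping).

Two concrete objectives are provided: seeded sums of negative Gaussian
wells (:func:`make_gaussian_landscape`), and a smooth pairwise
receptor-ligand potential over a torsion tree
(:func:`make_toy_docking_objective`).  Both expose analytic gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

TWO_PI = 2.0 * math.pi

#: Spatial dimensions (translation block) used by the octree and by
#: proximity filters.
SPATIAL_DIMS = 3


class WideDockError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(WideDockError, ValueError):
    """A precondition on an argument was violated."""


class InvalidStateError(WideDockError, RuntimeError):
    """An object was used before required fields were populated."""


# ---------------------------------------------------------------------------
# Degree-of-freedom layout and points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DofLayout:
    """Which dimensions of a point are spatial, rotational or torsional.

    ``rotation_block`` marks dims 3-5 as a single axis-angle rotation
    vector; ``n_torsions`` torsion angles occupy the trailing dimensions.
    Landscape objectives use ``rotation_block=False, n_torsions=0`` so all
    dimensions behave as plain bounded coordinates.
    """

    dim: int
    n_torsions: int = 0
    rotation_block: bool = False

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise InvalidArgumentError("dim must be >= 1")
        used = SPATIAL_DIMS * (1 if self.rotation_block else 0)
        if self.rotation_block and self.dim < 6 + self.n_torsions:
            raise InvalidArgumentError(
                "rotation block plus torsions do not fit in dim"
            )
        if self.n_torsions < 0 or self.n_torsions > self.dim:
            raise InvalidArgumentError("invalid torsion count")
        del used

    @property
    def torsion_start(self) -> int:
        return self.dim - self.n_torsions

    @property
    def torsion_mask(self) -> np.ndarray:
        m = np.zeros(self.dim, dtype=bool)
        if self.n_torsions:
            m[self.torsion_start:] = True
        return m

    @property
    def angle_mask(self) -> np.ndarray:
        """Boolean mask of all angular dimensions (rotation + torsions)."""
        m = self.torsion_mask
        if self.rotation_block:
            m[3:6] = True
        return m

    @classmethod
    def for_ligand(cls, rotatable_bonds: int) -> "DofLayout":
        if rotatable_bonds < 0:
            raise InvalidArgumentError("rotatable_bonds must be >= 0")
        return cls(dim=6 + rotatable_bonds, n_torsions=rotatable_bonds,
                   rotation_block=True)

    @classmethod
    def for_landscape(cls, dim: int) -> "DofLayout":
        return cls(dim=dim)


@dataclass
class SearchPoint:
    """A position in design space with its score and gradient.

    ``score`` and ``gradient`` are ``None`` until the point has been
    evaluated against an objective.
    """

    coords: np.ndarray
    score: float | None = None
    gradient: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float)

    @property
    def dim(self) -> int:
        return self.coords.shape[0]

    @property
    def evaluated(self) -> bool:
        return self.score is not None and self.gradient is not None

    def require_evaluated(self) -> None:
        if not self.evaluated:
            raise InvalidStateError("point has not been evaluated")


# ---------------------------------------------------------------------------
# Angle normalization and distances
# ---------------------------------------------------------------------------

def _wrap_symmetric(x: np.ndarray) -> np.ndarray:
    """Map angles into [-pi, pi)."""
    return (np.asarray(x, dtype=float) + math.pi) % TWO_PI - math.pi


def _wrap_wide(x: np.ndarray) -> np.ndarray:
    """Map angles into (-2*pi, 2*pi) keeping their sign (fmod)."""
    return np.fmod(np.asarray(x, dtype=float), TWO_PI)


def normalize_angles(coords: np.ndarray, layout: DofLayout,
                     mode: str = "symmetric") -> np.ndarray:
    """Return a copy of ``coords`` with angular components normalized.

    Torsion components are wrapped independently.  The rotation block
    (dims 3-5) is an axis-angle vector: wrapping its components
    independently would change the rotation it encodes, so it is
    normalized as a unit -- the rotation angle (the vector magnitude) is
    folded into the target range and the vector rescaled, which encodes
    the identical rotation.  Spatial components are untouched, so any
    objective score is invariant under normalization.

    ``mode`` is ``"symmetric"`` for [-pi, pi) (the default) or ``"wide"``
    for the sign-preserving fmod into (-2*pi, 2*pi).
    """
    if mode == "symmetric":
        wrap = _wrap_symmetric
    elif mode == "wide":
        wrap = _wrap_wide
    else:
        raise InvalidArgumentError(f"unknown normalization mode: {mode!r}")
    out = np.array(coords, dtype=float, copy=True)
    if out.shape[0] != layout.dim:
        raise InvalidArgumentError("point dimension does not match layout")
    tmask = layout.torsion_mask
    if tmask.any():
        out[tmask] = wrap(out[tmask])
    if layout.rotation_block:
        v = out[3:6]
        theta = float(np.linalg.norm(v))
        if theta > 0.0:
            wrapped = float(wrap(np.array([theta]))[0])
            if wrapped != theta:
                out[3:6] = v * (wrapped / theta)
    return out


def angular_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal per-component angular difference, in [-pi, pi)."""
    return _wrap_symmetric(np.asarray(a, float) - np.asarray(b, float))


def distance_many(candidate: np.ndarray, coords: np.ndarray,
                  layout: DofLayout | None = None) -> np.ndarray:
    """Full-N distances from one candidate to many points (vectorized).

    Same semantics as :func:`distance` with ``dims="all"``: angular
    components are compared via minimal angular difference.
    """
    candidate = np.asarray(candidate, float)
    coords = np.atleast_2d(np.asarray(coords, float))
    diff = coords - candidate[None, :]
    if layout is not None:
        mask = layout.angle_mask
        if mask.any():
            diff[:, mask] = _wrap_symmetric(diff[:, mask])
    return np.sqrt(np.sum(diff * diff, axis=1))


def distance(a, b, dims: str = "all", layout: DofLayout | None = None) -> float:
    """Euclidean distance between two points.

    ``dims="spatial"`` uses only the first three (translation) dimensions
    -- the proximity filter used by the shared archive.  ``dims="all"``
    uses every dimension; angular components are compared through their
    minimal angular difference after normalization.  Mixed units
    (Angstrom + radians) are combined without weighting.
    """
    ca = a.coords if isinstance(a, SearchPoint) else np.asarray(a, float)
    cb = b.coords if isinstance(b, SearchPoint) else np.asarray(b, float)
    if ca.shape != cb.shape:
        raise InvalidArgumentError("dimension mismatch")
    if dims == "spatial":
        d = ca[:SPATIAL_DIMS] - cb[:SPATIAL_DIMS]
        return float(np.linalg.norm(d))
    if dims != "all":
        raise InvalidArgumentError(f"unknown dims selector: {dims!r}")
    if layout is None or not layout.angle_mask.any():
        return float(np.linalg.norm(ca - cb))
    mask = layout.angle_mask
    diff = ca - cb
    diff = np.where(mask, angular_difference(ca, cb), diff)
    return float(np.linalg.norm(diff))


# ---------------------------------------------------------------------------
# Objective contract
# ---------------------------------------------------------------------------

class Objective:
    """Scoring contract: score and gradient at any point, plus bounds.

    Subclasses implement :meth:`evaluate` returning ``(score, gradient)``
    and must populate ``bounds`` (``(dim, 2)`` closed intervals; spatial
    dims come from the search box) and ``layout``.
    """

    layout: DofLayout
    bounds: np.ndarray

    @property
    def dim(self) -> int:
        return self.layout.dim

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def evaluate_point(self, coords: np.ndarray) -> SearchPoint:
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] != self.dim:
            raise InvalidArgumentError("point dimension does not match objective")
        score, grad = self.evaluate(coords)
        return SearchPoint(coords=coords.copy(), score=float(score),
                           gradient=np.asarray(grad, float))

    def pose_distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Distance used for clustering poses into modes (Angstrom-like)."""
        return distance(a, b, dims="all", layout=self.layout)

    def random_point(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return rng.uniform(lo, hi)


# ---------------------------------------------------------------------------
# Synthetic multi-well landscapes
# ---------------------------------------------------------------------------

def _make_gaussian_kernel():
    """Compile the landscape evaluation with numba when available.

    The search evaluates landscapes millions of times per run; the
    compiled kernel removes the array-dispatch overhead.  Pure-numpy
    evaluation remains the fallback (identical mathematics).
    """
    try:
        import numba
    except ImportError:          # pragma: no cover - numba is optional
        return None

    @numba.njit(cache=False)
    def kernel(x, centers, depths, widths, kvec, phase, amp):
        n_wells, dim = centers.shape
        score = 0.0
        grad = np.zeros(dim)
        for w in range(n_wells):
            q = 0.0
            for d in range(dim):
                diff = x[d] - centers[w, d]
                q += diff * diff
            sig2 = widths[w] * widths[w]
            well = -depths[w] * np.exp(-q / (2.0 * sig2))
            score += well
            for d in range(dim):
                grad[d] += (-well / sig2) * (x[d] - centers[w, d])
        for m in range(kvec.shape[0]):
            arg = phase[m]
            for d in range(dim):
                arg += kvec[m, d] * x[d]
            score += amp * np.cos(arg)
            s = amp * np.sin(arg)
            for d in range(dim):
                grad[d] -= s * kvec[m, d]
        return score, grad

    # trigger compilation once so per-call latency is flat afterwards
    kernel(np.zeros(2), np.zeros((1, 2)), np.ones(1), np.ones(1),
           np.zeros((0, 2)), np.zeros(0), 0.0)
    return kernel


_gaussian_kernel = _make_gaussian_kernel()


class GaussianLandscape(Objective):
    """Sum of negative Gaussian wells on a box, optionally textured.

    ``f(x) = -sum_i depth_i * exp(-|x - c_i|^2 / (2 sigma_i^2))`` with the
    analytic gradient; all dimensions are plain bounded coordinates.

    An optional smooth cosine *texture* -- ``amp * sum_m cos(k_m.x +
    phi_m)`` -- models the sub-Angstrom interpolation roughness of
    grid-based scoring functions.  It scatters local-optimization stop
    points over the basin bottoms with decorrelated residual gradients
    instead of letting every descent collapse onto one exact stationary
    point, which is the regime real docking stop points live in.
    """

    def __init__(self, centers: np.ndarray, depths: np.ndarray,
                 widths: np.ndarray, bounds: np.ndarray,
                 texture: tuple[np.ndarray, np.ndarray, float] | None = None):
        centers = np.atleast_2d(np.asarray(centers, float))
        self.centers = centers
        self.depths = np.asarray(depths, float)
        self.widths = np.asarray(widths, float)
        self.bounds = np.asarray(bounds, float)
        self.layout = DofLayout.for_landscape(centers.shape[1])
        self.texture = texture          # (wave vectors, phases, amplitude)

    @property
    def n_wells(self) -> int:
        return self.centers.shape[0]

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.ascontiguousarray(coords, dtype=float)
        if _gaussian_kernel is not None:
            if self.texture is not None:
                kvec, phase, amp = self.texture
            else:
                kvec = np.zeros((0, x.size))
                phase = np.zeros(0)
                amp = 0.0
            score, grad = _gaussian_kernel(
                x, self.centers, self.depths, self.widths,
                np.ascontiguousarray(kvec), phase, float(amp))
            return float(score), grad
        diff = x[None, :] - self.centers                   # (W, d)
        q = np.sum(diff * diff, axis=1) / (2.0 * self.widths ** 2)
        wells = -self.depths * np.exp(-q)                  # (W,)
        score = float(wells.sum())
        grad = np.sum((-wells / self.widths ** 2)[:, None] * diff, axis=0)
        if self.texture is not None:
            kvec, phase, amp = self.texture
            arg = kvec @ x + phase
            score += float(amp * np.cos(arg).sum())
            grad = grad - amp * (np.sin(arg)[:, None] * kvec).sum(axis=0)
        return score, grad

    # Ground truth -----------------------------------------------------
    @property
    def deepest_well(self) -> tuple[np.ndarray, float]:
        """Center and depth of the deepest recorded well."""
        i = int(np.argmax(self.depths))
        return self.centers[i].copy(), float(self.depths[i])

    def ground_truth_minimum(self) -> SearchPoint:
        """The global minimum, refined from the deepest-well center.

        On a smooth landscape a single quasi-Newton polish from the
        deepest-well center is exact (neighboring tails only shift the
        minimum negligibly).  With texture the basin bottom splits into
        several micro-minima, so a grid of perturbed starts around the
        center is refined and the deepest end point returned.
        """
        from scipy.optimize import minimize

        def refine(start):
            return minimize(self.evaluate, start, jac=True, method="BFGS",
                            options={"maxiter": 300})

        c, _ = self.deepest_well
        best = refine(c)
        if self.texture is not None:
            k = min(3, self.layout.dim)
            for off in np.ndindex(*(5,) * k):
                start = c.copy()
                start[:k] += np.asarray(off, float) - 2.0
                res = refine(start)
                if res.fun < best.fun:
                    best = res
        return SearchPoint(best.x, float(best.fun),
                           np.asarray(best.jac, float))


def make_gaussian_landscape(dim: int, n_wells: int, seed: int,
                            box_size: float = 30.0,
                            depth_range: tuple[float, float] = (2.0, 10.0),
                            width_range: tuple[float, float] = (1.5, 3.0),
                            margin: float = 4.0) -> GaussianLandscape:
    """Seeded random landscape of ``n_wells`` negative Gaussian wells.

    Wells are placed uniformly inside the box with an edge margin; depths
    and widths are uniform in the given ranges.  The deepest well is
    queryable as ground truth.
    """
    if dim < 1 or n_wells < 1:
        raise InvalidArgumentError("dim and n_wells must be >= 1")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(margin, box_size - margin, size=(n_wells, dim))
    depths = rng.uniform(*depth_range, size=n_wells)
    widths = rng.uniform(*width_range, size=n_wells)
    bounds = np.tile([0.0, box_size], (dim, 1))
    return GaussianLandscape(centers, depths, widths, bounds)


def make_two_well_landscape(seed: int, dim: int = 3,
                            depths: tuple[float, float] = (10.0, 6.0),
                            width: float = 3.0,
                            box_size: float = 75.0,
                            min_separation: float = 30.0,
                            margin: float = 5.0,
                            n_rough: int = 250,
                            rough_depth: tuple[float, float] = (0.3, 1.5),
                            rough_width: tuple[float, float] = (1.0, 2.0),
                            texture_amp: float = 0.25,
                            texture_terms: int = 6,
                            texture_wavelength: tuple[float, float] = (1.0, 1.5)
                            ) -> GaussianLandscape:
    """Two well-separated main wells on a rugged, textured background.

    The study configuration behind the synthetic search battery,
    emulating a wide blind-docking energy surface: a deep main well
    (depth 10) and a shallow one (depth 6) with centers at least
    ``min_separation`` apart (an order of magnitude wider than the basin
    width) in a wide box, ``n_rough`` shallow decoy minima (meso-scale
    ruggedness; kept >= 6 A from the main centers so the global minimum
    stays in the deep well), and a low-amplitude cosine texture
    (sub-Angstrom roughness emulating grid-interpolated scoring, which
    disperses optimization stop points within each basin).  Setting
    ``n_rough=0`` and ``texture_amp=0`` yields the clean two-well
    surface used by analytic unit tests.
    """
    rng = np.random.default_rng(seed)
    while True:
        mains = rng.uniform(margin, box_size - margin, size=(2, dim))
        if np.linalg.norm(mains[0] - mains[1]) >= min_separation:
            break
    rough: list[np.ndarray] = []
    while len(rough) < n_rough:
        c = rng.uniform(2.0, box_size - 2.0, size=dim)
        if min(np.linalg.norm(c - mains[0]),
               np.linalg.norm(c - mains[1])) >= 6.0:
            rough.append(c)
    centers = np.vstack([mains] + rough) if n_rough else mains
    depths_all = np.concatenate([np.asarray(depths, float),
                                 rng.uniform(*rough_depth, size=n_rough)])
    widths_all = np.concatenate([np.full(2, width),
                                 rng.uniform(*rough_width, size=n_rough)])
    bounds = np.tile([0.0, box_size], (dim, 1))
    texture = None
    if texture_amp > 0 and texture_terms > 0:
        trng = np.random.default_rng(seed + 777)
        dirs = trng.normal(size=(texture_terms, dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lam = trng.uniform(*texture_wavelength, size=texture_terms)
        kvec = dirs * (TWO_PI / lam)[:, None]
        phases = trng.uniform(0.0, TWO_PI, size=texture_terms)
        texture = (kvec, phases, float(texture_amp))
    return GaussianLandscape(centers, depths_all, widths_all, bounds,
                             texture=texture)


# ---------------------------------------------------------------------------
# Torsion trees and conformations
# ---------------------------------------------------------------------------

@dataclass
class LigandAtom:
    """One ligand atom (coordinates in Angstrom)."""

    element: str
    coords: np.ndarray
    is_heavy: bool = True
    name: str = ""
    serial: int = 0
    charge: float = 0.0
    ad_type: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class Branch:
    """A rotatable bond: rotation of ``moved`` atoms about parent->child."""

    parent: int
    child: int
    moved: list[int]


@dataclass
class TorsionTree:
    """A ligand as a rigid root plus nested rotatable branches.

    ``branches`` are stored in file (pre-order) order; each branch's
    ``moved`` set contains every atom inside the branch block, including
    atoms of nested branches, so applying branches in order transforms
    nested bodies consistently.  ``torsdof`` equals the branch count.
    """

    atoms: list[LigandAtom]
    root_atoms: list[int]
    branches: list[Branch] = field(default_factory=list)
    torsdof: int = 0
    records: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.torsdof == 0 and self.branches:
            self.torsdof = len(self.branches)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_rotatable_bonds(self) -> int:
        return len(self.branches)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def layout(self) -> DofLayout:
        return DofLayout.for_ligand(self.n_rotatable_bonds)

    @property
    def root_centroid(self) -> np.ndarray:
        return self.coords[self.root_atoms].mean(axis=0)

    def rigid_bodies(self) -> list[list[int]]:
        """Atom partition: root body plus one body per branch."""
        owner = {i: -1 for i in range(self.n_atoms)}
        for bi, br in enumerate(self.branches):
            for a in br.moved:
                owner[a] = bi       # innermost branch wins (pre-order)
        bodies: dict[int, list[int]] = {}
        for atom, bi in owner.items():
            bodies.setdefault(bi, []).append(atom)
        return [sorted(v) for _, v in sorted(bodies.items())]

    def validate(self) -> None:
        n = self.n_atoms
        seen_root = set(self.root_atoms)
        if not seen_root:
            raise InvalidArgumentError("torsion tree has an empty root")
        for br in self.branches:
            if br.child not in br.moved:
                raise InvalidArgumentError("branch child must be in moved set")
            if br.parent in br.moved:
                raise InvalidArgumentError("branch parent cannot move with it")
        covered = set(self.root_atoms)
        for br in self.branches:
            covered.update(br.moved)
        if covered != set(range(n)):
            raise InvalidArgumentError("atoms not covered by root/branches")


def _skew(u: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -u[2], u[1]],
                     [u[2], 0.0, -u[0]],
                     [-u[1], u[0], 0.0]])


def _so3_right_jacobian(v: np.ndarray) -> np.ndarray:
    """Right Jacobian of the exponential map on SO(3).

    Satisfies ``exp((v + d)^) ~= exp(v^) exp((J_r(v) d)^)`` for small d,
    which converts perturbations of the rotation-vector parameters into a
    body-frame rotation increment.
    """
    theta = float(np.linalg.norm(v))
    V = _skew(v)
    if theta < 1e-8:
        return np.eye(3) - 0.5 * V + (V @ V) / 6.0
    return (np.eye(3)
            - ((1.0 - math.cos(theta)) / theta ** 2) * V
            + ((theta - math.sin(theta)) / theta ** 3) * (V @ V))


def apply_conformation(tree: TorsionTree, point) -> np.ndarray:
    """Atom coordinates (Angstrom) of ``tree`` at a search point.

    Applies the rigid-body rotation (dims 3-5, axis-angle) about the root
    centroid, then the translation (dims 0-2), then each torsion about
    its branch bond axis to the branch's moved-atom set, in pre-order.
    The all-zero point is the identity transform.
    """
    pos, _ = _conformation(tree, point, want_jacobian=False)
    return pos


def conformation_with_jacobian(tree: TorsionTree, point
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Atom coordinates and the exact Jacobian d(coords)/d(point).

    Returns ``(pos, jac)`` with ``pos`` of shape ``(M, 3)`` and ``jac`` of
    shape ``(M, 3, N)``.  The orientation block uses the SO(3) right
    Jacobian of the rotation-vector parameterization; torsion axes are
    differentiated through the positions of their parent/child atoms
    (Rodrigues formula), so the Jacobian is exact for the full chain.
    """
    pos, jac = _conformation(tree, point, want_jacobian=True)
    return pos, jac


def _conformation(tree: TorsionTree, point, want_jacobian: bool):
    coords = point.coords if isinstance(point, SearchPoint) else np.asarray(point, float)
    n_dim = 6 + tree.n_rotatable_bonds
    if coords.shape[0] != n_dim:
        raise InvalidArgumentError(
            f"point has {coords.shape[0]} dims, ligand needs {n_dim}")
    x = tree.coords
    m = x.shape[0]
    c0 = tree.root_centroid
    t = coords[:3]
    v = coords[3:6]
    rot = Rotation.from_rotvec(v)
    u0 = x - c0
    pos = rot.apply(u0) + c0 + t

    jac = None
    if want_jacobian:
        jac = np.zeros((m, 3, n_dim))
        jac[:, :, :3] = np.eye(3)[None, :, :]
        Jr = _so3_right_jacobian(v)
        Rm = rot.as_matrix()
        # d(R u)/dv = -R [u]x J_r(v)
        for k in range(m):
            jac[k, :, 3:6] = -Rm @ _skew(u0[k]) @ Jr

    for bi, br in enumerate(tree.branches):
        theta = float(coords[6 + bi])
        P = pos[br.parent].copy()
        C = pos[br.child].copy()
        axis_vec = C - P
        rho = float(np.linalg.norm(axis_vec))
        if rho < 1e-12:
            raise InvalidArgumentError("degenerate branch bond (zero length)")
        n = axis_vec / rho
        ct, st = math.cos(theta), math.sin(theta)
        moved = np.asarray(br.moved, dtype=int)
        u = pos[moved] - P                                       # (b, 3)
        # Rodrigues: R u = u ct + (n x u) st + n (n.u)(1 - ct)
        nxu = np.cross(np.broadcast_to(n, u.shape), u)
        ndotu = u @ n
        ru = u * ct + nxu * st + np.outer(ndotu, n) * (1.0 - ct)

        if want_jacobian:
            jP = jac[br.parent].copy()                           # (3, N)
            jC = jac[br.child].copy()
            dn = ((np.eye(3) - np.outer(n, n)) / rho) @ (jC - jP)  # (3, N)
            Rb = (np.eye(3) * ct + _skew(n) * st
                  + np.outer(n, n) * (1.0 - ct))
            jmoved = jac[moved]                                   # (b, 3, N)
            # da' = dP + Rb (da - dP) + A(u) dn + w dtheta
            term = jP[None, :, :] + np.einsum(
                "ij,ajk->aik", Rb, jmoved - jP[None, :, :])
            # A(u) = -st [u]x + (1 - ct)(n u^T + (n.u) I)
            for idx, k in enumerate(moved):
                A = (-st * _skew(u[idx])
                     + (1.0 - ct) * (np.outer(n, u[idx])
                                     + ndotu[idx] * np.eye(3)))
                term[idx] += A @ dn
            w = -u * st + nxu * ct + np.outer(ndotu, n) * st      # (b, 3)
            term[:, :, 6 + bi] += w
            jac[moved] = term

        pos[moved] = P + ru

    return pos, jac


# ---------------------------------------------------------------------------
# Toy docking objective
# ---------------------------------------------------------------------------

#: Pair-potential constants: depth 1.0 at 3.5 A, steep repulsion below
#: ~2.5 A, smooth switch to zero between 6 and 8 A.  Arbitrary but fixed
#: so results are reproducible.
PAIR_DEPTH = 1.0
PAIR_R0 = 3.5
PAIR_STEEPNESS = 2.0
PAIR_R_SWITCH = 6.0
PAIR_R_CUT = 8.0


def pair_potential(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth receptor-ligand pair potential ``u(r)`` and ``du/dr``.

    A Morse well (minimum ``-PAIR_DEPTH`` at ``PAIR_R0``) multiplied by a
    C1 cubic switching function that takes the potential smoothly to zero
    at ``PAIR_R_CUT``.
    """
    r = np.asarray(r, dtype=float)
    e = np.exp(-PAIR_STEEPNESS * (r - PAIR_R0))
    morse = PAIR_DEPTH * ((1.0 - e) ** 2 - 1.0)
    dmorse = 2.0 * PAIR_DEPTH * PAIR_STEEPNESS * (1.0 - e) * e

    x = np.clip((r - PAIR_R_SWITCH) / (PAIR_R_CUT - PAIR_R_SWITCH), 0.0, 1.0)
    s = 1.0 - (3.0 * x * x - 2.0 * x ** 3)
    ds = np.where((r > PAIR_R_SWITCH) & (r < PAIR_R_CUT),
                  -(6.0 * x - 6.0 * x * x) / (PAIR_R_CUT - PAIR_R_SWITCH),
                  0.0)
    u = np.where(r >= PAIR_R_CUT, 0.0, morse * s)
    du = np.where(r >= PAIR_R_CUT, 0.0, dmorse * s + morse * ds)
    return u, du


class ToyDockingObjective(Objective):
    """Receptor-ligand score: sum of smooth pair potentials over heavy pairs.

    Composed with :func:`apply_conformation`; the gradient is exact via
    the conformation Jacobian (chain rule).  Translation dims are the
    displacement of the ligand root centroid from its input position, so
    spatial bounds are the search box shifted by that centroid.
    """

    def __init__(self, receptor_coords: np.ndarray, tree: TorsionTree,
                 box_lo: np.ndarray, box_hi: np.ndarray):
        receptor_coords = np.atleast_2d(np.asarray(receptor_coords, float))
        if receptor_coords.size == 0:
            raise InvalidArgumentError("empty receptor")
        if tree.n_atoms == 0:
            raise InvalidArgumentError("empty ligand")
        self.receptor_coords = receptor_coords
        self.tree = tree
        self.layout = tree.layout
        n = self.layout.dim
        c0 = tree.root_centroid
        bounds = np.empty((n, 2))
        bounds[:3, 0] = np.asarray(box_lo, float) - c0
        bounds[:3, 1] = np.asarray(box_hi, float) - c0
        bounds[3:, 0] = -math.pi
        bounds[3:, 1] = math.pi
        self.bounds = bounds
        self._heavy = tree.heavy_mask

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        pos, jac = conformation_with_jacobian(self.tree, coords)
        lig = pos[self._heavy]
        ljac = jac[self._heavy]
        diff = lig[:, None, :] - self.receptor_coords[None, :, :]   # (l, r, 3)
        r = np.sqrt(np.maximum(np.sum(diff * diff, axis=2), 1e-18))
        u, du = pair_potential(r)
        score = float(u.sum())
        # dscore/dpos_l = sum_r du * unit(diff)
        f = np.sum((du / r)[:, :, None] * diff, axis=1)             # (l, 3)
        grad = np.einsum("ai,aij->j", f, ljac)
        return score, grad

    def ligand_pose(self, coords: np.ndarray) -> np.ndarray:
        """Heavy-atom coordinates of the ligand at a point."""
        return apply_conformation(self.tree, coords)[self._heavy]

    def pose_distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Heavy-atom RMSD between two poses (no superposition)."""
        pa, pb = self.ligand_pose(a), self.ligand_pose(b)
        return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def make_toy_docking_objective(receptor_atoms, tree: TorsionTree,
                               box_lo, box_hi) -> ToyDockingObjective:
    """Build the toy docking objective from receptor atoms and a ligand.

    ``receptor_atoms`` may be an ``(R, 3)`` coordinate array or a sequence
    of objects with ``coords``/``is_heavy`` attributes (only heavy atoms
    are scored).
    """
    if hasattr(receptor_atoms, "shape") or (
            len(receptor_atoms) and not hasattr(receptor_atoms[0], "coords")):
        coords = np.atleast_2d(np.asarray(receptor_atoms, float))
    else:
        coords = np.array([a.coords for a in receptor_atoms
                           if getattr(a, "is_heavy", True)], dtype=float)
        if coords.size == 0:
            raise InvalidArgumentError("empty receptor")
    return ToyDockingObjective(coords, tree, np.asarray(box_lo, float),
                               np.asarray(box_hi, float))
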