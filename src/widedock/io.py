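"""File formats, search-box construction and fixture generation.

Covers the PDBQT subset used for rigid receptors and flexible ligands
(ATOM/HETATM records plus ROOT/BRANCH/ENDBRANCH/TORSDOF torsion-tree
records), Vina-style ``key = value`` configuration files, tab-separated
search traces, and seeded toy receptor/ligand fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import TraceRecord, local_optimize
from .objectives import (Branch, InvalidArgumentError, LigandAtom,
                         SearchPoint, TorsionTree, WideDockError,
                         apply_conformation, make_toy_docking_objective)

Atom = LigandAtom


class PDBQTParseError(WideDockError, ValueError):
    """Malformed PDBQT input; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


# ---------------------------------------------------------------------------
# PDBQT subset
# ---------------------------------------------------------------------------

_TYPE_TO_ELEMENT = {"A": "C", "HD": "H", "HS": "H", "NA": "N", "NS": "N",
                    "OA": "O", "OS": "O", "SA": "S"}


def _element_from_type(ad_type: str) -> str:
    ad_type = ad_type.strip()
    if ad_type in _TYPE_TO_ELEMENT:
        return _TYPE_TO_ELEMENT[ad_type]
    return "".join(c for c in ad_type if c.isalpha()) or "C"


def _parse_atom_line(line: str, lineno: int) -> LigandAtom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBQTParseError(f"bad ATOM record: {exc}", lineno) from None
    try:
        charge = float(line[70:76])
    except (ValueError, IndexError):
        charge = 0.0
    ad_type = line[77:79].strip() if len(line) > 77 else ""
    if not ad_type:
        ad_type = name[:1] or "C"
    element = _element_from_type(ad_type)
    return LigandAtom(element=element, coords=np.array([x, y, z]),
                      is_heavy=element != "H", name=name, serial=serial,
                      charge=charge, ad_type=ad_type)


def read_pdbqt(path, role: str = "ligand"):
    """Parse a PDBQT file.

    ``role="receptor"`` returns the atom list (branch records ignored);
    ``role="ligand"`` additionally builds the torsion tree from
    ROOT/BRANCH/TORSDOF records.  Unbalanced BRANCH/ENDBRANCH raises
    :class:`PDBQTParseError` with the line number; a TORSDOF that
    disagrees with the branch count warns, and the branch count wins.
    """
    if role not in ("ligand", "receptor"):
        raise InvalidArgumentError(f"unknown role: {role!r}")
    path = Path(path)
    atoms: list[LigandAtom] = []
    serial_to_idx: dict[int, int] = {}
    records: list[tuple] = []
    root_atoms: list[int] = []
    branches: list[Branch] = []
    branch_stack: list[Branch] = []   # open branches, innermost last
    in_root = False
    saw_root = False
    torsdof: int | None = None

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        tokens = line.split()
        tag = tokens[0].upper() if tokens else ""
        if tag in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            idx = len(atoms)
            atoms.append(atom)
            serial_to_idx[atom.serial] = idx
            records.append(("ATOM", idx, line[:6]))
            if role == "receptor":
                continue
            if in_root:
                root_atoms.append(idx)
            elif branch_stack:
                for br in branch_stack:
                    br.moved.append(idx)
            else:
                root_atoms.append(idx)   # atoms before ROOT: rigid
        elif role == "receptor":
            continue
        elif tag == "ROOT":
            in_root = True
            saw_root = True
            records.append(("ROOT",))
        elif tag == "ENDROOT":
            in_root = False
            records.append(("ENDROOT",))
        elif tag == "BRANCH":
            parts = line.split()
            if len(parts) != 3:
                raise PDBQTParseError("BRANCH needs two atom serials", lineno)
            a, b = int(parts[1]), int(parts[2])
            if a not in serial_to_idx:
                raise PDBQTParseError(f"BRANCH parent serial {a} unknown",
                                      lineno)
            br = Branch(parent=serial_to_idx[a], child=-1, moved=[])
            br._serials = (a, b)      # type: ignore[attr-defined]
            br._order = sum(1 for r in records if r[0] == "BRANCH")  # type: ignore[attr-defined]
            branch_stack.append(br)
            records.append(("BRANCH", a, b))
        elif tag == "ENDBRANCH":
            parts = line.split()
            if len(parts) != 3:
                raise PDBQTParseError("ENDBRANCH needs two atom serials",
                                      lineno)
            a, b = int(parts[1]), int(parts[2])
            if not branch_stack:
                raise PDBQTParseError("ENDBRANCH without open BRANCH", lineno)
            br = branch_stack.pop()
            if br._serials != (a, b):     # type: ignore[attr-defined]
                raise PDBQTParseError(
                    f"ENDBRANCH {a} {b} does not match open BRANCH "
                    f"{br._serials[0]} {br._serials[1]}", lineno)
            if b not in serial_to_idx:
                raise PDBQTParseError(f"BRANCH child serial {b} unknown",
                                      lineno)
            br.child = serial_to_idx[b]
            del br._serials               # type: ignore[attr-defined]
            branches.append(br)
            records.append(("ENDBRANCH", a, b))
        elif tag == "TORSDOF":
            torsdof = int(line.split()[1])
            records.append(("TORSDOF", torsdof))

    if role == "receptor":
        return atoms

    if branch_stack:
        raise PDBQTParseError(
            f"{len(branch_stack)} BRANCH record(s) never closed",
            lineno)
    if not saw_root and not branches:
        # plain coordinate file: whole molecule rigid
        root_atoms = list(range(len(atoms)))
    # restore pre-order (blocks close innermost-first while parsing)
    branches.sort(key=lambda br: br._order)       # type: ignore[attr-defined]
    for br in branches:
        del br._order                             # type: ignore[attr-defined]
    if torsdof is not None and torsdof != len(branches):
        warnings.warn(
            f"TORSDOF {torsdof} disagrees with {len(branches)} BRANCH "
            "records; using the branch count", stacklevel=2)
    tree = TorsionTree(atoms=atoms, root_atoms=root_atoms,
                       branches=branches, torsdof=len(branches),
                       records=records)
    tree.validate()
    return tree


def _format_atom(record: str, atom: LigandAtom, coords: np.ndarray,
                 serial: int) -> str:
    name = atom.name or atom.element
    return (f"{record:<6}{serial:>5} {name:<4} LIG A   1    "
            f"{coords[0]:>8.3f}{coords[1]:>8.3f}{coords[2]:>8.3f}"
            f"{1.00:>6.2f}{0.00:>6.2f}    {atom.charge:>6.3f} "
            f"{atom.ad_type or atom.element:<2}")


def write_pdbqt(atoms: Sequence[LigandAtom], path,
                coords: np.ndarray | None = None) -> None:
    """Write a rigid PDBQT (receptor-style: ATOM records only)."""
    coords = np.asarray(coords, float) if coords is not None else \
        np.array([a.coords for a in atoms])
    lines = [_format_atom("ATOM", a, coords[i], a.serial or i + 1)
             for i, a in enumerate(atoms)]
    Path(path).write_text("\n".join(lines) + "\n")


def _ligand_lines(tree: TorsionTree, coords: np.ndarray) -> list[str]:
    lines = []
    for rec in tree.records:
        if rec[0] == "ATOM":
            _, idx, kind = rec
            lines.append(_format_atom(kind, tree.atoms[idx], coords[idx],
                                      tree.atoms[idx].serial or idx + 1))
        elif rec[0] in ("ROOT", "ENDROOT"):
            lines.append(rec[0])
        elif rec[0] in ("BRANCH", "ENDBRANCH"):
            lines.append(f"{rec[0]} {rec[1]} {rec[2]}")
        elif rec[0] == "TORSDOF":
            lines.append(f"TORSDOF {rec[1]}")
    return lines


def write_ligand_pdbqt(tree: TorsionTree, path,
                       coords: np.ndarray | None = None) -> None:
    """Write a ligand PDBQT preserving its torsion-tree records."""
    coords = tree.coords if coords is None else np.asarray(coords, float)
    Path(path).write_text("\n".join(_ligand_lines(tree, coords)) + "\n")


def write_poses(poses, tree: TorsionTree, path) -> None:
    """Write ranked poses as a multi-model PDBQT.

    Each pose becomes ``MODEL k`` / ``REMARK RESULT score`` / transformed
    atom records / ``ENDMDL``, in score order.
    """
    if not poses:
        raise InvalidArgumentError("no poses to write")
    lines: list[str] = []
    for k, pose in enumerate(poses, start=1):
        coords = apply_conformation(tree, pose.point.coords)
        lines.append(f"MODEL {k}")
        lines.append(f"REMARK RESULT {pose.score:10.4f}")
        lines.extend(_ligand_lines(tree, coords))
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_models(path) -> list[tuple[float, np.ndarray]]:
    """Read (score, coordinates) for each MODEL of a poses file."""
    models: list[tuple[float, np.ndarray]] = []
    score = float("nan")
    coords: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        tag = line[:6].strip().upper()
        if tag == "MODEL":
            score, coords = float("nan"), []
        elif line.startswith("REMARK RESULT"):
            score = float(line.split()[2])
        elif tag in ("ATOM", "HETATM"):
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
        elif tag == "ENDMDL":
            models.append((score, np.array(coords)))
    return models


# ---------------------------------------------------------------------------
# Search boxes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxSpec:
    """A rectangular search box: center and size per axis (Angstrom)."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "size", np.asarray(self.size, float))
        if np.any(self.size <= 0):
            raise InvalidArgumentError("box sizes must be positive")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.size / 2.0

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.size / 2.0


def small_box(ligand_coords: np.ndarray, rng: np.random.Generator,
              pad: float = 5.0, extra: float = 5.0,
              min_dim: float = 22.5) -> BoxSpec:
    """Pocket-sized box around a reference ligand.

    Per dimension: the minimal extent plus ``pad`` on both sides, plus
    ``extra`` added on one randomly chosen side (decentralizing the box),
    then raised to ``min_dim`` (keeping the center) so the ligand can
    rotate.  The random side choice is drawn per dimension.
    """
    coords = np.atleast_2d(np.asarray(ligand_coords, float))
    if coords.size == 0:
        raise InvalidArgumentError("need at least one atom")
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    size = (hi - lo) + 2.0 * pad
    center = (hi + lo) / 2.0
    sides = rng.integers(0, 2, size=3) * 2 - 1     # -1 or +1 per dimension
    center = center + sides * extra / 2.0
    size = size + extra
    size = np.maximum(size, min_dim)
    return BoxSpec(center=center, size=size)


def large_box(receptor_coords: np.ndarray,
              ligand_coords: np.ndarray) -> BoxSpec:
    """Whole-surface box: receptor bounding box expanded on every side by
    the largest ligand dimension, centered on the receptor box center."""
    rec = np.atleast_2d(np.asarray(receptor_coords, float))
    lig = np.atleast_2d(np.asarray(ligand_coords, float))
    if rec.size == 0 or lig.size == 0:
        raise InvalidArgumentError("receptor and ligand must be non-empty")
    rlo, rhi = rec.min(axis=0), rec.max(axis=0)
    lig_extent = lig.max(axis=0) - lig.min(axis=0)
    biggest = float(lig_extent.max())
    return BoxSpec(center=(rlo + rhi) / 2.0,
                   size=(rhi - rlo) + 2.0 * biggest)


# ---------------------------------------------------------------------------
# Vina-style configuration files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"receptor", "ligand", "center_x", "center_y", "center_z",
                "size_x", "size_y", "size_z", "exhaustiveness", "seed",
                "num_modes", "step_multiplier", "mode", "out"}
_FLOAT_KEYS = {"center_x", "center_y", "center_z",
               "size_x", "size_y", "size_z"}
_INT_KEYS = {"exhaustiveness", "seed", "num_modes", "step_multiplier"}


@dataclass
class RunConfigFile:
    """Parsed run configuration (Vina-style key = value dialect)."""

    receptor: str | None = None
    ligand: str | None = None
    center: np.ndarray | None = None
    size: np.ndarray | None = None
    exhaustiveness: int = 8
    seed: int = 0
    num_modes: int = 9
    step_multiplier: int = 1
    mode: str = "small"
    out: str | None = None
    extras: dict = field(default_factory=dict)

    def box(self) -> BoxSpec | None:
        if self.center is None or self.size is None:
            return None
        return BoxSpec(center=self.center, size=self.size)


def read_config(path) -> RunConfigFile:
    """Parse a ``key = value`` configuration file.

    Unknown keys warn (and are kept in ``extras``) rather than fail.
    Explicit mode requires all six box numbers.
    """
    values: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidArgumentError(
                f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            warnings.warn(f"unknown config key {key!r} (ignored)",
                          stacklevel=2)
        values[key] = val

    cfg = RunConfigFile()
    cfg.extras = {k: v for k, v in values.items() if k not in _CONFIG_KEYS}
    for k in ("receptor", "ligand", "mode", "out"):
        if k in values:
            setattr(cfg, k, values[k])
    for k in _INT_KEYS:
        if k in values:
            setattr(cfg, k, int(values[k]))
    box_vals = {k: float(values[k]) for k in _FLOAT_KEYS if k in values}
    if any(k.startswith("center") for k in box_vals):
        missing = _FLOAT_KEYS - set(box_vals)
        if cfg.mode == "explicit" and missing:
            raise InvalidArgumentError(
                f"explicit box needs all six numbers; missing {sorted(missing)}")
        if not missing:
            cfg.center = np.array([box_vals["center_x"], box_vals["center_y"],
                                   box_vals["center_z"]])
            cfg.size = np.array([box_vals["size_x"], box_vals["size_y"],
                                 box_vals["size_z"]])
    return cfg


# ---------------------------------------------------------------------------
# Trace files
# ---------------------------------------------------------------------------

def write_trace(histories: Sequence[np.ndarray],
                trace: Sequence[TraceRecord], path) -> None:
    """Dump a run's trace as tab-separated text.

    One row per walker step: walker, step, stage outcome, p1, p2,
    end-point flag, proposal score, then the N visited coordinates.
    Step-0 rows carry the starting positions (outcome ``-``).
    """
    by_key = {(r.walker, r.step): r for r in trace}
    lines = []
    dim = np.atleast_2d(histories[0]).shape[1] if len(histories) else 0
    header = ["walker", "step", "outcome", "p1", "p2", "end", "score"] + \
        [f"c{i}" for i in range(dim)]
    lines.append("\t".join(header))
    for w, hist in enumerate(histories):
        hist = np.atleast_2d(hist)
        for t in range(hist.shape[0]):
            rec = by_key.get((w, t))
            out = rec.outcome if rec else "-"
            p1 = rec.p1 if rec else 0
            p2 = rec.p2 if rec else 0
            end = int(rec.is_end_point) if rec else 0
            score = f"{rec.score:.6f}" if rec else "nan"
            coords = "\t".join(f"{c:.6f}" for c in hist[t])
            lines.append(f"{w}\t{t}\t{out}\t{p1}\t{p2}\t{end}\t{score}\t"
                         f"{coords}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path) -> tuple[list[np.ndarray], list[TraceRecord]]:
    """Read a trace dump back into histories and trace records."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    n_coord = len([h for h in header if h.startswith("c")])
    hists: dict[int, list[tuple[int, np.ndarray]]] = {}
    trace: list[TraceRecord] = []
    for line in lines[1:]:
        parts = line.split("\t")
        w, t, out = int(parts[0]), int(parts[1]), parts[2]
        p1, p2, end = int(parts[3]), int(parts[4]), bool(int(parts[5]))
        score = float(parts[6])
        coords = np.array([float(x) for x in parts[7:7 + n_coord]])
        hists.setdefault(w, []).append((t, coords))
        if out != "-":
            trace.append(TraceRecord(walker=w, step=t, outcome=out, p1=p1,
                                     p2=p2, is_end_point=end, score=score))
    histories = [np.array([c for _, c in sorted(hists[w])])
                 for w in sorted(hists)]
    trace.sort(key=lambda r: (r.step, r.walker))
    return histories, trace


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _chain_ligand(n_heavy: int, n_rot: int, origin: np.ndarray) -> TorsionTree:
    """Zigzag carbon chain: rigid head plus ``n_rot`` nested branches."""
    if n_heavy < 2 or n_rot > n_heavy - 2:
        raise InvalidArgumentError("need n_heavy >= 2 and n_rot <= n_heavy-2")
    coords = np.zeros((n_heavy, 3))
    for i in range(n_heavy):
        coords[i] = origin + np.array([1.3 * i, 0.75 * (i % 2), 0.0])
    atoms = [LigandAtom(element="C", coords=c, name=f"C{i+1}", serial=i + 1,
                        charge=0.0, ad_type="C")
             for i, c in enumerate(coords)]
    n_root = n_heavy - n_rot
    root_atoms = list(range(n_root))
    branches = []
    for k in range(n_rot):
        parent = n_root - 1 + k
        child = n_root + k
        moved = list(range(child, n_heavy))
        branches.append(Branch(parent=parent, child=child, moved=moved))
    records: list[tuple] = [("ROOT",)]
    records += [("ATOM", i, "ATOM") for i in root_atoms]
    records.append(("ENDROOT",))
    for br in branches:
        records.append(("BRANCH", br.parent + 1, br.child + 1))
        records.append(("ATOM", br.child, "ATOM"))
    for br in reversed(branches):
        records.append(("ENDBRANCH", br.parent + 1, br.child + 1))
    records.append(("TORSDOF", n_rot))
    tree = TorsionTree(atoms=atoms, root_atoms=root_atoms, branches=branches,
                       torsdof=n_rot, records=records)
    tree.validate()
    return tree


def _pocket_rings(center: np.ndarray, n_rings: int, ring_radius: float,
                  rng: np.random.Generator) -> np.ndarray:
    """A tube of atom rings along x forming one binding pocket.

    Ring radii are deliberately irregular (jitter plus a few rim atoms)
    so the pocket has no rotational symmetry and a unique minimum pose.
    """
    pts = []
    for r in range(n_rings):
        x = center[0] + 2.0 * (r - (n_rings - 1) / 2.0)
        for a in range(8):
            ang = 2.0 * np.pi * a / 8 + 0.2 * r
            rad = ring_radius * (1.0 + 0.12 * np.sin(3 * ang + 1.1 * r))
            pts.append([x,
                        center[1] + rad * np.cos(ang),
                        center[2] + rad * np.sin(ang)])
    # asymmetric rim atoms anchor the orientation of the bound pose
    pts.append(center + np.array([2.0 * (n_rings - 1) / 2.0 + 2.5, 2.0, 1.0]))
    pts.append(center + np.array([-2.0 * (n_rings - 1) / 2.0 - 2.5,
                                  -1.5, 2.2]))
    pts = np.array(pts)
    return pts + rng.normal(0.0, 0.25, size=pts.shape)


FIXTURE_KINDS = ("funnel", "two-pocket", "rigid")


def generate_fixture(kind: str, seed: int, out_dir) -> dict:
    """Write a seeded toy receptor/ligand pair and its reference pose.

    ``funnel``: one tube pocket and a 3-bond 8-atom ligand.
    ``two-pocket``: a deep and a shallow pocket (two binding funnels).
    ``rigid``: one pocket and a rigid (TORSDOF 0) 6-atom ligand.

    Returns paths plus the refined ground-truth point and score.  The
    ground truth is the local-optimization end point started from the
    constructed in-pocket placement; tests confirm it is the global
    minimum by grid refinement.
    """
    if kind not in FIXTURE_KINDS:
        raise InvalidArgumentError(f"unknown fixture kind: {kind!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    pocket_a = np.array([15.0, 15.0, 15.0])
    if kind == "rigid":
        tree = _chain_ligand(6, 0, origin=np.array([5.0, 5.0, 5.0]))
        receptor = _pocket_rings(pocket_a, n_rings=5, ring_radius=4.1,
                                 rng=rng)
    else:
        tree = _chain_ligand(8, 3, origin=np.array([5.0, 5.0, 5.0]))
        receptor = _pocket_rings(pocket_a, n_rings=6, ring_radius=4.1,
                                 rng=rng)
        if kind == "two-pocket":
            pocket_b = np.array([32.0, 15.0, 15.0])
            receptor = np.vstack([
                receptor,
                _pocket_rings(pocket_b, n_rings=3, ring_radius=4.1, rng=rng)])

    rec_atoms = [LigandAtom(element="C", coords=c, name="C", serial=i + 1,
                            ad_type="C") for i, c in enumerate(receptor)]

    box_lo = receptor.min(axis=0) - 12.0
    box_hi = receptor.max(axis=0) + 12.0
    objective = make_toy_docking_objective(receptor, tree, box_lo, box_hi)

    # ground truth: coarse translation grid over the box, refine the best
    # starts (plus the constructed in-pocket guess) and keep the deepest
    # end point
    lig_centroid = tree.coords.mean(axis=0)
    starts = [pocket_a - lig_centroid]
    lo, hi = objective.bounds[:3, 0], objective.bounds[:3, 1]
    grid = [np.array([x, y, z])
            for x in np.linspace(lo[0], hi[0], 9)
            for y in np.linspace(lo[1], hi[1], 9)
            for z in np.linspace(lo[2], hi[2], 9)]
    scored = []
    for t in grid:
        p = np.zeros(objective.dim)
        p[:3] = t
        scored.append((objective.evaluate(p)[0], tuple(t)))
    scored.sort()
    starts.extend(np.asarray(t) for _, t in scored[:10])
    truth = None
    for t in starts:
        p = np.zeros(objective.dim)
        p[:3] = t
        end = local_optimize(objective.evaluate_point(p), objective,
                             max_iters=500)
        if truth is None or end.score < truth.score:
            truth = end

    receptor_path = out_dir / "receptor.pdbqt"
    ligand_path = out_dir / "ligand.pdbqt"
    reference_path = out_dir / "reference.pdbqt"
    truth_path = out_dir / "ground_truth.json"
    write_pdbqt(rec_atoms, receptor_path)
    write_ligand_pdbqt(tree, ligand_path)
    write_ligand_pdbqt(tree, reference_path,
                       apply_conformation(tree, truth.coords))
    truth_path.write_text(json.dumps(
        {"kind": kind, "seed": seed,
         "point": [round(float(c), 6) for c in truth.coords],
         "score": round(float(truth.score), 6)}, indent=1) + "\n")
    return {"receptor": receptor_path, "ligand": ligand_path,
            "reference": reference_path, "ground_truth": truth_path,
            "point": truth, "objective": objective}


def randomize_conformation(tree: TorsionTree, box: BoxSpec,
                           rng: np.random.Generator,
                           receptor_coords: np.ndarray | None = None,
                           clash_ceiling: float = 1.0,
                           max_tries: int = 1000) -> SearchPoint:
    """Draw a uniform random conformation in the box, rejecting poses
    that score above a steric-clash ceiling (when a receptor is given)."""
    objective = None
    if receptor_coords is not None and len(receptor_coords):
        objective = make_toy_docking_objective(receptor_coords, tree,
                                               box.lo, box.hi)
    c0 = tree.root_centroid
    n = 6 + tree.n_rotatable_bonds
    for _ in range(max_tries):
        point = np.zeros(n)
        point[:3] = rng.uniform(box.lo, box.hi) - c0
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        point[3:6] = axis * rng.uniform(0.0, np.pi)
        point[6:] = rng.uniform(-np.pi, np.pi, size=n - 6)
        if objective is None:
            return SearchPoint(point)
        sp = objective.evaluate_point(point)
        if sp.score < clash_ceiling:
            return sp
    raise WideDockError("could not draw a clash-free conformation")
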