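"""HOLE-style pore radius profiling along a channel axis.

At each axial position the largest sphere touching no van der Waals surface
is found by a deterministic coarse-grid search in the plane normal to the
axis followed by pattern-search refinement (no simulated annealing), so a
given configuration always reproduces the same profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._geom import plane_basis
from .structure import StructureModel, WaterSite

#: fallback Bondi-style radii for elements gemmi does not tabulate usefully
_VDW_OVERRIDES = {"X": 1.70}


@dataclass
class VdwTable:
    """Element → van der Waals radius (Å); defaults from gemmi's Bondi-style set."""

    overrides: dict[str, float] = field(default_factory=dict)

    def radius(self, element: str) -> float:
        r = self.overrides.get(element) or _VDW_OVERRIDES.get(element)
        if r is None:
            r = float(gemmi.Element(element).vdw_r)
            if r <= 0:
                r = 1.7
        if r <= 0:
            raise ValueError(f"non-positive vdW radius for {element}")
        return r


@dataclass
class ChannelAxis:
    """Channel axis; z = 0 at origin, negative z on the extracellular side."""

    origin: np.ndarray
    direction: np.ndarray
    z_range: tuple[float, float]

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero direction vector")
        self.direction = d / n
        if not self.z_range[0] < self.z_range[1]:
            raise ValueError("empty z_range")

    def z_of(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.origin) @ self.direction

    def lateral_of(self, coords: np.ndarray) -> np.ndarray:
        rel = np.asarray(coords) - self.origin
        z = rel @ self.direction
        return np.linalg.norm(rel - np.outer(np.atleast_1d(z), self.direction).reshape(rel.shape), axis=-1)

    def point_at(self, z: float) -> np.ndarray:
        return self.origin + z * self.direction


@dataclass
class PoreProfile:
    step: float
    samples: list[tuple[float, np.ndarray, float]]  # (z, center, radius)
    wall_water_labels: list[str] = field(default_factory=list)
    open_flags: list[bool] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples])

    @property
    def radius(self) -> np.ndarray:
        return np.array([s[2] for s in self.samples])

    def radius_at(self, z: float) -> float:
        i = int(np.argmin(np.abs(self.z - z)))
        return self.samples[i][2]


def find_npa_anchors(model: StructureModel, chain_id: str):
    """The two NPA asparagines of a chain (side-chain amide N atoms)."""
    from .structure import extract_sequence, npa_spacing

    seq = extract_sequence(model, chain_id)
    res = model.chain(chain_id)
    info = npa_spacing(seq)
    i, j = info["motif_indices"]
    return res[i], res[j]


def define_axis(
    model: StructureModel,
    chain_id: str,
    anchors=None,
    z_range: tuple[float, float] = (-25.0, 25.0),
    channel_waters: list[WaterSite] | None = None,
) -> ChannelAxis:
    """Axis through the channel: origin at the NPA amide-N midpoint by default.

    Direction is the least-squares line through labelled channel-water oxygens
    when at least four are available, else the line through the two anchors'
    Cα atoms.  Orientation follows the configured convention (extracellular
    negative); callers may flip the returned direction if their reference
    frame differs.
    """
    if channel_waters is None:
        channel_waters = [w for w in model.waters if w.label] or list(model.waters)
    if anchors is None:
        try:
            anchors = find_npa_anchors(model, chain_id)
        except Exception as exc:
            if len(channel_waters) >= 4:
                anchors = None  # water-line fallback below
            else:
                avail = [f"{r.name}{r.number}" for r in model.chain(chain_id)][:40]
                raise ValueError(
                    f"cannot locate NPA anchor residues ({exc}); "
                    f"residues present: {avail}..."
                ) from exc
    if anchors is not None:
        n1 = anchors[0].atom("ND2") or anchors[0].atom("CA")
        n2 = anchors[1].atom("ND2") or anchors[1].atom("CA")
        if n1 is None or n2 is None:
            raise ValueError("anchor residues lack ND2/CA atoms")
        origin = 0.5 * (n1.coords + n2.coords)
    else:
        origin = np.array([w.coords for w in channel_waters]).mean(axis=0)
    if len(channel_waters) >= 4:
        pts = np.array([w.coords for w in channel_waters])
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
    else:
        c1 = anchors[0].atom("CA")
        c2 = anchors[1].atom("CA")
        if c1 is None or c2 is None:
            raise ValueError("anchor residues lack CA atoms for direction")
        direction = c2.coords - c1.coords
    return ChannelAxis(origin, direction, z_range)


def _wall_atoms(
    model: StructureModel, vdw: VdwTable, wall_water_labels: list[str] | None
):
    coords, radii = [], []
    for a in model.polymer_atoms(primary_only=True):
        if a.is_hydrogen:
            continue
        coords.append(a.coords)
        radii.append(vdw.radius(a.element))
    for label in wall_water_labels or []:
        w = model.water_by_label(label)  # raises KeyError for unknown labels
        coords.append(w.coords)
        radii.append(vdw.radius("O"))
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


class _ClearanceField:
    """min over wall atoms of (distance − vdW), via per-radius KD-trees."""

    def __init__(self, coords: np.ndarray, radii: np.ndarray):
        self.groups = []
        rounded = np.round(radii, 3)
        for r in np.unique(rounded):
            pts = coords[rounded == r]
            self.groups.append((cKDTree(pts), float(r)))

    def eval(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        best = np.full(len(points), np.inf)
        for tree, r in self.groups:
            d, _ = tree.query(points, k=1)
            np.minimum(best, d - r, out=best)
        return best


def compute_profile(
    model: StructureModel,
    axis: ChannelAxis,
    step: float = 0.25,
    vdw: VdwTable | None = None,
    coarse: float = 0.2,
    fine: float = 0.02,
    max_offaxis: float = 8.0,
    r_cap: float = 10.0,
    wall_water_labels: list[str] | None = None,
) -> PoreProfile:
    """Maximal-inscribed-sphere radius r(z) along the axis.

    Only polymer heavy atoms form the wall by default; waters named in
    ``wall_water_labels`` are added with the oxygen vdW radius.  Planes with
    no wall atom within reach report ``r_cap`` with an open flag.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    vdw = vdw or VdwTable()
    coords, radii = _wall_atoms(model, vdw, wall_water_labels)
    if len(coords) == 0:
        raise ValueError("no wall atoms")
    field = _ClearanceField(coords, radii)
    u, v = plane_basis(axis.direction)
    zs = np.arange(axis.z_range[0], axis.z_range[1] + step / 2, step)
    n_coarse = int(np.floor(max_offaxis / coarse))
    offsets = np.array(
        [
            (i * coarse, j * coarse)
            for i in range(-n_coarse, n_coarse + 1)
            for j in range(-n_coarse, n_coarse + 1)
            if (i * coarse) ** 2 + (j * coarse) ** 2 <= max_offaxis**2
        ]
    )
    moves = np.array([(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1)])
    samples, open_flags = [], []
    for z in zs:
        p0 = axis.point_at(z)
        cand = p0 + offsets[:, :1] * u + offsets[:, 1:] * v
        clear = field.eval(cand)
        best_i = int(np.argmax(clear))
        best_xy = offsets[best_i].copy()
        best_r = float(clear[best_i])
        # deterministic pattern-search refinement
        h = coarse / 2
        while h >= fine:
            improved = True
            while improved:
                improved = False
                for m in moves:
                    xy = best_xy + m * h
                    if xy[0] ** 2 + xy[1] ** 2 > max_offaxis**2:
                        continue
                    r = float(field.eval(p0 + xy[0] * u + xy[1] * v)[0])
                    if r > best_r + 1e-12:
                        best_r, best_xy = r, xy
                        improved = True
            h /= 2
        center = p0 + best_xy[0] * u + best_xy[1] * v
        samples.append((float(z), center, min(best_r, r_cap)))
        open_flags.append(best_r >= r_cap)
    return PoreProfile(step, samples, list(wall_water_labels or []), open_flags)


def profile_with_wall_waters(
    model: StructureModel,
    axis: ChannelAxis,
    step: float = 0.25,
    vdw: VdwTable | None = None,
    water_labels: list[str] | None = None,
    **kwargs,
) -> PoreProfile:
    """Profile with the named waters' oxygens treated as part of the wall."""
    return compute_profile(
        model, axis, step=step, vdw=vdw, wall_water_labels=water_labels or [], **kwargs
    )


def min_constriction(profile: PoreProfile) -> tuple[float, float]:
    """(z, diameter) of the global minimum; ties resolved to the smallest z."""
    if not profile.samples:
        raise ValueError("empty profile")
    r = profile.radius
    i = int(np.argmin(r))  # argmin returns the first (smallest-z) minimum
    return profile.samples[i][0], 2.0 * float(r[i])


def pore_length(profile: PoreProfile, bulk_radius_threshold: float = 5.0) -> dict:
    """Contiguous z-extent around the constriction with radius < threshold."""
    r = profile.radius
    z = profile.z
    if np.all(r >= bulk_radius_threshold):
        raise ValueError("threshold never crossed: profile entirely above it")
    imin = int(np.argmin(r))
    lo = imin
    while lo > 0 and r[lo - 1] < bulk_radius_threshold:
        lo -= 1
    hi = imin
    while hi < len(r) - 1 and r[hi + 1] < bulk_radius_threshold:
        hi += 1
    return {"length": float(z[hi] - z[lo]), "z_start": float(z[lo]), "z_end": float(z[hi])}
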