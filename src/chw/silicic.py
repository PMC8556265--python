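"""Geometric placement of silicic acid, Si(OH)4, onto channel-water positions.

Silicic acid is an uncharged hydrophilic tetrahedron: four hydroxyl oxygens
1.63 Å from the silicon at the ideal tetrahedral angle (109.47°), giving an
O–O edge of 2·1.63·sin(109.47°/2) ≈ 2.662 Å.  Candidate positions in a
channel are generated by rigid-body superposition of the hydroxyl oxygens
onto subsets of crystallographic water oxygens — the premise being that the
hydroxyls favour the hydrated sites the waters mark — then screened for
steric clashes and scored by the hydrogen bonds they could donate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from ._geom import apply_rigid, kabsch
from .pore import ChannelAxis, VdwTable
from .structure import StructureModel, WaterSite
from .waters import POLAR_ELEMENTS

D_SIO = 1.63  # Å
TET_ANGLE = 109.47122063449069  # degrees, arccos(-1/3)


@dataclass
class SilicicAcid:
    si: np.ndarray
    oxygens: np.ndarray  # (4, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SilicicAcid":
        return SilicicAcid(
            apply_rigid(rotation, translation, self.si[None, :])[0],
            apply_rigid(rotation, translation, self.oxygens),
        )


@dataclass
class PlacementResult:
    silicic: SilicicAcid
    water_mapping: dict[int, str | int]  # oxygen index -> water label/id
    rmsd: float
    clashes: int
    hbond_partners: list[tuple[int, str, float]] = field(default_factory=list)
    mapped_indices: tuple[int, ...] = ()


def build_template() -> SilicicAcid:
    """Ideal Si(OH)4: Si at the origin, oxygens at tetrahedral vertices."""
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    return SilicicAcid(np.zeros(3), verts * D_SIO)


def _water_key(w: WaterSite):
    return w.label if w.label else w.oxygen.residue_number


def _axis_rotation(axis_vec: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis_vec / np.linalg.norm(axis_vec) * angle).as_matrix()


def fit_to_waters(
    template: SilicicAcid,
    waters: list[WaterSite],
    model: StructureModel | None = None,
    clash_tol: float = 0.4,
    vdw: VdwTable | None = None,
    d_max: float = 3.4,
    _ctx: "_ModelContext | None" = None,
) -> PlacementResult:
    """Best rigid fit of template hydroxyl oxygens onto 2–4 water positions.

    All injective oxygen↔water assignments are tried (brute force over ≤ 4!
    permutations); the best is chosen by (rmsd, clashes).  For two waters the
    rotation about the O–O axis is unconstrained by the fit and is resolved
    by minimizing clashes, then maximizing potential hydrogen-bond partners.
    """
    n = len(waters)
    if n < 2 or n > 4:
        raise ValueError("fit requires 2-4 waters (choose subsets upstream)")
    keys = [_water_key(w) for w in waters]
    if len(set(keys)) != n:
        raise ValueError("duplicate waters in fit")
    targets = np.array([w.coords for w in waters])
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(targets[i] - targets[j]) < 1e-6:
                raise ValueError("duplicate water coordinates in fit")
    ctx = _ctx if _ctx is not None else (_ModelContext(model, vdw) if model is not None else None)
    best: tuple | None = None
    for perm in permutations(range(4), n):
        pts = template.oxygens[list(perm)]
        if n == 2:
            placed, rmsd = _fit_two_point(template, perm, targets, ctx, clash_tol, vdw, d_max)
        else:
            rot, trans, rmsd = kabsch(pts, targets)
            placed = template.transformed(rot, trans)
        clashes = _count_clashes(placed, ctx, clash_tol, vdw)
        cand = (round(rmsd, 9), clashes, perm, placed)
        if best is None or cand[:2] < best[:2]:
            best = cand
    rmsd, clashes, perm, placed = best[0], best[1], best[2], best[3]
    mapping = {oxy_idx: keys[w_idx] for w_idx, oxy_idx in enumerate(perm)}
    result = PlacementResult(placed, mapping, float(rmsd), clashes, mapped_indices=tuple(perm))
    if ctx is not None:
        excluded = frozenset(id(w.oxygen) for w in waters)
        result.hbond_partners = _hbonds_from_ctx(placed.oxygens, ctx, d_max, excluded)
    return result


def _fit_two_point(template, perm, targets, ctx, clash_tol, vdw, d_max):
    """Two-point fit: superpose the O–O segment, then scan the free torsion."""
    pts = template.oxygens[list(perm)]
    with warnings.catch_warnings():
        # two points leave the rotation about their axis undefined; the
        # torsion scan below resolves it deliberately
        warnings.simplefilter("ignore", UserWarning)
        rot, trans, rmsd = kabsch(pts, targets)
    base = template.transformed(rot, trans)
    axis_vec = targets[1] - targets[0]
    pivot = targets.mean(axis=0)
    best = None
    for angle_deg in range(0, 360, 10):
        r = _axis_rotation(axis_vec, np.deg2rad(angle_deg))
        placed = SilicicAcid(
            r @ (base.si - pivot) + pivot,
            (base.oxygens - pivot) @ r.T + pivot,
        )
        clashes = _count_clashes(placed, ctx, clash_tol, vdw)
        n_hb = len(_hbonds_from_ctx(placed.oxygens, ctx, d_max))
        key = (clashes, -n_hb, angle_deg)
        if best is None or key < best[0]:
            best = (key, placed)
    return best[1], rmsd


class _ModelContext:
    """Precomputed atom arrays so many fits against one model stay cheap."""

    def __init__(self, model: StructureModel, vdw: VdwTable | None = None):
        vdw = vdw or VdwTable()
        coords, radii = [], []
        for a in model.polymer_atoms(primary_only=True):
            if not a.is_hydrogen:
                coords.append(a.coords)
                radii.append(vdw.radius(a.element))
        self.wall_coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.wall_radii = np.asarray(radii, dtype=float)
        polar, tags = [], []
        for a in model.iter_atoms(primary_only=True):
            if a.element in POLAR_ELEMENTS:
                polar.append(a.coords)
                tags.append((id(a), f"{a.residue_name}{a.residue_number}:{a.name}"))
        self.polar_coords = np.asarray(polar, dtype=float).reshape(-1, 3)
        self.polar_tags = tags


def _count_clashes(silicic: SilicicAcid, ctx, clash_tol, vdw) -> int:
    """Protein heavy atoms within (vdW sum − clash_tol) of Si or any O."""
    if ctx is None or len(ctx.wall_coords) == 0:
        return 0
    vdw = vdw or VdwTable()
    si_r = 2.1  # Bondi-style Si
    probe = np.vstack([silicic.si[None, :], silicic.oxygens])
    probe_r = np.array([si_r] + [vdw.radius("O")] * 4)
    d = np.linalg.norm(probe[:, None, :] - ctx.wall_coords[None, :, :], axis=2)
    clash = d < probe_r[:, None] + ctx.wall_radii[None, :] - clash_tol
    return int(np.count_nonzero(clash.any(axis=0)))


def placement_hbonds(
    placement: PlacementResult,
    model: StructureModel,
    d_max: float = 3.4,
    exclude: list[WaterSite] | None = None,
) -> list[tuple[int, str, float]]:
    """Polar partners within d_max of each hydroxyl oxygen.

    Waters the placement was fitted onto are excluded (the hydroxyls replace
    them); every hydroxyl is assumed donor-capable (hydrogens unmodelled).
    """
    excluded = frozenset(id(w.oxygen) for w in (exclude or []))
    ctx = _ModelContext(model)
    return _hbonds_from_ctx(placement.silicic.oxygens, ctx, d_max, excluded)


def _hbonds_from_ctx(oxygens, ctx, d_max, excluded_ids=frozenset()):
    if ctx is None or len(ctx.polar_coords) == 0:
        return []
    d = np.linalg.norm(np.asarray(oxygens)[:, None, :] - ctx.polar_coords[None, :, :], axis=2)
    out = []
    for i, j in zip(*np.nonzero(d <= d_max + 1e-9)):
        aid, tag = ctx.polar_tags[j]
        if aid in excluded_ids:
            continue
        out.append((int(i), tag, float(d[i, j])))
    return out


def enumerate_placements(
    model: StructureModel,
    channel_waters: list[WaterSite],
    axis: ChannelAxis | None = None,
    rmsd_max: float = 1.0,
    clash_tol: float = 0.4,
    dedup_radius: float = 2.0,
    combinatorial: bool = False,
) -> list[PlacementResult]:
    """Rank tetrahedron placements over z-contiguous windows of 2–4 waters.

    Windows mirror the axial ladder of candidate substrate positions along a
    channel; ``combinatorial=True`` instead tries every 2–4 subset.  Valid
    placements (rmsd ≤ rmsd_max, zero clashes) are ranked by mapped-oxygen
    count (descending) then rmsd, and near-duplicate silicon positions
    (Si–Si < ``dedup_radius``) keep only the better-ranked placement.
    """
    if len(channel_waters) < 2:
        raise ValueError("need at least two channel waters")
    waters = list(channel_waters)
    if axis is not None:
        waters.sort(key=lambda w: float(axis.z_of(w.coords)))
    template = build_template()
    ctx = _ModelContext(model) if model is not None else None
    subsets = []
    if combinatorial:
        from itertools import combinations

        for k in (4, 3, 2):
            subsets.extend(combinations(range(len(waters)), k))
    else:
        for k in (4, 3, 2):
            for i in range(len(waters) - k + 1):
                subsets.append(tuple(range(i, i + k)))
    results = []
    for subset in subsets:
        group = [waters[i] for i in subset]
        try:
            res = fit_to_waters(template, group, model=model, clash_tol=clash_tol,
                                _ctx=ctx)
        except ValueError:
            continue
        if res.rmsd <= rmsd_max and res.clashes == 0:
            results.append(res)
    results.sort(key=lambda r: (-len(r.water_mapping), r.rmsd))
    kept: list[PlacementResult] = []
    for res in results:
        if all(np.linalg.norm(res.silicic.si - k.silicic.si) >= dedup_radius for k in kept):
            kept.append(res)
    return kept
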