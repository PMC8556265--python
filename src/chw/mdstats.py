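"""Trajectory statistics: channel occupancy counts, site occupancy and
exchange (residence) times, permeation events, and axial density profiles.

The container is a plain frame-major coordinate array; file I/O (multi-frame
XYZ, multi-model PDB) goes through MDAnalysis.  A binding site is occupied
in a frame when at least one candidate atom lies within the site radius
(default 1.4 Å, one water radius, around the crystallographic position); the
exchange time τ is the mean length of maximal same-occupant residence
episodes, with interruptions up to ``gap_tolerance`` frames merged to
suppress single-frame flicker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Trajectory:
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å
    dt: float  # ns per frame
    names: list[str] = field(default_factory=list)
    resnames: list[str] = field(default_factory=list)
    resids: list[int] = field(default_factory=list)
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.coords.shape[1]
        if not self.names:
            self.names = ["O"] * n
        if not self.resnames:
            self.resnames = ["HOH"] * n
        if not self.resids:
            self.resids = list(range(1, n + 1))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, selection: str) -> np.ndarray:
        """Atom indices for a named selection: water_O, solute, or all."""
        if selection == "all":
            return np.arange(self.n_atoms)
        if selection == "water_O":
            return np.array(
                [i for i, (n, r) in enumerate(zip(self.names, self.resnames))
                 if r in ("HOH", "WAT", "TIP3", "SOL") and n.startswith("O")],
                dtype=int,
            )
        if selection == "solute":
            return np.array(
                [i for i, r in enumerate(self.resnames)
                 if r not in ("HOH", "WAT", "TIP3", "SOL")],
                dtype=int,
            )
        raise ValueError(f"unknown selection {selection!r}")


def read_trajectory(path: str | Path, dt: float, fmt: str | None = None) -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB file via MDAnalysis."""
    import MDAnalysis as mda

    u = mda.Universe(str(path), format=fmt, topology_format=fmt)
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    try:
        resnames = list(u.atoms.resnames)
        resids = list(u.atoms.resids)
    except Exception:  # XYZ files carry no residue metadata
        resnames, resids = [], []
    return Trajectory(coords, dt, names=list(u.atoms.names), resnames=resnames,
                      resids=resids)


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write frames as concatenated XYZ blocks (element + coordinates)."""
    import MDAnalysis as mda

    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    u.add_TopologyAttr("names", [n[:1] or "X" for n in traj.names])
    with mda.Writer(str(path), traj.n_atoms) as w:
        for frame in traj.coords:
            u.atoms.positions = frame
            w.write(u.atoms)


@dataclass
class Site:
    center: np.ndarray
    radius: float = 1.4
    label: str = "site"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("site radius must be positive")


@dataclass
class OccupancyStats:
    occupancy: float
    tau: float | None
    n_exchanges: int
    occupant_history: np.ndarray  # per-frame occupant index, -1 when vacant
    dt: float


@dataclass
class PermeationEvent:
    molecule: int
    entry_frame: int
    exit_frame: int
    direction: str  # in | out

    def __post_init__(self):
        if self.entry_frame >= self.exit_frame:
            raise ValueError("entry must precede exit")


def channel_counts(
    traj: Trajectory,
    z_interval: tuple[float, float],
    lateral_max: float,
    selection: str = "water_O",
    axis_origin=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
) -> dict:
    """Per-frame count of selected atoms inside the channel cylinder.

    Returns per-frame counts plus mean and population standard deviation.
    """
    idx = traj.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    origin = np.asarray(axis_origin, dtype=float)
    direction = np.asarray(axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    rel = traj.coords[:, idx, :] - origin
    z = rel @ direction
    lateral = np.linalg.norm(rel - z[..., None] * direction, axis=-1)
    inside = (z >= z_interval[0]) & (z <= z_interval[1]) & (lateral <= lateral_max)
    counts = inside.sum(axis=1)
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "sd": float(counts.std()),  # population sd
    }


def site_occupancy(traj: Trajectory, site: Site, candidates: np.ndarray | None = None) -> OccupancyStats:
    """Occupancy fraction and per-frame occupant identity for one site."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if candidates is None:
        candidates = np.arange(traj.n_atoms)
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        raise ValueError("no candidate atoms")
    d = np.linalg.norm(traj.coords[:, candidates, :] - site.center, axis=-1)
    within = d <= site.radius
    occupied = within.any(axis=1)
    nearest = candidates[np.argmin(d, axis=1)]
    history = np.where(occupied, nearest, -1)
    occupancy = float(occupied.mean())
    stats = OccupancyStats(occupancy, None, 0, history, traj.dt)
    if occupied.any():
        tau, n_ep = exchange_time(stats, traj.dt)
        stats.tau = tau
        stats.n_exchanges = n_ep
    return stats


def _episodes(history: np.ndarray, gap_tolerance: int) -> list[tuple[int, int, int]]:
    """Maximal same-occupant runs, merging vacancies ≤ gap_tolerance frames."""
    episodes = []
    cur_id, start, last_seen = None, None, None
    for f, occ in enumerate(history):
        if occ >= 0:
            if cur_id is None:
                cur_id, start = occ, f
            elif occ == cur_id and f - last_seen <= gap_tolerance + 1:
                pass
            else:
                episodes.append((cur_id, start, last_seen))
                cur_id, start = occ, f
            last_seen = f
        else:
            if cur_id is not None and f - last_seen > gap_tolerance:
                episodes.append((cur_id, start, last_seen))
                cur_id = None
    if cur_id is not None:
        episodes.append((cur_id, start, last_seen))
    return episodes


def exchange_time(stats: OccupancyStats, dt: float, gap_tolerance: int = 1) -> tuple[float, int]:
    """Mean residence-episode duration τ (ns) and the episode count."""
    eps = _episodes(stats.occupant_history, gap_tolerance)
    if not eps:
        raise ValueError("no residence episodes; tau undefined")
    durations = np.array([(e[2] - e[1] + 1) for e in eps], dtype=float)
    return float(durations.mean() * dt), len(eps)


def count_permeations(
    traj: Trajectory,
    z_top: float,
    z_bottom: float,
    selection: str = "solute",
    axis_origin=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
) -> list[PermeationEvent]:
    """Full channel crossings: enter one boundary plane, exit the other.

    ``direction='in'`` means top → bottom (extracellular → intracellular under
    the axis convention).  A molecule that re-crosses its entry boundary
    before reaching the far one is a partial entry and is discarded.  When a
    periodic box is present the axial coordinate is unwrapped first.
    """
    if z_top <= z_bottom:
        raise ValueError("z_top must exceed z_bottom")
    idx = traj.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    origin = np.asarray(axis_origin, dtype=float)
    direction = np.asarray(axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    z = (traj.coords[:, idx, :] - origin) @ direction  # (frames, molecules)
    if traj.box is not None:
        lz = float(np.median(traj.box[:, 2]))
        dz = np.diff(z, axis=0)
        dz -= lz * np.rint(dz / lz)
        z = np.vstack([z[:1], z[:1] + np.cumsum(dz, axis=0)])
    events = []
    for m in range(z.shape[1]):
        state = "outside"  # outside | from_top | from_bottom
        entry_frame = -1
        for f in range(1, z.shape[0]):
            prev, cur = z[f - 1, m], z[f, m]
            if state == "outside":
                if prev > z_top >= cur:
                    state, entry_frame = "from_top", f
                elif prev < z_bottom <= cur:
                    state, entry_frame = "from_bottom", f
            elif state == "from_top":
                if cur < z_bottom:
                    events.append(PermeationEvent(int(idx[m]), entry_frame, f, "in"))
                    state = "outside"
                elif cur > z_top:
                    state = "outside"  # retreated: partial entry
            elif state == "from_bottom":
                if cur > z_top:
                    events.append(PermeationEvent(int(idx[m]), entry_frame, f, "out"))
                    state = "outside"
                elif cur < z_bottom:
                    state = "outside"
    return events


def axial_density(
    traj: Trajectory,
    selection: str = "solute",
    bin_width: float = 1.0,
    z_range: tuple[float, float] = (-20.0, 20.0),
    lateral_max: float | None = None,
    bottleneck_fraction: float = 0.25,
    axis_origin=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
) -> dict:
    """Per-frame-normalized axial density histogram with bottleneck detection.

    A bottleneck is a contiguous run of bins whose density falls below
    ``bottleneck_fraction`` × median, flanked on both sides by higher density.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    idx = traj.select(selection)
    origin = np.asarray(axis_origin, dtype=float)
    direction = np.asarray(axis_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    rel = traj.coords[:, idx, :] - origin
    z = rel @ direction
    mask = np.ones_like(z, dtype=bool)
    if lateral_max is not None:
        lateral = np.linalg.norm(rel - z[..., None] * direction, axis=-1)
        mask = lateral <= lateral_max
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    hist, _ = np.histogram(z[mask], bins=edges)
    density = hist / traj.n_frames
    med = float(np.median(density))
    low = density < bottleneck_fraction * med if med > 0 else np.zeros_like(density, dtype=bool)
    bottlenecks = []
    i = 0
    while i < len(density):
        if low[i]:
            j = i
            while j + 1 < len(density) and low[j + 1]:
                j += 1
            if i > 0 and j < len(density) - 1:  # flanked by higher density
                bottlenecks.append((float(edges[i]), float(edges[j + 1])))
            i = j + 1
        else:
            i += 1
    return {"edges": edges, "density": density, "bottlenecks": bottlenecks}
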