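"""Synthetic fixtures with known ground truth for every pipeline stage.

Generators emulate the study conditions each analysis is meant for — a
membrane-channel-like pore built from pseudo-atom rings with a prescribed
radius profile and placed waters, Wilson-like (exponential) reflection
intensities modulated by the two-lattice translocation model, two-state
Markov site occupancy with geometric dwell times (the discrete analogue of
exponential residence), and scripted permeation paths.  All randomness
flows through one explicitly passed seeded generator; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ltd import DefectModel, ReflectionSet, modulate_intensities
from .mdstats import Trajectory
from .structure import Atom, Residue, StructureModel, WaterSite


@dataclass
class PoreSpec:
    """Stacked pseudo-atom rings realizing a radius profile, plus waters."""

    radius_profile: Callable[[float], float]
    z_range: tuple[float, float] = (-20.0, 20.0)
    ring_spacing: float = 0.5
    atoms_per_ring: int = 16
    vdw: float = 1.7
    n_shells: int = 3  # concentric shells make the wall radially solid
    shell_gap: float = 2.0
    water_positions: Sequence[tuple[float, float]] = ()  # (z, lateral offset)

    def __post_init__(self):
        if self.ring_spacing <= 0:
            raise ValueError("ring spacing must be positive")


def make_toy_pore(spec: PoreSpec) -> StructureModel:
    """Deterministic toy channel: pseudo-atom rings stacked along +z.

    Rings are stored as glycine-named pseudo-residues of carbon atoms so the
    file round-trips through PDB as polymer (the profiler sees only element
    and coordinates); waters are placed at (z, lateral) with the lateral
    offset along +x.  Successive rings are rotated by half the angular
    spacing so ring gaps do not align into artificial side channels.
    """
    model = StructureModel(identifier="toy_pore")
    residues = []
    zs = np.arange(spec.z_range[0], spec.z_range[1] + spec.ring_spacing / 2,
                   spec.ring_spacing)
    resnum = 1
    for k, z in enumerate(zs):
        r = float(spec.radius_profile(float(z)))
        if r <= spec.vdw:
            raise ValueError(f"ring radius {r} at z={z} not larger than vdW {spec.vdw}")
        atoms = []
        i = 0
        for shell in range(spec.n_shells):
            r_shell = r + shell * spec.shell_gap
            # keep the azimuthal atom spacing roughly constant across shells
            n_at = max(3, int(round(spec.atoms_per_ring * r_shell / r)))
            angles = (np.arange(n_at) + 0.5 * (k % 2)) * (2 * np.pi / n_at)
            for th in angles:
                i += 1
                atoms.append(
                    Atom(
                        element="C", name=f"C{i}", alt_loc="",
                        coords=np.array([r_shell * np.cos(th), r_shell * np.sin(th), z]),
                        b_factor=20.0, occupancy=1.0, residue_name="GLY",
                        residue_number=resnum, insertion_code="", chain_id="A",
                        is_hetero=False, is_water=False,
                    )
                )
        residues.append(Residue("GLY", resnum, "", "A", atoms))
        resnum += 1
    model.chains["A"] = residues
    for j, (z, lateral) in enumerate(spec.water_positions, start=1):
        oxy = Atom(
            element="O", name="O", alt_loc="",
            coords=np.array([lateral, 0.0, z]),
            b_factor=30.0, occupancy=1.0, residue_name="HOH",
            residue_number=1000 + j, insertion_code="", chain_id="W",
            is_hetero=True, is_water=True,
        )
        model.waters.append(WaterSite(oxygen=oxy))
    return model


def make_defect_reflections(
    n: int,
    model: DefectModel,
    wilson_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    hkl_max: int = 30,
) -> tuple[ReflectionSet, ReflectionSet]:
    """(truth, observed) reflection sets under the two-lattice defect model.

    I_unit is exponential with mean ``wilson_scale`` (acentric Wilson
    statistics); I_total = f(h)·I_unit + Gaussian noise of sd ``noise_sd``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seen: set[tuple[int, int, int]] = set()
    hkl = []
    while len(hkl) < n:
        cand = rng.integers(-hkl_max, hkl_max + 1, size=(n, 3))
        for row in cand:
            key = tuple(int(x) for x in row)
            if key == (0, 0, 0) or key in seen:
                continue
            seen.add(key)
            hkl.append(key)
            if len(hkl) == n:
                break
    hkl = np.array(hkl, dtype=int)
    i_unit = rng.exponential(wilson_scale, size=n)
    truth = ReflectionSet(hkl, i_unit, np.full(n, max(wilson_scale * 0.05, 1e-6)),
                          kind="corrected_unit")
    observed = modulate_intensities(
        ReflectionSet(hkl.copy(), i_unit, truth.sigma.copy(), kind="observed_total"),
        model,
    )
    if noise_sd > 0:
        observed.intensity = observed.intensity + rng.normal(0.0, noise_sd, size=n)
        observed.sigma = np.sqrt(observed.sigma**2 + noise_sd**2)
    observed.kind = "observed_total"
    return truth, observed


@dataclass
class TrajectorySpec:
    n_frames: int = 5000
    dt: float = 0.1  # ns per frame
    seed: int = 0
    p_occupied: float = 0.9
    mean_dwell_frames: float = 15.0
    n_candidates: int = 32  # candidate pool mirroring the many waters near a site
    site_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    site_radius: float = 1.4
    permeation_script: Sequence[Sequence[float]] = ()
    jitter: float = 0.0
    achieved_p: float = field(init=False, default=0.0)
    achieved_dwell: float = field(init=False, default=0.0)

    def __post_init__(self):
        if not 0.0 <= self.p_occupied <= 1.0:
            raise ValueError("p_occupied must be in [0, 1]")
        if self.mean_dwell_frames < 1:
            raise ValueError("mean dwell must be at least one frame")
        # discrete two-state chain: leave probability q = 1/dwell, entry
        # probability r = q p/(1-p) clamped to 1; the clamp makes very high
        # requested occupancies slightly infeasible, so the achievable
        # stationary values are recorded as the generator's ground truth
        q = 1.0 / self.mean_dwell_frames
        if self.p_occupied >= 1.0:
            r, q = 1.0, 0.0  # permanently occupied
            self.achieved_p = 1.0
            self.achieved_dwell = float("inf")
        else:
            r = min(1.0, q * self.p_occupied / (1.0 - self.p_occupied))
            self.achieved_p = r / (r + q)
            self.achieved_dwell = self.mean_dwell_frames
        self.entry_prob = r
        self.leave_prob = q


def make_two_state_trajectory(spec: TrajectorySpec) -> Trajectory:
    """One tracked site alternating occupied/vacant as a two-state Markov chain.

    While occupied, the current occupant atom sits within 0.3 Å of the site
    center; vacant frames park every candidate far away.  The occupant
    identity is resampled uniformly on each re-entry.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.site_center, dtype=float)
    n, k = spec.n_frames, spec.n_candidates
    coords = np.zeros((n, k, 3))
    far = center + np.array([50.0, 50.0, 50.0])
    parked = far + np.arange(k)[:, None] * np.array([3.0, 0.0, 0.0])
    occupied = rng.random() < spec.achieved_p
    occupant = int(rng.integers(k)) if occupied else -1
    for f in range(n):
        coords[f] = parked
        if occupied:
            coords[f, occupant] = center + rng.normal(0.0, 0.1, 3).clip(-0.3, 0.3)
            if rng.random() < spec.leave_prob:
                occupied = False
                occupant = -1
        else:
            if rng.random() < spec.entry_prob:
                occupied = True
                occupant = int(rng.integers(k))
    return Trajectory(coords, spec.dt, names=["O"] * k, resnames=["HOH"] * k)


def make_permeation_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Solute molecules following scripted axial waypoint paths.

    Each script entry is a sequence of z waypoints visited at evenly spaced
    frames (linear interpolation between them); x/y stay near the axis with
    optional Gaussian jitter on all coordinates.
    """
    if not spec.permeation_script:
        raise ValueError("permeation script is empty")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    m = len(spec.permeation_script)
    coords = np.zeros((n, m, 3))
    for j, waypoints in enumerate(spec.permeation_script):
        wp = np.asarray(waypoints, dtype=float)
        t_wp = np.linspace(0, n - 1, len(wp))
        z = np.interp(np.arange(n), t_wp, wp)
        coords[:, j, 2] = z
        if spec.jitter > 0:
            coords[:, j, :] += rng.normal(0.0, spec.jitter, size=(n, 3))
    return Trajectory(coords, spec.dt, names=["Si"] * m, resnames=["SIH"] * m)


def make_count_trajectory(
    n_frames: int,
    lam: float,
    seed: int = 0,
    z_interval: tuple[float, float] = (-15.0, 15.0),
    lateral_max: float = 5.0,
    max_molecules: int | None = None,
    dt: float = 0.1,
) -> tuple[Trajectory, np.ndarray]:
    """Poisson-occupancy channel counts: per frame, N ~ Poisson(lam) waters
    placed uniformly inside the channel cylinder; the rest parked outside.

    Returns the trajectory and the scripted per-frame truth counts.
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=n_frames)
    if max_molecules is None:
        max_molecules = int(counts.max() + 10)
    counts = np.minimum(counts, max_molecules)
    coords = np.zeros((n_frames, max_molecules, 3))
    for f in range(n_frames):
        coords[f, :, :] = np.array([100.0, 100.0, 100.0]) + np.arange(max_molecules)[:, None]
        c = counts[f]
        if c:
            z = rng.uniform(z_interval[0], z_interval[1], c)
            r = lateral_max * np.sqrt(rng.uniform(0, 1, c))
            th = rng.uniform(0, 2 * np.pi, c)
            coords[f, :c, 0] = r * np.cos(th)
            coords[f, :c, 1] = r * np.sin(th)
            coords[f, :c, 2] = z
    traj = Trajectory(coords, dt, names=["O"] * max_molecules,
                      resnames=["HOH"] * max_molecules)
    return traj, counts
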