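"""Small shared geometry helpers (rigid superposition, frames)."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ moving[i] + translation ~= fixed[i]``.  Proper rotation
    (det = +1) is guaranteed.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = moving.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    with warnings.catch_warnings():
        # collinear sets leave one rotational degree of freedom; the residual
        # (hence the rmsd) is still well defined and the solver's choice is
        # deterministic
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(fixed - cf, moving - cm)
    rmsd = float(rssd) / np.sqrt(n)
    rotation = rot.as_matrix()
    translation = cf - rotation @ cm
    return rotation, translation, rmsd


def apply_rigid(rotation: np.ndarray, translation: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane normal to ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    seed = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, seed)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()
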