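"""Rigid-body superposition over per-residue representative points.

Every RMSD in the pipeline is computed on one representative point per
nucleotide (the geometric centre of the six backbone atoms C3', C4', C5',
O3', O5' and P); full-atom RMSD is never used.  Two computation modes
exist and must not be confused:

* :func:`kabsch` fits the optimal proper rotation + translation and
  reports the minimised RMSD (used for k-stack matching and the
  consensus transform);
* :func:`rmsd_under` evaluates the RMSD under a *fixed* transform
  without refitting (used for all loop-region distances, which are
  anchored on the consensus stack superposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "kabsch", "rmsd_under", "as_points", "random_rigid_transform"]

#: tolerance for the orthonormality / unit-determinant invariant
ORTHO_TOL = 1e-9


def as_points(points) -> np.ndarray:
    """Coerce a point list to a float (n, 3) array."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 3)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point list, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("point list contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> rotation @ x + translation (no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        trans = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("reflections are not rigid transforms")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Rotate then translate every point; preserves pairwise distances."""
        return as_points(points) @ self.rotation.T + self.translation

    def apply_point(self, point) -> np.ndarray:
        return self.apply(np.asarray(point, dtype=float).reshape(1, 3))[0]

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def kabsch(P, Q) -> tuple[RigidTransform, float]:
    """Optimal superposition of ``P`` onto ``Q`` (SVD Kabsch, reflection-safe).

    Returns the proper rigid transform minimising the RMSD of
    ``transform(P)`` against ``Q`` (correspondence by list position) and
    the minimised RMSD itself.
    """
    P = as_points(P)
    Q = as_points(Q)
    if P.shape != Q.shape:
        raise ValueError(f"point lists differ in length: {len(P)} vs {len(Q)}")
    if len(P) < 1:
        raise ValueError("superposition needs at least one point")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    rmsd = rmsd_under(transform, P, Q)
    return transform, rmsd


def rmsd_under(transform: RigidTransform, P, Q) -> float:
    """RMSD of ``transform(P)`` against ``Q`` without refitting."""
    P = as_points(P)
    Q = as_points(Q)
    if P.shape != Q.shape:
        raise ValueError(f"point lists differ in length: {len(P)} vs {len(Q)}")
    if len(P) < 1:
        raise ValueError("RMSD of empty point lists is undefined")
    diff = transform.apply(P) - Q
    return float(np.sqrt((diff * diff).sum() / len(P)))


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 50.0) -> RigidTransform:
    """Uniform random rotation (QR of a Gaussian matrix) plus a random shift."""
    A = rng.normal(size=(3, 3))
    Qm, Rm = np.linalg.qr(A)
    Qm = Qm @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(Qm, t)
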