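"""Optimal rigid-body least-squares superposition (Kabsch algorithm).

This is the primitive beneath every deviation metric in the package: a frame
is superposed onto a reference by the proper rotation + translation that
minimises the RMSD over a chosen fit selection, and the transform is then
applied to *all* atoms.  Reflections are explicitly excluded (the sign of the
smallest singular vector is corrected so that det(R) = +1), which matters for
chiral point sets such as protein backbones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ShapeError

__all__ = [
    "RigidTransform",
    "kabsch_superpose",
    "apply_transform",
    "rmsd",
    "superposed_rmsd",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body transform x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ShapeError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) not allowed")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the transform to an (n, 3) array (or a single 3-vector)."""
        coords = np.asarray(coords, dtype=float)
        single = coords.ndim == 1
        pts = np.atleast_2d(coords)
        if pts.shape[-1] != 3:
            raise ShapeError("coords must be (..., 3)")
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def apply_transform(transform: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return transform.apply(coords)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no superposition) root-mean-square deviation between point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def _check_fit_points(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateGeometryError(
            f"need at least 3 fit points, got {points.shape[0]}"
        )
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] <= 1e-10 * scale:
        raise DegenerateGeometryError("fit points are collinear or coincident")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
    strict: bool = True,
) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation and translation are determined over
    ``fit_indices`` (all atoms when None) and applied to every mobile atom.

    With ``strict=True`` (default) fewer than 3 or collinear fit points raise
    :class:`DegenerateGeometryError`.  ``strict=False`` accepts such sets:
    the minimising transform is then not unique, but the minimum RMSD value
    still is, and the SVD picks one optimal proper rotation
    deterministically (useful e.g. for two-atom worked examples).

    Returns
    -------
    (RigidTransform, ndarray)
        The fitted transform and the transformed mobile coordinates.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeError(
            f"mobile {mobile.shape} and reference {reference.shape} must be "
            "equal (n, 3) arrays"
        )
    if fit_indices is None:
        fit_indices = np.arange(mobile.shape[0])
    fit_indices = np.asarray(fit_indices, dtype=int)
    mob_fit = mobile[fit_indices]
    ref_fit = reference[fit_indices]
    if strict:
        _check_fit_points(mob_fit)
        _check_fit_points(ref_fit)
    elif len(mob_fit) == 0:
        raise DegenerateGeometryError("empty fit selection")

    mob_centroid = mob_fit.mean(axis=0)
    ref_centroid = ref_fit.mean(axis=0)
    H = (mob_fit - mob_centroid).T @ (ref_fit - ref_centroid)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = ref_centroid - R @ mob_centroid
    transform = RigidTransform(R, t)
    return transform, transform.apply(mobile)


def superposed_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
    measure_indices: np.ndarray | None = None,
    strict: bool = True,
) -> float:
    """RMSD over ``measure_indices`` after fitting over ``fit_indices``.

    ``measure_indices`` defaults to the fit selection (which itself defaults
    to all atoms).
    """
    if measure_indices is None:
        measure_indices = (np.arange(np.asarray(mobile).shape[0])
                           if fit_indices is None else fit_indices)
    _, moved = kabsch_superpose(mobile, reference, fit_indices, strict=strict)
    measure_indices = np.asarray(measure_indices, dtype=int)
    return rmsd(moved[measure_indices], np.asarray(reference)[measure_indices])
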