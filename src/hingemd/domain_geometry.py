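"""Compactness and domain-motion observables.

Radius of gyration (mass-weighted RMS distance from the centre of mass),
inter-domain centre distances, and the hinge angle at a vertex domain:

    theta = arccos( BA . BC / (|BA| |BC|) )

with A, B, C the per-frame centres of the three domains.  Following common
practice for C-alpha-based domain tracking, distances use mass-weighted
centres of mass while angles use unweighted centres of geometry; both flavors
are computed over C-alpha atoms only.  All three observables are invariant
under global rigid motion, so no superposition is involved.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateGeometryError, EmptySelectionError
from .series import MetricSeries
from .structure_io import DomainSet, Trajectory, select

__all__ = [
    "DomainCenters",
    "radius_of_gyration",
    "domain_centers",
    "interdomain_distance",
    "hinge_angle",
]


@dataclass
class DomainCenters:
    """Per-frame centres for each domain.

    ``centers`` maps domain name to an (n_frames, 3) array; ``flavor`` is
    ``"com"`` (mass-weighted) or ``"cog"`` (unweighted geometric centre).
    """

    centers: dict[str, np.ndarray]
    times: np.ndarray
    flavor: str = "com"

    def __post_init__(self) -> None:
        if self.flavor not in ("com", "cog"):
            raise ConfigError(f"unknown center flavor {self.flavor!r}")
        for name, arr in self.centers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ConfigError(f"centers for {name!r} must be (n_frames, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite centers for domain {name!r}")
            self.centers[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.centers:
            raise ConfigError(
                f"unknown domain {name!r}; known: {sorted(self.centers)}"
            )
        return self.centers[name]


def radius_of_gyration(traj: Trajectory, indices: np.ndarray | None = None) -> MetricSeries:
    """Mass-weighted radius of gyration per frame, angstrom.

    Rg(t) = sqrt( (1/M) sum_i m_i |r_i(t) - R(t)|^2 ) with R(t) the
    mass-weighted centre of the selection.  ``indices`` defaults to all
    atoms.
    """
    if indices is None:
        indices = np.arange(traj.n_atoms)
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        raise EmptySelectionError("radius of gyration of an empty selection")
    masses = traj.topology.masses[indices]
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass in Rg selection")
    coords = traj.frames[:, indices, :]  # (F, n, 3)
    com = np.einsum("fni,n->fi", coords, masses) / total
    sq = np.sum((coords - com[:, None, :]) ** 2, axis=-1)  # (F, n)
    rg = np.sqrt(np.einsum("fn,n->f", sq, masses) / total)
    return MetricSeries("rg", rg, traj.times, units="A",
                        selection=f"{len(indices)} atoms")


def domain_centers(
    traj: Trajectory,
    domains: DomainSet,
    flavor: str = "com",
    atom_name: str = "CA",
) -> DomainCenters:
    """Per-frame, per-domain centres over C-alpha atoms.

    ``flavor="com"`` gives mass-weighted centres of mass (used for
    inter-domain distances); ``flavor="cog"`` gives unweighted centres of
    geometry (used for hinge angles).
    """
    if flavor not in ("com", "cog"):
        raise ConfigError(f"unknown center flavor {flavor!r}")
    centers: dict[str, np.ndarray] = {}
    for name in domains.names():
        idx = select(traj, f"{atom_name} and domain {name}", domains)
        coords = traj.frames[:, idx, :]
        if flavor == "com":
            masses = traj.topology.masses[idx]
            centers[name] = (
                np.einsum("fni,n->fi", coords, masses) / masses.sum()
            )
        else:
            centers[name] = coords.mean(axis=1)
    return DomainCenters(centers, traj.times, flavor=flavor)


def interdomain_distance(centers: DomainCenters, a: str, b: str) -> MetricSeries:
    """Euclidean distance between two domain centres per frame, angstrom."""
    d = np.linalg.norm(centers[a] - centers[b], axis=1)
    return MetricSeries("distance", d, centers.times, units="A",
                        selection=f"{a}-{b} ({centers.flavor})")


def hinge_angle(centers: DomainCenters, a: str, vertex: str, c: str) -> MetricSeries:
    """Angle A–vertex–C between domain centres per frame, degrees in [0, 180].

    Raises :class:`DegenerateGeometryError` if either arm vector has zero
    length in any frame (coincident centres).
    """
    ba = centers[a] - centers[vertex]
    bc = centers[c] - centers[vertex]
    norm_ba = np.linalg.norm(ba, axis=1)
    norm_bc = np.linalg.norm(bc, axis=1)
    if np.any(norm_ba <= 1e-12) or np.any(norm_bc <= 1e-12):
        bad = int(np.argmax((norm_ba <= 1e-12) | (norm_bc <= 1e-12)))
        raise DegenerateGeometryError(
            f"coincident domain centers at frame {bad}: hinge angle undefined"
        )
    cosine = np.einsum("fi,fi->f", ba, bc) / (norm_ba * norm_bc)
    theta = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
    return MetricSeries("angle", theta, centers.times, units="deg",
                        selection=f"{a}-{vertex}-{c} ({centers.flavor})")
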