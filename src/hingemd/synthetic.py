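"""Coarse-grained three-domain hinge-protein trajectory generator.

The model emulates, at desk scale, the dynamics of a three-domain protein
whose terminal domains (I, III) swing about a central domain (II): each
domain is a rigid shell of pseudo-C-alpha beads, the two arms (II->I and
II->III) have fixed length, and the inter-arm hinge angle theta(t) follows a
programmable path — closed until an optional transition frame, then
interpolating over 10% of the run to

    theta_park = theta_closed + park_fraction * (theta_open - theta_closed)

and staying parked (park_fraction 1 = fully open, 0.5 = intermediate).
Linker beads are straight chains re-anchored between domain centres each
frame.  Isotropic i.i.d. Gaussian noise of ``noise_sigma`` per coordinate is
added to every bead of every frame, which gives closed-form expectations
(per-atom RMSF -> sqrt(3) * sigma in a parked phase).  Designed inter-domain
contacts — a bead of domain I and a bead of domain III placed 3.5 A apart
while the hinge is closed — exist only in the closed phase, mimicking
closed-state-specific domain I–III interactions.  Contact placement is
centroid-preserving (the displaced bead's shift is compensated across the
remaining beads of its domain), so programmed hinge angles and centre
distances remain exact ground truth.

All stochasticity flows from the single integer ``seed``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .structure_io import (
    Atom,
    DomainSet,
    Structure,
    Trajectory,
    write_multimodel_pdb,
    write_structure,
)

__all__ = [
    "HingeModelParams",
    "GroundTruth",
    "generate_references",
    "generate_trajectory",
    "write_fixture_set",
]

_CONTACT_DISTANCE = 3.5  # A between designed contact beads when active
_BEAD_MASS = 12.011


@dataclass(frozen=True)
class HingeModelParams:
    """Parameters of the synthetic hinge model (distances in A, angles deg)."""

    atoms_per_domain: int = 30
    domain_radius: float = 7.0
    linker_length: int = 6
    theta_closed: float = 60.0
    theta_open: float = 110.0
    arm_length: float = 22.0
    noise_sigma: float = 0.3
    n_frames: int = 400
    transition_frame: int | None = None
    park_fraction: float = 1.0
    designed_contacts: tuple = ()  # pairs of sequence residues (dom I, dom III)
    theta_contact: float | None = None  # contacts active while theta <= this
    seed: int = 1234
    dt_ns: float = 0.1
    offset: int = 0

    def __post_init__(self) -> None:
        if self.atoms_per_domain < 4:
            raise ConfigError("atoms_per_domain must be >= 4")
        if not (0 < self.theta_closed < self.theta_open <= 180):
            raise ConfigError("require 0 < theta_closed < theta_open <= 180")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.transition_frame is not None and not (
                0 <= self.transition_frame < self.n_frames):
            raise ConfigError("transition_frame must lie within the run")
        if not 0.0 <= self.park_fraction <= 1.0:
            raise ConfigError("park_fraction must be in [0, 1]")
        if self.linker_length < 0:
            raise ConfigError("linker_length must be >= 0")
        n, L = self.atoms_per_domain, self.linker_length
        dom_i = set(range(1, n + 1))
        dom_iii = set(range(2 * n + 2 * L + 1, 3 * n + 2 * L + 1))
        for a, b in self.designed_contacts:
            if a not in dom_i or b not in dom_iii:
                raise ConfigError(
                    f"designed contact ({a}, {b}) must pair a domain I "
                    "residue with a domain III residue"
                )

    # --- residue layout -------------------------------------------------
    @property
    def n_residues(self) -> int:
        return 3 * self.atoms_per_domain + 2 * self.linker_length

    def domain_ranges(self) -> dict:
        n, L = self.atoms_per_domain, self.linker_length
        return {
            "I": [(1, n)],
            "II": [(n + L + 1, 2 * n + L)],
            "III": [(2 * n + 2 * L + 1, 3 * n + 2 * L)],
        }

    def domain_set(self) -> DomainSet:
        return DomainSet(self.domain_ranges(), offset=self.offset)

    def contacts(self) -> tuple:
        """Designed contacts; defaults to one mid-shell domain I–III pair."""
        if self.designed_contacts:
            return tuple(tuple(c) for c in self.designed_contacts)
        n, L = self.atoms_per_domain, self.linker_length
        return ((n // 2, 2 * n + 2 * L + n // 2),)

    @property
    def theta_contact_effective(self) -> float:
        if self.theta_contact is not None:
            return self.theta_contact
        return self.theta_closed + 1.0

    @property
    def theta_park(self) -> float:
        return self.theta_closed + self.park_fraction * (
            self.theta_open - self.theta_closed)


@dataclass
class GroundTruth:
    """Noise-free per-frame observables the generator guarantees."""

    theta_t: np.ndarray
    rg_t: np.ndarray
    com_distance_t: dict  # "I-II" / "I-III" / "II-III" -> (n_frames,) arrays
    contact_active_t: dict  # "resA-resB" -> bool array
    state_label_t: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        data = {
            "theta_t": [float(x) for x in self.theta_t],
            "rg_t": [float(x) for x in self.rg_t],
            "com_distance_t": {k: [float(x) for x in v]
                               for k, v in self.com_distance_t.items()},
            "contact_active_t": {k: [bool(x) for x in v]
                                 for k, v in self.contact_active_t.items()},
            "state_label_t": list(self.state_label_t),
        }
        Path(path).write_text(json.dumps(data, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            theta_t=np.asarray(data["theta_t"], dtype=float),
            rg_t=np.asarray(data["rg_t"], dtype=float),
            com_distance_t={k: np.asarray(v, dtype=float)
                            for k, v in data["com_distance_t"].items()},
            contact_active_t={k: np.asarray(v, dtype=bool)
                              for k, v in data["contact_active_t"].items()},
            state_label_t=list(data["state_label_t"]),
        )


# ---------------------------------------------------------------------------
# Deterministic geometry
# ---------------------------------------------------------------------------

def _shell_points(n: int, radius: float) -> np.ndarray:
    """Antipodally symmetric spherical shell: centroid exactly at origin."""
    m = n // 2
    k = np.arange(m)
    z = (k + 0.5) / m  # upper hemisphere only; antipodes fill the lower one
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    upper = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts = np.concatenate([upper, -upper])
    if n % 2:
        pts = np.concatenate([pts, np.zeros((1, 3))])
    return pts * radius


def _domain_centers(params: HingeModelParams, theta_deg: float):
    half = np.radians(theta_deg) / 2.0
    arm = params.arm_length
    center_b = np.zeros(3)
    center_a = arm * np.array([np.sin(half), np.cos(half), 0.0])
    center_c = arm * np.array([-np.sin(half), np.cos(half), 0.0])
    return center_a, center_b, center_c


def _noise_free_frame(params: HingeModelParams, theta_deg: float,
                      contacts_active: bool) -> np.ndarray:
    """Coordinates of all beads for one frame before noise."""
    n, L = params.atoms_per_domain, params.linker_length
    shell = _shell_points(n, params.domain_radius)
    center_a, center_b, center_c = _domain_centers(params, theta_deg)

    coords = np.empty((params.n_residues, 3))
    pos = 0
    dom_slices = {}
    for name, center, nxt in (("I", center_a, center_b),
                              ("II", center_b, center_c)):
        dom_slices[name] = slice(pos, pos + n)
        coords[pos:pos + n] = center + shell
        pos += n
        for k in range(1, L + 1):  # linker re-anchored between centres
            coords[pos] = center + (nxt - center) * k / (L + 1)
            pos += 1
    dom_slices["III"] = slice(pos, pos + n)
    coords[pos:pos + n] = center_c + shell
    pos += n

    if contacts_active:
        site = 0.5 * (center_a + center_c)
        axis = center_c - center_a
        axis = axis / np.linalg.norm(axis)
        shifts = {"I": np.zeros(3), "III": np.zeros(3)}
        placed = {"I": [], "III": []}
        for res_i, res_j in params.contacts():
            idx_i = res_i - 1
            idx_j = res_j - 1
            target_i = site - 0.5 * _CONTACT_DISTANCE * axis
            target_j = site + 0.5 * _CONTACT_DISTANCE * axis
            shifts["I"] += target_i - coords[idx_i]
            shifts["III"] += target_j - coords[idx_j]
            coords[idx_i] = target_i
            coords[idx_j] = target_j
            placed["I"].append(idx_i)
            placed["III"].append(idx_j)
        for name in ("I", "III"):
            sl = dom_slices[name]
            others = [i for i in range(sl.start, sl.stop)
                      if i not in placed[name]]
            if others:
                coords[others] -= shifts[name] / len(others)
    return coords


def _theta_path(params: HingeModelParams) -> np.ndarray:
    theta = np.full(params.n_frames, params.theta_closed)
    if params.transition_frame is None:
        return theta
    ramp = max(1, int(round(0.1 * params.n_frames)))
    t0 = params.transition_frame
    for f in range(t0, params.n_frames):
        lam = min(1.0, (f - t0) / ramp)
        theta[f] = params.theta_closed + lam * (
            params.theta_park - params.theta_closed)
    return theta


def _topology(params: HingeModelParams, coords: np.ndarray) -> Structure:
    n, L = params.atoms_per_domain, params.linker_length
    names = {}
    contact_negative = {c[0] for c in params.contacts()}
    contact_positive = {c[1] for c in params.contacts()}
    dom = params.domain_set()
    atoms = []
    for seq in range(1, params.n_residues + 1):
        if seq in contact_negative:
            res_name = "ASP"
        elif seq in contact_positive:
            res_name = "LYS"
        elif dom.domain_of(seq) is None:
            res_name = "GLY"
        else:
            res_name = "LEU"
        atoms.append(Atom(
            serial=seq, name="CA", residue_number=seq + params.offset,
            residue_name=res_name, chain="A", coords=coords[seq - 1],
            element="C", mass=_BEAD_MASS,
        ))
    return Structure(atoms)


def _state_labels(params: HingeModelParams, theta: np.ndarray) -> list:
    span = params.theta_open - params.theta_closed
    s = (theta - params.theta_closed) / span
    labels = []
    for x in s:
        if x <= 0.2:
            labels.append("closed")
        elif x >= 0.8:
            labels.append("open")
        else:
            labels.append("intermediate")
    return labels


def _ground_truth(params: HingeModelParams, theta: np.ndarray,
                  frames: np.ndarray) -> GroundTruth:
    dom = params.domain_set()
    centers = {}
    for name in ("I", "II", "III"):
        idx = [r - 1 for r in dom.residues(name)]
        centers[name] = frames[:, idx, :].mean(axis=1)
    com_dist = {
        "I-II": np.linalg.norm(centers["I"] - centers["II"], axis=1),
        "I-III": np.linalg.norm(centers["I"] - centers["III"], axis=1),
        "II-III": np.linalg.norm(centers["II"] - centers["III"], axis=1),
    }
    mean = frames.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=-1), axis=1))
    active = theta <= params.theta_contact_effective
    contact_active = {f"{a}-{b}": active.copy() for a, b in params.contacts()}
    return GroundTruth(theta_t=theta.copy(), rg_t=rg,
                       com_distance_t=com_dist,
                       contact_active_t=contact_active,
                       state_label_t=_state_labels(params, theta))


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def generate_references(params: HingeModelParams) -> tuple[Structure, Structure]:
    """Noise-free closed and open reference structures (identical topology).

    The closed reference is built at theta_closed with designed contacts in
    place; the open reference at theta_open without them (contacts are
    closed-phase only).
    """
    closed_coords = _noise_free_frame(
        params, params.theta_closed,
        params.theta_closed <= params.theta_contact_effective)
    open_coords = _noise_free_frame(
        params, params.theta_open,
        params.theta_open <= params.theta_contact_effective)
    closed = _topology(params, closed_coords)
    open_ = _topology(params, open_coords)
    return closed, open_


def generate_trajectory(params: HingeModelParams) -> tuple[Trajectory, GroundTruth]:
    """A noisy hinge trajectory plus its exact noise-free ground truth."""
    theta = _theta_path(params)
    active = theta <= params.theta_contact_effective
    frames = np.empty((params.n_frames, params.n_residues, 3))
    cache: dict = {}
    for f in range(params.n_frames):
        key = (round(float(theta[f]), 12), bool(active[f]))
        if key not in cache:
            cache[key] = _noise_free_frame(params, theta[f], bool(active[f]))
        frames[f] = cache[key]
    truth = _ground_truth(params, theta, frames)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        frames = frames + rng.normal(0.0, params.noise_sigma, frames.shape)
    topology = _topology(params, frames[0])
    traj = Trajectory(topology, frames, dt_ns=params.dt_ns)
    return traj, truth


def write_fixture_set(out_dir: str | Path,
                      params: HingeModelParams | None = None) -> dict:
    """Emit the canonical fixture files for pipeline-level testing.

    Writes closed.pdb / open.pdb (references), three trajectories
    (traj_closed: no transition; traj_open: parked open; traj_mutantlike:
    mid-run transition parked halfway), domains.yaml and ground_truth.json.
    Returns a mapping of fixture name to path.
    """
    params = params or HingeModelParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    closed, open_ = generate_references(params)
    paths = {"closed": out / "closed.pdb", "open": out / "open.pdb"}
    write_structure(closed, paths["closed"])
    write_structure(open_, paths["open"])

    variants = {
        "traj_closed": replace(params, transition_frame=None),
        "traj_open": replace(params, transition_frame=0, park_fraction=1.0,
                             seed=params.seed + 1),
        "traj_mutantlike": replace(params,
                                   transition_frame=params.n_frames // 2,
                                   park_fraction=0.5, seed=params.seed + 2),
    }
    truths = {}
    for name, p in variants.items():
        traj, truth = generate_trajectory(p)
        paths[name] = out / f"{name}.pdb"
        write_multimodel_pdb(traj, paths[name])
        truths[name] = truth

    paths["domains"] = out / "domains.yaml"
    params.domain_set().to_yaml(paths["domains"])

    paths["ground_truth"] = out / "ground_truth.json"
    merged = {}
    for name, truth in truths.items():
        merged[name] = json.loads(
            json.dumps({
                "theta_t": [float(x) for x in truth.theta_t],
                "rg_t": [float(x) for x in truth.rg_t],
                "com_distance_t": {k: [float(x) for x in v]
                                   for k, v in truth.com_distance_t.items()},
                "contact_active_t": {k: [bool(x) for x in v]
                                     for k, v in truth.contact_active_t.items()},
                "state_label_t": list(truth.state_label_t),
            })
        )
    Path(paths["ground_truth"]).write_text(json.dumps(merged, sort_keys=True))
    return paths
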