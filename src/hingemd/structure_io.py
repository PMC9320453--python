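"""Structure and trajectory I/O, atom selection, and domain definitions.

Trajectories are exchanged as multi-model PDB files (one MODEL per frame),
parsed and written through biotite.  In-memory, a :class:`Trajectory` is a
topology (:class:`Structure`, an ordered list of :class:`Atom`) plus an
``(n_frames, n_atoms, 3)`` coordinate array and per-frame times in ns.

Residue numbering follows the convention that all user-facing numbers are
*sequence* numbers; a per-:class:`DomainSet` integer ``offset`` maps sequence
position to the numbering used inside the coordinate file (for the SBDS NMR
reference structure the offset is +2, so sequence residue 19 is file residue
21).
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    EmptyInputError,
    EmptySelectionError,
    FormatError,
    ShapeError,
)
from .series import MetricSeries, ResidueProfile

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "DomainSet",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_structure",
    "select",
    "write_metric_series",
    "read_metric_series",
    "write_residue_profile",
    "standard_mass",
]

# Standard atomic masses (amu) by element symbol; coarse C-alpha beads use
# plain carbon.  Extend via the `masses` argument of read_multimodel_pdb.
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,  # the element calcium, not the C-alpha atom name
    "K": 39.098,
    "NA": 22.990,
    "CL": 35.45,
}

BACKBONE_NAMES = ("N", "CA", "C", "O")


def standard_mass(element: str) -> float:
    """Standard atomic mass in amu for an element symbol (default carbon)."""
    return _ELEMENT_MASSES.get(element.upper().strip(), 12.011)


@dataclass
class Atom:
    """One named atom of one frame; coordinates in angstrom, mass in amu."""

    serial: int
    name: str
    residue_number: int
    residue_name: str
    chain: str
    coords: np.ndarray
    element: str = "C"
    mass: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ShapeError("atom coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coords must be finite")
        if self.mass is None:
            self.mass = standard_mass(self.element)
        if self.mass <= 0:
            raise ValueError("atom mass must be positive")


class Structure:
    """An ordered set of atoms with coordinates for a single frame/model."""

    def __init__(self, atoms: Sequence[Atom], model_id: int = 1):
        if len(atoms) == 0:
            raise EmptyInputError("a Structure must contain at least one atom")
        self.atoms = list(atoms)
        self.model_id = model_id
        keys = [(a.chain, a.residue_number, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise FormatError("(chain, residue_number, name) not unique within frame")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def atom_names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @property
    def residue_numbers(self) -> np.ndarray:
        """File-numbering residue id per atom."""
        return np.array([a.residue_number for a in self.atoms], dtype=int)

    @property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        """A copy of this structure carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ShapeError(
                f"expected coords of shape {(len(self.atoms), 3)}, got {coords.shape}"
            )
        atoms = [
            Atom(a.serial, a.name, a.residue_number, a.residue_name, a.chain,
                 c, a.element, a.mass)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, model_id=model_id or self.model_id)


class Trajectory:
    """Ordered frames of coordinates sharing one topology.

    Attributes
    ----------
    topology : Structure
        Atom metadata; its coordinates are those of the first frame.
    frames : ndarray, shape (n_frames, n_atoms, 3)
    times : ndarray, shape (n_frames,), ns, strictly increasing.
    """

    def __init__(self, topology: Structure, frames: np.ndarray,
                 times: np.ndarray | None = None, dt_ns: float = 0.1):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ShapeError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[0] == 0:
            raise EmptyInputError("trajectory has zero frames")
        if frames.shape[1] != len(topology):
            raise ShapeError(
                f"frames carry {frames.shape[1]} atoms but topology has "
                f"{len(topology)}"
            )
        if times is None:
            times = np.arange(frames.shape[0]) * dt_ns
        times = np.asarray(times, dtype=float)
        if times.shape != (frames.shape[0],):
            raise ShapeError("one time per frame required")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, i: int) -> Structure:
        """Frame ``i`` as a Structure."""
        return self.topology.with_coords(self.frames[i], model_id=i + 1)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class DomainSet:
    """Named residue ranges in sequence numbering plus a file-numbering offset.

    ``domains`` maps a domain name (e.g. ``"I"``) to a list of inclusive
    ``(start, end)`` ranges in sequence numbering.  ``offset`` is added to a
    sequence position to obtain the residue number used in coordinate files.
    """

    domains: dict[str, list[tuple[int, int]]]
    offset: int = 0

    def __post_init__(self) -> None:
        norm: dict[str, list[tuple[int, int]]] = {}
        for name, ranges in self.domains.items():
            out = []
            for r in ranges:
                start, end = int(r[0]), int(r[1])
                if end < start:
                    raise ConfigError(f"domain {name!r}: range {r} has end < start")
                out.append((start, end))
            norm[str(name)] = out
        self.domains = norm
        seen: dict[int, str] = {}
        for name, ranges in self.domains.items():
            for start, end in ranges:
                for res in range(start, end + 1):
                    if res in seen:
                        raise ConfigError(
                            f"residue {res} in both domain {seen[res]!r} and {name!r}"
                        )
                    seen[res] = name

    def names(self) -> list[str]:
        return list(self.domains)

    def residues(self, name: str) -> list[int]:
        """All sequence residue numbers of a domain."""
        if name not in self.domains:
            raise ConfigError(
                f"unknown domain {name!r}; known: {sorted(self.domains)}"
            )
        out: list[int] = []
        for start, end in self.domains[name]:
            out.extend(range(start, end + 1))
        return out

    def file_residues(self, name: str) -> list[int]:
        """File-numbering residue numbers of a domain (offset applied)."""
        return [r + self.offset for r in self.residues(name)]

    def domain_of(self, sequence_residue: int) -> str | None:
        """Domain name containing a sequence residue, or None for linkers."""
        for name, ranges in self.domains.items():
            for start, end in ranges:
                if start <= sequence_residue <= end:
                    return name
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "domains" not in raw:
            raise ConfigError(f"{path}: expected mapping with a 'domains' key")
        return cls(domains={k: [tuple(r) for r in v]
                            for k, v in raw["domains"].items()},
                   offset=int(raw.get("offset", 0)))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "offset": self.offset,
            "domains": {k: [list(r) for r in v] for k, v in self.domains.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _model_atom_counts(text: str) -> list[int]:
    """ATOM/HETATM record count per MODEL block (for error reporting)."""
    counts: list[int] = []
    current: int | None = None
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = 0
        elif rec == "ENDMDL":
            counts.append(current or 0)
            current = None
        elif rec in ("ATOM", "HETATM"):
            # atoms before any MODEL record form a single implicit model
            current = (0 if current is None else current) + 1
    if current is not None:
        counts.append(current)
    return counts


def read_multimodel_pdb(path: str | Path, dt_ns: float = 0.1,
                        times: np.ndarray | None = None) -> Trajectory:
    """Read a multi-model PDB file as a Trajectory (one frame per MODEL).

    The topology (atom names, residues, elements, masses) is taken from the
    first model; every model must list the same atoms in the same order.
    Frame times default to ``dt_ns`` spacing starting at 0.

    Raises
    ------
    EmptyInputError
        If the file contains no atoms.
    FormatError
        If models disagree in atom count; the message names the first
        offending model.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    text = path.read_text()
    counts = _model_atom_counts(text)
    if not counts or all(c == 0 for c in counts):
        raise EmptyInputError(f"{path}: no models / no atoms found")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise FormatError(
            f"{path}: MODEL {bad} has {counts[bad - 1]} atoms, "
            f"expected {counts[0]} (from MODEL 1)"
        )

    pdb = PDBFile.read(io.StringIO(text))
    stack = pdb.get_structure(model=None)  # AtomArrayStack
    n_frames = stack.stack_depth()
    atoms = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]) if stack.element[i] else "C"
        atoms.append(Atom(
            serial=i + 1,
            name=str(stack.atom_name[i]),
            residue_number=int(stack.res_id[i]),
            residue_name=str(stack.res_name[i]),
            chain=str(stack.chain_id[i]) or "A",
            coords=stack.coord[0, i],
            element=element,
        ))
    topology = Structure(atoms, model_id=1)
    return Trajectory(topology, stack.coord.copy(), times=times, dt_ns=dt_ns)


def read_structure(path: str | Path) -> Structure:
    """Read the first model of a PDB file as a Structure."""
    return read_multimodel_pdb(path).frame(0)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB file (one MODEL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = traj.topology
    n_atoms = len(top)
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.coord[:] = traj.frames
    stack.chain_id = np.array([a.chain for a in top.atoms], dtype="U4")
    stack.res_id = np.array([a.residue_number for a in top.atoms], dtype=int)
    stack.res_name = np.array([a.residue_name for a in top.atoms], dtype="U5")
    stack.atom_name = np.array([a.name for a in top.atoms], dtype="U6")
    stack.element = np.array([a.element for a in top.atoms], dtype="U2")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single Structure as a one-model PDB file."""
    traj = Trajectory(structure, structure.coords[None, :, :])
    write_multimodel_pdb(traj, path)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_RESIDUE_CLAUSE = re.compile(r"^residues?\s+(.+)$")
_DOMAIN_CLAUSE = re.compile(r"^domain\s+(.+)$")
_NAME_CLAUSE = re.compile(r"^name\s+(\S+)$")


def _parse_residue_list(text: str) -> list[int]:
    out: list[int] = []
    for token in text.replace(" ", "").split(","):
        if not token:
            continue
        if "-" in token[1:]:  # allow leading minus, though residues are positive
            lo, hi = token.split("-", 1)
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(token))
    return out


def select(traj: Trajectory | Structure, spec: str,
           domains: DomainSet | None = None) -> np.ndarray:
    """Resolve a selection expression to atom indices in topology order.

    The grammar is a conjunction of clauses joined by ``and``:

    - ``all`` — every atom
    - ``backbone`` — atoms named N, CA, C, O
    - ``CA`` or ``name CA`` — atoms with that name
    - ``domain I`` — atoms of the named domain (requires ``domains``)
    - ``residues 3-10,15`` — sequence residue numbers; the DomainSet offset
      (0 when no DomainSet is given) is applied to obtain file numbering

    Raises
    ------
    ConfigError
        For an unknown domain name or a domain clause without a DomainSet.
    EmptySelectionError
        If no atom matches.
    """
    top = traj.topology if isinstance(traj, Trajectory) else traj
    names = top.atom_names
    resnums = top.residue_numbers
    offset = domains.offset if domains is not None else 0

    mask = np.ones(len(top), dtype=bool)
    spec = spec.strip()
    if not spec:
        raise EmptySelectionError("empty selection expression")
    for clause in re.split(r"\s+and\s+", spec):
        clause = clause.strip()
        low = clause.lower()
        if low == "all":
            continue
        if low == "backbone":
            mask &= np.isin(names, BACKBONE_NAMES)
            continue
        m = _DOMAIN_CLAUSE.match(low)
        if m:
            if domains is None:
                raise ConfigError(
                    f"selection {clause!r} requires a DomainSet"
                )
            # recover the original-case domain name from the clause
            dom_name = clause.split(None, 1)[1].strip()
            file_res = domains.file_residues(dom_name)
            mask &= np.isin(resnums, file_res)
            continue
        m = _RESIDUE_CLAUSE.match(low)
        if m:
            seq_res = _parse_residue_list(m.group(1))
            mask &= np.isin(resnums, [r + offset for r in seq_res])
            continue
        m = _NAME_CLAUSE.match(clause)
        if m:
            mask &= names == m.group(1)
            continue
        # bare token: an atom name
        if re.fullmatch(r"[A-Za-z0-9']+", clause):
            mask &= names == clause.upper()
        else:
            raise ConfigError(f"cannot parse selection clause {clause!r}")
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        raise EmptySelectionError(f"selection {spec!r} matched no atoms")
    return indices


# ---------------------------------------------------------------------------
# Metric series CSV I/O
# ---------------------------------------------------------------------------

def _series_column(series: MetricSeries) -> str:
    unit = series.units.strip()
    return f"{series.metric}_{unit}" if unit else series.metric


def write_metric_series(series: MetricSeries, path: str | Path) -> None:
    """Write a metric series as a two-column CSV (time_ns, value).

    Values are written with 10 significant digits, so a read-back reproduces
    them well beyond 1e-6 relative accuracy.
    """
    if len(series) == 0:
        raise EmptyInputError("refusing to write an empty metric series")
    df = pd.DataFrame({
        "time_ns": series.times,
        _series_column(series): series.values,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_metric_series(path: str | Path) -> MetricSeries:
    """Read back a CSV written by :func:`write_metric_series`."""
    df = pd.read_csv(path)
    if df.shape[1] != 2 or df.columns[0] != "time_ns":
        raise FormatError(f"{path}: expected columns (time_ns, <metric>_<units>)")
    label = df.columns[1]
    metric, _, units = label.rpartition("_")
    if not metric:
        metric, units = label, ""
    return MetricSeries(metric=metric, values=df[label].to_numpy(),
                        times=df["time_ns"].to_numpy(), units=units)


def write_residue_profile(profile: ResidueProfile, path: str | Path) -> None:
    """Write a per-residue profile as CSV (residue, value)."""
    if len(profile) == 0:
        raise EmptyInputError("refusing to write an empty residue profile")
    unit = profile.units.strip()
    col = f"{profile.metric}_{unit}" if unit else profile.metric
    df = pd.DataFrame({
        "residue": profile.residue_numbers,
        col: profile.values,
    })
    df.to_csv(path, index=False, float_format="%.10g")
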