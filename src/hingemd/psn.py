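"""Persistence-filtered protein structure networks (PSN).

Residues are nodes; edges are non-covalent interactions of three classes —
salt bridges (SB), hydrogen bonds (HB) and hydrophobic contacts (HC) — that
satisfy class-specific geometric criteria in a sufficient fraction of
production-run frames (their *persistence*).  The persistence threshold
p_crit is chosen by the largest-hydrophobic-cluster criterion: scanning the
threshold upward, p_crit sits at the largest single-step drop in the size of
the biggest connected component of the HC-only graph.

Two detection modes are supported:

- ``all_atom``: geometric criteria on side-chain atom groups (charged-group
  minimum distance for SB, donor/acceptor heavy-atom distance plus an
  optional D-H...A angle for HB, side-chain-centre distance for HC);
- ``residue_center``: per-class cutoffs on a single representative point per
  residue (the C-alpha / bead position), for coarse-grained models.

Default cutoffs (SB 4.5 A, HB 3.5 A / 120 deg, HC 5.0 A) follow the
conventional values of published interaction-network tools and are
configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, EmptyInputError
from .structure_io import BACKBONE_NAMES, DomainSet, Structure, Trajectory

__all__ = [
    "InteractionParams",
    "InteractionRecord",
    "PSNGraph",
    "HubReport",
    "detect_interactions",
    "interaction_persistence",
    "persistence_threshold",
    "build_psn",
    "find_hubs",
    "delta_degree",
    "interdomain_table",
]

CLASSES = ("SB", "HB", "HC")

NEGATIVE_RESIDUES = {"ASP", "GLU"}
POSITIVE_RESIDUES = {"LYS", "ARG"}  # HIS added when his_charged
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
# residues capable of side-chain hydrogen bonding (residue_center mode)
POLAR_RESIDUES = {"SER", "THR", "ASN", "GLN", "TYR", "HIS", "LYS", "ARG",
                  "ASP", "GLU", "TRP", "CYS"}

# charged-group atoms for salt bridges (all_atom mode)
CHARGED_GROUP_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}

# heavy-atom hydrogen-bond donors/acceptors (all_atom mode); backbone N is a
# donor (except proline) and backbone O an acceptor for every residue
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "TRP": {"NE1"}, "CYS": {"SG"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "MET": {"SD"}, "CYS": {"SG"},
}


@dataclass(frozen=True)
class InteractionParams:
    """Geometric criteria and mode for interaction detection."""

    mode: str = "all_atom"  # or "residue_center"
    cutoffs: dict = field(default_factory=lambda: {
        "SB": 4.5, "HB": 3.5, "HC": 5.0,
    })
    hb_angle_deg: float = 120.0
    his_charged: bool = True
    min_seq_sep: int = 2  # exclude pairs with |i - j| < min_seq_sep
    representative_atom: str = "CA"

    def __post_init__(self) -> None:
        if self.mode not in ("all_atom", "residue_center"):
            raise ConfigError(f"unknown detection mode {self.mode!r}")
        for cls in CLASSES:
            if cls not in self.cutoffs:
                raise ConfigError(f"missing cutoff for class {cls}")

    def with_mode(self, mode: str) -> "InteractionParams":
        return replace(self, mode=mode)


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """A residue pair, its interaction class, and its persistence."""

    residue_a: int
    residue_b: int
    iclass: str
    persistence: float

    def __post_init__(self) -> None:
        if self.residue_a >= self.residue_b:
            raise ValueError("records must have residue_a < residue_b")
        if self.iclass not in CLASSES:
            raise ConfigError(f"unknown interaction class {self.iclass!r}")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.residue_a, self.residue_b)


# ---------------------------------------------------------------------------
# Residue bookkeeping
# ---------------------------------------------------------------------------

class _ResidueView:
    """Atom indices, names and representative points grouped by residue."""

    def __init__(self, structure: Structure, params: InteractionParams):
        res_numbers = structure.residue_numbers
        res_names = structure.residue_names
        atom_names = structure.atom_names
        elements = structure.elements
        order: list[int] = []
        seen = set()
        for r in res_numbers:
            if r not in seen:
                seen.add(r)
                order.append(int(r))
        self.residues = order
        self.res_name = {}
        self.atom_idx = {r: [] for r in order}
        for i, r in enumerate(res_numbers):
            self.atom_idx[int(r)].append(i)
            self.res_name[int(r)] = str(res_names[i])
        self.atom_names = atom_names
        self.elements = elements
        self.params = params
        if params.mode == "residue_center":
            rep = params.representative_atom
            self.rep_idx = {}
            for r in order:
                cand = [i for i in self.atom_idx[r] if atom_names[i] == rep]
                if not cand:
                    raise ConfigError(
                        f"residue {r} has no {rep!r} atom for residue_center "
                        "mode"
                    )
                self.rep_idx[r] = cand[0]

    def positive(self, r: int) -> bool:
        name = self.res_name[r]
        return name in POSITIVE_RESIDUES or (
            self.params.his_charged and name == "HIS")

    def negative(self, r: int) -> bool:
        return self.res_name[r] in NEGATIVE_RESIDUES

    def hydrophobic(self, r: int) -> bool:
        return self.res_name[r] in HYDROPHOBIC_RESIDUES

    def polar(self, r: int) -> bool:
        return self.res_name[r] in POLAR_RESIDUES

    def sidechain_heavy(self, r: int) -> list[int]:
        out = []
        for i in self.atom_idx[r]:
            if (self.atom_names[i] not in BACKBONE_NAMES
                    and self.atom_names[i] != "OXT"
                    and self.elements[i].upper() != "H"):
                out.append(i)
        return out

    def group_atoms(self, r: int, table: dict) -> list[int]:
        wanted = table.get(self.res_name[r], set())
        return [i for i in self.atom_idx[r] if self.atom_names[i] in wanted]

    def donors(self, r: int) -> list[int]:
        out = self.group_atoms(r, SIDECHAIN_DONORS)
        if self.res_name[r] != "PRO":
            out += [i for i in self.atom_idx[r] if self.atom_names[i] == "N"]
        return out

    def acceptors(self, r: int) -> list[int]:
        out = self.group_atoms(r, SIDECHAIN_ACCEPTORS)
        out += [i for i in self.atom_idx[r] if self.atom_names[i] == "O"]
        return out

    def hydrogens_of(self, coords: np.ndarray, donor: int) -> list[int]:
        """Hydrogens covalently bound to a donor heavy atom (<= 1.3 A)."""
        r = None
        for res, idxs in self.atom_idx.items():
            if donor in idxs:
                r = res
                break
        out = []
        for i in self.atom_idx[r]:
            if self.elements[i].upper() == "H":
                if np.linalg.norm(coords[i] - coords[donor]) <= 1.3:
                    out.append(i)
        return out


def _eligible(view: _ResidueView, iclass: str, r: int) -> bool:
    if iclass == "SB":
        return view.positive(r) or view.negative(r)
    if iclass == "HB":
        return True if view.params.mode == "all_atom" else view.polar(r)
    if iclass == "HC":
        return view.hydrophobic(r)
    raise ConfigError(f"unknown interaction class {iclass!r}")


def _pair_allowed(view: _ResidueView, iclass: str, ra: int, rb: int) -> bool:
    if abs(ra - rb) < view.params.min_seq_sep:
        return False
    if iclass == "SB":
        return ((view.positive(ra) and view.negative(rb))
                or (view.negative(ra) and view.positive(rb)))
    if iclass == "HB":
        if view.params.mode == "residue_center":
            return view.polar(ra) and view.polar(rb)
        return True
    if iclass == "HC":
        return view.hydrophobic(ra) and view.hydrophobic(rb)
    return False


def _detect_frame(view: _ResidueView, coords: np.ndarray, iclass: str) -> set:
    """Residue pairs of one class satisfied in one frame (file numbering)."""
    params = view.params
    cutoff = params.cutoffs[iclass]
    pairs: set[tuple[int, int]] = set()
    residues = [r for r in view.residues if _eligible(view, iclass, r)]

    if params.mode == "residue_center":
        pts = np.array([coords[view.rep_idx[r]] for r in residues])
        if len(residues) >= 2:
            dmat = cdist(pts, pts)
            for i in range(len(residues)):
                for j in range(i + 1, len(residues)):
                    ra, rb = residues[i], residues[j]
                    if dmat[i, j] <= cutoff and _pair_allowed(view, iclass, ra, rb):
                        pairs.add((min(ra, rb), max(ra, rb)))
        return pairs

    # all-atom mode
    if iclass == "SB":
        groups = {r: view.group_atoms(r, CHARGED_GROUP_ATOMS) for r in residues}
        residues = [r for r in residues if groups[r]]
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                ra, rb = residues[i], residues[j]
                if not _pair_allowed(view, iclass, ra, rb):
                    continue
                d = cdist(coords[groups[ra]], coords[groups[rb]]).min()
                if d <= cutoff:
                    pairs.add((min(ra, rb), max(ra, rb)))
    elif iclass == "HC":
        centers = {}
        for r in residues:
            sc = view.sidechain_heavy(r)
            if sc:
                centers[r] = coords[sc].mean(axis=0)
        residues = [r for r in residues if r in centers]
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                ra, rb = residues[i], residues[j]
                if not _pair_allowed(view, iclass, ra, rb):
                    continue
                if np.linalg.norm(centers[ra] - centers[rb]) <= cutoff:
                    pairs.add((min(ra, rb), max(ra, rb)))
    elif iclass == "HB":
        all_res = view.residues
        donors = {r: view.donors(r) for r in all_res}
        acceptors = {r: view.acceptors(r) for r in all_res}
        for i in range(len(all_res)):
            for j in range(i + 1, len(all_res)):
                ra, rb = all_res[i], all_res[j]
                if not _pair_allowed(view, iclass, ra, rb):
                    continue
                if _hbond(view, coords, donors[ra], acceptors[rb], cutoff) or \
                   _hbond(view, coords, donors[rb], acceptors[ra], cutoff):
                    pairs.add((min(ra, rb), max(ra, rb)))
    return pairs


def _hbond(view: _ResidueView, coords: np.ndarray, donors: list[int],
           acceptors: list[int], cutoff: float) -> bool:
    for d in donors:
        for a in acceptors:
            if np.linalg.norm(coords[d] - coords[a]) > cutoff:
                continue
            hydrogens = view.hydrogens_of(coords, d)
            if not hydrogens:
                return True  # no explicit hydrogens: distance criterion only
            for h in hydrogens:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
                angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if angle >= view.params.hb_angle_deg:
                    return True
    return False


def detect_interactions(
    frame: Structure,
    iclass: str,
    params: InteractionParams | None = None,
) -> set:
    """Residue pairs (file numbering, a < b) of one class present in a frame."""
    if iclass not in CLASSES:
        raise ConfigError(f"unknown interaction class {iclass!r}; "
                          f"choose from {CLASSES}")
    params = params or InteractionParams()
    if params.mode == "all_atom":
        names = set(frame.atom_names)
        if names <= {"CA"}:
            raise ConfigError(
                "all_atom mode requires side-chain atoms; this structure has "
                "only CA atoms — use mode='residue_center'"
            )
    view = _ResidueView(frame, params)
    return _detect_frame(view, frame.coords, iclass)


def interaction_persistence(
    traj: Trajectory,
    iclass: str,
    params: InteractionParams | None = None,
    production_start: int = 0,
    offset: int = 0,
) -> list:
    """Persistence of every observed pair of one class over the production run.

    Persistence = (frames in which the pair satisfies its criteria) /
    (production-run frames), computed in exact integer arithmetic before the
    final division.  Residue numbers in the returned records are *sequence*
    numbers (``offset`` subtracted from file numbering).  Pairs never
    detected are absent from the output.
    """
    if iclass not in CLASSES:
        raise ConfigError(f"unknown interaction class {iclass!r}")
    params = params or InteractionParams()
    n_prod = traj.n_frames - production_start
    if n_prod <= 0:
        raise EmptyInputError("empty production run")
    view = _ResidueView(traj.topology, params)

    counts: dict[tuple[int, int], int] = {}
    if params.mode == "residue_center":
        # vectorised over frames: distances only for sequence-eligible pairs
        residues = [r for r in view.residues if _eligible(view, iclass, r)]
        rep = np.array([view.rep_idx[r] for r in residues], dtype=int)
        pair_idx = []
        pair_res = []
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                if _pair_allowed(view, iclass, residues[i], residues[j]):
                    pair_idx.append((i, j))
                    pair_res.append((residues[i], residues[j]))
        if pair_idx:
            pi = np.array(pair_idx, dtype=int)
            coords = traj.frames[production_start:, rep, :]
            diff = coords[:, pi[:, 0], :] - coords[:, pi[:, 1], :]
            within = np.linalg.norm(diff, axis=-1) <= params.cutoffs[iclass]
            hits = within.sum(axis=0)
            for (ra, rb), h in zip(pair_res, hits):
                if h:
                    counts[(min(ra, rb), max(ra, rb))] = int(h)
    else:
        for f in range(production_start, traj.n_frames):
            for pair in _detect_frame(view, traj.frames[f], iclass):
                counts[pair] = counts.get(pair, 0) + 1

    records = [
        InteractionRecord(a - offset, b - offset, iclass, c / n_prod)
        for (a, b), c in counts.items()
    ]
    return sorted(records)


# ---------------------------------------------------------------------------
# Threshold selection, graph assembly, hubs
# ---------------------------------------------------------------------------

def largest_cluster_sizes(
    hc_records: list,
    step: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Largest connected-component size of the HC graph along a threshold scan.

    Returns (thresholds, sizes).  The scan covers [0, 1] in ``step``
    increments plus one virtual step above 1.0 at which every edge has
    vanished, so a final collapse is always observable.  Isolated residues
    count as clusters of size 1.
    """
    if not hc_records:
        raise EmptyInputError(
            "no hydrophobic-contact records: supply an explicit p_crit"
        )
    nodes = sorted({r for rec in hc_records for r in rec.pair})
    thresholds = np.append(np.arange(0.0, 1.0 + step / 2, step), 1.0 + step)
    sizes = np.empty(len(thresholds), dtype=int)
    for k, p in enumerate(thresholds):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(rec.pair for rec in hc_records
                         if rec.persistence >= p - 1e-12)
        sizes[k] = max(len(c) for c in nx.connected_components(g))
    return thresholds, sizes


def persistence_threshold(hc_records: list, step: float = 0.02) -> float:
    """p_crit by the largest-hydrophobic-cluster-size criterion.

    Scanning the persistence threshold upward, p_crit is the grid value just
    above the largest single-step drop in the largest HC cluster size; ties
    resolve to the smallest such threshold.
    """
    thresholds, sizes = largest_cluster_sizes(hc_records, step)
    drops = sizes[:-1] - sizes[1:]
    best = int(np.argmax(drops))  # argmax takes the first (smallest p) on ties
    if drops[best] <= 0:
        # degenerate: no drop anywhere (single-node graph); use final boundary
        return float(thresholds[-1])
    return float(round(thresholds[best + 1], 10))


class PSNGraph:
    """A merged, persistence-filtered interaction graph.

    Thin wrapper around a :class:`networkx.Graph`; each edge carries an
    ``interactions`` dict mapping class -> persistence.  Node degree counts
    distinct residue pairs by default (a pair linked by both SB and HB
    contributes 1); ``per_class=True`` counts each class separately.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = (a, b) if a < b else (b, a)
            for cls, p in sorted(data["interactions"].items()):
                out.append(InteractionRecord(a, b, cls, p))
        return sorted(out)

    def degree(self, residue: int, per_class: bool = False) -> int:
        if residue not in self.graph:
            return 0
        if not per_class:
            return int(self.graph.degree(residue))
        return sum(len(d["interactions"])
                   for _, _, d in self.graph.edges(residue, data=True))

    def degrees(self, per_class: bool = False) -> dict:
        return {n: self.degree(n, per_class) for n in self.nodes}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_edge_dataframe(self) -> pd.DataFrame:
        rows = [
            {"residue_a": r.residue_a, "residue_b": r.residue_b,
             "class": r.iclass, "persistence": r.persistence}
            for r in self.edges
        ]
        return pd.DataFrame(rows, columns=["residue_a", "residue_b",
                                           "class", "persistence"])

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for a, b, data in self.graph.edges(data=True):
            attrs = {cls: float(p) for cls, p in data["interactions"].items()}
            attrs["classes"] = ",".join(sorted(data["interactions"]))
            g.add_edge(a, b, **attrs)
        nx.write_graphml(g, path)


def build_psn(
    records_by_class: dict,
    p_crit: dict | float,
    nodes: list | None = None,
) -> PSNGraph:
    """Merge per-class interaction records into one persistence-filtered PSN.

    ``p_crit`` is either one threshold applied to every class or a mapping
    class -> threshold; edges with ``persistence >= p_crit`` of their class
    are kept.  ``nodes`` optionally pre-populates the node set (e.g. every
    residue of the protein) so degree-0 residues are represented.
    """
    if not isinstance(p_crit, dict):
        p_crit = {cls: float(p_crit) for cls in CLASSES}
    for cls, p in p_crit.items():
        if not 0.0 <= p <= 1.0 + 0.05:
            raise ConfigError(f"p_crit for {cls} out of range: {p}")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(int(n) for n in nodes)
    for cls, records in records_by_class.items():
        if cls not in CLASSES:
            raise ConfigError(f"unknown interaction class {cls!r}")
        threshold = p_crit.get(cls, 0.0)
        for rec in records:
            if rec.iclass != cls:
                raise ConfigError(
                    f"record {rec} filed under class {cls!r}"
                )
            if rec.persistence >= threshold - 1e-12:
                a, b = rec.pair
                if g.has_edge(a, b):
                    g[a][b]["interactions"][cls] = rec.persistence
                else:
                    g.add_edge(a, b, interactions={cls: rec.persistence})
    return PSNGraph(g)


@dataclass
class HubReport:
    """Hub residues and their degrees across systems.

    ``table`` has one row per residue that is a hub (degree strictly greater
    than ``k_min`` in at least one system), with a degree column per system.
    """

    table: pd.DataFrame
    k_min: int
    systems: list

    @property
    def hubs(self) -> list[int]:
        return list(self.table.index)


def find_hubs(graphs: dict, k_min: int = 6) -> HubReport:
    """Residues with degree strictly above k_min in at least one system."""
    if not graphs:
        raise EmptyInputError("no graphs supplied for hub analysis")
    if k_min < 1:
        raise ConfigError("k_min must be >= 1")
    systems = list(graphs)
    residues = sorted({n for g in graphs.values() for n in g.nodes})
    rows = {}
    for res in residues:
        degs = {sys: graphs[sys].degree(res) for sys in systems}
        if any(d > k_min for d in degs.values()):
            rows[res] = degs
    table = pd.DataFrame.from_dict(rows, orient="index", columns=systems,
                                   dtype=int)
    table.index.name = "residue"
    return HubReport(table, k_min, systems)


def delta_degree(
    open_graph: PSNGraph,
    closed_graph: PSNGraph,
    residues: list | None = None,
) -> dict:
    """Per-residue degree change k_open - k_closed (exact integers).

    ``residues`` defaults to the union of both node sets; a residue absent
    from one graph has degree 0 there.
    """
    if residues is None:
        residues = sorted(set(open_graph.nodes) | set(closed_graph.nodes))
    return {int(r): open_graph.degree(int(r)) - closed_graph.degree(int(r))
            for r in residues}


def interdomain_table(
    records: list,
    p_crit: dict | float,
    domains: DomainSet,
    a: str,
    b: str,
) -> pd.DataFrame:
    """Cross-domain interactions with persistence strictly above threshold.

    Rows pair one residue of domain ``a`` with one of domain ``b`` (sequence
    numbering), keeping only records whose persistence exceeds their class
    p_crit, sorted by descending persistence.
    """
    res_a = set(domains.residues(a))
    res_b = set(domains.residues(b))
    if res_a & res_b:
        raise ConfigError(f"domains {a!r} and {b!r} overlap")
    if not isinstance(p_crit, dict):
        p_crit = {cls: float(p_crit) for cls in CLASSES}
    rows = []
    for rec in records:
        pa, pb = rec.pair
        in_ab = pa in res_a and pb in res_b
        in_ba = pa in res_b and pb in res_a
        if not (in_ab or in_ba):
            continue
        if rec.persistence > p_crit.get(rec.iclass, 0.0):
            ra, rb = (pa, pb) if in_ab else (pb, pa)
            rows.append({"residue_a": ra, "residue_b": rb,
                         "class": rec.iclass, "persistence": rec.persistence})
    df = pd.DataFrame(rows, columns=["residue_a", "residue_b", "class",
                                     "persistence"])
    return df.sort_values(["persistence", "residue_a", "residue_b", "class"],
                          ascending=[False, True, True, True],
                          ignore_index=True)
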