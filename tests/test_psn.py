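"""Protein structure network: detection, persistence, p_crit, hubs, tables."""
import numpy as np
import pytest

from conftest import make_ca_structure, make_trajectory
from hingemd.errors import ConfigError, EmptyInputError
from hingemd.psn import (
    InteractionParams,
    InteractionRecord,
    build_psn,
    delta_degree,
    detect_interactions,
    find_hubs,
    interaction_persistence,
    interdomain_table,
    largest_cluster_sizes,
    persistence_threshold,
)
from hingemd.structure_io import Atom, DomainSet, Structure

CENTER_MODE = InteractionParams(mode="residue_center")


def build_residues(residues):
    """Structure from [(resnum, resname, {atom_name: xyz}), ...]."""
    atoms = []
    serial = 1
    for resnum, resname, atom_map in residues:
        for name, xyz in atom_map.items():
            element = "H" if name.startswith("H") else name[0]
            atoms.append(Atom(serial, name, resnum, resname, "A",
                              np.asarray(xyz, dtype=float), element=element))
            serial += 1
    return Structure(atoms)


class TestDetectInteractionsAllAtom:
    @pytest.mark.parametrize("gap,expected", [(4.0, True), (5.0, False)])
    def test_salt_bridge_cutoff_on_charged_groups(self, gap, expected):
        frame = build_residues([
            (2, "ASP", {"CA": (0, 0, 0), "CB": (1, 0, 0),
                        "OD1": (2, 0, 0), "OD2": (2, 1, 0)}),
            (10, "LYS", {"CA": (10, 0, 0), "NZ": (2 + gap, 0, 0)}),
        ])
        pairs = detect_interactions(frame, "SB")
        assert ((2, 10) in pairs) is expected

    def test_hydrophobic_contact_needs_both_residues_hydrophobic(self):
        leu_leu = build_residues([
            (1, "LEU", {"CA": (0, 0, 0), "CB": (1, 0, 0)}),
            (4, "LEU", {"CA": (7, 0, 0), "CB": (5.9, 0, 0)}),
        ])
        assert (1, 4) in detect_interactions(leu_leu, "HC")
        ser_leu = build_residues([
            (1, "SER", {"CA": (0, 0, 0), "OG": (1, 0, 0)}),
            (4, "LEU", {"CA": (7, 0, 0), "CB": (5.9, 0, 0)}),
        ])
        assert detect_interactions(ser_leu, "HC") == set()

    def test_hydrogen_bond_distance_and_angle(self):
        # donor N (res 1) to acceptor O (res 3) at 3.0 A with a straight H
        good = build_residues([
            (1, "GLY", {"N": (0, 0, 0), "CA": (1.5, 0, 0), "C": (2.5, 1, 0),
                        "O": (9, 9, 9), "H": (1.0, 0, 0)}),
            (3, "GLY", {"N": (8, 0, 0), "CA": (5, 0, 0), "C": (4, 0, 0),
                        "O": (3.0, 0, 0)}),
        ])
        assert (1, 3) in detect_interactions(good, "HB")
        # same geometry but the H points away: D-H...A angle ~ 0 deg
        bad = build_residues([
            (1, "GLY", {"N": (0, 0, 0), "CA": (1.5, 1, 0), "C": (2.5, 1, 0),
                        "O": (9, 9, 9), "H": (-1.0, 0, 0)}),
            (3, "GLY", {"N": (8, 0, 0), "CA": (5, 0, 0), "C": (4, 0, 0),
                        "O": (3.0, 0, 0)}),
        ])
        assert (1, 3) not in detect_interactions(bad, "HB")

    def test_sequence_neighbors_excluded(self):
        frame = build_residues([
            (1, "LEU", {"CA": (0, 0, 0), "CB": (1, 0, 0)}),
            (2, "LEU", {"CA": (3, 0, 0), "CB": (2, 0, 0)}),
        ])
        assert detect_interactions(frame, "HC") == set()

    def test_no_self_pairs_and_symmetric_determinism(self):
        frame = build_residues([
            (1, "LEU", {"CA": (0, 0, 0), "CB": (1, 0, 0)}),
            (4, "LEU", {"CA": (7, 0, 0), "CB": (4, 0, 0)}),
            (7, "LEU", {"CA": (9, 0, 0), "CB": (7, 0, 0)}),
        ])
        pairs = detect_interactions(frame, "HC")
        assert pairs == detect_interactions(frame, "HC")
        assert all(a < b for a, b in pairs)

    def test_all_atom_mode_on_ca_only_input_is_a_mode_error(self):
        frame = make_ca_structure(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(ConfigError, match="residue_center"):
            detect_interactions(frame, "HC")

    def test_unknown_class_rejected(self):
        frame = make_ca_structure(np.eye(3))
        with pytest.raises(ConfigError):
            detect_interactions(frame, "XX", CENTER_MODE)


class TestInteractionPersistence:
    def _two_leu_traj(self, n_frames, n_close):
        frames = np.zeros((n_frames, 2, 3))
        frames[:, 1, 0] = 10.0
        frames[:n_close, 1, 0] = 4.0
        return make_trajectory(frames, residue_numbers=[1, 3],
                               resnames=["LEU", "LEU"])

    def test_always_in_contact_gives_one(self):
        traj = self._two_leu_traj(50, 50)
        recs = interaction_persistence(traj, "HC", CENTER_MODE)
        assert recs == [InteractionRecord(1, 3, "HC", 1.0)]

    def test_seventy_of_hundred_frames_gives_exactly_point_seven(self):
        traj = self._two_leu_traj(100, 70)
        recs = interaction_persistence(traj, "HC", CENTER_MODE)
        assert len(recs) == 1
        assert recs[0].persistence == 0.70

    def test_pair_never_in_contact_is_absent(self):
        traj = self._two_leu_traj(20, 0)
        assert interaction_persistence(traj, "HC", CENTER_MODE) == []

    def test_production_start_restricts_the_denominator(self):
        traj = self._two_leu_traj(100, 70)
        recs = interaction_persistence(traj, "HC", CENTER_MODE,
                                       production_start=50)
        assert recs[0].persistence == pytest.approx(20 / 50)

    def test_offset_converts_to_sequence_numbering(self):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 4.0
        traj = make_trajectory(frames, residue_numbers=[11, 13],
                               resnames=["LEU", "LEU"])
        recs = interaction_persistence(traj, "HC", CENTER_MODE, offset=10)
        assert recs[0].pair == (1, 3)

    def test_empty_production_run_rejected(self):
        traj = self._two_leu_traj(10, 10)
        with pytest.raises(EmptyInputError):
            interaction_persistence(traj, "HC", CENTER_MODE,
                                    production_start=10)


def hc(a, b, p):
    return InteractionRecord(a, b, "HC", p)


class TestPersistenceThreshold:
    # 10-residue chain with alternating strong/weak links: removing the weak
    # ones shatters the chain into pairs, the largest single-step drop
    LADDER = [hc(i, i + 1, 0.9 if i % 2 else 0.35) for i in range(1, 10)]

    def test_ladder_pcrit_at_the_weak_rung(self):
        # edges (1,2),(3,4),... weak at 0.35; (2,3),(4,5),... strong at 0.9
        assert persistence_threshold(self.LADDER) == pytest.approx(0.36)

    def test_ladder_cluster_curve_matches_hand_enumeration(self):
        thresholds, sizes = largest_cluster_sizes(self.LADDER)
        by_p = dict(zip(np.round(thresholds, 2), sizes))
        assert by_p[0.0] == 10
        assert by_p[0.34] == 10
        assert by_p[0.36] == 2  # only strong pairs remain
        assert by_p[0.90] == 2
        assert by_p[0.92] == 1
        assert np.all(np.diff(sizes) <= 0)  # non-increasing in the threshold

    def test_single_record_at_half(self):
        assert persistence_threshold([hc(1, 5, 0.5)]) == pytest.approx(0.52)

    def test_all_persistences_one_collapse_at_final_boundary(self):
        records = [hc(1, 3, 1.0), hc(3, 5, 1.0)]
        assert persistence_threshold(records) == pytest.approx(1.02)

    def test_no_records_instructs_explicit_threshold(self):
        with pytest.raises(EmptyInputError, match="p_crit"):
            persistence_threshold([])


class TestBuildPsn:
    def test_empty_inputs_give_empty_graph(self):
        graph = build_psn({"SB": [], "HB": [], "HC": []}, 0.5,
                          nodes=[1, 2, 3])
        assert graph.n_edges == 0
        assert all(d == 0 for d in graph.degrees().values())

    def test_triangle_gives_degree_two_everywhere(self):
        recs = {"HC": [hc(1, 3, 0.8), hc(3, 5, 0.8), hc(1, 5, 0.8)]}
        graph = build_psn(recs, 0.5)
        assert graph.degrees() == {1: 2, 3: 2, 5: 2}

    def test_hand_built_eight_residue_system(self):
        records = {
            "SB": [InteractionRecord(1, 4, "SB", 0.9),
                   InteractionRecord(2, 5, "SB", 0.95)],
            "HB": [InteractionRecord(1, 6, "HB", 0.8),
                   InteractionRecord(2, 5, "HB", 0.9),
                   InteractionRecord(6, 8, "HB", 0.3)],  # below threshold
            "HC": [InteractionRecord(4, 6, "HC", 0.7),
                   InteractionRecord(3, 8, "HC", 0.6),
                   InteractionRecord(5, 8, "HC", 0.55)],
        }
        graph = build_psn(records, 0.5, nodes=range(1, 9))
        # hand count: (1,4),(1,6),(4,6),(2,5) [SB+HB merged],(3,8),(5,8)
        assert graph.degrees() == {1: 2, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2,
                                   7: 0, 8: 2}
        assert graph.n_edges == 6
        assert sum(graph.degrees().values()) == 2 * graph.n_edges
        # a pair linked by SB and HB counts once pairwise, twice per class
        assert graph.degree(2) == 1
        assert graph.degree(2, per_class=True) == 2

    def test_per_class_thresholds(self):
        records = {
            "SB": [InteractionRecord(1, 4, "SB", 0.6)],
            "HC": [hc(2, 6, 0.6)],
        }
        graph = build_psn(records, {"SB": 0.7, "HB": 0.5, "HC": 0.5})
        assert graph.degree(1) == 0 and graph.degree(2) == 1

    def test_raising_threshold_never_adds_edges(self, rng):
        records = {"HC": [hc(a, a + 2 + k, float(p)) for k, (a, p) in
                          enumerate(zip(rng.integers(1, 40, 25),
                                        rng.uniform(0, 1, 25)))]}
        edge_sets = []
        for p in (0.0, 0.3, 0.6, 0.9):
            g = build_psn(records, p)
            edge_sets.append({(r.residue_a, r.residue_b) for r in g.edges})
        for low, high in zip(edge_sets, edge_sets[1:]):
            assert high <= low


class TestHubsAndDeltaDegree:
    @staticmethod
    def star(center, n_leaves):
        recs = {"HC": [hc(min(center, center + 2 + 2 * i),
                          max(center, center + 2 + 2 * i), 1.0)
                       for i in range(n_leaves)]}
        return build_psn(recs, 0.5)

    def test_hub_rule_is_strict_inequality(self):
        graphs = {"A": self.star(1, 7), "B": self.star(1, 6)}
        report = find_hubs(graphs, k_min=6)
        assert report.hubs == [1]  # degree 7 in A qualifies
        only_six = find_hubs({"B": self.star(1, 6)}, k_min=6)
        assert only_six.hubs == []  # degree exactly 6 is not a hub

    def test_all_degrees_at_or_below_kmin_gives_empty_report(self):
        report = find_hubs({"A": self.star(1, 3)}, k_min=4)
        assert report.hubs == []

    def test_hub_in_one_system_reports_degrees_in_all(self):
        graphs = {"A": self.star(1, 5), "B": self.star(50, 2)}
        report = find_hubs(graphs, k_min=4)
        assert report.hubs == [1]
        assert report.table.loc[1, "A"] == 5
        assert report.table.loc[1, "B"] == 0

    def test_hub_sets_nest_with_threshold(self):
        graphs = {"A": self.star(1, 7), "B": self.star(30, 5)}
        at4 = set(find_hubs(graphs, k_min=4).hubs)
        at6 = set(find_hubs(graphs, k_min=6).hubs)
        assert at6 <= at4

    def test_empty_graph_set_rejected(self):
        with pytest.raises(EmptyInputError):
            find_hubs({}, k_min=4)

    def test_identical_graphs_have_zero_delta_degree(self):
        g = self.star(1, 4)
        assert set(delta_degree(g, g).values()) == {0}

    def test_simple_difference(self):
        g_open = self.star(1, 3)
        g_closed = self.star(1, 5)
        assert delta_degree(g_open, g_closed)[1] == -2

    def test_sum_rule_and_mostly_negative_when_open_loses_edges(self):
        closed_records = {"HC": [hc(1, 3, 1.0), hc(1, 5, 1.0), hc(3, 5, 1.0),
                                 hc(5, 7, 1.0), hc(7, 9, 1.0), hc(3, 9, 1.0)]}
        open_records = {"HC": [hc(1, 3, 1.0), hc(5, 7, 1.0)]}
        g_closed = build_psn(closed_records, 0.5)
        g_open = build_psn(open_records, 0.5)
        dd = delta_degree(g_open, g_closed)
        assert sum(dd.values()) == 2 * (g_open.n_edges - g_closed.n_edges)
        assert sum(1 for v in dd.values() if v < 0) > len(dd) / 2


class TestInterdomainTable:
    DOMAINS = DomainSet({"I": [(1, 4)], "II": [(5, 8)], "III": [(9, 12)]})

    def test_no_cross_domain_records_gives_empty_table(self):
        records = [hc(1, 3, 0.9), hc(9, 11, 0.9)]
        table = interdomain_table(records, 0.5, self.DOMAINS, "I", "III")
        assert table.empty

    def test_single_qualifying_salt_bridge(self):
        records = [InteractionRecord(2, 10, "SB", 0.8)]
        table = interdomain_table(records, 0.5, self.DOMAINS, "I", "III")
        assert len(table) == 1
        assert tuple(table.iloc[0][["residue_a", "residue_b"]]) == (2, 10)

    def test_threshold_is_strict(self):
        records = [InteractionRecord(2, 10, "SB", 0.5)]
        table = interdomain_table(records, 0.5, self.DOMAINS, "I", "III")
        assert table.empty

    def test_sorted_by_descending_persistence(self):
        records = [InteractionRecord(2, 10, "SB", 0.6),
                   InteractionRecord(3, 11, "HB", 0.9)]
        table = interdomain_table(records, 0.5, self.DOMAINS, "I", "III")
        assert list(table["persistence"]) == [0.9, 0.6]

    def test_overlapping_domains_rejected(self):
        # DomainSet refuses overlapping ranges at construction, so the only
        # overlap reachable here is a domain paired with itself
        records = [InteractionRecord(2, 10, "SB", 0.8)]
        with pytest.raises(ConfigError):
            interdomain_table(records, 0.5, self.DOMAINS, "I", "I")
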