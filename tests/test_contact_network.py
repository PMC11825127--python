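"""Contact probabilities, stable graphs, communities, difference networks."""

import networkx as nx
import numpy as np
import pytest

from rafdimer.contact_network import (
    ContactMap,
    PartitionError,
    community_average_contacts,
    community_protomer_labels,
    contact_probabilities,
    detect_communities,
    diff_network,
    stable_contact_graph,
)
from rafdimer.structure_io import AtomRecord, KinaseStructure, Protomer
from rafdimer.synthetic_data import make_contact_scenario
from rafdimer.trajectory import EmptyDataError, Trajectory


def _toy_topology(positions):
    """One CA per residue at the given (chain, resnum) → xyz positions."""
    chains: dict[str, list[AtomRecord]] = {}
    for (chain, resnum), xyz in positions.items():
        chains.setdefault(chain, []).append(
            AtomRecord("CA", "C", "GLY", resnum, chain, "", np.asarray(xyz, float))
        )
    return KinaseStructure([Protomer(c, atoms) for c, atoms in chains.items()], [])


def _traj_from_frames(topology, frames):
    return Trajectory(topology, np.asarray(frames, dtype=float))


def test_fixed_contact_probability_one():
    topo = _toy_topology({("A", 1): (0, 0, 0), ("A", 10): (3, 0, 0)})
    traj = _traj_from_frames(topo, [topo.coordinates()] * 5)
    cmap = contact_probabilities(traj)
    assert cmap.probability(("A", 1), ("A", 10)) == 1.0


def test_toggling_contact_seven_of_ten():
    topo = _toy_topology({("A", 1): (0, 0, 0), ("A", 10): (3, 0, 0)})
    near = topo.coordinates()
    far = near.copy()
    far[1, 0] = 30.0
    frames = [near] * 7 + [far] * 3
    cmap = contact_probabilities(_traj_from_frames(topo, frames))
    assert cmap.probability(("A", 1), ("A", 10)) == pytest.approx(0.7)


def test_distant_residues_absent():
    topo = _toy_topology({("A", 1): (0, 0, 0), ("A", 10): (20, 0, 0)})
    cmap = contact_probabilities(_traj_from_frames(topo, [topo.coordinates()] * 3))
    assert cmap.probability(("A", 1), ("A", 10)) == 0.0
    assert cmap.pair_probabilities == {}


def test_sequence_adjacent_pairs_excluded():
    topo = _toy_topology({("A", 1): (0, 0, 0), ("A", 2): (3, 0, 0), ("A", 3): (6, 0, 0), ("A", 4): (3, 3, 0)})
    cmap = contact_probabilities(_traj_from_frames(topo, [topo.coordinates()] * 2))
    # |Δresnum| ≤ 2 in the same chain never forms a contact edge
    assert cmap.probability(("A", 1), ("A", 2)) == 0.0
    assert cmap.probability(("A", 1), ("A", 3)) == 0.0
    assert cmap.probability(("A", 1), ("A", 4)) > 0.0


def test_empty_trajectory_raises():
    topo = _toy_topology({("A", 1): (0, 0, 0)})
    with pytest.raises(EmptyDataError):
        contact_probabilities(Trajectory(topo, np.empty((0, 1, 3))))


def test_concatenation_is_frame_weighted_mean():
    topo = _toy_topology({("A", 1): (0, 0, 0), ("A", 10): (3, 0, 0)})
    near = topo.coordinates()
    far = near.copy()
    far[1, 0] = 30.0
    t1 = _traj_from_frames(topo, [near] * 4)  # p = 1.0 over 4 frames
    t2 = _traj_from_frames(topo, [near] * 1 + [far] * 5)  # p = 1/6 over 6 frames
    combined = contact_probabilities(t1.concatenated(t2))
    p1 = contact_probabilities(t1).probability(("A", 1), ("A", 10))
    p2 = contact_probabilities(t2).probability(("A", 1), ("A", 10))
    expected = (4 * p1 + 6 * p2) / 10
    assert combined.probability(("A", 1), ("A", 10)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# stable graph and communities


def test_stable_threshold_closed_boundary():
    pairs = {
        (("A", 1), ("A", 10)): 0.7,
        (("A", 1), ("A", 20)): 0.69,
    }
    cmap = ContactMap(pairs, n_frames=100, cutoff=4.5, residues=(("A", 1), ("A", 10), ("A", 20)))
    g = stable_contact_graph(cmap, threshold=0.7)
    assert g.has_edge(("A", 1), ("A", 10))
    assert not g.has_edge(("A", 1), ("A", 20))


def test_stable_graph_equals_brute_force_filter(rng):
    residues = [("A", i) for i in range(1, 40, 3)]
    pairs = {}
    for i, a in enumerate(residues):
        for b in residues[i + 1 :]:
            pairs[(a, b)] = float(rng.random())
    cmap = ContactMap(pairs, n_frames=10, cutoff=4.5, residues=tuple(residues))
    g = stable_contact_graph(cmap, threshold=0.7)
    expected = {tuple(sorted(k)) for k, p in pairs.items() if p >= 0.7}
    assert {tuple(sorted(e)) for e in g.edges} == expected


def _clique(chain, start, size, next_chain_offset=0):
    return [(chain, start + 3 * i) for i in range(size)]


def _clique_graph(cliques, bridges):
    g = nx.Graph()
    for c in cliques:
        for i, a in enumerate(c):
            for b in c[i + 1 :]:
                g.add_edge(a, b)
    for a, b in bridges:
        g.add_edge(a, b)
    return g


def test_two_cliques_one_bridge_k2():
    c1 = _clique("A", 1, 10)
    c2 = _clique("B", 1, 10)
    g = _clique_graph([c1, c2], [(c1[0], c2[0])])
    part = detect_communities(g, k=2)
    assert part.members(part.assignment[c1[0]]) == set(c1)
    assert part.members(part.assignment[c2[0]]) == set(c2)


def test_four_cliques_in_ring_k4_recovers_cliques():
    cliques = [_clique(ch, start, 4) for ch, start in [("A", 1), ("A", 101), ("B", 1), ("B", 101)]]
    bridges = [
        (cliques[0][0], cliques[1][0]),
        (cliques[1][1], cliques[2][1]),
        (cliques[2][2], cliques[3][2]),
        (cliques[3][3], cliques[0][3]),
    ]
    g = _clique_graph(cliques, bridges)
    part = detect_communities(g, k=4)
    found = {frozenset(part.members(c)) for c in part.communities()}
    assert found == {frozenset(c) for c in cliques}
    # the recovered partition is at least as modular as any seen during the cut
    q = nx.community.modularity(g, [set(c) for c in cliques])
    assert nx.community.modularity(g, [part.members(c) for c in part.communities()]) == pytest.approx(q)


def test_isolated_residue_joins_nearest_in_sequence():
    c1 = _clique("A", 1, 5)
    c2 = _clique("A", 101, 5)
    g = _clique_graph([c1, c2], [])
    g.add_node(("A", 50))  # isolate, nearer in sequence to the 1..13 block
    part = detect_communities(g, k=2)
    assert part.assignment[("A", 50)] == part.assignment[("A", 13)]


def test_partition_error_when_k_unreachable():
    g = nx.Graph()
    g.add_edge(("A", 1), ("A", 10))
    with pytest.raises(PartitionError):
        detect_communities(g, k=3)


def test_determinism_of_partition():
    cliques = [_clique(ch, start, 4) for ch, start in [("A", 1), ("A", 101), ("B", 1), ("B", 101)]]
    bridges = [(cliques[i][0], cliques[(i + 1) % 4][0]) for i in range(4)]
    g = _clique_graph(cliques, bridges)
    p1 = detect_communities(g, k=4)
    p2 = detect_communities(g, k=4)
    assert p1.assignment == p2.assignment


# ---------------------------------------------------------------------------
# community averages and difference networks


def _simple_partition():
    assignment = {("A", 1): 0, ("A", 10): 0, ("A", 101): 1, ("B", 1): 2, ("B", 101): 3}
    from rafdimer.contact_network import CommunityPartition

    return CommunityPartition(assignment, 4)


def test_community_average_contacts_hand_summed():
    part = _simple_partition()
    pairs = {
        (("A", 1), ("A", 101)): 0.5,   # communities 0–1
        (("A", 10), ("A", 101)): 0.25,  # communities 0–1
        (("A", 1), ("B", 1)): 1.0,     # communities 0–2
        (("B", 1), ("B", 101)): 0.4,   # communities 2–3
        (("A", 1), ("A", 10)): 0.9,    # within community 0
    }
    cmap = ContactMap(pairs, n_frames=10, cutoff=4.5, residues=tuple(part.assignment))
    avg = community_average_contacts(cmap, part)
    assert avg[(0, 1)] == pytest.approx(0.75)
    assert avg[(0, 2)] == pytest.approx(1.0)
    assert avg[(2, 3)] == pytest.approx(0.4)
    assert avg[(0, 0)] == pytest.approx(0.9)
    assert avg[(1, 3)] == 0.0


def test_community_average_contacts_replica_mean():
    part = _simple_partition()
    maps = []
    for p in (0.2, 0.4):
        maps.append(
            ContactMap({(("A", 1), ("B", 1)): p}, n_frames=10, cutoff=4.5, residues=tuple(part.assignment))
        )
    avg = community_average_contacts(maps, part)
    assert avg[(0, 2)] == pytest.approx(0.3)


def test_residue_missing_from_partition_raises():
    part = _simple_partition()
    cmap = ContactMap({(("A", 1), ("C", 7)): 0.5}, n_frames=10, cutoff=4.5)
    with pytest.raises(ValueError, match="missing"):
        community_average_contacts(cmap, part)


def test_diff_network_constructed_deltas_sum():
    protomer_of = {0: "A", 1: "A", 2: "B", 3: "B"}
    apo = {(0, 3): 0.0, (1, 3): 0.2, (0, 1): 1.0}
    holo = {(0, 3): 0.5, (1, 3): 0.0, (0, 1): 1.0}
    diff = diff_network(holo, apo, protomer_of)
    # interprotomer deltas: +0.5 (N_A–C_B) and −0.2 (C_A–C_B) → +0.3
    assert diff.interprotomer_sum == pytest.approx(0.3)
    # intraprotomer edge (0,1) does not contribute
    assert diff.edges[(0, 1)] == 0.0
    # internal consistency: the sum equals the displayed interprotomer edges
    manual = sum(v for (i, j), v in diff.edges.items() if i != j and protomer_of[i] != protomer_of[j])
    assert diff.interprotomer_sum == pytest.approx(manual)


def test_diff_network_antisymmetry_and_zero():
    protomer_of = {0: "A", 1: "B"}
    x = {(0, 1): 0.7, (0, 0): 0.2}
    y = {(0, 1): 0.4, (0, 0): 0.5}
    zero = diff_network(x, x, protomer_of)
    assert zero.interprotomer_sum == 0.0
    assert all(v == 0.0 for v in zero.edges.values())
    fwd = diff_network(x, y, protomer_of)
    rev = diff_network(y, x, protomer_of)
    assert fwd.interprotomer_sum == pytest.approx(-rev.interprotomer_sum)
    for k in fwd.edges:
        assert fwd.edges[k] == pytest.approx(-rev.edges[k])


def test_diff_network_mismatched_universe():
    with pytest.raises(ValueError, match="universes"):
        diff_network({(0, 1): 0.1}, {(0, 2): 0.1}, {0: "A", 1: "B", 2: "B"})


# ---------------------------------------------------------------------------
# end-to-end planted scenario


def test_planted_scenario_recovers_blocks_and_delta_sum():
    apo = {("N_A", "C_B"): 0.2, ("C_A", "C_B"): 0.5}
    holo = {("N_A", "C_B"): 0.7, ("C_A", "C_B"): 0.3}
    apo_t, holo_t, layout = make_contact_scenario(apo, holo, n_frames=1500, n_replicas=3, seed=9)
    apo_maps = [contact_probabilities(t) for t in apo_t]
    holo_maps = [contact_probabilities(t) for t in holo_t]
    part = detect_communities(stable_contact_graph(apo_maps[0]), 4)
    found = {frozenset(part.members(c)) for c in part.communities()}
    assert found == {frozenset(v) for v in layout["blocks"].values()}
    labels = community_protomer_labels(part)
    diff = diff_network(
        community_average_contacts(holo_maps, part),
        community_average_contacts(apo_maps, part),
        labels,
    )
    # planted delta: (0.7 − 0.2) + (0.3 − 0.5) = +0.3, within sampling error
    n = 3 * 1500
    tol = 3 * np.sqrt(2 * 0.25 / n)
    assert diff.interprotomer_sum == pytest.approx(0.3, abs=tol)


def test_identical_scenarios_give_zero_sum():
    probs = {("N_A", "C_B"): 0.4}
    apo_t, holo_t, _ = make_contact_scenario(probs, probs, n_frames=1500, n_replicas=3, seed=10)
    apo_maps = [contact_probabilities(t) for t in apo_t]
    holo_maps = [contact_probabilities(t) for t in holo_t]
    part = detect_communities(stable_contact_graph(apo_maps[0]), 4)
    labels = community_protomer_labels(part)
    diff = diff_network(
        community_average_contacts(holo_maps, part),
        community_average_contacts(apo_maps, part),
        labels,
    )
    assert abs(diff.interprotomer_sum) < 3 * np.sqrt(0.24 / (3 * 1500)) * 2
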