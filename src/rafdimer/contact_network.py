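"""Difference contact network analysis of apo vs holo ensembles.

The pipeline follows the difference-contact-network approach used for
comparing two simulation ensembles of the same dimer:

1. residue-pair **contact probabilities** — fraction of frames in which any
   heavy-atom pair of two residues lies within 4.5 Å (sequence-adjacent
   pairs excluded);
2. a **stable-contact graph** keeping pairs with probability ≥ 0.7;
3. a deterministic **community partition** of that graph into k = 4
   communities (divisive edge-betweenness / Girvan–Newman), which for a
   kinase dimer recovers the N- and C-lobes of the two protomers;
4. **community-level average contacts** (summed pair probabilities, i.e.
   expected numbers of simultaneous contacts) for each ensemble; and
5. the **difference network** holo − apo, with the signed sum over
   community pairs that span the two protomers as the headline measure of
   inhibitor-induced dimer-interface (de)stabilisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .trajectory import EmptyDataError, Trajectory

__all__ = [
    "CONTACT_CUTOFF",
    "STABLE_CONTACT_THRESHOLD",
    "N_COMMUNITIES",
    "ResidueKey",
    "ContactMap",
    "CommunityPartition",
    "DiffNetwork",
    "PartitionError",
    "contact_probabilities",
    "stable_contact_graph",
    "detect_communities",
    "community_average_contacts",
    "community_protomer_labels",
    "diff_network",
]

CONTACT_CUTOFF = 4.5  # Å, heavy-atom distance defining a residue contact
STABLE_CONTACT_THRESHOLD = 0.7  # fraction of frames for a stable contact
N_COMMUNITIES = 4
SEQUENCE_EXCLUSION = 2  # |Δresnum| ≤ 2 within a chain: trivial neighbours

ResidueKey = tuple[str, int]  # (chain id, residue number)


class PartitionError(ValueError):
    """The requested number of communities cannot be reached."""


@dataclass
class ContactMap:
    """Symmetric residue-pair contact probabilities from one ensemble."""

    pair_probabilities: dict[tuple[ResidueKey, ResidueKey], float]
    n_frames: int
    cutoff: float
    residues: tuple[ResidueKey, ...] = ()

    def __post_init__(self):
        for (a, b), p in self.pair_probabilities.items():
            if a == b:
                raise ValueError(f"self-pair {a} in contact map")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} for pair {a}-{b} outside [0, 1]")

    def probability(self, a: ResidueKey, b: ResidueKey) -> float:
        return self.pair_probabilities.get(_ordered(a, b), 0.0)


def _ordered(a: ResidueKey, b: ResidueKey) -> tuple[ResidueKey, ResidueKey]:
    return (a, b) if a <= b else (b, a)


def contact_probabilities(
    trajectory: Trajectory,
    cutoff: float = CONTACT_CUTOFF,
    sequence_exclusion: int = SEQUENCE_EXCLUSION,
) -> ContactMap:
    """Fraction of frames in which each residue pair is in contact.

    A pair is in contact in a frame when any heavy-atom pair of the two
    residues is within *cutoff*.  Pairs with |Δ residue number| ≤
    *sequence_exclusion* in the same chain are excluded as trivial covalent
    neighbours.
    """
    if trajectory.n_frames == 0:
        raise EmptyDataError("contact probabilities of an empty trajectory")
    atoms = trajectory.topology.flat_atoms()
    atom_res = [(a.chain_id, a.residue_number) for a in atoms]
    residues = tuple(dict.fromkeys(atom_res))
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for f in range(trajectory.n_frames):
        tree = cKDTree(trajectory.coords[f])
        seen: set[tuple[ResidueKey, ResidueKey]] = set()
        for i, j in tree.query_pairs(cutoff):
            ra, rb = atom_res[i], atom_res[j]
            if ra == rb:
                continue
            if ra[0] == rb[0] and abs(ra[1] - rb[1]) <= sequence_exclusion:
                continue
            seen.add(_ordered(ra, rb))
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    probs = {pair: c / trajectory.n_frames for pair, c in counts.items()}
    return ContactMap(probs, trajectory.n_frames, cutoff, residues)


def stable_contact_graph(cmap: ContactMap, threshold: float = STABLE_CONTACT_THRESHOLD) -> nx.Graph:
    """Graph of residues whose contact probability reaches the threshold.

    The threshold comparison is closed: probability ≥ threshold keeps the
    edge.  All residues of the map become nodes, so residues with no stable
    contact appear as isolates.
    """
    g = nx.Graph()
    g.add_nodes_from(cmap.residues)
    for (a, b), p in cmap.pair_probabilities.items():
        g.add_node(a)
        g.add_node(b)
        if p >= threshold:
            g.add_edge(a, b, probability=p)
    return g


@dataclass
class CommunityPartition:
    assignment: dict[ResidueKey, int]
    n_communities: int

    def __post_init__(self):
        found = len(set(self.assignment.values()))
        if found != self.n_communities:
            raise ValueError(f"{found} communities assigned, expected {self.n_communities}")

    def members(self, community: int) -> set[ResidueKey]:
        return {r for r, c in self.assignment.items() if c == community}

    def communities(self) -> list[int]:
        return sorted(set(self.assignment.values()))


def detect_communities(graph: nx.Graph, k: int = N_COMMUNITIES) -> CommunityPartition:
    """Deterministic divisive edge-betweenness partition into *k* communities.

    Edges of maximal betweenness are removed until the graph splits into
    *k* connected components; among equal-betweenness edges the
    lexicographically smallest ``(chainA, resA, chainB, resB)`` is removed,
    which makes the partition reproducible.  Isolated residues do not count
    as communities: each joins the community of the nearest-in-sequence
    assigned residue of its own chain.
    """
    if graph.number_of_nodes() == 0:
        raise PartitionError("cannot partition an empty graph")
    isolates = [n for n in graph.nodes if graph.degree(n) == 0]
    work = graph.subgraph([n for n in graph.nodes if graph.degree(n) > 0]).copy()
    if work.number_of_nodes() == 0:
        raise PartitionError("graph has no edges; no community structure to detect")

    while nx.number_connected_components(work) < k:
        if work.number_of_edges() == 0:
            raise PartitionError(
                f"ran out of edges at {nx.number_connected_components(work)} components, "
                f"needed {k}"
            )
        betweenness = nx.edge_betweenness_centrality(work)
        best = max(betweenness.values())
        candidates = [e for e, v in betweenness.items() if abs(v - best) < 1e-12]
        edge = min(tuple(sorted(e)) for e in candidates)
        work.remove_edge(*edge)

    components = sorted(nx.connected_components(work), key=lambda c: min(c))
    if len(components) != k:
        # removing one edge can split a component into at most two parts, so
        # overshoot is impossible; guard anyway
        raise PartitionError(f"got {len(components)} components, expected {k}")
    assignment: dict[ResidueKey, int] = {}
    for cid, comp in enumerate(components):
        for r in comp:
            assignment[r] = cid
    for node in isolates:
        chain, resnum = node
        same_chain = [r for r in assignment if r[0] == chain]
        pool = same_chain or list(assignment)
        nearest = min(pool, key=lambda r: (abs(r[1] - resnum), r))
        assignment[node] = assignment[nearest]
    return CommunityPartition(assignment, k)


def community_protomer_labels(partition: CommunityPartition) -> dict[int, str]:
    """Protomer (chain) label of each community, by majority of its members."""
    labels: dict[int, str] = {}
    for c in partition.communities():
        chains = [r[0] for r in partition.members(c)]
        labels[c] = max(sorted(set(chains)), key=chains.count)
    return labels


def community_average_contacts(
    cmap: ContactMap | list[ContactMap],
    partition: CommunityPartition,
) -> dict[tuple[int, int], float]:
    """Average number of simultaneous contacts between community pairs.

    The value for a community pair is the sum of the residue-pair contact
    probabilities between the two communities (the expected number of
    contacts present in a frame).  A list of maps (replicas) is averaged.
    """
    if isinstance(cmap, list):
        per_replica = [community_average_contacts(m, partition) for m in cmap]
        keys = set().union(*per_replica)
        return {k: float(np.mean([d.get(k, 0.0) for d in per_replica])) for k in keys}
    out: dict[tuple[int, int], float] = {
        (ci, cj): 0.0
        for ci, cj in combinations_with_replacement(partition.communities(), 2)
    }
    for (a, b), p in cmap.pair_probabilities.items():
        if a not in partition.assignment or b not in partition.assignment:
            raise ValueError(f"residue {a if a not in partition.assignment else b} missing from partition")
        ci, cj = sorted((partition.assignment[a], partition.assignment[b]))
        out[(ci, cj)] += p
    return out


@dataclass
class DiffNetwork:
    """Community-level holo − apo contact changes."""

    edges: dict[tuple[int, int], float]
    interprotomer_sum: float


def diff_network(
    holo_avgs: dict[tuple[int, int], float],
    apo_avgs: dict[tuple[int, int], float],
    protomer_of: dict[int, str],
) -> DiffNetwork:
    """Edge-wise holo − apo differences and the inter-protomer change sum.

    The inter-protomer sum adds the deltas over community pairs whose two
    communities belong to different protomers, each unordered pair counted
    once; a positive sum means inhibitor binding increased inter-protomer
    contacts.  Swapping the inputs negates every edge and the sum.
    """
    holo_comms = {c for pair in holo_avgs for c in pair}
    apo_comms = {c for pair in apo_avgs for c in pair}
    if holo_comms != apo_comms:
        raise ValueError(f"community universes differ: {sorted(holo_comms)} vs {sorted(apo_comms)}")
    missing = holo_comms - set(protomer_of)
    if missing:
        raise ValueError(f"communities without protomer label: {sorted(missing)}")
    keys = {tuple(sorted(k)) for k in holo_avgs} | {tuple(sorted(k)) for k in apo_avgs}
    edges = {
        k: holo_avgs.get(k, 0.0) - apo_avgs.get(k, 0.0)
        for k in sorted(keys)
    }
    total = sum(
        delta
        for (ci, cj), delta in edges.items()
        if ci != cj and protomer_of[ci] != protomer_of[cj]
    )
    return DiffNetwork(edges=edges, interprotomer_sum=float(total))
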