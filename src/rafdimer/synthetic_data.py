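"""Synthetic kinase structures and trajectories with planted descriptor values.

The generator builds minimal BRAF-numbered protomers containing exactly the
atoms the descriptors need, placed so that every descriptor evaluates to a
requested target.  Each descriptor is controlled independently:

* the αC position slides the Asn500/Glu501/Val502 Cα triplet along a fixed
  axis from the Ile582 Cα;
* the DFG pseudo-dihedral rotates the Phe595 Cα about the Gly593–Asp594
  axis;
* the Lys483–Glu501 distance slides the Lys483 NZ along the carboxylate
  OE1→ direction;
* the ligand–Glu501 h-bond distance slides the ligand's amide nitrogen
  along a third, orthogonal direction from OE1.

Trajectories realise per-frame draws from stated distributions (normal for
distances, wrapped-normal mixtures for the dihedral, Bernoulli occupancy
for the salt bridge and h-bond), reproducibly from a seed; replicas differ
only by sub-seed.  The geometry is deliberately not physical — no bonds,
no sterics — it emulates only the statistical structure of the descriptor
series (bimodal αC, broad DFG, Bernoulli salt bridge, n = 3 replicas) so
that every analysis stage is testable without any structure download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import (
    AtomRecord,
    KinaseStructure,
    LigandRecord,
    LIGAND_ANNOTATIONS,
    Protomer,
)
from .trajectory import Trajectory

__all__ = [
    "SyntheticSpec",
    "GenerationError",
    "make_structure",
    "make_trajectory",
    "make_contact_scenario",
]


class GenerationError(ValueError):
    """The requested synthetic geometry is infeasible."""


# scalar target, (mean, sd) distribution, or a per-protomer list of either
Target = float | tuple[float, float] | list


@dataclass
class SyntheticSpec:
    """Targets for one synthetic system.

    Point targets (floats) produce static structures; ``(mean, sd)`` pairs
    or mixture component lists produce per-frame draws.  ``ke_occupancy``
    plants a Bernoulli salt bridge: an "on" frame draws the NZ–carboxylate
    distance inside the 4 Å criterion, an "off" frame outside it.
    """

    n_protomers: int = 2
    alpha_c_target: Target = 19.1
    dfg_target: Target = 210.0  # degrees, or [(mean, sd, weight), ...]
    ke_target: Target = 3.5
    ke_occupancy: float | list[float] | None = None
    ligand_present: bool | list[bool] = False
    ligand_resname: str = "PHI"
    ligand_glu501_hbond: bool | list[bool] = True
    ligand_glu501_hbond_prob: float | None = None
    asp594_mode: str = "accepts"  # accepts | donates | none
    his574_hbond: bool = True
    leu505_contact: bool = True
    n_frames: int = 10_000
    n_replicas: int = 3
    seed: int = 0
    contact_scenario: dict[tuple[str, str], float] | None = None

    def __post_init__(self):
        if self.n_protomers not in (1, 2):
            raise GenerationError("n_protomers must be 1 or 2")
        if self.n_frames < 1:
            raise GenerationError("n_frames must be ≥ 1")
        for p in self._probabilities():
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"probability {p} outside [0, 1]")

    def _probabilities(self):
        probs = []
        if self.ke_occupancy is not None:
            probs += list(np.atleast_1d(self.ke_occupancy))
        if self.ligand_glu501_hbond_prob is not None:
            probs.append(self.ligand_glu501_hbond_prob)
        if self.contact_scenario:
            probs += list(self.contact_scenario.values())
        return probs

    def per_protomer(self, value, i: int):
        if isinstance(value, list) and value and isinstance(value[0], (list, tuple, float, int, bool)):
            # per-protomer list only when its length matches n_protomers and
            # it is not a mixture-component list
            if len(value) == self.n_protomers and not (
                isinstance(value[0], (list, tuple)) and len(value[0]) == 3
            ):
                return value[i]
        return value


# ---------------------------------------------------------------------------
# geometry template

_HB_ON = 2.9  # Å, planted donor–acceptor distance when an h-bond is present
_HB_OFF = 6.5  # Å, planted distance when absent (beyond the 3.5 Å criterion)

_CHAIN_OFFSETS = {0: np.zeros(3), 1: np.array([80.0, 0.0, 0.0])}
_CHAIN_IDS = ("A", "B")


def _dihedral_p4(p2, p3, angle_deg, branch=(-1.3, 2.2)):
    """Place the fourth point of a torsion quadruple at the requested angle.

    With p1 = p2 + (branch_x, branch_y, 0) and the p2→p3 axis along +x,
    the torsion of (p1, p2, p3, p4) equals ``angle_deg`` for
    p4 = p3 + (−branch_x, branch_y·cosθ, branch_y·sinθ) under the
    right-hand convention used by :func:`rafdimer.descriptors.pseudo_dihedral`.
    """
    theta = np.radians(np.asarray(angle_deg, dtype=float))
    bx, by = branch
    dx = np.full_like(theta, -bx)
    return p3 + np.stack([dx, by * np.cos(theta), by * np.sin(theta)], axis=-1)


def _protomer_template(chain_id: str, offset: np.ndarray, alpha_c: float, dfg: float, ke: float):
    """Atom list realising the point targets exactly; returns (atoms, anchors)."""
    if alpha_c <= 0 or ke <= 0:
        raise GenerationError("distance targets must be positive")

    def A(name, element, resname, resnum, xyz):
        return AtomRecord(name, element, resname, resnum, chain_id, "", offset + np.asarray(xyz, float))

    atoms: list[AtomRecord] = []
    # β7 reference and αC centre: centroid of the three Cα sits at (d, 0, 0)
    atoms.append(A("CA", "C", "ILE", 582, (0.0, 0.0, 0.0)))
    atoms.append(A("CA", "C", "ASN", 500, (alpha_c, -1.55, 0.0)))
    atoms.append(A("CA", "C", "GLU", 501, (alpha_c, 0.0, 0.0)))
    atoms.append(A("CA", "C", "VAL", 502, (alpha_c, 1.55, 0.0)))
    # Glu501 sidechain down to the carboxylate
    cd = np.array([alpha_c + 1.5, 0.0, 3.9])
    oe1 = cd + np.array([0.0, 1.0, 0.75])
    oe2 = cd + np.array([0.0, -1.0, 0.75])
    atoms.append(A("CB", "C", "GLU", 501, (alpha_c + 0.5, 0.0, 1.3)))
    atoms.append(A("CG", "C", "GLU", 501, (alpha_c + 1.0, 0.0, 2.6)))
    atoms.append(A("CD", "C", "GLU", 501, cd))
    atoms.append(A("OE1", "O", "GLU", 501, oe1))
    atoms.append(A("OE2", "O", "GLU", 501, oe2))
    # Lys483: NZ along +y from OE1 so that min(NZ–OE1, NZ–OE2) = ke exactly
    nz = oe1 + np.array([0.0, ke, 0.0])
    atoms.append(A("NZ", "N", "LYS", 483, nz))
    atoms.append(A("CA", "C", "LYS", 483, nz + np.array([0.0, 2.0, 2.0])))
    # Leu505 hydrophobic anchor
    ca505 = np.array([alpha_c, 4.65, 0.0])
    cd1_505 = ca505 + np.array([1.2, 1.2, -1.8])  # kept clear of the Lys483 region (z > 0)
    atoms.append(A("CA", "C", "LEU", 505, ca505))
    atoms.append(A("CB", "C", "LEU", 505, ca505 + np.array([0.8, 0.8, -1.0])))
    atoms.append(A("CD1", "C", "LEU", 505, cd1_505))
    # His574 backbone (h-bond acceptor carbonyl), placed away from the αC axis
    ca574 = np.array([-8.0, 12.0, 4.0])
    o574 = ca574 + np.array([1.2, 1.0, 0.0])
    atoms.append(A("N", "N", "HIS", 574, ca574 + np.array([-1.2, -0.8, 0.0])))
    atoms.append(A("CA", "C", "HIS", 574, ca574))
    atoms.append(A("C", "C", "HIS", 574, ca574 + np.array([1.3, 0.2, 0.0])))
    atoms.append(A("O", "O", "HIS", 574, o574))
    # DFG quadruple in its own region; Phe595 Cα set by the target torsion
    dfg_base = np.array([0.0, 25.0, 0.0])
    p2 = dfg_base
    p3 = dfg_base + np.array([3.8, 0.0, 0.0])
    p1 = dfg_base + np.array([-1.3, 2.2, 0.0])
    p4 = _dihedral_p4(p2, p3, dfg)
    atoms.append(A("CA", "C", "ILE", 592, p1))
    atoms.append(A("CA", "C", "GLY", 593, p2))
    n594 = p3 + np.array([-0.9, -1.1, 0.0])
    atoms.append(A("N", "N", "ASP", 594, n594))
    atoms.append(A("CA", "C", "ASP", 594, p3))
    c594 = p3 + np.array([1.2, 0.8, 0.0])
    o594 = c594 + np.array([0.6, 1.05, 0.0])
    atoms.append(A("C", "C", "ASP", 594, c594))
    atoms.append(A("O", "O", "ASP", 594, o594))
    atoms.append(A("CA", "C", "PHE", 595, p4))
    anchors = {
        "oe1": offset + oe1,
        "oe2": offset + oe2,
        "n594": offset + n594,
        "o594": offset + o594,
        "o574": offset + o574,
        "cd1_505": offset + cd1_505,
    }
    return atoms, anchors


_LIGAND_RESNUM = 901


def _ligand_atoms(chain_id: str, resname: str, anchors, glu_dist: float,
                  asp594_mode: str, his574: bool, leu505: bool):
    """Synthetic inhibitor with the annotated atom names of the shipped table."""

    def L(name, element, xyz):
        return AtomRecord(name, element, resname, _LIGAND_RESNUM, chain_id, "",
                          np.asarray(xyz, float), is_hetero=True)

    atoms = []
    # amide donor N1 along +z from OE1 (orthogonal to the NZ direction)
    n1 = anchors["oe1"] + np.array([0.0, 0.0, glu_dist])
    atoms.append(L("N1", "N", n1))
    atoms.append(L("C1", "C", n1 + np.array([0.0, 0.6, 1.1])))
    if asp594_mode == "accepts":
        # ligand carbonyl O1 accepts from the Asp594 backbone amide N
        o1 = anchors["n594"] + 2.9 * _unit([-0.6, -0.8, 0.0])
    else:
        o1 = anchors["n594"] + 8.0 * _unit([-0.6, -0.8, 0.0])
    atoms.append(L("O1", "O", o1))
    if asp594_mode == "donates":
        # sulfonamide-style donor N3 donates to the Asp594 backbone carbonyl O
        n3 = anchors["o594"] + 2.9 * _unit([0.7, 0.7, 0.2])
    else:
        n3 = anchors["o594"] + 8.0 * _unit([0.7, 0.7, 0.2])
    atoms.append(L("N3", "N", n3))
    n2 = anchors["o574"] + (2.9 if his574 else 8.0) * _unit([0.3, 1.0, 0.4])
    atoms.append(L("N2", "N", n2))
    # aliphatic carbons near Leu505 CD1 (non-aromatic 4.5 Å criterion)
    c_near = anchors["cd1_505"] + np.array([0.0, 0.0, -4.0 if leu505 else -8.0])
    atoms.append(L("C2", "C", c_near))
    atoms.append(L("C3", "C", c_near + np.array([1.4, 0.0, -0.3])))
    # a small aromatic patch, away from the protein
    ring0 = anchors["oe1"] + np.array([0.0, -6.0, 6.0])
    for i, name in enumerate(("C6", "C7", "C8")):
        atoms.append(L(name, "C", ring0 + np.array([1.4 * i, 0.0, 0.0])))
    return atoms


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _as_point(value, what: str) -> float:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    raise GenerationError(f"{what}: static generation needs a point target, got {value!r}")


def make_structure(spec: SyntheticSpec) -> KinaseStructure:
    """Build a static structure whose descriptors equal the spec's targets.

    Point targets are realised exactly (to float precision); writing to PDB
    and re-reading preserves them to the 1e-3 Å precision of the format.
    """
    protomers = []
    ligands = []
    for i in range(spec.n_protomers):
        chain_id = _CHAIN_IDS[i]
        offset = _CHAIN_OFFSETS[i]
        alpha_c = _as_point(spec.per_protomer(spec.alpha_c_target, i), "alpha_c_target")
        dfg = _as_point(spec.per_protomer(spec.dfg_target, i), "dfg_target")
        ke = _as_point(spec.per_protomer(spec.ke_target, i), "ke_target")
        atoms, anchors = _protomer_template(chain_id, offset, alpha_c, dfg, ke)
        protomers.append(Protomer(chain_id, atoms))
        if spec.per_protomer(spec.ligand_present, i):
            hbond = spec.per_protomer(spec.ligand_glu501_hbond, i)
            glu_dist = _HB_ON if hbond else _HB_OFF
            lig_atoms = _ligand_atoms(
                chain_id, spec.ligand_resname, anchors, glu_dist,
                spec.asp594_mode, spec.his574_hbond, spec.leu505_contact,
            )
            ann = LIGAND_ANNOTATIONS.get(spec.ligand_resname)
            names = {a.atom_name for a in lig_atoms}
            ligands.append(
                LigandRecord(
                    residue_name=spec.ligand_resname,
                    chain_id=chain_id,
                    atoms=lig_atoms,
                    donor_atoms=(ann.donors if ann else frozenset()) & names,
                    acceptor_atoms=(ann.acceptors if ann else frozenset()) & names,
                    aromatic_atoms=(ann.aromatic if ann else frozenset()) & names,
                    residue_number=_LIGAND_RESNUM,
                    annotated=ann is not None,
                )
            )
    return KinaseStructure(protomers, ligands, source_id=f"synthetic(seed={spec.seed})")


# ---------------------------------------------------------------------------
# trajectories


def _draw_distance(rng, target, n, floor=0.5):
    if isinstance(target, tuple):
        mean, sd = target
        return np.maximum(rng.normal(mean, sd, size=n), floor)
    return np.full(n, float(target))


def _draw_dihedral(rng, target, n):
    if isinstance(target, (int, float)):
        return np.full(n, float(target) % 360.0)
    if isinstance(target, tuple) and len(target) == 2:
        target = [(target[0], target[1], 1.0)]
    comps = list(target)
    weights = np.array([w for _, _, w in comps], dtype=float)
    weights = weights / weights.sum()
    which = rng.choice(len(comps), size=n, p=weights)
    out = np.empty(n)
    for ci, (mean, sd, _w) in enumerate(comps):
        mask = which == ci
        # wrapped-normal approximation to a circular law
        out[mask] = np.mod(rng.normal(mean, sd, size=int(mask.sum())), 360.0)
    return out


def _draw_ke(rng, spec: SyntheticSpec, i: int, n: int):
    occ = spec.per_protomer(spec.ke_occupancy, i) if spec.ke_occupancy is not None else None
    if occ is not None:
        on = rng.random(n) < float(occ)
        dist = np.where(
            on,
            np.clip(rng.normal(3.0, 0.25, size=n), 2.6, 3.95),
            5.5 + np.abs(rng.normal(0.0, 0.8, size=n)),
        )
        return dist
    return _draw_distance(rng, spec.per_protomer(spec.ke_target, i), n, floor=1.5)


def make_trajectory(spec: SyntheticSpec) -> list[Trajectory]:
    """One synthetic trajectory per replica, drawn from the spec's targets.

    Frame *t* of replica *r* realises an independent draw of every
    controlled descriptor; the same seed reproduces the same coordinates
    bit for bit, and replicas use independent sub-streams of the seed.
    """
    base = make_structure(_static_spec(spec))
    index = base.atom_index()
    template = base.coordinates()
    n = spec.n_frames
    trajectories = []
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicas)
    for r in range(spec.n_replicas):
        rng = np.random.default_rng(seeds[r])
        coords = np.tile(template, (n, 1, 1))
        for i in range(spec.n_protomers):
            cid = _CHAIN_IDS[i]
            offset = _CHAIN_OFFSETS[i]
            alpha = _draw_distance(rng, spec.per_protomer(spec.alpha_c_target, i), n, floor=5.0)
            dfg = _draw_dihedral(rng, spec.per_protomer(spec.dfg_target, i), n)
            ke = _draw_ke(rng, spec, i, n)
            # αC: slide the helix-centre Cα triplet along x
            for resnum in (500, 501, 502):
                j = index[(cid, resnum, "CA")]
                coords[:, j, 0] = offset[0] + alpha
            # K–E: slide NZ along +y from OE1
            oe1 = template[index[(cid, 501, "OE1")]]
            j = index[(cid, 483, "NZ")]
            coords[:, j, :] = oe1 + np.outer(ke, np.array([0.0, 1.0, 0.0]))
            jca = index[(cid, 483, "CA")]
            coords[:, jca, :] = coords[:, j, :] + np.array([0.0, 2.0, 2.0])
            # DFG: rotate the Phe595 Cα
            p2 = template[index[(cid, 593, "CA")]]
            p3 = template[index[(cid, 594, "CA")]]
            coords[:, index[(cid, 595, "CA")], :] = _dihedral_p4(p2, p3, dfg)
            # ligand amide N1: Bernoulli h-bond occupancy if requested
            key = (cid, _LIGAND_RESNUM, "N1")
            if key in index:
                if spec.ligand_glu501_hbond_prob is not None:
                    on = rng.random(n) < spec.ligand_glu501_hbond_prob
                    d = np.where(
                        on,
                        np.clip(rng.normal(2.9, 0.15, size=n), 2.6, 3.45),
                        5.5 + np.abs(rng.normal(0.0, 0.8, size=n)),
                    )
                else:
                    hbond = spec.per_protomer(spec.ligand_glu501_hbond, i)
                    d = np.full(n, _HB_ON if hbond else _HB_OFF)
                coords[:, index[key], :] = oe1 + np.outer(d, np.array([0.0, 0.0, 1.0]))
        trajectories.append(Trajectory(base, coords, replica_id=r))
    return trajectories


def _static_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Point-target version of *spec* used to build the trajectory topology."""

    def point(value, default):
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        if isinstance(value, tuple):
            return float(value[0])
        if isinstance(value, list):
            if value and isinstance(value[0], (tuple, list)) and len(value[0]) == 3:
                return float(value[0][0])
            return [point(v, default) for v in value]
        return default

    import dataclasses as _dc

    return _dc.replace(
        spec,
        alpha_c_target=point(spec.alpha_c_target, 20.0),
        dfg_target=point(spec.dfg_target, 210.0),
        ke_target=point(spec.ke_target, 3.5) if spec.ke_occupancy is None else 3.5,
        ke_occupancy=None,
        ligand_glu501_hbond_prob=None,
    )


# ---------------------------------------------------------------------------
# contact scenarios

# four planted residue blocks: N- and C-lobe of each protomer
_BLOCKS = {
    "N_A": ("A", (10, 13, 16), np.array([0.0, 0.0, 0.0])),
    "C_A": ("A", (110, 113, 116), np.array([0.0, 60.0, 0.0])),
    "N_B": ("B", (10, 13, 16), np.array([60.0, 0.0, 0.0])),
    "C_B": ("B", (110, 113, 116), np.array([60.0, 60.0, 0.0])),
}
_BLOCK_PAIRS = (
    ("N_A", "C_A"),
    ("N_A", "N_B"),
    ("N_A", "C_B"),
    ("C_A", "N_B"),
    ("C_A", "C_B"),
    ("N_B", "C_B"),
)


def _scenario_topology() -> tuple[KinaseStructure, dict]:
    """Four 3-residue blocks plus one toggling bridge atom per block pair."""
    chains: dict[str, list[AtomRecord]] = {"A": [], "B": []}
    block_residues: dict[str, list[tuple[str, int]]] = {}
    for name, (chain, resnums, center) in _BLOCKS.items():
        block_residues[name] = []
        # equilateral triangle of side 4.0 Å: all intra-block pairs in contact
        verts = [
            center + np.array([0.0, 0.0, 0.0]),
            center + np.array([4.0, 0.0, 0.0]),
            center + np.array([2.0, 3.4641016, 0.0]),
        ]
        for resnum, v in zip(resnums, verts):
            chains[chain].append(AtomRecord("CA", "C", "GLY", resnum, chain, "", v))
            block_residues[name].append((chain, resnum))
    # bridge atoms: CB on a dedicated residue of each block in the pair,
    # meeting in a region unique to that pair when the contact is "on"
    bridge_info = {}
    used: dict[str, int] = {b: 0 for b in _BLOCKS}
    for p, (bi, bj) in enumerate(_BLOCK_PAIRS):
        region = np.array([200.0 + 30.0 * p, -60.0, 0.0])
        ri = block_residues[bi][used[bi]]
        rj = block_residues[bj][used[bj]]
        used[bi] += 1
        used[bj] += 1
        chains[ri[0]].append(AtomRecord("CB", "C", "GLY", ri[1], ri[0], "", region))
        chains[rj[0]].append(AtomRecord("CB", "C", "GLY", rj[1], rj[0], "", region + np.array([3.0, 0.0, 0.0])))
        bridge_info[(bi, bj)] = {"pair": (ri, rj), "region": region}
    topo = KinaseStructure(
        [Protomer("A", chains["A"]), Protomer("B", chains["B"])],
        [],
        source_id="synthetic-contact-scenario",
    )
    return topo, {"blocks": block_residues, "bridges": bridge_info}


def make_contact_scenario(
    apo_probabilities: dict[tuple[str, str], float],
    holo_probabilities: dict[tuple[str, str], float],
    n_frames: int = 2_000,
    n_replicas: int = 3,
    seed: int = 0,
) -> tuple[list[Trajectory], list[Trajectory], dict]:
    """Apo-like and holo-like trajectories with planted block-pair contacts.

    Probabilities are given per unordered block pair, keyed by the block
    names ``N_A, C_A, N_B, C_B``; unlisted pairs have no contact.  Returns
    ``(apo_replicas, holo_replicas, layout)`` where the layout records the
    planted blocks and bridge residues.
    """
    for probs in (apo_probabilities, holo_probabilities):
        for pair, p in probs.items():
            if tuple(sorted(pair)) not in {tuple(sorted(bp)) for bp in _BLOCK_PAIRS}:
                raise GenerationError(f"unknown block pair {pair}")
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"contact probability {p} outside [0, 1]")
    topo, layout = _scenario_topology()
    index = topo.atom_index()
    template = topo.coordinates()
    root = np.random.SeedSequence(seed).spawn(2)

    def build(probs, seq) -> list[Trajectory]:
        normalised = {tuple(sorted(k)): v for k, v in probs.items()}
        replicas = []
        for r, child in enumerate(seq.spawn(n_replicas)):
            rng = np.random.default_rng(child)
            coords = np.tile(template, (n_frames, 1, 1))
            for pair_key, info in layout["bridges"].items():
                p = normalised.get(tuple(sorted(pair_key)), 0.0)
                (ci, ni), _rj = info["pair"]
                j = index[(ci, ni, "CB")]
                on = rng.random(n_frames) < p
                # off frames park the bridge atom 40 Å away from its partner
                coords[~on, j, 1] -= 40.0
            replicas.append(Trajectory(topo, coords, replica_id=r))
        return replicas

    apo = build(apo_probabilities, root[0])
    holo = build(holo_probabilities, root[1])
    return apo, holo, layout
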