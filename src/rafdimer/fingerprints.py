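"""Protein–ligand interaction fingerprints and back-pocket occupancy.

A fingerprint records, per protein residue, which interaction categories the
ligand makes: hydrophobic, h-bond donor (ligand donates) and h-bond acceptor
(ligand accepts).  Criteria are heavy-atom distances: 3.5 Å donor–acceptor
for hydrogen bonds, 4.0 Å carbon–carbon when both atoms are aromatic and
4.5 Å otherwise for hydrophobic contacts.  Aromatic face-to-face stacking is
not distinguished from hydrophobic contact.

Three hydrogen bonds that discriminate inhibitor classes are flagged
explicitly: the ligand-to-Glu501-carboxylate h-bond (the dimer-compatibility
hallmark), the h-bond with the Asp594 backbone (whose direction differs
between dimer-compatible amides and monomer-selective sulfonamides) and the
ligand-to-His574-backbone-carbonyl h-bond.

Back pockets BP-I…BP-IV behind the ATP site follow the KLIFS nomenclature;
their residue membership is configuration, not code, and the shipped default
maps them onto BRAF numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord, LigandRecord, Protomer

__all__ = [
    "HBOND_CUTOFF",
    "HYDROPHOBIC_AROMATIC_CUTOFF",
    "HYDROPHOBIC_CUTOFF",
    "HBondContact",
    "InteractionFingerprint",
    "BackPocketMap",
    "DEFAULT_BACK_POCKETS",
    "LigandTypingError",
    "hbond_contacts",
    "hydrophobic_contacts",
    "build_fingerprint",
    "pocket_occupancy",
]

HBOND_CUTOFF = 3.5  # Å, heavy-atom donor–acceptor
HYDROPHOBIC_AROMATIC_CUTOFF = 4.0  # Å, C–C when both carbons aromatic
HYDROPHOBIC_CUTOFF = 4.5  # Å, C–C otherwise

# Protein h-bond typing from standard amino-acid chemistry.  Backbone N
# donates (except proline), backbone O/OXT accepts.  Histidine ring
# nitrogens are typed both ways because the protonation state is unknown
# in a crystal structure.
SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "TRP": frozenset({"NE1"}),
}
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
}
AROMATIC_CARBONS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
}


class LigandTypingError(ValueError):
    """Ligand lacks donor/acceptor annotation and the heuristic is disabled."""


def _protein_is_donor(atom: AtomRecord) -> bool:
    if atom.atom_name == "N" and atom.residue_name != "PRO":
        return True
    return atom.atom_name in SIDECHAIN_DONORS.get(atom.residue_name, frozenset())


def _protein_is_acceptor(atom: AtomRecord) -> bool:
    if atom.atom_name in ("O", "OXT"):
        return True
    return atom.atom_name in SIDECHAIN_ACCEPTORS.get(atom.residue_name, frozenset())


def _protein_is_aromatic_carbon(atom: AtomRecord) -> bool:
    return atom.element == "C" and atom.atom_name in AROMATIC_CARBONS.get(
        atom.residue_name, frozenset()
    )


@dataclass(frozen=True)
class HBondContact:
    protein_atom: AtomRecord
    ligand_atom: AtomRecord
    direction: str  # "ligand_donates" | "ligand_accepts"
    distance: float


@dataclass
class InteractionFingerprint:
    """Per-residue ligand interaction categories plus the hallmark flags."""

    entries: dict[tuple[str, int], set[str]] = field(default_factory=dict)
    ligand_id: str = ""
    glu501_hbond: bool = False
    asp594_backbone_hbond: str = "none"  # ligand_accepts | ligand_donates | none
    his574_backbone_hbond: bool = False


def _check_typing(ligand: LigandRecord, allow_heuristic: bool) -> None:
    if not ligand.annotated and not allow_heuristic:
        raise LigandTypingError(
            f"ligand {ligand.residue_name} has no donor/acceptor annotation; "
            "register one with register_ligand_annotation or enable the heuristic"
        )


def hbond_contacts(
    protomer: Protomer,
    ligand: LigandRecord,
    cutoff: float = HBOND_CUTOFF,
    allow_heuristic: bool = True,
) -> list[HBondContact]:
    """All donor–acceptor pairs within *cutoff* between protomer and ligand.

    The direction records which side donates.  Both directions are scanned:
    ligand donors against protein acceptors and protein donors against
    ligand acceptors.
    """
    _check_typing(ligand, allow_heuristic)
    lig_atoms = ligand.heavy_atoms()
    contacts: list[HBondContact] = []
    for lig_atom in lig_atoms:
        is_don = lig_atom.atom_name in ligand.donor_atoms
        is_acc = lig_atom.atom_name in ligand.acceptor_atoms
        if not (is_don or is_acc):
            continue
        for prot_atom in protomer.atoms:
            d = float(np.linalg.norm(prot_atom.coords - lig_atom.coords))
            if d > cutoff:
                continue
            if is_don and _protein_is_acceptor(prot_atom):
                contacts.append(HBondContact(prot_atom, lig_atom, "ligand_donates", d))
            if is_acc and _protein_is_donor(prot_atom):
                contacts.append(HBondContact(prot_atom, lig_atom, "ligand_accepts", d))
    return contacts


def hydrophobic_contacts(
    protomer: Protomer,
    ligand: LigandRecord,
    aromatic_cutoff: float = HYDROPHOBIC_AROMATIC_CUTOFF,
    nonaromatic_cutoff: float = HYDROPHOBIC_CUTOFF,
) -> set[tuple[str, int]]:
    """Residues with a carbon–carbon contact to the ligand.

    The 4.0 Å cutoff applies when both carbons are aromatic; the 4.5 Å
    cutoff otherwise.
    """
    lig_carbons = [a for a in ligand.heavy_atoms() if a.element == "C"]
    residues: set[tuple[str, int]] = set()
    for prot_atom in protomer.atoms:
        if prot_atom.element != "C":
            continue
        prot_arom = _protein_is_aromatic_carbon(prot_atom)
        key = (prot_atom.chain_id, prot_atom.residue_number)
        if key in residues:
            continue
        for lig_atom in lig_carbons:
            both_aromatic = prot_arom and lig_atom.atom_name in ligand.aromatic_atoms
            cutoff = aromatic_cutoff if both_aromatic else nonaromatic_cutoff
            if np.linalg.norm(prot_atom.coords - lig_atom.coords) <= cutoff:
                residues.add(key)
                break
    return residues


def build_fingerprint(
    protomer: Protomer,
    ligand: LigandRecord,
    hbond_cutoff: float = HBOND_CUTOFF,
    aromatic_cutoff: float = HYDROPHOBIC_AROMATIC_CUTOFF,
    nonaromatic_cutoff: float = HYDROPHOBIC_CUTOFF,
    allow_heuristic: bool = True,
) -> InteractionFingerprint:
    """Merge h-bond and hydrophobic contacts into one per-residue fingerprint."""
    fp = InteractionFingerprint(ligand_id=ligand.residue_name)
    hbonds = hbond_contacts(protomer, ligand, hbond_cutoff, allow_heuristic)
    for hb in hbonds:
        key = (hb.protein_atom.chain_id, hb.protein_atom.residue_number)
        category = "h_donor" if hb.direction == "ligand_donates" else "h_acceptor"
        fp.entries.setdefault(key, set()).add(category)
        p = hb.protein_atom
        if (
            hb.direction == "ligand_donates"
            and p.residue_number == 501
            and p.atom_name in ("OE1", "OE2")
        ):
            fp.glu501_hbond = True
        if p.residue_number == 594 and p.atom_name in ("N", "O"):
            # prefer the ligand-accepts reading (amide carbonyl accepting from
            # the Asp594 backbone amide) when both directions are in range
            if hb.direction == "ligand_accepts" and p.atom_name == "N":
                fp.asp594_backbone_hbond = "ligand_accepts"
            elif hb.direction == "ligand_donates" and fp.asp594_backbone_hbond == "none":
                fp.asp594_backbone_hbond = "ligand_donates"
        if hb.direction == "ligand_donates" and p.residue_number == 574 and p.atom_name == "O":
            fp.his574_backbone_hbond = True
    for key in hydrophobic_contacts(protomer, ligand, aromatic_cutoff, nonaromatic_cutoff):
        fp.entries.setdefault(key, set()).add("hydrophobic")
    return fp


@dataclass
class BackPocketMap:
    """Residue membership of the back pockets, in BRAF numbering."""

    pockets: dict[str, frozenset[int]]
    contact_cutoff: float = 4.5

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")


# Default BRAF back-pocket membership.  BP-I sits around the catalytic
# Lys483 and the gatekeeper Thr529; BP-II is the αC/DFG back cavity
# (Glu501, Leu505, the His574 sidechain, Asp594); BP-III is the subpocket
# vacated by Phe595 in DFG-out; BP-IV extends past the DFG toward the HRD
# backbone.  Membership is configuration — supply your own map to change it.
DEFAULT_BACK_POCKETS = BackPocketMap(
    pockets={
        "BP-I": frozenset({463, 471, 481, 483, 529, 530}),
        "BP-II": frozenset({500, 501, 504, 505, 513, 566, 574, 594}),
        "BP-III": frozenset({564, 567, 575, 576, 594, 595}),
        "BP-IV": frozenset({574, 575, 576, 577, 595}),
    }
)


def pocket_occupancy(
    ligand: LigandRecord,
    pocket_map: BackPocketMap = DEFAULT_BACK_POCKETS,
    protomer: Protomer | None = None,
) -> set[str]:
    """Back pockets the ligand occupies.

    A pocket is occupied when any ligand heavy atom lies within the map's
    contact cutoff of any heavy atom of the pocket's residues.
    """
    if protomer is None:
        raise ValueError("a protomer is required to locate the pocket residues")
    lig = np.array([a.coords for a in ligand.heavy_atoms()])
    occupied: set[str] = set()
    for label, resnums in pocket_map.pockets.items():
        pocket_atoms = [a.coords for a in protomer.atoms if a.residue_number in resnums]
        if not pocket_atoms:
            continue
        prot = np.array(pocket_atoms)
        dists = np.linalg.norm(lig[:, None, :] - prot[None, :, :], axis=-1)
        if np.min(dists) <= pocket_map.contact_cutoff:
            occupied.add(label)
    return occupied
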