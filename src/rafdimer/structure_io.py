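"""Reading and writing kinase structures.

Static structures (PDB or mmCIF) are parsed into a :class:`KinaseStructure`:
protein chains become protomers, non-water/non-ion HETATM residues become
ligands, and coordinates are addressable by ``(chain, residue number, atom
name)`` in the author numbering of the source file.  Alternate locations are
collapsed to a single conformer (highest occupancy, ties broken by alt-loc
identifier) so that all downstream geometry is single-valued.  Hydrogens are
dropped on input: every distance criterion used in this package is defined on
heavy atoms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Protomer",
    "LigandRecord",
    "KinaseStructure",
    "LigandAnnotation",
    "LIGAND_ANNOTATIONS",
    "register_ligand_annotation",
    "read_structure",
    "write_pdb",
    "StructureError",
    "StructureFormatError",
    "EmptyStructureError",
    "AtomLookupError",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(Exception):
    """Base class for structure-handling errors."""


class StructureFormatError(StructureError):
    """The input file could not be parsed under the named standard."""


class EmptyStructureError(StructureError):
    """No protein chain was found in the input."""


class AtomLookupError(StructureError, KeyError):
    """A requested (chain, residue, atom) triple does not exist."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with author numbering and resolved coordinates."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    alt_loc: str
    coords: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Protomer:
    """One kinase-domain subunit: a protein chain and its atoms."""

    chain_id: str
    atoms: list[AtomRecord]
    _index: dict[tuple[int, str], AtomRecord] = field(default=None, repr=False, compare=False)

    def _build_index(self):
        self._index = {(a.residue_number, a.atom_name): a for a in self.atoms}

    def atom(self, resnum: int, atom_name: str) -> AtomRecord:
        if self._index is None or len(self._index) != len(self.atoms):
            self._build_index()
        try:
            return self._index[(resnum, atom_name)]
        except KeyError:
            raise AtomLookupError(self._missing_message(resnum, atom_name)) from None

    def coords(self, resnum: int, atom_name: str) -> np.ndarray:
        return self.atom(resnum, atom_name).coords

    def has_atom(self, resnum: int, atom_name: str) -> bool:
        if self._index is None or len(self._index) != len(self.atoms):
            self._build_index()
        return (resnum, atom_name) in self._index

    def residue_atoms(self, resnum: int) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue_number == resnum]

    def residue_numbers(self) -> list[int]:
        seen = dict.fromkeys(a.residue_number for a in self.atoms)
        return list(seen)

    def _missing_message(self, resnum: int, atom_name: str) -> str:
        present = sorted({a.residue_number for a in self.atoms})
        if not present:
            return f"chain {self.chain_id} has no atoms"
        nearest = min(present, key=lambda r: abs(r - resnum))
        return (
            f"atom {atom_name} of residue {resnum} not found in chain "
            f"{self.chain_id}; nearest residue present is {nearest} "
            f"(possible unresolved region)"
        )


@dataclass
class LigandAnnotation:
    """Donor/acceptor/aromatic atom typing for one het-code."""

    donors: frozenset[str]
    acceptors: frozenset[str]
    aromatic: frozenset[str] = frozenset()


# Curated typing for the inhibitors this package ships synthetic models of:
# the dimer-selective PHI1 (ponatinib hybrid inhibitor 1), the equipotent
# LY3009120 and the monomer-selective vemurafenib.  Atom names follow the
# synthetic ligand templates in :mod:`rafdimer.synthetic_data`; annotations
# for deposited het-codes can be registered at run time.
LIGAND_ANNOTATIONS: dict[str, LigandAnnotation] = {
    # amide linker N1 donates to Glu501; carbonyl O1 accepts from the Asp594
    # backbone amide; amino N2 next to the morpholine donates to His574 C=O.
    "PHI": LigandAnnotation(
        donors=frozenset({"N1", "N2"}),
        acceptors=frozenset({"O1"}),
        aromatic=frozenset({"C6", "C7", "C8"}),
    ),
    # amide linker donates to Glu501; carbonyl accepts from Asp594.
    "LY3": LigandAnnotation(
        donors=frozenset({"N1"}),
        acceptors=frozenset({"O1"}),
        aromatic=frozenset({"C6", "C7", "C8"}),
    ),
    # sulfonamide N3 donates to the Asp594 backbone; no Glu501 donor reaches
    # the carboxylate.
    "VEM": LigandAnnotation(
        donors=frozenset({"N3"}),
        acceptors=frozenset({"O1"}),
        aromatic=frozenset({"C6", "C7", "C8"}),
    ),
}


def register_ligand_annotation(het_code: str, annotation: LigandAnnotation) -> None:
    """Register (or replace) donor/acceptor/aromatic typing for a het-code."""
    LIGAND_ANNOTATIONS[het_code] = annotation


def _heuristic_annotation(atoms: list[AtomRecord]) -> LigandAnnotation:
    # Crystal structures carry no hydrogens, so donor assignment cannot use
    # H counts: nitrogens are typed as donor+acceptor, oxygens as acceptors.
    donors = {a.atom_name for a in atoms if a.element == "N"}
    acceptors = {a.atom_name for a in atoms if a.element in ("N", "O")}
    return LigandAnnotation(frozenset(donors), frozenset(acceptors), frozenset())


@dataclass
class LigandRecord:
    """A bound small molecule with its h-bond/aromatic atom typing."""

    residue_name: str
    chain_id: str
    atoms: list[AtomRecord]
    donor_atoms: frozenset[str] = frozenset()
    acceptor_atoms: frozenset[str] = frozenset()
    aromatic_atoms: frozenset[str] = frozenset()
    residue_number: int = 0
    annotated: bool = False

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"ligand {self.residue_name}: empty atom list")
        names = {a.atom_name for a in self.atoms}
        for label, subset in (
            ("donor", self.donor_atoms),
            ("acceptor", self.acceptor_atoms),
            ("aromatic", self.aromatic_atoms),
        ):
            extra = set(subset) - names
            if extra:
                raise ValueError(f"ligand {self.residue_name}: {label} set names absent atoms {sorted(extra)}")

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class KinaseStructure:
    """Protomers plus ligands parsed from one structure file."""

    protomers: list[Protomer]
    ligands: list[LigandRecord]
    source_id: str = ""
    resolution_note: str = ""

    def __post_init__(self):
        if not self.protomers:
            raise EmptyStructureError(f"{self.source_id or 'structure'}: no protein chain")
        seen: set[int] = set()
        for p in self.protomers:
            ids = {id(a) for a in p.atoms}
            if seen & ids:
                raise ValueError("an atom belongs to two protomers")
            seen |= ids

    @property
    def chain_ids(self) -> list[str]:
        return [p.chain_id for p in self.protomers]

    def protomer(self, chain_id: str) -> Protomer:
        for p in self.protomers:
            if p.chain_id == chain_id:
                return p
        raise AtomLookupError(f"no protomer with chain id {chain_id!r}; have {self.chain_ids}")

    def get_atom(self, chain: str, resnum: int, atom: str) -> np.ndarray:
        """Resolved coordinate of one protein atom (Å)."""
        return self.protomer(chain).coords(resnum, atom)

    def ligands_on_chain(self, chain_id: str) -> list[LigandRecord]:
        return [l for l in self.ligands if l.chain_id == chain_id]

    def ligand(self, het_code: str, chain_id: str | None = None) -> LigandRecord:
        hits = [
            l
            for l in self.ligands
            if l.residue_name == het_code and (chain_id is None or l.chain_id == chain_id)
        ]
        if not hits:
            raise AtomLookupError(
                f"no ligand {het_code!r}"
                + (f" on chain {chain_id}" if chain_id else "")
                + f"; ligands present: {[(l.residue_name, l.chain_id) for l in self.ligands]}"
            )
        return hits[0]

    # --- flat atom ordering used by the trajectory machinery -------------
    def flat_atoms(self) -> list[AtomRecord]:
        out: list[AtomRecord] = []
        for p in self.protomers:
            out.extend(p.atoms)
        for l in self.ligands:
            out.extend(l.atoms)
        return out

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        return {
            (a.chain_id, a.residue_number, a.atom_name): i
            for i, a in enumerate(self.flat_atoms())
        }

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.flat_atoms()], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "KinaseStructure":
        """A copy of this structure with all atom coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        flat = self.flat_atoms()
        if coords.shape != (len(flat), 3):
            raise ValueError(f"expected coordinates of shape {(len(flat), 3)}, got {coords.shape}")
        it = iter(coords)
        protomers = [
            Protomer(p.chain_id, [dataclasses.replace(a, coords=next(it)) for a in p.atoms])
            for p in self.protomers
        ]
        ligands = [
            dataclasses.replace(l, atoms=[dataclasses.replace(a, coords=next(it)) for a in l.atoms])
            for l in self.ligands
        ]
        return KinaseStructure(protomers, ligands, self.source_id, self.resolution_note)


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy conformer per atom; ties by alt-loc order."""
    best: dict[tuple[str, int, str], AtomRecord] = {}
    for rec in records:
        key = (rec.chain_id, rec.residue_number, rec.atom_name)
        prev = best.get(key)
        if prev is None or (rec.occupancy, _neg_altloc(rec.alt_loc)) > (
            prev.occupancy,
            _neg_altloc(prev.alt_loc),
        ):
            best[key] = rec
    # preserve file order
    kept = set(map(id, best.values()))
    return [r for r in records if id(r) in kept]


def _neg_altloc(alt: str):
    # higher sort rank for earlier alt-loc letters ('' > 'A' > 'B' ...)
    return -ord(alt) if alt else 0


def read_structure(path: str | Path, fmt: str | None = None) -> KinaseStructure:
    """Parse a PDB or mmCIF file into a :class:`KinaseStructure`.

    Parameters
    ----------
    path:
        Structure file.  The format is detected from the contents/extension
        unless *fmt* (``"pdb"`` or ``"mmcif"``) is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise StructureFormatError(f"{path.name}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: file contains no model")
    return structure_from_gemmi(st, source_id=st.name or path.stem)


def structure_from_gemmi(st: gemmi.Structure, source_id: str = "", model_index: int = 0) -> KinaseStructure:
    model = st[model_index]
    protein: dict[str, list[AtomRecord]] = {}
    het: dict[tuple[str, str, int], list[AtomRecord]] = {}
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES or res.is_water():
                continue
            recs = []
            for atom in res:
                if atom.element.name == "H" or atom.element.name == "D":
                    continue
                alt = atom.altloc if atom.altloc not in ("\x00", "") else ""
                recs.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=atom.element.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        alt_loc=alt,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        is_hetero=(res.het_flag == "H"),
                    )
                )
            if not recs:
                continue
            if res.het_flag == "H":
                het[(chain.name, res.name, res.seqid.num)] = recs
            else:
                protein.setdefault(chain.name, []).extend(recs)

    protomers = []
    for chain_id, records in protein.items():
        protomers.append(Protomer(chain_id, _resolve_altlocs(records)))
    if not protomers:
        raise EmptyStructureError(f"{source_id or 'structure'}: no protein chain found")

    ligands = []
    for (chain_id, resname, resnum), records in het.items():
        records = _resolve_altlocs(records)
        if len(records) < 2:  # monoatomic het residues are ions, never ligands
            continue
        ann = LIGAND_ANNOTATIONS.get(resname)
        annotated = ann is not None
        if ann is None:
            ann = _heuristic_annotation(records)
        names = {a.atom_name for a in records}
        ligands.append(
            LigandRecord(
                residue_name=resname,
                chain_id=chain_id,
                atoms=records,
                donor_atoms=ann.donors & names,
                acceptor_atoms=ann.acceptors & names,
                aromatic_atoms=ann.aromatic & names,
                residue_number=resnum,
                annotated=annotated,
            )
        )
    return KinaseStructure(protomers, ligands, source_id=source_id)


# ---------------------------------------------------------------------------
# writing


def to_gemmi(structure: KinaseStructure, model_name: str = "1") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.source_id or "rafdimer"
    model = gemmi.Model(model_name)
    by_chain: dict[str, gemmi.Chain] = {}

    def chain_for(cid: str) -> gemmi.Chain:
        if cid not in by_chain:
            by_chain[cid] = gemmi.Chain(cid)
        return by_chain[cid]

    def add_residue(cid: str, resname: str, resnum: int, atoms: list[AtomRecord], het: bool):
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resnum, " ")
        res.het_flag = "H" if het else "A"
        for rec in atoms:
            a = gemmi.Atom()
            a.name = rec.atom_name
            a.element = gemmi.Element(rec.element)
            a.pos = gemmi.Position(*rec.coords)
            a.occ = rec.occupancy
            a.b_iso = 0.0
            if rec.alt_loc:
                a.altloc = rec.alt_loc
            res.add_atom(a)
        chain_for(cid).add_residue(res)

    for p in structure.protomers:
        groups: dict[tuple[int, str], list[AtomRecord]] = {}
        for a in p.atoms:
            groups.setdefault((a.residue_number, a.residue_name), []).append(a)
        for (resnum, resname), atoms in groups.items():
            add_residue(p.chain_id, resname, resnum, atoms, het=False)
    for l in structure.ligands:
        add_residue(l.chain_id, l.residue_name, l.residue_number, l.atoms, het=True)

    for ch in by_chain.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: KinaseStructure, path: str | Path) -> None:
    """Write the structure as a single-model PDB file."""
    to_gemmi(structure).write_pdb(str(path))
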