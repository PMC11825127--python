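"""Per-protomer conformational descriptors of the BRAF kinase domain.

Three descriptors characterise the regulatory spine of each protomer:

* **αC position** — distance between the Cα of Ile582 (a stable β7 reference
  point) and the unweighted centroid of the Cα atoms of Asn500, Glu501 and
  Val502 at the centre of the αC helix.  Below 19.6 Å the helix is "in",
  at or above it is "out".
* **DFG pseudo-dihedral** — torsion of the Cα atoms of Ile592, Gly593,
  Asp594 and Phe595, reported on [0, 360)°.  At or above 140° the DFG motif
  is "out", below it is "in".
* **Lys483–Glu501 salt bridge** — the catalytic-lysine/αC-glutamate pairing,
  measured both as the Lys483 NZ to nearest Glu501 carboxylate-oxygen
  distance (4.0 Å criterion) and as the minimum heavy-atom distance between
  the two sidechains (4.5 Å criterion).

All descriptors are pure functions of heavy-atom coordinates and are
invariant under rigid rotation and translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomLookupError, Protomer

__all__ = [
    "ALPHA_C_BOUNDARY",
    "DFG_BOUNDARY",
    "SALT_BRIDGE_NO_CUTOFF",
    "SALT_BRIDGE_SIDECHAIN_CUTOFF",
    "ProtomerGeometry",
    "DescriptorUnavailableError",
    "UndefinedDihedralError",
    "alpha_c_distance",
    "classify_alpha_c",
    "pseudo_dihedral",
    "dfg_pseudo_dihedral",
    "classify_dfg",
    "ke_distances",
    "compute_descriptors",
]

ALPHA_C_BOUNDARY = 19.6  # Å; αC-in strictly below, αC-out at or above
DFG_BOUNDARY = 140.0  # degrees; DFG-out at or above
SALT_BRIDGE_NO_CUTOFF = 4.0  # Å, Lys483 NZ to nearest Glu501 OE1/OE2
SALT_BRIDGE_SIDECHAIN_CUTOFF = 4.5  # Å, minimum sidechain heavy-atom distance

# αC-helix centre residues and the β7 reference
_ALPHA_C_CENTER = (500, 501, 502)
_ALPHA_C_REF = 582
_DFG_QUAD = (592, 593, 594, 595)

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class DescriptorUnavailableError(AtomLookupError):
    """A descriptor cannot be computed because required atoms are missing."""


class UndefinedDihedralError(ValueError):
    """Torsion is undefined: three consecutive points are collinear."""


@dataclass
class ProtomerGeometry:
    """The descriptor record for one protomer.

    Fields whose atoms are missing (unresolved loops) are ``None`` and the
    reason is recorded in :attr:`unavailable`.
    """

    chain_id: str = ""
    alpha_c_distance: float | None = None
    alpha_c_state: str | None = None
    ke_no_distance: float | None = None
    ke_min_sidechain_distance: float | None = None
    salt_bridge_4A: bool | None = None
    salt_bridge_45A: bool | None = None
    dfg_pseudo_dihedral: float | None = None
    dfg_state: str | None = None
    unavailable: dict[str, str] = field(default_factory=dict)


def _require(protomer: Protomer, resnum: int, atom: str) -> np.ndarray:
    try:
        return protomer.coords(resnum, atom)
    except AtomLookupError as exc:
        raise DescriptorUnavailableError(
            f"residue {resnum} atom {atom}: {exc.args[0] if exc.args else exc}"
        ) from None


def alpha_c_distance(protomer: Protomer) -> float:
    """αC position (Å): Ile582 Cα to the Cα centroid of Asn500–Val502.

    The centre of mass is the unweighted centroid — the four atoms are all
    Cα carbons of identical mass.
    """
    ref = _require(protomer, _ALPHA_C_REF, "CA")
    center = np.mean([_require(protomer, r, "CA") for r in _ALPHA_C_CENTER], axis=0)
    return float(np.linalg.norm(ref - center))


def classify_alpha_c(distance: float) -> str:
    """``"in"`` strictly below the 19.6 Å boundary, ``"out"`` otherwise."""
    if distance < 0:
        raise ValueError(f"αC distance must be non-negative, got {distance}")
    return "in" if distance < ALPHA_C_BOUNDARY else "out"


def pseudo_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, in degrees on [0, 360).

    The sign follows the right-hand (IUPAC) convention before wrapping:
    angles in (−180, 0) map to (180, 360).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedDihedralError("three consecutive points are (nearly) collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(-np.dot(m1, n2), np.dot(n1, n2)))
    return float(angle % 360.0)


def dfg_pseudo_dihedral(protomer: Protomer) -> float:
    """DFG pseudo-dihedral: Cα torsion of Ile592–Gly593–Asp594–Phe595."""
    pts = [_require(protomer, r, "CA") for r in _DFG_QUAD]
    return pseudo_dihedral(*pts)


def classify_dfg(angle: float) -> str:
    """``"out"`` at or above the 140° boundary, ``"in"`` below."""
    if not 0.0 <= angle < 360.0:
        raise ValueError(f"DFG pseudo-dihedral must lie in [0, 360), got {angle}")
    return "out" if angle >= DFG_BOUNDARY else "in"


def _sidechain_atoms(protomer: Protomer, resnum: int, include_cb: bool = True):
    atoms = [
        a
        for a in protomer.residue_atoms(resnum)
        if a.atom_name not in _BACKBONE_NAMES and a.element != "H"
    ]
    if not include_cb:
        atoms = [a for a in atoms if a.atom_name != "CB"]
    return atoms


def ke_distances(protomer: Protomer, include_cb: bool = True) -> tuple[float, float]:
    """Lys483–Glu501 distances (Å).

    Returns ``(ke_no, ke_min_sidechain)``: the Lys483 NZ to nearest Glu501
    carboxylate oxygen distance, and the minimum over all sidechain
    heavy-atom pairs.  The sidechain is every heavy atom beyond Cα (Cβ
    included by default; set ``include_cb=False`` to exclude it).
    """
    nz = _require(protomer, 483, "NZ")
    carboxylate = [protomer.coords(501, n) for n in ("OE1", "OE2") if protomer.has_atom(501, n)]
    if not carboxylate:
        raise DescriptorUnavailableError("Glu501 carboxylate oxygens (OE1/OE2) are missing")
    ke_no = min(float(np.linalg.norm(nz - o)) for o in carboxylate)

    lys_side = _sidechain_atoms(protomer, 483, include_cb)
    glu_side = _sidechain_atoms(protomer, 501, include_cb)
    if not lys_side or not glu_side:
        raise DescriptorUnavailableError("Lys483 or Glu501 sidechain heavy atoms are missing")
    a = np.array([x.coords for x in lys_side])
    b = np.array([x.coords for x in glu_side])
    ke_min = float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)))
    return ke_no, ke_min


def compute_descriptors(protomer: Protomer, include_cb: bool = True) -> ProtomerGeometry:
    """All descriptors for one protomer; missing atoms degrade per-descriptor.

    A residue unresolved in the crystal (e.g. an activation loop) makes only
    the descriptors that need it unavailable; the rest are still computed.
    """
    geom = ProtomerGeometry(chain_id=protomer.chain_id)
    try:
        geom.alpha_c_distance = alpha_c_distance(protomer)
        geom.alpha_c_state = classify_alpha_c(geom.alpha_c_distance)
    except DescriptorUnavailableError as exc:
        geom.unavailable["alpha_c"] = str(exc)
    try:
        geom.ke_no_distance, geom.ke_min_sidechain_distance = ke_distances(protomer, include_cb)
        geom.salt_bridge_4A = geom.ke_no_distance <= SALT_BRIDGE_NO_CUTOFF
        geom.salt_bridge_45A = geom.ke_min_sidechain_distance <= SALT_BRIDGE_SIDECHAIN_CUTOFF
    except DescriptorUnavailableError as exc:
        geom.unavailable["ke"] = str(exc)
    try:
        geom.dfg_pseudo_dihedral = dfg_pseudo_dihedral(protomer)
        geom.dfg_state = classify_dfg(geom.dfg_pseudo_dihedral)
    except (DescriptorUnavailableError, UndefinedDihedralError) as exc:
        geom.unavailable["dfg"] = str(exc)
    return geom
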