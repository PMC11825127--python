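"""Empirical co-crystal-based assessment of inhibitor dimer selectivity.

The decision rule operates on a dimeric co-crystal structure:

1. no ligand h-bond to the Glu501 carboxylate → **monomer selective**;
2. Glu501 h-bond present, but the αC position and/or the Lys483–Glu501
   (K–E) distance differ between the two protomers by 0.3 Å or more →
   **equipotent**;
3. Glu501 h-bond present and (nearly) identical αC position and K–E
   distance in both protomers → **likely dimer selective** — the stable
   h-bond restrains the αC helix symmetrically.

Inter-protomer deviations are rounded to 0.1 Å before comparison with the
threshold, matching the precision at which crystal-structure geometry is
meaningfully reported; raw values are retained in the returned record.
The rule is a screen, not a substitute for potency measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

from .descriptors import alpha_c_distance, ke_distances
from .fingerprints import build_fingerprint
from .structure_io import KinaseStructure

__all__ = [
    "DEVIATION_THRESHOLD",
    "SelectivityCall",
    "ProtomerArityError",
    "protomer_deviations",
    "classify_selectivity",
    "classify_structure",
]

DEVIATION_THRESHOLD = 0.3  # Å, inter-protomer deviation marking "inconsistent"

LABELS = ("monomer_selective", "equipotent", "likely_dimer_selective")


class ProtomerArityError(ValueError):
    """The structure does not contain exactly two protomers."""


@dataclass
class SelectivityCall:
    label: str
    glu501_hbond: bool
    delta_alpha_c: float
    delta_ke: float
    threshold: float
    evidence_notes: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def protomer_deviations(structure: KinaseStructure) -> tuple[float, float]:
    """Absolute inter-protomer differences (Å) of αC position and K–E distance.

    Returned at full precision; round to 0.1 Å for classification.  The K–E
    distance is the Lys483 NZ to nearest Glu501 carboxylate-oxygen distance,
    as in co-crystal tables.
    """
    if len(structure.protomers) != 2:
        raise ProtomerArityError(
            f"protomer deviations need exactly 2 protomers, found {len(structure.protomers)}"
        )
    a, b = structure.protomers
    d_ac = abs(alpha_c_distance(a) - alpha_c_distance(b))
    d_ke = abs(ke_distances(a)[0] - ke_distances(b)[0])
    return float(d_ac), float(d_ke)


def classify_selectivity(
    glu501_hbond: bool,
    delta_alpha_c: float,
    delta_ke: float,
    threshold: float = DEVIATION_THRESHOLD,
) -> SelectivityCall:
    """Apply the three-way decision table to the h-bond flag and deviations."""
    if delta_alpha_c < 0 or delta_ke < 0:
        raise ValueError("inter-protomer deviations must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    r_ac = round(delta_alpha_c, 1)
    r_ke = round(delta_ke, 1)
    if not glu501_hbond:
        label = "monomer_selective"
        note = "no ligand h-bond to the Glu501 carboxylate"
    elif r_ac >= threshold or r_ke >= threshold:
        label = "equipotent"
        fired = []
        if r_ac >= threshold:
            fired.append(f"ΔαC {r_ac:.1f} Å")
        if r_ke >= threshold:
            fired.append(f"ΔK–E {r_ke:.1f} Å")
        note = (
            "Glu501 h-bond present but inter-protomer geometry inconsistent ("
            + ", ".join(fired)
            + f" ≥ {threshold:.1f} Å)"
        )
    else:
        label = "likely_dimer_selective"
        note = (
            f"Glu501 h-bond present with consistent protomers "
            f"(ΔαC {r_ac:.1f} Å, ΔK–E {r_ke:.1f} Å < {threshold:.1f} Å)"
        )
    return SelectivityCall(
        label=label,
        glu501_hbond=glu501_hbond,
        delta_alpha_c=delta_alpha_c,
        delta_ke=delta_ke,
        threshold=threshold,
        evidence_notes=note,
    )


def classify_structure(
    structure: KinaseStructure,
    ligand_id: str,
    threshold: float = DEVIATION_THRESHOLD,
    allow_heuristic: bool = True,
) -> SelectivityCall:
    """End-to-end call on a dimeric co-crystal structure with the named ligand.

    The Glu501 h-bond counts as present if it is formed in at least one
    protomer.
    """
    d_ac, d_ke = protomer_deviations(structure)
    ligands = [l for l in structure.ligands if l.residue_name == ligand_id]
    if not ligands:
        raise KeyError(
            f"ligand {ligand_id!r} not found; present: "
            f"{sorted({l.residue_name for l in structure.ligands})}"
        )
    hbond = False
    for lig in ligands:
        try:
            protomer = structure.protomer(lig.chain_id)
        except KeyError:
            continue
        fp = build_fingerprint(protomer, lig, allow_heuristic=allow_heuristic)
        if fp.glu501_hbond:
            hbond = True
            break
    return classify_selectivity(hbond, d_ac, d_ke, threshold)
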