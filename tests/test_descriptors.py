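"""Conformational descriptors: geometry, classification boundaries, invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rafdimer.descriptors import (
    DescriptorUnavailableError,
    UndefinedDihedralError,
    alpha_c_distance,
    classify_alpha_c,
    classify_dfg,
    compute_descriptors,
    dfg_pseudo_dihedral,
    ke_distances,
    pseudo_dihedral,
)
from rafdimer.structure_io import AtomRecord, Protomer
from rafdimer.synthetic_data import SyntheticSpec, make_structure

from conftest import apply_rigid, random_rigid_transform


def _protomer(atom_specs):
    atoms = [
        AtomRecord(name, element, resname, resnum, "A", "", np.asarray(xyz, float))
        for (name, element, resname, resnum, xyz) in atom_specs
    ]
    return Protomer("A", atoms)


# ---------------------------------------------------------------------------
# αC position


def test_alpha_c_distance_hand_computed_centroid():
    p = _protomer(
        [
            ("CA", "C", "ILE", 582, (0, 0, 0)),
            ("CA", "C", "ASN", 500, (18, 0, 0)),
            ("CA", "C", "GLU", 501, (20, 0, 0)),
            ("CA", "C", "VAL", 502, (22, 0, 0)),
        ]
    )
    assert alpha_c_distance(p) == pytest.approx(20.0, abs=1e-12)


def test_alpha_c_distance_zero_at_centroid():
    p = _protomer(
        [
            ("CA", "C", "ILE", 582, (1, 1, 1)),
            ("CA", "C", "ASN", 500, (0, 0, 0)),
            ("CA", "C", "GLU", 501, (1.5, 1.5, 1.5)),
            ("CA", "C", "VAL", 502, (1.5, 1.5, 1.5)),
        ]
    )
    assert alpha_c_distance(p) == pytest.approx(0.0, abs=1e-12)


def test_alpha_c_missing_atom_names_residue():
    p = _protomer([("CA", "C", "ILE", 582, (0, 0, 0))])
    with pytest.raises(DescriptorUnavailableError, match="50"):
        alpha_c_distance(p)


@pytest.mark.parametrize(
    "distance,state",
    [(19.1, "in"), (19.0, "in"), (23.2, "out"), (22.0, "out"), (19.6, "out"), (19.599, "in")],
)
def test_classify_alpha_c(distance, state):
    assert classify_alpha_c(distance) == state


def test_classify_alpha_c_rejects_negative():
    with pytest.raises(ValueError):
        classify_alpha_c(-0.1)


# ---------------------------------------------------------------------------
# DFG pseudo-dihedral


def test_pseudo_dihedral_planar_limits():
    # cis: 1st and 4th points on the same side of the central bond
    assert pseudo_dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0, abs=1e-9)
    # trans: opposite sides
    assert pseudo_dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0, abs=1e-9)


def _torsion_oracle(p1, p2, p3, p4):
    """Independent torsion formulation: project the outer bonds onto the
    plane perpendicular to the central bond and take the signed angle."""
    b0 = np.subtract(p1, p2)
    b1 = np.subtract(p3, p2)
    b2 = np.subtract(p4, p3)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x)) % 360.0


def test_pseudo_dihedral_matches_independent_oracles(rng):
    """100 random quadruples agree with a projection-based torsion oracle
    (and with the MDAnalysis routine, at its float noise level)."""
    from MDAnalysis.lib.distances import calc_dihedrals

    for _ in range(100):
        pts = rng.uniform(-10, 10, size=(4, 3))
        try:
            mine = pseudo_dihedral(*pts)
        except UndefinedDihedralError:
            continue
        assert mine == pytest.approx(_torsion_oracle(*pts), abs=1e-6)
        ref = np.degrees(
            calc_dihedrals(*[p[None].astype(np.float64) for p in pts])[0]
        ) % 360.0
        assert mine == pytest.approx(ref, abs=1e-4)


def test_pseudo_dihedral_collinear_raises():
    with pytest.raises(UndefinedDihedralError):
        pseudo_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


@pytest.mark.parametrize("angle,state", [(210.0, "out"), (290.0, "out"), (140.0, "out"), (139.9, "in"), (100.0, "in"), (0.0, "in")])
def test_classify_dfg(angle, state):
    assert classify_dfg(angle) == state


@pytest.mark.parametrize("angle", [-1.0, 360.0, 400.0])
def test_classify_dfg_rejects_out_of_range(angle):
    with pytest.raises(ValueError):
        classify_dfg(angle)


# ---------------------------------------------------------------------------
# Lys483–Glu501 distances


def test_ke_distances_minimum_selection():
    p = _protomer(
        [
            ("NZ", "N", "LYS", 483, (0, 0, 0)),
            ("CD", "C", "GLU", 501, (4, 0, 0)),
            ("OE1", "O", "GLU", 501, (3, 0, 0)),
            ("OE2", "O", "GLU", 501, (5, 0, 0)),
        ]
    )
    ke_no, ke_min = ke_distances(p)
    assert ke_no == pytest.approx(3.0)
    assert ke_min <= ke_no


def test_ke_distances_brute_force_oracle(rng):
    """ke_min equals the exhaustive pairwise minimum over sidechain atoms."""
    lys_names = ["CB", "CG", "CD", "CE", "NZ"]
    glu_names = ["CB", "CG", "CD", "OE1", "OE2"]
    for _ in range(20):
        lys = {n: rng.uniform(-5, 5, 3) for n in lys_names}
        glu = {n: rng.uniform(-5, 5, 3) + np.array([6.0, 0, 0]) for n in glu_names}
        specs = [(n, "N" if n == "NZ" else "C", "LYS", 483, xyz) for n, xyz in lys.items()]
        specs += [(n, "O" if n.startswith("OE") else "C", "GLU", 501, xyz) for n, xyz in glu.items()]
        p = _protomer(specs)
        ke_no, ke_min = ke_distances(p)
        expect_no = min(np.linalg.norm(lys["NZ"] - glu[o]) for o in ("OE1", "OE2"))
        expect_min = min(
            np.linalg.norm(a - b) for a in lys.values() for b in glu.values()
        )
        assert ke_no == pytest.approx(expect_no, abs=1e-9)
        assert ke_min == pytest.approx(expect_min, abs=1e-9)
        assert ke_min <= ke_no + 1e-12


def test_ke_distances_exclude_cb():
    p = _protomer(
        [
            ("CB", "C", "LYS", 483, (0.5, 0, 0)),
            ("NZ", "N", "LYS", 483, (0, 0, 0)),
            ("CB", "C", "GLU", 501, (1.0, 0, 0)),
            ("OE1", "O", "GLU", 501, (3, 0, 0)),
            ("OE2", "O", "GLU", 501, (5, 0, 0)),
        ]
    )
    _, with_cb = ke_distances(p, include_cb=True)
    _, without_cb = ke_distances(p, include_cb=False)
    assert with_cb == pytest.approx(0.5)  # CB–CB pair
    assert without_cb == pytest.approx(3.0)  # NZ–OE1


def test_ke_missing_sidechain_raises():
    p = _protomer([("NZ", "N", "LYS", 483, (0, 0, 0))])
    with pytest.raises(DescriptorUnavailableError):
        ke_distances(p)


# ---------------------------------------------------------------------------
# aggregation and invariance


def test_compute_descriptors_planted_targets_exact():
    spec = SyntheticSpec(
        n_protomers=1, alpha_c_target=22.0, dfg_target=210.0, ke_target=3.5
    )
    geom = compute_descriptors(make_structure(spec).protomers[0])
    assert geom.alpha_c_distance == pytest.approx(22.0, abs=1e-6)
    assert geom.dfg_pseudo_dihedral == pytest.approx(210.0, abs=1e-6)
    assert geom.ke_no_distance == pytest.approx(3.5, abs=1e-6)
    assert geom.alpha_c_state == "out"
    assert geom.dfg_state == "out"
    assert geom.salt_bridge_4A is True
    assert geom.salt_bridge_45A is True
    assert not geom.unavailable


def test_compute_descriptors_missing_phe595_degrades_gracefully():
    st = make_structure(SyntheticSpec(n_protomers=1, alpha_c_target=20.0, dfg_target=210.0, ke_target=3.0))
    p = st.protomers[0]
    pruned = Protomer("A", [a for a in p.atoms if a.residue_number != 595])
    geom = compute_descriptors(pruned)
    assert geom.dfg_pseudo_dihedral is None
    assert "dfg" in geom.unavailable
    assert geom.alpha_c_distance == pytest.approx(20.0, abs=1e-6)
    assert geom.ke_no_distance == pytest.approx(3.0, abs=1e-6)


def test_descriptors_invariant_under_rigid_transform(rng):
    st = make_structure(
        SyntheticSpec(n_protomers=2, alpha_c_target=[19.1, 19.0], dfg_target=290.0, ke_target=2.8, ligand_present=True)
    )
    ref = [compute_descriptors(p) for p in st.protomers]
    for _ in range(5):
        rot, trans = random_rigid_transform(rng)
        moved = apply_rigid(st, rot, trans)
        for before, protomer in zip(ref, moved.protomers):
            after = compute_descriptors(protomer)
            assert after.alpha_c_distance == pytest.approx(before.alpha_c_distance, abs=1e-6)
            assert after.dfg_pseudo_dihedral == pytest.approx(before.dfg_pseudo_dihedral, abs=1e-6)
            assert after.ke_no_distance == pytest.approx(before.ke_no_distance, abs=1e-6)
            assert after.ke_min_sidechain_distance == pytest.approx(
                before.ke_min_sidechain_distance, abs=1e-6
            )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    alpha=st.floats(5.0, 40.0),
    dfg=st.floats(0.0, 359.0),
    ke=st.floats(1.0, 10.0),
)
def test_state_fields_consistent_with_classifiers(alpha, dfg, ke):
    spec = SyntheticSpec(n_protomers=1, alpha_c_target=alpha, dfg_target=dfg, ke_target=ke)
    geom = compute_descriptors(make_structure(spec).protomers[0])
    assert geom.alpha_c_state == classify_alpha_c(geom.alpha_c_distance)
    assert geom.dfg_state == classify_dfg(geom.dfg_pseudo_dihedral)
    assert geom.ke_min_sidechain_distance <= geom.ke_no_distance + 1e-9
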