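"""Distances, torsions, rotamer wells, H-bond bins, the Gln222 flip."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfpstate import (Atom, StructureModel, build_structure, chi1,
                      classify_hbond, classify_rotamer, dihedral, distance,
                      gln222_orientation, measure)
from gfpstate.geometry import GeometryError, HBondStrengthScheme
from gfpstate.structure_io import SiteLookupError
from gfpstate.synthetic import STRUCTURE_PRESETS, StructurePreset, place_atom


def _atom(resnum, resname, atname, pos, element=None):
    return Atom(chain_id="A", residue_number=resnum, residue_name=resname,
                atom_name=atname, altloc="", occupancy=1.0, b_factor=20.0,
                position=np.asarray(pos, float), element=element or atname[0])


def test_distance_345_triangle():
    a = _atom(1, "ALA", "CA", [0, 0, 0])
    b = _atom(1, "ALA", "CB", [3, 4, 0])
    assert distance(a, b) == pytest.approx(5.0)
    assert distance(a, a) == 0.0
    assert distance(a, b) == distance(b, a)


def _rotate_about_axis(point, axis_point, axis_dir, angle_deg):
    """Independent Rodrigues rotation used as the torsion-construction oracle."""
    k = np.asarray(axis_dir, float)
    k = k / np.linalg.norm(k)
    v = np.asarray(point, float) - axis_point
    th = math.radians(angle_deg)
    rot = (v * math.cos(th) + np.cross(k, v) * math.sin(th)
           + k * np.dot(k, v) * (1 - math.cos(th)))
    return axis_point + rot


@pytest.mark.parametrize("torsion", [0.0, 180.0, -60.0, 60.0, 90.0, -135.5, 179.9])
def test_dihedral_matches_rotation_construction(torsion):
    # build p4 by rotating the cis reference about the p2-p3 axis; the IUPAC
    # sign convention makes the rotation angle equal the measured torsion
    p1 = np.array([1.0, 1.0, 0.0])
    p2 = np.array([0.0, 0.0, 0.0])
    p3 = np.array([1.5, 0.0, 0.0])
    p4_cis = np.array([2.5, 1.0, 0.0])   # torsion 0 by construction
    assert dihedral(p1, p2, p3, p4_cis) == pytest.approx(0.0, abs=1e-9)
    p4 = _rotate_about_axis(p4_cis, p3, p3 - p2, torsion)
    expect = torsion if torsion != 180.0 else 180.0
    assert dihedral(p1, p2, p3, p4) == pytest.approx(expect, abs=1e-6)


def test_dihedral_anti_is_180():
    assert dihedral([1, 1, 0], [0, 0, 0], [1.5, 0, 0], [2.5, -1, 0]) == \
        pytest.approx(180.0, abs=1e-9)


def test_dihedral_collinear_raises():
    with pytest.raises(GeometryError):
        dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


@pytest.mark.parametrize("resname,chi", [("VAL", -60.0), ("THR", 60.0),
                                         ("ILE", -170.0), ("THR", 180.0)])
def test_chi1_recovers_constructed_torsion(resname, chi):
    preset = StructurePreset(name="t", d_his=2.85, pos203_residue=resname,
                             d_203=3.3, chi1_203=chi)
    model = build_structure(preset)
    assert chi1(model, 203) == pytest.approx(chi, abs=1e-6)


def test_chi1_missing_atom_raises():
    m = StructureModel("x", [_atom(203, "VAL", "N", [0, 0, 0]),
                             _atom(203, "VAL", "CA", [1.4, 0, 0])])
    with pytest.raises(SiteLookupError):
        chi1(m, 203)


@pytest.mark.parametrize("angle,label", [
    (-60.0, "gauche-"), (180.0, "trans"), (-120.0, "gauche-"),
    (60.0, "gauche+"), (0.0, "gauche+"), (120.0, "trans"),
    (-150.0, "trans"), (119.9, "gauche+"),
])
def test_rotamer_bins(angle, label):
    assert classify_rotamer(angle) == label


@given(st.floats(min_value=-179.999, max_value=180.0))
@settings(max_examples=200, derandomize=True)
def test_rotamer_partition_is_total(angle):
    assert classify_rotamer(angle) in {"gauche-", "gauche+", "trans"}


@pytest.mark.parametrize("d,label", [
    (2.85, "normal"), (3.24, "weak"), (3.6, "none"),
    (3.0, "normal"), (3.5, "weak"), (2.5, "normal"), (2.4, "clash"),
])
def test_hbond_bins(d, label):
    assert classify_hbond(d) == label


def test_hbond_scheme_validation():
    with pytest.raises(ValueError):
        HBondStrengthScheme(normal_max=3.6, weak_max=3.5)
    with pytest.raises(ValueError):
        classify_hbond(-1.0)


class TestGln222Orientation:
    def test_amide_flip_between_presets(self, preset_models):
        assert gln222_orientation(preset_models["A_like_low_pH"]) == "OE1->Ser65"
        assert gln222_orientation(preset_models["I_like"]) == "NE2->Ser65"

    def test_equidistant_is_undetermined(self):
        atoms = [
            _atom(66, "CRO", "OH", [0, 0, 0], element="O"),
            _atom(66, "CRO", "OG1", [-6, 0, 0], element="O"),
            _atom(222, "GLN", "OE1", [-6, 2.8, 0], element="O"),
            _atom(222, "GLN", "NE2", [-6, -2.8, 0], element="N"),
        ]
        assert gln222_orientation(StructureModel("tie", atoms)) == "undetermined"

    def test_non_gln_glu_at_222_raises(self):
        atoms = [_atom(66, "CRO", "OH", [0, 0, 0], element="O"),
                 _atom(66, "CRO", "OG1", [-6, 0, 0], element="O"),
                 _atom(222, "ALA", "CB", [-6, 3, 0])]
        with pytest.raises(SiteLookupError):
            gln222_orientation(StructureModel("bad", atoms))


class TestMeasure:
    def test_round_trip_of_prescribed_distances(self, i_like):
        r = measure(i_like)
        assert r.d_his == pytest.approx(2.85, abs=1e-6)
        assert r.d_203 == pytest.approx(3.6, abs=1e-6)
        assert r.d_wat3 == pytest.approx(2.7, abs=1e-5)
        assert r.rotamer_203 == "gauche-"

    def test_no_water_means_absent_d_wat3(self):
        preset = StructurePreset(name="dry", d_his=2.85, pos203_residue="VAL",
                                 d_203=3.6, include_wat3=False)
        r = measure(build_structure(preset))
        assert r.d_wat3 is None
        assert r.d_his == pytest.approx(2.85, abs=1e-6)

    def test_d_val_cz_only_for_valine(self, preset_models):
        assert measure(preset_models["I_like"]).d_val_cz is not None
        assert measure(preset_models["A_like_wt"]).d_val_cz is None

    def test_hbond_list_within_threshold(self, preset_models):
        for m in preset_models.values():
            for hb in measure(m).hbond_list:
                assert hb["distance"] <= 3.5
                assert hb["strength"] in {"normal", "weak", "clash"}


def _random_rigid(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-20, 20, 3)


def test_distance_and_dihedral_rigid_motion_invariant(rng):
    pts = rng.uniform(-5, 5, (4, 3))
    d0 = np.linalg.norm(pts[0] - pts[1])
    t0 = dihedral(*pts)
    for _ in range(10):
        rot, shift = _random_rigid(rng)
        moved = pts @ rot.T + shift
        assert np.linalg.norm(moved[0] - moved[1]) == pytest.approx(d0, abs=1e-9)
        assert dihedral(*moved) == pytest.approx(t0, abs=1e-9)


def test_measure_rigid_motion_invariant(rng):
    model = build_structure(STRUCTURE_PRESETS["B_like_E222Q"])
    ref = measure(model)
    rot, shift = _random_rigid(rng)
    moved = StructureModel(model.structure_id, [
        Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
             a.altloc, a.occupancy, a.b_factor, rot @ a.position + shift,
             a.element) for a in model.atoms], dpi=model.dpi)
    got = measure(moved)
    assert got.d_his == pytest.approx(ref.d_his, abs=1e-9)
    assert got.d_203 == pytest.approx(ref.d_203, abs=1e-9)
    assert got.chi1_203 == pytest.approx(ref.chi1_203, abs=1e-7)
    assert got.gln222_orientation == ref.gln222_orientation
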