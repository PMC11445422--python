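"""Promolecular density, reduced density gradient and sign(lambda2)rho."""

import math

import numpy as np
import pytest

from gfpstate import (DensityModel, build_density_fixture, nci_scan,
                      promolecular_density, reduced_gradient, signed_density,
                      write_cube)
from gfpstate.rdg import (BOHR_PER_ANGSTROM, GridTooLargeError, ParameterError,
                          slater_terms)

ANG = 1.0 / BOHR_PER_ANGSTROM  # one bohr expressed in angstrom


def _single_exp_model():
    # rho(r) = e^(-2r): c=1, p=0, decay length zeta=0.5 bohr
    return DensityModel(elements=["H"], positions=[[0.0, 0.0, 0.0]],
                        params={"H": [(1.0, 0, 0.5)]})


def test_density_spherically_symmetric():
    m = _single_exp_model()
    rx, _, _ = promolecular_density(m, [ANG, 0, 0])
    ry, _, _ = promolecular_density(m, [0, ANG, 0])
    assert rx == pytest.approx(ry, rel=1e-12)


def test_closed_form_density_value():
    m = _single_exp_model()
    rho, grad, hess = promolecular_density(m, [2 * ANG, 0, 0])
    assert rho == pytest.approx(math.exp(-4), rel=1e-9)
    # radial derivative of e^(-2r) is -2 rho, directed along +x here
    assert grad[0] == pytest.approx(-2 * math.exp(-4), rel=1e-9)
    assert abs(grad[1]) < 1e-12 and abs(grad[2]) < 1e-12


def test_gradient_vanishes_at_symmetric_midpoint():
    m = DensityModel(elements=["H", "H"],
                     positions=[[0, 0, 0], [2.0, 0, 0]])
    rho, grad, _ = promolecular_density(m, [1.0, 0, 0])
    assert np.linalg.norm(grad) < 1e-12
    assert reduced_gradient(rho, np.linalg.norm(grad)) == 0.0


def test_slater_terms_integrate_to_electron_count():
    # 4*pi * int r^2 rho(r) dr must equal the element's electron number
    from scipy.integrate import quad
    for elem, ne in (("H", 1), ("C", 6), ("O", 8), ("NE", 10), ("S", 16)):
        terms = slater_terms(elem)
        total = 4 * math.pi * quad(
            lambda r: r ** 2 * sum(c * r ** p * math.exp(-r / z)
                                   for c, p, z in terms), 0, 60, limit=200)[0]
        assert total == pytest.approx(ne, rel=1e-6)


def test_unknown_element_raises():
    with pytest.raises(ParameterError):
        DensityModel(elements=["XX"], positions=[[0, 0, 0]])


def test_reduced_gradient_definition():
    const = 2 * (3 * math.pi ** 2) ** (1 / 3)
    assert reduced_gradient(0.01, 0.02) == pytest.approx(0.02 / (const * 0.01 ** (4 / 3)))
    assert reduced_gradient(0.01, 0.04) == pytest.approx(2 * reduced_gradient(0.01, 0.02))
    with pytest.raises(ValueError):
        reduced_gradient(0.0, 0.1)


def test_single_exponential_closed_form_on_grid():
    # for rho = e^(-2r), |grad rho| = 2 rho, so s = rho^(-1/3)/(3 pi^2)^(1/3)
    m = _single_exp_model()
    field, _ = nci_scan(m, region=((0.08, 0.08, 0.08), (1.2, 1.2, 1.2)),
                        spacing=0.25)
    ax = [field.axis_points(i) for i in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)  # bohr, nucleus at origin
    expect = np.exp(2 * r / 3) / (3 * math.pi ** 2) ** (1 / 3)
    assert np.max(np.abs(field.s - expect)) < 1e-6


@pytest.mark.parametrize("diag,expect_sign", [((-2, -1, 3), -1), ((-2, 1, 3), 1),
                                              ((-1, 0, 2), 1)])
def test_signed_density_uses_middle_eigenvalue(diag, expect_sign):
    assert signed_density(np.diag(diag), 0.01) == pytest.approx(expect_sign * 0.01)


def test_signed_density_rejects_asymmetric():
    h = np.array([[1.0, 0.5, 0], [0.1, 1.0, 0], [0, 0, 1.0]])
    with pytest.raises(ValueError):
        signed_density(h, 0.01)


def test_hbond_midpoint_density_concentrated_along_axis():
    # numeric check: between H and O at hydrogen-bond geometry the second
    # Hessian eigenvalue is negative, so sign(lambda2) rho < 0
    m = build_density_fixture("hbond_triplet")
    # density saddle lies between the H (x=1.0 A) and the O (x=2.85 A)
    xs = np.linspace(1.3, 2.6, 40)
    rhos = [promolecular_density(m, [x, 0, 0])[0] for x in xs]
    x0 = xs[int(np.argmin(rhos))]
    rho, _, hess = promolecular_density(m, [x0, 0, 0])
    assert signed_density(hess, rho) < 0


class TestNciScan:
    def test_hbond_triplet_attractive_cluster(self):
        _, summary = nci_scan(build_density_fixture("hbond_triplet"))
        attractive = [c for c in summary if c["class"] == "attraction"]
        assert attractive
        assert attractive[0]["signed_rho_at_min_s"] < -0.01

    def test_vdw_pair_weak_cluster(self):
        _, summary = nci_scan(build_density_fixture("vdw_pair"))
        weak = [c for c in summary if c["class"] == "weak"]
        assert weak
        assert abs(weak[0]["signed_rho_at_min_s"]) <= 0.01

    def test_single_atom_no_clusters(self):
        _, summary = nci_scan(build_density_fixture("single_atom"))
        assert summary == []

    def test_eigenvalue_ordering_and_s_nonnegative(self):
        field, _ = nci_scan(build_density_fixture("vdw_pair"), spacing=0.4)
        assert np.all(field.s >= 0)
        assert np.all(np.abs(np.abs(field.signed_rho) - field.rho) < 1e-12)

    def test_field_invariant_under_atom_permutation(self):
        m1 = build_density_fixture("hbond_triplet")
        m2 = DensityModel(elements=list(reversed(m1.elements)),
                          positions=m1.positions[::-1].copy())
        region = ((0, -1, -1), (2.85, 1, 1))
        f1, _ = nci_scan(m1, region=region, spacing=0.3)
        f2, _ = nci_scan(m2, region=region, spacing=0.3)
        assert np.array_equal(f1.s, f2.s)
        assert np.array_equal(f1.signed_rho, f2.signed_rho)

    def test_rotation_rotates_the_field(self, rng):
        m = build_density_fixture("vdw_pair")
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        m_rot = DensityModel(elements=m.elements, positions=m.positions @ rot.T)
        pts = rng.uniform(-1.5, 4.5, (50, 3))
        rho1, g1, _ = promolecular_density(m, pts)
        rho2, g2, _ = promolecular_density(m_rot, pts @ rot.T)
        s1 = reduced_gradient(rho1, np.linalg.norm(g1, axis=1))
        s2 = reduced_gradient(rho2, np.linalg.norm(g2, axis=1))
        assert np.allclose(s1, s2, atol=1e-8)

    def test_grid_guard(self):
        with pytest.raises(GridTooLargeError):
            nci_scan(build_density_fixture("vdw_pair"), spacing=0.01,
                     max_points=10_000)


def test_cube_files_written(tmp_path):
    m = build_density_fixture("vdw_pair")
    field, _ = nci_scan(m, spacing=0.5)
    write_cube(field, m, tmp_path / "s.cube", which="s")
    text = (tmp_path / "s.cube").read_text().splitlines()
    assert int(text[2].split()[0]) == 2  # two atoms
    nx = int(text[3].split()[0])
    assert nx == field.shape[0]
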