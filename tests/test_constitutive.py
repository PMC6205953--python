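"""Constitutive module: parameter derivations, stresses, tangents, permeability."""

from __future__ import annotations

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

import porogel as pg
from porogel.constitutive import round_half_up
from porogel.errors import (
    IncompressibleLimitError,
    KinematicsError,
    ValidationError,
)

VARIANTS = ("NH1", "NH2", "NH3")


# ---------------------------------------------------------------- parameters


@pytest.mark.parametrize(
    "G_kPa, nu, field, expected, decimals",
    [
        (0.3375, 0.2, "K", 0.4500, 4),
        (0.3375, 0.2, "C10", 0.1688, 4),
        (0.3375, 0.2, "D1", 4.444, 3),
        (0.3750, 0.2, "K", 0.5000, 4),
        (0.3750, 0.2, "C10", 0.1875, 4),
        (0.3750, 0.2, "D1", 4.000, 3),
        (0.4500, 0.2, "K", 0.6000, 4),
        (0.4500, 0.2, "C10", 0.2250, 4),
        (0.4500, 0.2, "D1", 3.333, 3),
    ],
)
def test_derive_material_reproduces_printed_cells(G_kPa, nu, field, expected, decimals):
    """(G, nu=0.2) reproduces every printed parameter cell at printed precision."""
    mat = pg.derive_material(G_kPa * 1e3, nu, 1e-10, 2.0)
    value = {"K": mat.K / 1e3, "C10": mat.C10 / 1e3, "D1": mat.D1 * 1e3}[field]
    assert round_half_up(value, decimals) == pytest.approx(expected, abs=1e-12)


def test_derive_material_closed_form_nu_zero():
    mat = pg.derive_material(1.0, 0.0, 1.0, 0.0)
    assert mat.K == pytest.approx(2.0 / 3.0, rel=1e-14)
    assert mat.D1 == pytest.approx(2.0 / mat.K, rel=1e-14) == pytest.approx(3.0)


def test_derive_material_validation():
    with pytest.raises(IncompressibleLimitError):
        pg.derive_material(1.0, 0.5, 1.0, 0.0)
    with pytest.raises(ValidationError):
        pg.derive_material(-1.0, 0.2, 1.0, 0.0)
    with pytest.raises(ValidationError):
        pg.derive_material(1.0, 0.2, 0.0, 0.0)


def test_table1_materials_contents(materials):
    """The bundled sets carry the printed values, converted to SI."""
    c030, c040 = materials["c030"], materials["c040"]
    assert c030.k0 == pytest.approx(1.20e-10)
    assert c030.M == pytest.approx(2.1)
    assert c040.M == pytest.approx(3.5)
    assert c040.D1 * 1e3 == pytest.approx(3.333)
    for mat in materials.values():
        assert mat.C10 / mat.G == pytest.approx(0.5, rel=2e-3)
        assert mat.nu == 0.2


# ------------------------------------------------------------------ stresses


@pytest.mark.parametrize("variant", VARIANTS)
def test_zero_stress_at_reference(materials, variant):
    for mat in materials.values():
        assert abs(pg.confined_stress(variant, mat, 1.0)) < 1e-12 * mat.G


def test_confined_stress_frozen_values(c030):
    """Worked values at lam = 0.95 for the 0.30% gel (cross-checked
    symbolically in test_stress_matches_symbolic_energy_derivative)."""
    s2 = pg.confined_stress("NH2", c030, 0.95)
    s3 = pg.confined_stress("NH3", c030, 0.95)
    assert s2 == pytest.approx(-51.985, abs=0.01)
    assert s3 == pytest.approx(-51.55, abs=0.01)
    assert abs(s3 - s2) / abs(s2) < 0.01
    # the incompressible-form completion is softer volumetrically
    assert pg.confined_stress("NH1", c030, 0.95) == pytest.approx(-38.487, abs=0.01)


@pytest.mark.parametrize("variant", ("NH2", "NH3"))
def test_small_strain_aggregate_modulus(variant):
    """NH2 and NH3 tangents at lam = 1 equal K + 4G/3 as an identity."""
    mat = pg.derive_material(375.0, 0.2, 1e-10, 2.0)
    expected = mat.K + 4.0 * mat.G / 3.0
    assert pg.confined_tangent(variant, mat, 1.0) == pytest.approx(
        expected, rel=1e-12
    )


def test_nh1_aggregate_modulus_is_twice_shear():
    mat = pg.derive_material(375.0, 0.2, 1e-10, 2.0)
    assert pg.confined_tangent("NH1", mat, 1.0) == pytest.approx(
        2.0 * mat.G, rel=1e-12
    )


def test_stress_matches_symbolic_energy_derivative(c030):
    """Independent oracle: differentiate each strain energy with sympy under
    F = diag(1, 1, lam) and compare with the implemented stress on a grid."""
    lam = sp.symbols("lam", positive=True)
    G, K, C10, D1 = c030.G, c030.K, c030.C10, c030.D1
    I1 = 2 + lam**2
    J = lam
    W = {
        "NH1": C10 * (I1 - 3) - 2 * C10 * sp.log(J),
        "NH2": G / 2 * (I1 - 3) - G * sp.log(J) + (K - 2 * G / 3) / 2 * sp.log(J) ** 2,
        "NH3": C10 * (J ** sp.Rational(-2, 3) * I1 - 3) + (J - 1) ** 2 / D1,
    }
    grid = np.linspace(0.82, 1.18, 13)
    for variant, energy in W.items():
        dW = sp.lambdify(lam, sp.diff(energy, lam), "numpy")
        got = pg.confined_stress(variant, c030, grid)
        assert np.allclose(got, dW(grid), rtol=1e-12, atol=1e-12 * c030.G)


@pytest.mark.parametrize("variant", VARIANTS)
def test_energy_consistency(materials, variant):
    """confined_stress equals the numerical derivative of strain_energy."""
    h = 1e-6
    lam = np.linspace(0.85, 1.15, 7)
    for mat in materials.values():
        fd = (
            pg.strain_energy(variant, mat, lam + h)
            - pg.strain_energy(variant, mat, lam - h)
        ) / (2 * h)
        sig = pg.confined_stress(variant, mat, lam)
        assert np.allclose(sig, fd, rtol=1e-6, atol=1e-6 * mat.G)


@given(lam=st.floats(0.8, 1.2), iv=st.integers(0, 2), im=st.integers(0, 2))
@settings(max_examples=120, deadline=None, derandomize=True)
def test_tangent_matches_finite_difference(lam, iv, im):
    """Analytic tangent agrees with a central difference of the stress."""
    mat = pg.table1_materials()[im]
    variant = VARIANTS[iv]
    h = 1e-6
    fd = (
        pg.confined_stress(variant, mat, lam + h)
        - pg.confined_stress(variant, mat, lam - h)
    ) / (2 * h)
    assert pg.confined_tangent(variant, mat, lam) == pytest.approx(
        fd, rel=1e-6, abs=1e-6 * mat.G
    )


@pytest.mark.parametrize("variant", VARIANTS)
def test_stress_monotonic_in_stretch(materials, variant):
    """No material instability in the working range lam in [0.8, 1.2]."""
    lam = np.linspace(0.8, 1.2, 401)
    for mat in materials.values():
        sig = pg.confined_stress(variant, mat, lam)
        assert np.all(np.diff(sig) > 0)
        assert np.all(pg.confined_tangent(variant, mat, lam) > 0)


def test_stress_kinematics_errors(c030):
    with pytest.raises(KinematicsError):
        pg.confined_stress("NH2", c030, 0.0)
    with pytest.raises(KinematicsError):
        pg.confined_stress("NH2", c030, -0.5)
    with pytest.raises(ValidationError):
        pg.confined_stress("NH9", c030, 1.0)


# -------------------------------------------------------------- permeability


def test_permeability_values(c030):
    assert pg.permeability(c030, 1.0) == pytest.approx(c030.k0, rel=1e-15)
    # k0 * 0.9**2.1, checked against log-domain evaluation
    expected = c030.k0 * np.exp(2.1 * np.log(0.9))
    assert pg.permeability(c030, 0.9) == pytest.approx(expected, rel=1e-13)
    assert pg.permeability(c030, 0.9) == pytest.approx(9.618e-11, rel=1e-3)
    m0 = pg.derive_material(300.0, 0.2, 2e-10, 0.0)
    for J in (0.5, 0.9, 1.3):
        assert pg.permeability(m0, J) == pytest.approx(2e-10, rel=1e-15)


@given(J=st.floats(0.5, 1.5), im=st.integers(0, 2))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_permeability_log_linear(J, im):
    """log k is linear in log J with slope M, and k stays positive."""
    mat = pg.table1_materials()[im]
    k = pg.permeability(mat, J)
    assert k > 0
    assert np.log(k / mat.k0) == pytest.approx(mat.M * np.log(J), abs=1e-12)


def test_permeability_kinematics_error(c030):
    with pytest.raises(KinematicsError):
        pg.permeability(c030, 0.0)
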