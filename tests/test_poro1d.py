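"""Nonlinear consolidation solver: equilibria, conservation, invariants."""

from __future__ import annotations

import numpy as np
import pytest

import porogel as pg
from porogel.errors import SolverError, ValidationError

from conftest import linear_displacement_reference


@pytest.fixture(scope="module")
def busby_c030_run(request):
    """One moderately resolved reference run with snapshots, shared."""
    mats = pg.table1_materials()
    from porogel.config import load_protocol_blocks

    proto = load_protocol_blocks()["busby"]
    settings = pg.SolverSettings(n_elements=60, substeps=4, first_step_substeps=16)
    return pg.simulate(mats[1], "NH2", proto, settings, store_snapshots=True)


# ------------------------------------------------------------- domain types


def test_protocol_validation():
    with pytest.raises(ValidationError):
        pg.LoadingProtocol("x", 10.0, 290.0, 0.0, 0.005)
    with pytest.raises(ValidationError):
        pg.LoadingProtocol("x", 0.0, 290.0, 0.05, 0.005)
    with pytest.raises(ValidationError):
        pg.LoadingProtocol("x", 10.0, -1.0, 0.05, 0.005)
    with pytest.raises(ValidationError):
        pg.LoadingProtocol("x", 10.0, 290.0, 0.05, 0.0)


def test_settings_validation():
    with pytest.raises(ValidationError):
        pg.SolverSettings(n_elements=3)
    with pytest.raises(ValidationError):
        pg.SolverSettings(newton_tol=1e-2)
    with pytest.raises(ValidationError):
        pg.SolverSettings(permeability_frame="bogus")
    # a ramp must contain at least 10 time steps
    proto = pg.LoadingProtocol("x", 10.0, 0.0, 0.05, 0.005)
    with pytest.raises(ValidationError):
        pg.SolverSettings(dt_ramp=2.0).resolve(proto)


def test_effective_stress_arithmetic():
    assert pg.effective_stress(0.0, -100.0) == 100.0
    assert pg.effective_stress(100.0, -100.0) == 200.0
    assert pg.effective_stress(50.0, 0.0) == 50.0


# ------------------------------------------------------------ trivial limits


def test_null_load_gives_null_history(c030):
    proto = pg.LoadingProtocol("null", 10.0, 50.0, 1e-9, 0.005)
    h = pg.simulate(c030, "NH2", proto, pg.SolverSettings(n_elements=20))
    scale = c030.G * 1e-9
    assert np.all(np.abs(h.total_stress) < 1e3 * scale)
    assert np.all(np.abs(h.bottom_effective_stress) < 1e3 * scale)


def test_initial_state_undeformed(busby_c030_run):
    s0 = busby_c030_run.snapshots[0]
    assert s0.time == 0.0
    assert np.all(s0.stretch_field == 1.0)
    assert np.all(s0.pressure_field == 0.0)


def test_drained_long_time_limit(c030):
    """After >= 10 time constants of hold the bottom effective stress is the
    closed-form drained stress and the bottom pressure has vanished."""
    HA = pg.aggregate_modulus("NH2", c030)
    tau = 0.005**2 / (HA * c030.k0)
    proto = pg.LoadingProtocol("long", 10.0, 10.0 * tau, 0.05, 0.005)
    h = pg.simulate(c030, "NH2", proto, pg.SolverSettings(n_elements=50))
    drained = abs(pg.confined_stress("NH2", c030, 0.95))
    assert h.end_effective == pytest.approx(drained, rel=5e-3)
    assert abs(h.bottom_pressure[-1]) < 1e-3 * drained


# --------------------------------------------------------------- conservation


def test_mass_balance_reference_run(busby_c030_run):
    assert pg.mass_balance_check(busby_c030_run) < 1e-4


def test_mass_balance_against_trapezoid_quadrature(busby_c030_run):
    """Volume lost (trapezoidal quadrature of the stretch profile) equals the
    accumulated outflow."""
    h = busby_c030_run
    final = h.snapshots[-1]
    Z = final.material_coordinates
    lam = final.stretch_field
    # extend to the faces with edge values for trapezoidal quadrature
    Zx = np.concatenate(([0.0], Z, [final.height]))
    lamx = np.concatenate(([lam[0]], lam, [lam[-1]]))
    vol = np.trapezoid(lamx, Zx)
    lost = final.height - vol
    assert lost == pytest.approx(h.cumulative_outflow[-1], rel=2e-3)
    # nondecreasing within solver tolerance
    assert np.all(
        np.diff(h.cumulative_outflow) >= -1e-8 * h.cumulative_outflow[-1]
    )


def test_sealed_faces_degeneracy(c030):
    """No drainage + incompressible constituents: no consolidation at all."""
    proto = pg.LoadingProtocol("sealed", 10.0, 50.0, 1e-12, 0.005)
    settings = pg.SolverSettings(n_elements=20, drained_top=False)
    h = pg.simulate(c030, "NH2", proto, settings, store_snapshots=True)
    assert np.all(h.cumulative_outflow == 0.0)
    assert h.snapshots[-1].mixture_volume() == pytest.approx(0.005, rel=1e-12)
    # a finite compression is kinematically inadmissible when sealed
    bad = pg.LoadingProtocol("sealed", 10.0, 50.0, 0.05, 0.005)
    with pytest.raises(SolverError):
        pg.simulate(c030, "NH2", bad, settings)


# ----------------------------------------------------------------- invariants


def test_total_stress_uniformity(busby_c030_run, c030):
    """sigma_e(lam_e) - p_e reconstructed per cell is uniform at every step."""
    h = busby_c030_run
    for snap, s_tot in zip(h.snapshots[1:], h.total_stress[1:]):
        sig = np.asarray(pg.confined_stress("NH2", c030, snap.stretch_field))
        per_cell = sig - snap.pressure_field
        spread = per_cell.max() - per_cell.min()
        assert spread <= 1e-8 * max(abs(s_tot), 1.0)


def test_pressure_positivity_under_compression(busby_c030_run):
    h = busby_c030_run
    smax = np.abs(h.total_stress).max()
    for snap in h.snapshots:
        assert np.all(snap.pressure_field >= -1e-9 * smax)
    assert np.all(h.bottom_pressure >= -1e-9 * smax)


def test_drained_face_pressure_is_zero(busby_c030_run):
    Z, p = busby_c030_run.snapshots[-1].pressure_profile()
    assert Z[-1] == busby_c030_run.snapshots[-1].height
    assert p[-1] == 0.0


def test_relaxation_monotonic_during_hold(busby_c030_run):
    h = busby_c030_run
    hold = h.times > 10.0
    stress = np.abs(h.total_stress[hold])
    assert np.all(np.diff(stress) <= 1e-9 * stress[0])


def test_peak_and_end_summaries(busby_c030_run):
    h = busby_c030_run
    assert h.peak_effective == np.abs(h.bottom_effective_stress).max()
    assert h.end_effective == h.bottom_effective_stress[-1]
    # ramp-hold relaxation: peak at end of ramp exceeds the drained end value
    assert h.peak_effective > h.end_effective


# ------------------------------------------------------ linear verification


@pytest.mark.parametrize("frame", ["spatial", "material"])
def test_solver_matches_linear_reference(linear_material, frame):
    """With M = 0 and a vanishing strain the nonlinear solver reproduces the
    independent brute-force linear solve in either permeability frame."""
    proto = pg.LoadingProtocol("lin", 10.0, 190.0, 1e-3, 0.005)
    settings = pg.SolverSettings(
        n_elements=100, substeps=6, first_step_substeps=24, permeability_frame=frame
    )
    h = pg.simulate(linear_material, "NH2", proto, settings)
    HA = pg.aggregate_modulus("NH2", linear_material)
    sig_ref, p_ref = linear_displacement_reference(
        HA, linear_material.k0, 0.005, 1e-3, 10.0, h.times[1:], n_nodes=301
    )
    assert np.all(
        np.abs(h.total_stress[1:] - sig_ref) <= 0.01 * np.abs(sig_ref)
    )
    assert np.allclose(h.bottom_pressure[1:], p_ref, atol=0.01 * HA * 1e-3)


# ------------------------------------------------------------------- errors


def test_newton_failure_names_the_step(c030):
    proto = pg.LoadingProtocol("x", 10.0, 0.0, 0.05, 0.005)
    settings = pg.SolverSettings(n_elements=20, max_newton_iter=1)
    with pytest.raises(SolverError, match="step"):
        pg.simulate(c030, "NH2", proto, settings)
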