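"""Shared fixtures and the independent linear-consolidation reference solver.

The brute-force reference here deliberately uses a different formulation and
discretisation from the package: nodal finite differences on the
displacement field integrated with a stiff ODE solver, versus the package's
cell-centred finite volumes with monolithic Newton stepping.  It exists so
the analytic series and the nonlinear solver can both be checked against an
implementation that shares no code path with either.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import porogel as pg
from porogel.config import load_protocol_blocks


@pytest.fixture(scope="session")
def materials() -> dict[str, pg.HydrogelMaterial]:
    return dict(zip(("c020", "c030", "c040"), pg.table1_materials()))


@pytest.fixture(scope="session")
def protocols() -> dict[str, pg.LoadingProtocol]:
    return load_protocol_blocks()


@pytest.fixture(scope="session")
def c030(materials) -> pg.HydrogelMaterial:
    return materials["c030"]


@pytest.fixture(scope="session")
def linear_material(c030) -> pg.HydrogelMaterial:
    """The 0.30% gel with M = 0, i.e. constant permeability."""
    return pg.derive_material(c030.G, c030.nu, c030.k0, 0.0, label="linearised 0.30%")


@pytest.fixture(scope="session")
def cheap_settings() -> pg.SolverSettings:
    """Coarse but valid solver settings for fast smoke-level runs."""
    return pg.SolverSettings(
        n_elements=30, substeps=2, first_step_substeps=6, hold_growth=1.5
    )


def linear_displacement_reference(
    HA: float,
    k: float,
    H: float,
    eps0: float,
    t0: float,
    times: np.ndarray,
    n_nodes: int = 201,
):
    """Brute-force displacement-controlled linear consolidation.

    Solves the heat equation in the displacement, ``u_t = c u_ZZ`` with
    ``u(0, t) = 0`` and ``u(H, t) = -eps0 H min(t/t0, 1)``, by nodal central
    differences and an implicit stiff integrator, then recovers

    * total stress  ``sigma(t) = HA u_Z(H, t)`` (one-sided 2nd order), and
    * bottom pore pressure ``p(0, t) = HA (u_Z(0, t) - u_Z(H, t))``.

    Returns ``(sigma, p_bottom)`` sampled at ``times``.
    """
    c = HA * k
    dZ = H / (n_nodes - 1)

    def top(t):
        return -eps0 * H * min(t / t0, 1.0)

    def rhs(t, u_int):
        u = np.empty(n_nodes)
        u[0] = 0.0
        u[-1] = top(t)
        u[1:-1] = u_int
        return c * (u[2:] - 2.0 * u[1:-1] + u[:-2]) / dZ**2

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        np.zeros(n_nodes - 2),
        method="BDF",
        t_eval=times,
        rtol=1e-8,
        atol=1e-14 * H,
    )
    assert sol.success, sol.message
    sigma = np.empty(times.size)
    p_bot = np.empty(times.size)
    for j, t in enumerate(times):
        u = np.empty(n_nodes)
        u[0] = 0.0
        u[-1] = top(t)
        u[1:-1] = sol.y[:, j]
        du_top = (3.0 * u[-1] - 4.0 * u[-2] + u[-3]) / (2.0 * dZ)
        du_bot = (-3.0 * u[0] + 4.0 * u[1] - u[2]) / (2.0 * dZ)
        sigma[j] = HA * du_top
        p_bot[j] = HA * (du_bot - du_top)
    return sigma, p_bot


def linear_step_load_reference(
    HA: float,
    k: float,
    H: float,
    eps0: float,
    Z_eval: np.ndarray,
    times: np.ndarray,
    n_nodes: int = 201,
):
    """Brute-force step-load (Terzaghi) pore pressure.

    Heat equation directly in the pressure with uniform initial value
    ``HA eps0``, sealed bottom (ghost-node Neumann) and drained top.
    Returns p(Z_eval, times) with shape (len(times), len(Z_eval)).
    """
    c = HA * k
    dZ = H / (n_nodes - 1)
    Z = np.linspace(0.0, H, n_nodes)

    def rhs(t, p_int):
        # p_int: nodes 0..n-2 (top node pinned at 0); sealed bottom via ghost
        p = np.concatenate((p_int, [0.0]))
        lap = np.empty(n_nodes - 1)
        lap[0] = 2.0 * (p[1] - p[0]) / dZ**2
        lap[1:] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / dZ**2
        return c * lap

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        np.full(n_nodes - 1, HA * eps0),
        method="BDF",
        t_eval=times,
        rtol=1e-8,
        atol=1e-12 * HA * eps0,
    )
    assert sol.success, sol.message
    out = np.empty((times.size, Z_eval.size))
    for j in range(times.size):
        p = np.concatenate((sol.y[:, j], [0.0]))
        out[j] = np.interp(Z_eval, Z, p)
    return out
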