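"""Finite-strain 1D confined-compression consolidation solver.

The sample occupies the material interval ``Z in [0, H]`` with an
impermeable rigid bottom at Z = 0 (the monitored layer) and the loaded,
freely draining face at Z = H (pore pressure 0).  Lateral confinement makes
the kinematics uniaxial: the local deformation gradient is
``diag(1, 1, lam(Z, t))`` and the volume ratio equals the axial stretch.

Governing equations (both constituents intrinsically incompressible):

* quasi-static momentum balance — the total axial Cauchy stress
  ``sigma_zz = sigma_e(lam) - p`` is spatially uniform at every instant;
* mass balance on the material frame —
  ``d lam / dt = d/dZ [ k_eff(lam) dp/dZ ]``, where ``k_eff`` is the van der
  Voet permeability ``k0 lam**M`` pulled back to the material grid (an extra
  ``1/lam`` factor when the law is interpreted in the spatial frame, the
  default).

Discretisation: finite volumes with cell-wise constant stretch, cell-centred
pressure and a fully implicit (backward Euler) step solved by Newton
iteration on the unknowns ``(lam_1..lam_N, sigma_zz)``; the uniform total
stress acts as the Lagrange multiplier of the prescribed-displacement
constraint ``integral(lam) dZ = H - delta(t)``.  Eliminating the pressure
through the momentum balance (``p_e = sigma_e(lam_e) - sigma_zz``) keeps the
total stress uniform to machine precision by construction, and the scheme is
exactly mass-conservative: the discrete outflow through the top face equals
the loss of mixture volume step by step.

The monitored output is the bottom-layer effective stress reconstructed as
``p - sigma_zz_skeleton`` from the bottom pore pressure and the bottom-layer
skeleton stress; by momentum balance this equals the compressive total
stress magnitude, which is how ramp-hold relaxation curves are read off a
confined-compression rig.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constitutive import (
    HydrogelMaterial,
    ModelVariant,
    confined_stress,
    confined_tangent,
)
from .errors import (
    ConstitutiveInstabilityError,
    SolverError,
    ValidationError,
)

__all__ = [
    "LoadingProtocol",
    "SolverSettings",
    "ConsolidationState",
    "StressHistory",
    "simulate",
    "effective_stress",
    "mass_balance_check",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoadingProtocol:
    """Ramp-hold displacement history and drainage geometry.

    applied_strain is the compressive engineering strain fraction reached at
    the end of the ramp; height is the drainage path length along the
    loading axis, m.
    """

    label: str
    ramp_duration: float
    hold_duration: float
    applied_strain: float
    height: float

    def __post_init__(self) -> None:
        if not 0.0 < self.applied_strain < 1.0:
            raise ValidationError("applied_strain must lie in (0, 1)")
        if not self.ramp_duration > 0:
            raise ValidationError("ramp_duration must be > 0")
        if self.hold_duration < 0:
            raise ValidationError("hold_duration must be >= 0")
        if not self.height > 0:
            raise ValidationError("height must be > 0")

    def displacement(self, t: float) -> float:
        """Prescribed top-face settlement delta(t), m (>= 0)."""
        frac = min(max(t, 0.0) / self.ramp_duration, 1.0)
        return self.applied_strain * self.height * frac


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for :func:`simulate`.

    ``dt_ramp`` / ``dt_hold`` default (None) to ramp_duration/50 and
    hold_duration/100; hold steps grow geometrically from the ramp step up
    to ``dt_hold``.  ``permeability_frame`` selects whether the power law is
    a spatial (true) permeability pulled back to the material grid
    ("spatial", default) or is applied on the material grid directly
    ("material").  ``drained_top=False`` seals both faces, which only admits
    the undeformed state (see :func:`simulate`).
    """

    n_elements: int = 100
    dt_ramp: float | None = None
    dt_hold: float | None = None
    newton_tol: float = 1e-9
    max_newton_iter: int = 30
    permeability_frame: str = "spatial"
    drained_top: bool = True
    hold_growth: float = 1.2
    substeps: int = 8
    first_step_substeps: int = 32

    def __post_init__(self) -> None:
        if self.n_elements < 4:
            raise ValidationError("n_elements must be >= 4")
        if self.dt_ramp is not None and not self.dt_ramp > 0:
            raise ValidationError("dt_ramp must be > 0")
        if self.dt_hold is not None and not self.dt_hold > 0:
            raise ValidationError("dt_hold must be > 0")
        if not 0.0 < self.newton_tol <= 1e-3:
            raise ValidationError("newton_tol must lie in (0, 1e-3]")
        if self.max_newton_iter < 1:
            raise ValidationError("max_newton_iter must be >= 1")
        if self.permeability_frame not in ("spatial", "material"):
            raise ValidationError(
                "permeability_frame must be 'spatial' or 'material'"
            )
        if not self.hold_growth > 1.0:
            raise ValidationError("hold_growth must be > 1")
        if self.substeps < 1:
            raise ValidationError("substeps must be >= 1")
        if self.first_step_substeps < 0:
            raise ValidationError("first_step_substeps must be >= 0")

    def resolve(self, protocol: LoadingProtocol) -> "SolverSettings":
        """Fill protocol-dependent defaults and check step-count invariants."""
        dt_ramp = self.dt_ramp or protocol.ramp_duration / 50.0
        dt_hold = self.dt_hold or max(protocol.hold_duration / 100.0, dt_ramp)
        if protocol.ramp_duration / dt_ramp < 10.0 - 1e-12:
            raise ValidationError("the ramp must contain at least 10 time steps")
        return replace(self, dt_ramp=dt_ramp, dt_hold=dt_hold)


@dataclass(frozen=True)
class ConsolidationState:
    """Spatial fields at one instant on the fixed material-frame grid.

    ``material_coordinates`` are cell centres; ``stretch_field`` and
    ``pressure_field`` are the cell values.  The drained top face carries
    p = 0 whenever drainage is active; :meth:`pressure_profile` returns the
    fields extended with the boundary values (p(0) from the sealed-face
    zero-gradient condition, p(H) = 0).
    """

    time: float
    height: float
    material_coordinates: np.ndarray
    stretch_field: np.ndarray
    pressure_field: np.ndarray
    drained_top: bool = True

    def pressure_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(Z, p) including both boundary faces."""
        Z = np.concatenate(([0.0], self.material_coordinates, [self.height]))
        p_top = 0.0 if self.drained_top else float(self.pressure_field[-1])
        p = np.concatenate(
            ([float(self.pressure_field[0])], self.pressure_field, [p_top])
        )
        return Z, p

    def mixture_volume(self) -> float:
        """integral(lam) dZ per unit cross-section, m (midpoint quadrature)."""
        dZ = self.height / self.stretch_field.size
        return float(np.sum(self.stretch_field) * dZ)


@dataclass
class StressHistory:
    """Time series of the monitored quantities for one simulation.

    All stresses are SI and tension-positive (compression negative);
    ``bottom_effective_stress`` is positive in compression by the
    ``p - sigma_zz`` reconstruction.  ``cumulative_outflow`` is the fluid
    volume expelled through the top face per unit cross-section, m.
    """

    times: np.ndarray
    total_stress: np.ndarray
    bottom_pressure: np.ndarray
    bottom_effective_stress: np.ndarray
    cumulative_outflow: np.ndarray
    n_newton_total: int
    converged: bool
    material_label: str = ""
    variant: str = ""
    protocol_label: str = ""
    snapshots: list[ConsolidationState] | None = None

    @property
    def peak_effective(self) -> float:
        """max over times of |bottom effective stress|, Pa."""
        return float(np.max(np.abs(self.bottom_effective_stress)))

    @property
    def end_effective(self) -> float:
        """Final-time bottom effective stress, Pa."""
        return float(self.bottom_effective_stress[-1])


def effective_stress(p, sigma_zz):
    """Bottom-layer effective stress ``p - sigma_zz``, Pa.

    ``sigma_zz`` is the axial skeleton (drained effective) stress in the
    tension-positive convention, so the result is positive in compression:
    with the load fully drained (p = 0, sigma_zz = -100 Pa) it is 100 Pa;
    with the load fully on the fluid (sigma_zz = 0, p = 50 Pa) it is 50 Pa.
    """
    return p - sigma_zz


def _time_grid(protocol: LoadingProtocol, settings: SolverSettings) -> np.ndarray:
    """t = 0, uniform ramp steps, geometrically growing hold steps."""
    n_ramp = max(int(round(protocol.ramp_duration / settings.dt_ramp)), 10)
    times = list(np.linspace(0.0, protocol.ramp_duration, n_ramp + 1))
    t_end = protocol.ramp_duration + protocol.hold_duration
    dt = settings.dt_ramp
    while times[-1] < t_end - 1e-12 * t_end:
        dt = min(dt * settings.hold_growth, settings.dt_hold)
        times.append(min(times[-1] + dt, t_end))
    return np.asarray(times)


def _integration_grid(
    times: np.ndarray, ramp_end: float, substeps: int, first_step_substeps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Integration times plus a mask marking the recorded output times.

    Backward Euler is first order, and the consolidation response has
    square-root-of-time behaviour after each rate discontinuity of the
    prescribed displacement (the ramp start and the ramp/hold transition),
    where the pointwise error of a single implicit step does not vanish with
    the step size.  Every output interval is therefore subdivided uniformly
    by ``substeps``, and the interval that immediately follows a
    discontinuity by the larger ``first_step_substeps``; the extra points
    are internal only and are not recorded.
    """
    pieces = [np.asarray([times[0]])]
    record = [np.asarray([True])]
    for k in range(1, times.size):
        a, b = times[k - 1], times[k]
        after_kink = k == 1 or abs(a - ramp_end) <= 1e-12 * max(ramp_end, 1.0)
        n_sub = max(first_step_substeps if after_kink else substeps, 1)
        inner = np.linspace(a, b, n_sub + 1)[1:]
        pieces.append(inner)
        rec = np.zeros(inner.size, dtype=bool)
        rec[-1] = True
        record.append(rec)
    return np.concatenate(pieces), np.concatenate(record)


def _effective_permeability(
    material: HydrogelMaterial, lam: np.ndarray, frame: str
) -> tuple[np.ndarray, np.ndarray]:
    """Material-grid conductivity k_eff(lam) and its derivative.

    Spatial frame: the power law is the true (spatial) permeability, and the
    1D pull-back to the material grid divides by lam, giving
    ``k0 lam**(M-1)``; material frame applies ``k0 lam**M`` directly.
    """
    m = material.M if frame == "material" else material.M - 1.0
    k = material.k0 * lam**m
    dk = material.k0 * m * lam ** (m - 1.0)
    return k, dk


def _sealed_simulate(
    material: HydrogelMaterial,
    variant: ModelVariant,
    protocol: LoadingProtocol,
    settings: SolverSettings,
    store_snapshots: bool,
) -> StressHistory:
    """Both faces impermeable: the incompressible mixture cannot change
    volume, so only a vanishing prescribed settlement is admissible and the
    skeleton stays undeformed (any imposed load would be carried entirely by
    an indeterminate uniform pore pressure, which is gauged to zero here)."""
    if protocol.applied_strain * protocol.height > 1e-9 * protocol.height:
        raise SolverError(
            "sealed boundaries: incompressible constituents cannot accommodate "
            f"a prescribed compression of {protocol.applied_strain:.3g}"
        )
    times = _time_grid(protocol, settings)
    zeros = np.zeros_like(times)
    N = settings.n_elements
    dZ = protocol.height / N
    centers = (np.arange(N) + 0.5) * dZ
    snaps = None
    if store_snapshots:
        snaps = [
            ConsolidationState(
                time=float(t),
                height=protocol.height,
                material_coordinates=centers,
                stretch_field=np.ones(N),
                pressure_field=np.zeros(N),
                drained_top=False,
            )
            for t in times
        ]
    return StressHistory(
        times=times,
        total_stress=zeros.copy(),
        bottom_pressure=zeros.copy(),
        bottom_effective_stress=zeros.copy(),
        cumulative_outflow=zeros.copy(),
        n_newton_total=0,
        converged=True,
        material_label=material.label,
        variant=variant.value,
        protocol_label=protocol.label,
        snapshots=snaps,
    )


def simulate(
    material: HydrogelMaterial,
    variant: ModelVariant | str,
    protocol: LoadingProtocol,
    settings: SolverSettings | None = None,
    store_snapshots: bool = False,
) -> StressHistory:
    """Run one ramp-hold confined-compression consolidation simulation.

    Returns the :class:`StressHistory` monitored at the impermeable bottom
    layer; with ``store_snapshots`` the full stretch/pressure fields at every
    time step are attached.

    Raises :class:`SolverError` (naming the failing step) if Newton does not
    converge, and :class:`ConstitutiveInstabilityError` if the constitutive
    tangent loses positivity.
    """
    variant = ModelVariant.coerce(variant)
    settings = (settings or SolverSettings()).resolve(protocol)
    if not settings.drained_top:
        return _sealed_simulate(material, variant, protocol, settings, store_snapshots)

    N = settings.n_elements
    H = protocol.height
    dZ = H / N
    centers = (np.arange(N) + 0.5) * dZ
    times = _time_grid(protocol, settings)
    t_int, record = _integration_grid(
        times,
        protocol.ramp_duration,
        settings.substeps,
        settings.first_step_substeps,
    )

    lam = np.ones(N)
    s = 0.0  # total axial stress, Pa (tension-positive)
    outflow = 0.0
    n_newton_total = 0

    total_stress = [0.0]
    bottom_pressure = [0.0]
    bottom_eff = [0.0]
    cum_outflow = [0.0]
    snaps: list[ConsolidationState] | None = None
    if store_snapshots:
        snaps = [
            ConsolidationState(
                time=0.0,
                height=H,
                material_coordinates=centers,
                stretch_field=lam.copy(),
                pressure_field=np.zeros(N),
            )
        ]

    for n in range(1, t_int.size):
        t = t_int[n]
        dt = t - t_int[n - 1]
        target = H - protocol.displacement(t)
        lam_n = lam.copy()
        lam_new = lam.copy()
        s_new = s
        norm0 = None
        converged_step = False
        for it in range(settings.max_newton_iter):
            R, J_mat, q_top, p = _residual_jacobian(
                material,
                variant,
                lam_new,
                lam_n,
                s_new,
                dt,
                dZ,
                target,
                settings.permeability_frame,
            )
            # dimensionless residual norm: strain units for mass rows,
            # fraction of H for the constraint row
            norm = max(np.max(np.abs(R[:-1])) / dZ, abs(R[-1]) / H)
            if norm0 is None:
                norm0 = max(norm, 1.0)
            if norm < settings.newton_tol:
                converged_step = True
                break
            dx = np.linalg.solve(J_mat, -R)
            step_scale = 1.0
            # keep stretches physical
            lam_trial = lam_new + dx[:-1]
            while np.any(lam_trial <= 0.05) and step_scale > 1e-4:
                step_scale *= 0.5
                lam_trial = lam_new + step_scale * dx[:-1]
            lam_new = lam_trial
            s_new = s_new + step_scale * dx[-1]
            n_newton_total += 1
        if not converged_step:
            raise SolverError(
                f"Newton failed to converge at step {n} (t = {t:.6g} s) "
                f"after {settings.max_newton_iter} iterations "
                f"(residual {norm:.3e})"
            )
        lam, s = lam_new, s_new
        outflow += dt * q_top
        logger.debug(
            "step %d t=%.4g s sigma=%.6g Pa outflow=%.4g m newton_it=%d",
            n,
            t,
            s,
            outflow,
            it,
        )

        if not record[n]:
            continue
        sigma_e_bottom = float(confined_stress(variant, material, lam[0]))
        total_stress.append(s)
        bottom_pressure.append(float(p[0]))
        bottom_eff.append(float(effective_stress(p[0], sigma_e_bottom)))
        cum_outflow.append(outflow)
        if store_snapshots:
            snaps.append(
                ConsolidationState(
                    time=float(t),
                    height=H,
                    material_coordinates=centers,
                    stretch_field=lam.copy(),
                    pressure_field=p.copy(),
                )
            )

    history = StressHistory(
        times=times,
        total_stress=np.asarray(total_stress),
        bottom_pressure=np.asarray(bottom_pressure),
        bottom_effective_stress=np.asarray(bottom_eff),
        cumulative_outflow=np.asarray(cum_outflow),
        n_newton_total=n_newton_total,
        converged=True,
        material_label=material.label,
        variant=variant.value,
        protocol_label=protocol.label,
        snapshots=snaps,
    )
    logger.info(
        "%s / %s / %s: peak %.4g kPa, end %.4g kPa, %d Newton iterations",
        protocol.label,
        material.label,
        variant.value,
        history.peak_effective / 1e3,
        history.end_effective / 1e3,
        n_newton_total,
    )
    return history


def _residual_jacobian(
    material: HydrogelMaterial,
    variant: ModelVariant,
    lam: np.ndarray,
    lam_n: np.ndarray,
    s: float,
    dt: float,
    dZ: float,
    target: float,
    frame: str,
):
    """Backward-Euler residual and analytic Jacobian.

    Unknowns ``x = (lam_1..lam_N, sigma_total)``.  Mass rows:
    ``(lam - lam_n) dZ + dt (q_out - q_in)``; constraint row:
    ``sum(lam) dZ - target``.  Interface fluxes use arithmetic-mean
    conductivities; the drained top face uses a half-cell gradient to the
    p = 0 surface.
    """
    N = lam.size
    sig_e = np.asarray(confined_stress(variant, material, lam))
    T = np.asarray(confined_tangent(variant, material, lam))
    if np.any(T <= 0.0):
        raise ConstitutiveInstabilityError(
            "non-positive constitutive tangent encountered "
            f"(min {float(np.min(T)):.3e} Pa at stretch "
            f"{float(lam[np.argmin(T)]):.4f})"
        )
    p = sig_e - s
    k, dk = _effective_permeability(material, lam, frame)

    # interface conductivities (arithmetic mean) and fluxes, +Z positive
    k_if = 0.5 * (k[:-1] + k[1:])
    dp = p[1:] - p[:-1]
    q_int = -k_if * dp / dZ  # flux between cell i-1 and i, i = 1..N-1
    k_top = k[-1]
    q_top = 2.0 * k_top * p[-1] / dZ  # outflow through the drained surface

    q = np.empty(N + 1)
    q[0] = 0.0
    q[1:N] = q_int
    q[N] = q_top

    R = np.empty(N + 1)
    R[:-1] = (lam - lam_n) * dZ + dt * (q[1:] - q[:-1])
    R[-1] = np.sum(lam) * dZ - target

    J = np.zeros((N + 1, N + 1))
    idx = np.arange(N)
    J[idx, idx] = dZ

    # interior flux derivatives
    # q_i = -k_if_i (p_i - p_{i-1}) / dZ ; i = 1..N-1 (cells i-1, i)
    dq_dlam_left = -(0.5 * dk[:-1] * dp - k_if * T[:-1]) / dZ
    dq_dlam_right = -(0.5 * dk[1:] * dp + k_if * T[1:]) / dZ

    # R_e gains +dt*q_{e+1} and -dt*q_e
    # contribution of interior interface i to R_{i-1} (as q_{e+1}) and R_i (as q_e)
    i = np.arange(1, N)
    np.add.at(J, (i - 1, i - 1), dt * dq_dlam_left)
    np.add.at(J, (i - 1, i), dt * dq_dlam_right)
    np.add.at(J, (i, i - 1), -dt * dq_dlam_left)
    np.add.at(J, (i, i), -dt * dq_dlam_right)

    # top flux derivatives enter R_{N-1} with +dt
    dqtop_dlam = 2.0 * (dk[-1] * p[-1] + k_top * T[-1]) / dZ
    dqtop_ds = -2.0 * k_top / dZ
    J[N - 1, N - 1] += dt * dqtop_dlam
    J[N - 1, N] += dt * dqtop_ds

    # constraint row
    J[N, :N] = dZ
    J[N, N] = 0.0
    return R, J, q_top, p


def mass_balance_check(
    history: StressHistory, snapshots: list[ConsolidationState] | None = None
) -> float:
    """Relative mixture-volume imbalance at the final time.

    ``|(H - integral(lam) dZ) - cumulative_outflow| / max(outflow, tiny)``.
    Below 1e-4 for a converged run; exactly conservative schemes give
    round-off-level values.
    """
    snapshots = snapshots if snapshots is not None else history.snapshots
    if not snapshots:
        raise ValidationError("mass_balance_check requires consolidation snapshots")
    final = snapshots[-1]
    if not math.isclose(final.time, history.times[-1], rel_tol=1e-9, abs_tol=1e-12):
        raise ValidationError("snapshots do not cover the full simulation")
    H = final.height
    lost = H - final.mixture_volume()
    out = float(history.cumulative_outflow[-1])
    return abs(lost - out) / max(abs(out), 1e-30)
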