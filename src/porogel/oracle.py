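"""Small-strain linear consolidation series solutions.

Linearising the biphasic confined-compression problem (constant permeability
``k``, aggregate modulus ``HA = K + 4G/3``) reduces it to one-dimensional
consolidation with coefficient ``c = HA k`` over the drainage path ``H``
(sealed face at Z = 0, drained face p = 0 at Z = H); ``tau = H**2 / c`` is
the characteristic pressure-dissipation time.

Two classical boundary-value problems are covered, and they are *not* the
same solution:

* **Step load** (:func:`step_strain_pressure`): a total stress ``HA eps0``
  applied instantaneously and held.  The excess pore pressure starts uniform
  at ``HA eps0`` and dissipates on the mixed cosine modes
  ``alpha_n = (2n - 1) pi / 2`` — Terzaghi's textbook solution.
* **Displacement control** (:func:`ramp_hold_total_stress`,
  :func:`ramp_hold_bottom_pressure`): the platen displacement is prescribed
  (linear ramp to compressive strain ``eps0`` over ``t0``, then held).
  Because the total stress is the unknown here, the problem is cleanest in
  the displacement field, which itself obeys the heat equation with
  Dirichlet data, ``u_t = c u_ZZ``, ``u(0) = 0``, ``u(H) = -delta(t)``;
  eigenmodes are ``sin(n pi Z / H)`` with rates ``mu_n = n**2 pi**2 / tau``.
  This is the configuration the nonlinear solver simulates, and the series
  here is its independent verification surface (with M = 0 and vanishing
  strain the nonlinear problem degenerates to exactly this one).

Duhamel superposition of the boundary ramp gives, with ``m = min(t, t0)``::

    sigma(t) = -HA eps0 [ m/t0
               + sum_n (2 tau / (n^2 pi^2 t0)) (e^{-mu_n (t-m)} - e^{-mu_n t}) ]
    p(0, t)  =  HA eps0   sum_{n odd} (4 tau / (n^2 pi^2 t0))
                                       (e^{-mu_n (t-m)} - e^{-mu_n t})

As ``t0 -> 0`` the bracket tends to ``1 + 2 sum_n e^{-mu_n t}`` — the
instantaneous-displacement limit, whose initial stress diverges (an
incompressible biphasic layer shows an impulsive force under a true
displacement step), which is why the step-load idealisation above is the one
with a finite initial pressure.

Sign conventions match the rest of the package: stress compression-negative,
``eps0`` a positive compressive fraction, pore pressure positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constitutive import HydrogelMaterial, ModelVariant, aggregate_modulus
from .errors import ValidationError

__all__ = [
    "LinearPoroParams",
    "linearise",
    "step_strain_pressure",
    "ramp_hold_total_stress",
    "ramp_hold_bottom_pressure",
]


@dataclass(frozen=True)
class LinearPoroParams:
    """Parameters of the linearised confined-compression problem.

    HA : aggregate modulus K + 4G/3, Pa.
    k  : constant hydraulic permeability, m^2/(Pa s).
    H  : drainage path length, m.
    c  : consolidation coefficient HA * k, m^2/s (derived).
    """

    HA: float
    k: float
    H: float
    c: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.HA > 0 and self.k > 0 and self.H > 0):
            raise ValidationError("HA, k and H must all be positive")
        object.__setattr__(self, "c", self.HA * self.k)

    @property
    def tau(self) -> float:
        """Characteristic consolidation time H^2 / c, s."""
        return self.H**2 / self.c


def linearise(
    material: HydrogelMaterial, variant: ModelVariant | str, height: float
) -> LinearPoroParams:
    """LinearPoroParams of a material/variant about the reference state."""
    return LinearPoroParams(
        HA=aggregate_modulus(variant, material), k=material.k0, H=height
    )


def _truncation_check(terms: np.ndarray) -> None:
    """Warn when the series has not decayed to 1e-10 of its leading term."""
    lead = np.max(np.abs(terms[..., 0]))
    last = np.max(np.abs(terms[..., -1]))
    if lead > 0 and last > 1e-10 * lead:
        warnings.warn(
            "series truncation: last retained term exceeds 1e-10 of the "
            "leading term; increase n_terms or avoid t -> 0",
            RuntimeWarning,
            stacklevel=3,
        )


def step_strain_pressure(
    params: LinearPoroParams, eps0: float, Z, t, n_terms: int = 200
):
    """Terzaghi pore pressure after a step in total load ``HA eps0``, Pa.

    The instantaneous (undrained) state carries the whole load in the fluid,
    ``p(Z, 0+) = HA eps0`` for Z < H, and consolidation proceeds toward the
    drained strain ``eps0``::

        p(Z, t) = HA eps0 sum_n (2 (-1)**(n+1) / alpha_n)
                  cos(alpha_n Z / H) exp(-alpha_n**2 t / tau)

    with ``alpha_n = (2n - 1) pi / 2``.  Satisfies p(H, t) = 0,
    dp/dZ(0, t) = 0 and p -> 0 as t -> infinity.  ``Z`` and ``t`` broadcast.
    """
    Z = np.asarray(Z, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(Z < 0) or np.any(Z > params.H):
        raise ValidationError("Z must lie in [0, H]")
    if np.any(t <= 0):
        raise ValidationError("t must be > 0 (the series is for t > 0)")
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    n = np.arange(1, n_terms + 1)
    a = (2.0 * n - 1.0) * np.pi / 2.0
    coeff = 2.0 * (-1.0) ** (n + 1) / a
    terms = (
        coeff
        * np.cos(a * (Z[..., None] / params.H))
        * np.exp(-(a**2) * t[..., None] / params.tau)
    )
    _truncation_check(terms)
    out = params.HA * eps0 * np.sum(terms, axis=-1)
    return out if out.ndim else float(out)


def _mode_relaxation_sum(
    params: LinearPoroParams,
    t0: float,
    x: np.ndarray,
    n_terms: int,
    odd_only: bool,
) -> np.ndarray:
    """``sum_n w / (mu_n t0) * exp(-mu_n x)`` over the Dirichlet modes.

    ``w = 2`` over all modes, or ``w = 4`` over odd modes only.  The
    elapsed-time argument ``x >= 0`` is measured from the relevant rate
    discontinuity.  At ``x = 0`` the full sums have closed forms
    (``tau/(3 t0)`` and ``tau/(2 t0)`` respectively, via
    ``sum 1/n**2 = pi**2/6`` and ``sum_odd 1/n**2 = pi**2/8``), which are
    used exactly so the truncated tail never enters; for ``x > 0`` the
    series converges exponentially.
    """
    n = np.arange(1, n_terms + 1)
    if odd_only:
        n = n[n % 2 == 1]
        exact0 = params.tau / (2.0 * t0)
        w = 4.0
    else:
        exact0 = params.tau / (3.0 * t0)
        w = 2.0
    mu = n**2 * np.pi**2 / params.tau
    x = np.asarray(x, dtype=float)
    terms = (w / (mu * t0)) * np.exp(-mu * x[..., None])
    # truncation bound for the smallest positive x requested
    x1 = np.atleast_1d(x)
    pos = x1[x1 > 0]
    if pos.size:
        a = np.pi**2 * float(pos.min()) / params.tau
        n_max = float(n[-1])
        tail = (w * params.tau / (np.pi**2 * t0)) * np.exp(
            -((n_max + 1.0) ** 2) * a
        ) / n_max
        if tail > 1e-10 * exact0:
            warnings.warn(
                "series truncation: the retained tail exceeds 1e-10 of the "
                "leading term; increase n_terms or avoid t -> 0+",
                RuntimeWarning,
                stacklevel=4,
            )
    out = np.sum(terms, axis=-1)
    return np.where(x == 0.0, exact0, out)


def _check_ramp_args(t0: float, times: np.ndarray, n_terms: int) -> None:
    if t0 <= 0:
        raise ValidationError("ramp duration t0 must be > 0")
    if np.any(times < 0):
        raise ValidationError("times must be >= 0")
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")


def ramp_hold_total_stress(
    params: LinearPoroParams, eps0: float, t0: float, times, n_terms: int = 200
):
    """Total axial stress for a displacement ramp to ``eps0`` over ``t0``.

    Compression negative; zero at t = 0; tends to the drained equilibrium
    ``-HA eps0`` at long times with no overshoot for slow ramps.  The
    history shows the classic ramp-hold relaxation: the stress overshoots
    the drained value during a fast ramp (pore pressure carries the excess)
    and relaxes back as the pressure dissipates.  Written as
    ``sigma = -HA eps0 [ m/t0 + A(t - m) - A(t) ]`` with
    ``A(x) = sum_n (2/(mu_n t0)) e^{-mu_n x}`` so each series term decays
    exponentially (``A(0) = tau/(3 t0)`` exactly).
    """
    times = np.asarray(times, dtype=float)
    _check_ramp_args(t0, times, n_terms)
    m = np.minimum(times, t0)
    A_rel = _mode_relaxation_sum(params, t0, times - m, n_terms, odd_only=False)
    A_full = _mode_relaxation_sum(params, t0, times, n_terms, odd_only=False)
    out = -params.HA * eps0 * (m / t0 + A_rel - A_full)
    return out if out.ndim else float(out)


def ramp_hold_bottom_pressure(
    params: LinearPoroParams, eps0: float, t0: float, times, n_terms: int = 200
):
    """Pore pressure at the sealed bottom face for the same ramp-hold input.

    Only odd modes reach the bottom face:
    ``p(0, t) = HA eps0 [ B(t - m) - B(t) ]`` with
    ``B(x) = sum_{n odd} (4/(mu_n t0)) e^{-mu_n x}``, ``B(0) = tau/(2 t0)``.
    """
    times = np.asarray(times, dtype=float)
    _check_ramp_args(t0, times, n_terms)
    m = np.minimum(times, t0)
    B_rel = _mode_relaxation_sum(params, t0, times - m, n_terms, odd_only=True)
    B_full = _mode_relaxation_sum(params, t0, times, n_terms, odd_only=True)
    out = params.HA * eps0 * (B_rel - B_full)
    return out if out.ndim else float(out)
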