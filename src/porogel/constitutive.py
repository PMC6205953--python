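"""Hyperelastic skeleton models and strain-dependent permeability.

Collagen hydrogels are modelled as biphasic (poroelastic) continua whose
drained solid skeleton follows one of three Neo-Hookean strain-energy
variants.  This module evaluates those energies, their axial Cauchy stress
and tangent under *confined uniaxial kinematics* — rigid impermeable lateral
walls, so the deformation gradient is ``F = diag(1, 1, lam)`` and the volume
ratio is ``J = lam`` — together with the van der Voet strain-dependent
hydraulic permeability ``k(J) = k0 * J**M``.

The three variants:

``NH1``
    Incompressible-form Neo-Hookean, ``W = C10 (I1 - 3)``, completed here to
    the minimal unconstrained energy with a stress-free reference state,
    ``W = C10 (I1 - 3) - 2 C10 ln J``, i.e. effective Cauchy stress
    ``sigma = (2 C10 / J)(B - I)``.  A consolidating biphasic skeleton must
    change volume as fluid leaves, so a hard J = 1 constraint is not
    admissible; this completion keeps the stiffness parameter and deviatoric
    response of the incompressible form.
``NH2``
    Compressible Neo-Hookean in shear/bulk moduli (Bonet-Wood form),
    ``W = G/2 (I1 - 3) - G ln J + (K - 2G/3)/2 (ln J)**2`` giving
    ``sigma = (G/J)(B - I) + ((K - 2G/3)/J) ln J * I``.
``NH3``
    Generic-compressibility Neo-Hookean on the isochoric first invariant,
    ``W = C10 (I1bar - 3) + (1/D1)(J - 1)**2``.

All quantities are SI (Pa, m, s) internally; stresses are tension-positive,
so compression is negative.
"""

from __future__ import annotations

import decimal
import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import IncompressibleLimitError, KinematicsError, ValidationError

__all__ = [
    "HydrogelMaterial",
    "ModelVariant",
    "derive_material",
    "table1_materials",
    "confined_stress",
    "confined_tangent",
    "strain_energy",
    "permeability",
    "aggregate_modulus",
]

#: relative slack allowed between stored parameters and their defining
#: relations (C10 = G/2, D1 = 2/K, K from (G, nu)); covers values that were
#: rounded to 3-4 printed digits.
_ROUNDING_RTOL = 5e-3


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(x)).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    )


class ModelVariant(str, enum.Enum):
    """The three Neo-Hookean constitutive variants."""

    NH1 = "NH1"
    NH2 = "NH2"
    NH3 = "NH3"

    @classmethod
    def coerce(cls, value: "ModelVariant | str") -> "ModelVariant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValidationError(
                f"unknown model variant {value!r}; expected one of "
                f"{[v.value for v in cls]}"
            ) from None


@dataclass(frozen=True)
class HydrogelMaterial:
    """Full constitutive parameter set for one collagen concentration.

    Parameters
    ----------
    label : str
        Human-readable identifier, e.g. ``"collagen 0.30%"``.
    G, K, C10 : float
        Shear modulus, drained bulk modulus and Neo-Hookean stiffness
        parameter, Pa.
    D1 : float
        Compressibility parameter of the generic Neo-Hookean form, 1/Pa.
    k0 : float
        Zero-strain hydraulic permeability, m^2/(Pa s) (identically
        m^4/(N s)).
    M : float
        Dimensionless exponent of the strain-dependent permeability law.
    nu : float
        Drained Poisson's ratio, in [0, 0.5).
    """

    label: str
    G: float
    K: float
    C10: float
    D1: float
    k0: float
    M: float
    nu: float

    def __post_init__(self) -> None:
        if not self.G > 0:
            raise ValidationError(f"{self.label}: shear modulus G must be > 0")
        if not self.K > 0:
            raise ValidationError(f"{self.label}: bulk modulus K must be > 0")
        if not self.k0 > 0:
            raise ValidationError(f"{self.label}: permeability k0 must be > 0")
        if self.M < 0:
            raise ValidationError(f"{self.label}: permeability exponent M must be >= 0")
        if not 0.0 <= self.nu < 0.5:
            raise IncompressibleLimitError(
                f"{self.label}: drained Poisson's ratio must lie in [0, 0.5)"
            )
        checks = (
            ("C10 = G/2", self.C10, self.G / 2.0),
            ("D1 = 2/K", self.D1, 2.0 / self.K),
            (
                "K = 2G(1+nu)/(3(1-2nu))",
                self.K,
                2.0 * self.G * (1.0 + self.nu) / (3.0 * (1.0 - 2.0 * self.nu)),
            ),
        )
        for name, actual, expected in checks:
            if abs(actual - expected) > _ROUNDING_RTOL * abs(expected):
                raise ValidationError(
                    f"{self.label}: inconsistent parameter set, {name} violated "
                    f"({actual:.6g} vs {expected:.6g})"
                )

    @property
    def lame_lambda(self) -> float:
        """First Lame parameter K - 2G/3, Pa."""
        return self.K - 2.0 * self.G / 3.0


def derive_material(
    G: float, nu: float, k0: float, M: float, label: str = "derived"
) -> HydrogelMaterial:
    """Build a full parameter set from (G, nu, k0, M).

    C10 = G/2; K = 2G(1+nu)/(3(1-2nu)); D1 = 2/K.  Raises
    :class:`IncompressibleLimitError` for nu >= 0.5 (K is undefined there)
    and :class:`ValidationError` for non-positive G or k0.
    """
    if not G > 0:
        raise ValidationError("shear modulus G must be > 0")
    if not k0 > 0:
        raise ValidationError("permeability k0 must be > 0")
    if M < 0:
        raise ValidationError("permeability exponent M must be >= 0")
    if nu >= 0.5:
        raise IncompressibleLimitError(
            "nu >= 0.5: drained bulk modulus is undefined in the incompressible limit"
        )
    if nu < 0:
        raise ValidationError("drained Poisson's ratio must be >= 0")
    K = 2.0 * G * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
    return HydrogelMaterial(
        label=label, G=G, K=K, C10=G / 2.0, D1=2.0 / K, k0=k0, M=M, nu=nu
    )


def _load_material_blocks() -> dict:
    text = resources.files("porogel.data").joinpath("materials.yaml").read_text()
    return yaml.safe_load(text)


def material_from_block(block: dict) -> HydrogelMaterial:
    """Construct a material from a unit-suffixed config block (kPa -> Pa)."""
    required = {
        "label",
        "G_kPa",
        "K_kPa",
        "C10_kPa",
        "D1_per_kPa",
        "k0_m4_per_Ns",
        "M",
        "nu",
    }
    unknown = set(block) - required
    if unknown:
        raise ValidationError(f"unknown material keys: {sorted(unknown)}")
    missing = required - set(block)
    if missing:
        raise ValidationError(f"missing material keys: {sorted(missing)}")
    return HydrogelMaterial(
        label=str(block["label"]),
        G=float(block["G_kPa"]) * 1e3,
        K=float(block["K_kPa"]) * 1e3,
        C10=float(block["C10_kPa"]) * 1e3,
        D1=float(block["D1_per_kPa"]) * 1e-3,
        k0=float(block["k0_m4_per_Ns"]),
        M=float(block["M"]),
        nu=float(block["nu"]),
    )


def table1_materials() -> list[HydrogelMaterial]:
    """The bundled 0.20 / 0.30 / 0.40% collagen parameter sets (SI units).

    Round-tripping each set through :func:`derive_material` from its (G, nu)
    reproduces every stored value at the precision it is printed with in the
    bundled fixture (4 decimals for kPa cells, 3-4 significant figures for
    D1), which is asserted here on every load.
    """
    blocks = _load_material_blocks()
    materials = []
    for key in ("c020", "c030", "c040"):
        mat = material_from_block(blocks[key])
        derived = derive_material(mat.G, mat.nu, mat.k0, mat.M, label=mat.label)
        for printed, exact, decimals in (
            (mat.C10 / 1e3, derived.C10 / 1e3, 4),
            (mat.K / 1e3, derived.K / 1e3, 4),
            (mat.D1 * 1e3, derived.D1 * 1e3, 3),
        ):
            if abs(round_half_up(exact, decimals) - printed) > 1e-9:
                raise ValidationError(
                    f"{mat.label}: fixture value {printed} does not round-trip "
                    f"against derived value {exact!r}"
                )
        materials.append(mat)
    return materials


def _as_positive_stretch(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise KinematicsError("axial stretch must be > 0")
    return lam


def confined_stress(
    variant: ModelVariant | str, material: HydrogelMaterial, lam
) -> np.ndarray | float:
    """Axial effective Cauchy stress of the drained skeleton, Pa.

    Confined uniaxial kinematics: ``F = diag(1, 1, lam)``, ``J = lam``.
    Negative in compression; exactly zero at ``lam = 1`` for every variant.
    Accepts scalar or array ``lam``.
    """
    variant = ModelVariant.coerce(variant)
    lam = _as_positive_stretch(lam)
    if variant is ModelVariant.NH1:
        out = (2.0 * material.C10 / lam) * (lam**2 - 1.0)
    elif variant is ModelVariant.NH2:
        out = (material.G / lam) * (lam**2 - 1.0) + (
            material.lame_lambda / lam
        ) * np.log(lam)
    else:  # NH3
        out = (4.0 * material.C10 / 3.0) * lam ** (-5.0 / 3.0) * (lam**2 - 1.0) + (
            2.0 / material.D1
        ) * (lam - 1.0)
    return out if out.ndim else float(out)


def confined_tangent(
    variant: ModelVariant | str, material: HydrogelMaterial, lam
) -> np.ndarray | float:
    """Analytic derivative d(sigma_e_zz)/d(lam) of :func:`confined_stress`, Pa.

    At ``lam = 1`` this is the small-strain aggregate modulus: ``K + 4G/3``
    for NH2 and NH3, ``4 C10 = 2G`` for the NH1 completion.
    """
    variant = ModelVariant.coerce(variant)
    lam = _as_positive_stretch(lam)
    if variant is ModelVariant.NH1:
        out = 2.0 * material.C10 * (1.0 + lam**-2)
    elif variant is ModelVariant.NH2:
        out = material.G * (1.0 + lam**-2) + material.lame_lambda * (
            1.0 - np.log(lam)
        ) * lam**-2
    else:  # NH3
        out = (4.0 * material.C10 / 9.0) * lam ** (-8.0 / 3.0) * (lam**2 + 5.0) + (
            2.0 / material.D1
        )
    return out if out.ndim else float(out)


def strain_energy(
    variant: ModelVariant | str, material: HydrogelMaterial, lam
) -> np.ndarray | float:
    """Strain-energy density W(lam) per unit reference volume, Pa.

    Under confined kinematics the axial first Piola-Kirchhoff stress equals
    the axial Cauchy stress (reference and current cross-sections coincide),
    so ``confined_stress == dW/dlam`` — a consistency that the test suite
    checks numerically.
    """
    variant = ModelVariant.coerce(variant)
    lam = _as_positive_stretch(lam)
    I1 = 2.0 + lam**2
    lnJ = np.log(lam)
    if variant is ModelVariant.NH1:
        out = material.C10 * (I1 - 3.0) - 2.0 * material.C10 * lnJ
    elif variant is ModelVariant.NH2:
        out = (
            material.G / 2.0 * (I1 - 3.0)
            - material.G * lnJ
            + material.lame_lambda / 2.0 * lnJ**2
        )
    else:  # NH3
        I1_bar = lam ** (-2.0 / 3.0) * I1
        out = material.C10 * (I1_bar - 3.0) + (1.0 / material.D1) * (lam - 1.0) ** 2
    return out if out.ndim else float(out)


def permeability(material: HydrogelMaterial, J) -> np.ndarray | float:
    """Strain-dependent hydraulic permeability ``k0 * J**M``, m^2/(Pa s).

    Equals ``k0`` at J = 1 and decreases under compaction (J < 1) for M > 0.
    """
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0.0):
        raise KinematicsError("volume ratio J must be > 0")
    out = material.k0 * J**material.M
    return out if out.ndim else float(out)


def aggregate_modulus(
    variant: ModelVariant | str, material: HydrogelMaterial
) -> float:
    """Small-strain confined-compression modulus, ``confined_tangent`` at 1."""
    return float(confined_tangent(variant, material, 1.0))
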