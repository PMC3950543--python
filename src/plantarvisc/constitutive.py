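"""Transversely isotropic hyperelastic material point, uniaxial and incompressible.

The tissue is modelled as an incompressible ground matrix (neo-Hookean,
shear stiffness ``mu``) reinforced by collagen fibers aligned with the
loading (proximal-distal) axis.  The fiber family stiffens
exponentially in tension and carries no load in compression.  The
strain energy density, per unit reference volume, is

    W = U_mat(J) + (mu/2) (I1~ - 3)
        + (k / (2 alpha)) [exp(alpha <I4~ - 1>) - alpha <I4~ - 1> - 1]

with modified invariants ``I1~ = tr(C~)`` and ``I4~ = C~ : (M (x) M)``
of the volume-preserving right Cauchy-Green tensor ``C~ = J^(-2/3) C``,
and ``<x> = max(x, 0)`` the tension switch.  The fiber term is written
so that both the energy and its I4-derivative vanish at I4 = 1: the
reference state is stress free and the fibers engage smoothly.

Incompressibility is enforced exactly (J = 1).  Under uniaxial tension
along the fiber axis with symmetric transverse behavior, the transverse
stretches are lam^(-1/2), and the hydrostatic variable p of U_mat is
eliminated analytically by imposing zero stress in the transverse
directions, yielding the closed-form axial Cauchy stress

    sigma(lam) = mu (lam^2 - 1/lam) + k lam^2 [exp(alpha <lam^2 - 1>) - 1].

Stress measures are related at J = 1 by nominal = lam * S_pk2 and
cauchy = lam^2 * S_pk2, with S_pk2 the axial second Piola-Kirchhoff
component.  All stresses are in MPa, stretches dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HyperelasticParams",
    "KinematicState",
    "StressValue",
    "STRESS_MEASURES",
    "kinematics_from_stretch",
    "strain_energy",
    "elastic_axial_stress",
    "convert_stress",
]

STRESS_MEASURES = ("second_pk", "nominal", "cauchy")


@dataclass(frozen=True)
class HyperelasticParams:
    """Ground-matrix and fiber stiffness parameters.

    Parameters
    ----------
    mu : float
        Shear stiffness of the ground matrix at small strains, MPa.
    k : float
        Fiber stiffness scale, MPa.
    alpha : float
        Dimensionless fiber strain-stiffening exponent.
    """

    mu: float
    k: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @classmethod
    def from_dict(cls, d: dict) -> "HyperelasticParams":
        return cls(mu=d["mu_MPa"], k=d["k_MPa"], alpha=d["alpha"])

    def to_dict(self) -> dict:
        return {"mu_MPa": self.mu, "k_MPa": self.k, "alpha": self.alpha}


@dataclass(frozen=True)
class KinematicState:
    """Incompressible uniaxial kinematic state at axial stretch ``lam``."""

    lam: float
    lam_t: float
    I1: float
    I4: float
    J: float = 1.0


@dataclass(frozen=True)
class StressValue:
    """Axial stress in the three standard measures at stretch ``lam`` (MPa)."""

    second_pk: float
    nominal: float
    cauchy: float
    lam: float


def kinematics_from_stretch(lam: float) -> KinematicState:
    """Build the incompressible uniaxial kinematic state for stretch ``lam``.

    The transverse stretches equal ``lam**-0.5`` (volume conservation with
    transverse symmetry), so ``I1 = lam**2 + 2/lam`` and ``I4 = lam**2``
    with the fiber direction fixed along the loading axis.
    """
    if not lam > 0:
        raise ValueError(f"stretch must be positive, got {lam}")
    lam = float(lam)
    lam_t = lam ** -0.5
    return KinematicState(
        lam=lam,
        lam_t=lam_t,
        I1=lam * lam + 2.0 / lam,
        I4=lam * lam,
    )


def _fiber_energy(k: float, alpha: float, I4: float) -> float:
    e = max(I4 - 1.0, 0.0)
    if e == 0.0 or k == 0.0:
        return 0.0
    return k / (2.0 * alpha) * (math.exp(alpha * e) - alpha * e - 1.0)


def strain_energy(hp: HyperelasticParams, ks: KinematicState) -> float:
    """Strain energy density W (MPa) at the given state.

    At J = 1 the volumetric term contributes nothing; the matrix term is
    (mu/2)(I1 - 3) and the fiber term engages only for I4 > 1.
    """
    w_mat = 0.5 * hp.mu * (ks.I1 - 3.0)
    return w_mat + _fiber_energy(hp.k, hp.alpha, ks.I4)


def elastic_axial_stress(hp: HyperelasticParams, lam: float) -> StressValue:
    """Closed-form axial stress under incompressible uniaxial tension.

    The hydrostatic pressure is eliminated by the zero-transverse-stress
    condition, giving the axial Cauchy stress

        sigma = mu (lam^2 - 1/lam) + k lam^2 [exp(alpha <lam^2 - 1>) - 1].

    The fiber contribution vanishes identically for lam <= 1.
    """
    if not lam > 0:
        raise ValueError(f"stretch must be positive, got {lam}")
    lam = float(lam)
    sigma = hp.mu * (lam * lam - 1.0 / lam)
    e = lam * lam - 1.0
    if e > 0.0 and hp.k > 0.0:
        sigma += hp.k * lam * lam * math.expm1(hp.alpha * e)
    return StressValue(
        second_pk=sigma / (lam * lam),
        nominal=sigma / lam,
        cauchy=sigma,
        lam=lam,
    )


def convert_stress(value, lam, from_measure: str, to_measure: str):
    """Convert an axial stress between second_pk/nominal/cauchy at J = 1.

    Accepts scalars or arrays; ``lam`` broadcasts against ``value``.
    """
    for m in (from_measure, to_measure):
        if m not in STRESS_MEASURES:
            raise ValueError(
                f"unknown stress measure {m!r}; expected one of {STRESS_MEASURES}"
            )
    value = np.asarray(value, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    # exponent of lambda relating each measure to second PK
    power = {"second_pk": 0, "nominal": 1, "cauchy": 2}
    out = value * lam ** (power[to_measure] - power[from_measure])
    return out if out.ndim else float(out)
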