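"""Ligand-field decomposition of the Cu(II) hyperfine coupling (DELFT-style).

For a d(x²−y²)-dominated SOMO in a distorted square-pyramidal geometry,
with orbital coefficients a (d(x²−y²)) and b (d(z²)), a² + b² = 1, the
parallel hyperfine component obeys

    A3 = −Pd [ K + (4/7) α²(a²−b²)
               − (3a−3b) Δg2 / (14(a+3b))
               − (3a+3b) Δg1 / (14(a−3b))
               − Δg3 ]

and the isotropic average

    Aiso = Pd [ −K + (Δg1 + Δg2 + Δg3)/3 ]

where Pd is the free-ion dipolar parameter (1180 MHz for Cu(II)),
K the dimensionless Fermi-contact parameter (Fermi contact = −Pd·K),
α² the ground-state spin density on copper, and Δg_n = g_n − 2.0023.

Given experimental g values, a sign-resolved Aiso and a signed A3, these
two relations determine the Fermi contact and α², from which the
Fermi / dipolar / orbital breakdown of the hyperfine coupling follows.
The parallel-direction terms are exact within the model; the
perpendicular terms use the leading-order expressions and are flagged
approximate.

Also here: the substrate-coupling thermodynamic conversion
exp(ΔΔE/RT) turning a copper–superoxide binding-energy difference into
an equilibrium stabilization ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import BOLTZMANN_KCAL
from .spin_core import GTensor

__all__ = [
    "DEFAULT_PD",
    "LigandFieldParams",
    "HyperfineDecomposition",
    "ThermoCoupling",
    "fermi_contact",
    "kappa_from_aiso",
    "a3_from_params",
    "solve_spin_density",
    "decompose_hyperfine",
    "recompose_parallel",
    "dz2_mixing",
    "stability_ratio",
]

#: Cu(II) free-ion dipolar hyperfine parameter, MHz
DEFAULT_PD = 1180.0


@dataclass(frozen=True)
class LigandFieldParams:
    """Symbols of the ligand-field hyperfine equations."""

    Pd: float = DEFAULT_PD  # MHz
    kappa: float = 0.0  # dimensionless Fermi-contact parameter K
    alpha2: float = 1.0  # ground-state Cu spin density
    a: float = 1.0  # d(x2-y2) coefficient
    b: float = 0.0  # d(z2) coefficient
    dg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if abs(self.a**2 + self.b**2 - 1.0) > 1e-9:
            raise ValueError("orbital coefficients must satisfy a^2 + b^2 = 1")
        if not (0.0 <= self.alpha2 <= 1.2):
            raise ValueError("alpha^2 outside [0, 1.2]")
        if self.b**2 > 0.1:
            warnings.warn(f"d(z2) mixing b^2 = {self.b**2:.3f} unusually large")


@dataclass(frozen=True)
class HyperfineDecomposition:
    """Fermi / dipolar / orbital contributions to the Cu hyperfine, MHz.

    ``perp_approximate`` marks the perpendicular entries as leading-order
    estimates (the parallel entries reconstruct the input A3 exactly).
    """

    fermi: float
    dipolar_para: float
    dipolar_perp: float
    orbital_para: float
    orbital_perp: float
    alpha2: float
    perp_approximate: bool = True


@dataclass(frozen=True)
class ThermoCoupling:
    """Copper–superoxide point-energy differences for the five- (dE1) and
    four-coordinate (dE2) sites, kcal/mol."""

    dE1: float = 0.0
    dE2: float = 0.0
    temperature: float = 298.0

    def __post_init__(self):
        if not math.isfinite(self.ddE):
            raise ValueError("ddE must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def ddE(self) -> float:
        return self.dE1 - self.dE2


def fermi_contact(aiso: float, g: GTensor, Pd: float = DEFAULT_PD) -> float:
    """Fermi-contact contribution −Pd·K = Aiso − (Pd/3)·ΣΔg_n, in MHz."""
    if Pd <= 0:
        raise ValueError("Pd must be > 0")
    return aiso - (Pd / 3.0) * sum(g.dg)


def kappa_from_aiso(aiso: float, g: GTensor, Pd: float = DEFAULT_PD) -> float:
    """Dimensionless Fermi-contact parameter K from the Aiso relation."""
    return -fermi_contact(aiso, g, Pd) / Pd


def a3_from_params(alpha2: float, g: GTensor, kappa: float, b2: float,
                   Pd: float = DEFAULT_PD) -> float:
    """Evaluate the rhombic A3 ligand-field expression (signed, MHz)."""
    if not (0.0 <= b2 <= 0.1):
        raise ValueError("b2 must lie in [0, 0.1]")
    a = math.sqrt(1.0 - b2)
    b = math.sqrt(b2)
    dg1, dg2, dg3 = g.dg
    bracket = (kappa
               + 4.0 * alpha2 * (a * a - b * b) / 7.0
               - (3.0 * a - 3.0 * b) * dg2 / (14.0 * (a + 3.0 * b))
               - (3.0 * a + 3.0 * b) * dg1 / (14.0 * (a - 3.0 * b))
               - dg3)
    return -Pd * bracket


def solve_spin_density(A3_signed: float, g: GTensor, kappa: float, b2: float,
                       Pd: float = DEFAULT_PD) -> float:
    """Ground-state Cu spin density α² solving the A3 equation.

    The equation is linear in α², but it is solved by bracketing so that
    inconsistent inputs (no root in [0, 1.2]) fail loudly rather than
    extrapolate.
    """
    lo, hi = 0.0, 1.2
    f = lambda x: a3_from_params(x, g, kappa, b2, Pd) - A3_signed
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"no spin density in [0, 1.2] reproduces A3 = {A3_signed} MHz; "
            "check signs, kappa or b2")
    return brentq(f, lo, hi, xtol=1e-12)


def decompose_hyperfine(g: GTensor, aiso: float, A3_signed: float,
                        b2: float = 0.02, Pd: float = DEFAULT_PD
                        ) -> HyperfineDecomposition:
    """Break the Cu hyperfine into Fermi, dipolar and orbital parts.

    Parallel terms: Fermi contact from the Aiso relation, spin density
    from the A3 equation, dipolar_para = −Pd·(4/7)·α²·(a²−b²), and
    orbital_para as the remainder — so fermi + dipolar_para + orbital_para
    reconstructs the signed A3 exactly.  Perpendicular terms use the
    leading-order expressions (+Pd·(2/7)·α²·(a²−b²) and the mean of the
    in-plane Δg) and are flagged approximate.
    """
    fermi = fermi_contact(aiso, g, Pd)
    kappa = -fermi / Pd
    alpha2 = solve_spin_density(A3_signed, g, kappa, b2, Pd)
    a2mb2 = (1.0 - b2) - b2
    dipolar_para = -Pd * (4.0 / 7.0) * alpha2 * a2mb2
    orbital_para = A3_signed - fermi - dipolar_para
    dipolar_perp = +Pd * (2.0 / 7.0) * alpha2 * a2mb2
    dg1, dg2, _ = g.dg
    orbital_perp = Pd * 0.5 * (dg1 + dg2)
    return HyperfineDecomposition(fermi, dipolar_para, dipolar_perp,
                                  orbital_para, orbital_perp, alpha2)


def recompose_parallel(d: HyperfineDecomposition) -> float:
    """Sum of the parallel-direction contributions; equals the signed A3."""
    return d.fermi + d.dipolar_para + d.orbital_para


#: calibration for the b² surrogate: chosen so that the substrate-free
#: in-plane splitting g2 − g1 = 0.068 maps to b² = 0.02
_B2_SLOPE = 0.02 / 0.068


def dz2_mixing(g: GTensor, mode: str = "fixed", fixed_b2: float = 0.02,
               slope: float = _B2_SLOPE) -> float:
    """d(z²) admixture b² of the ground state.

    mode='fixed' returns ``fixed_b2`` (default 2%, the value estimated
    from the in-plane g splitting for the five-coordinate site).
    mode='estimate' uses a linear surrogate b² = slope·(g2 − g1); the
    slope is calibrated on the five-coordinate anchor and configurable.
    """
    if mode == "fixed":
        return fixed_b2
    if mode == "estimate":
        est = slope * (g.g2 - g.g1)
        if est < 0:
            warnings.warn("negative b^2 estimate clipped to 0")
            return 0.0
        return est
    raise ValueError(f"mode must be 'fixed' or 'estimate', got {mode!r}")


def stability_ratio(tc: ThermoCoupling) -> float:
    """Equilibrium stabilization exp(ΔΔE/RT), assuming ΔΔG ≈ ΔΔE."""
    return math.exp(tc.ddE / (BOLTZMANN_KCAL * tc.temperature))
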