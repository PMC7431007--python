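"""Core spin-Hamiltonian bookkeeping for Cu(II) CW-EPR analysis.

Holds the tensor containers shared by every other module (g matrix, copper
hyperfine with partially known signs, nitrogen superhyperfine couplings,
strains/linewidths), plus the small arithmetic they need: isotropic
averages, enumeration of sign assignments compatible with DFT-derived
constraints, resonance-field conversion, and gyromagnetic rescaling of
nitrogen couplings between the ¹⁴N and ¹⁵N isotopologues.

Axis convention: principal values are labelled 1..3 with g1 ≤ g2 ≤ g3 and
the copper hyperfine sharing axes with g.  Inputs violating the ordering
are re-sorted (jointly with A) with a warning.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .constants import G_ELECTRON, MHZ_PER_MT, N15_OVER_N14

__all__ = [
    "GTensor",
    "CuHyperfine",
    "NitrogenSHF",
    "SpinSystem",
    "isotropic_average",
    "enumerate_hyperfine_signs",
    "resonance_field",
    "rescale_nitrogen_coupling",
    "read_spin_systems",
    "write_spin_systems",
]

#: plausibility window for Cu(II) g values — outside it we warn, never fail
_G_PLAUSIBLE = (1.8, 2.6)


def _check_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite input: {v!r}")


def isotropic_average(v1: float, v2: float, v3: float) -> float:
    """Rotational average (v1+v2+v3)/3 of three principal values.

    Full precision is returned; presentation layers round (integer MHz for
    Aiso, three decimals for g) when mirroring published tables.
    """
    _check_finite(v1, v2, v3)
    return (v1 + v2 + v3) / 3.0


@dataclass(frozen=True)
class GTensor:
    """Principal g values of an S = 1/2 centre, stored sorted g1 ≤ g2 ≤ g3."""

    g1: float
    g2: float
    g3: float

    def __post_init__(self):
        _check_finite(self.g1, self.g2, self.g3)
        vals = (self.g1, self.g2, self.g3)
        if list(vals) != sorted(vals):
            warnings.warn(
                f"g values {vals} not in ascending order; re-sorting to the "
                "g1 <= g2 <= g3 convention", stacklevel=3)
            s = sorted(vals)
            object.__setattr__(self, "g1", s[0])
            object.__setattr__(self, "g2", s[1])
            object.__setattr__(self, "g3", s[2])
        for v in (self.g1, self.g2, self.g3):
            if not (_G_PLAUSIBLE[0] < v < _G_PLAUSIBLE[1]):
                warnings.warn(
                    f"g value {v} outside the usual Cu(II) window "
                    f"{_G_PLAUSIBLE}", stacklevel=3)

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.g1, self.g2, self.g3)

    @property
    def giso(self) -> float:
        return isotropic_average(self.g1, self.g2, self.g3)

    @property
    def dg(self) -> tuple[float, float, float]:
        """Deviations Δg_n = g_n − g_e from the free-electron value."""
        return tuple(g - G_ELECTRON for g in self.values)


def enumerate_hyperfine_signs(
    magnitudes: tuple[float, float, float],
    constraints: tuple[str, str, str] = ("unknown", "unknown", "unknown"),
) -> list[tuple[tuple[float, float, float], float]]:
    """All signed hyperfine triples compatible with per-axis constraints.

    CW-EPR determines only |A_n|; signs come from elsewhere (here typically
    DFT).  Each constraint is '+', '-' or 'unknown'.  Returns a list of
    (signed triple, Aiso) in deterministic lexicographic order with '+'
    before '-' on each unknown axis.
    """
    if len(magnitudes) != 3 or len(constraints) != 3:
        raise ValueError("magnitudes and constraints must be triples")
    for m in magnitudes:
        _check_finite(m)
        if m < 0:
            raise ValueError("hyperfine magnitudes must be >= 0")
    choices = []
    for c in constraints:
        if c == "+":
            choices.append((1.0,))
        elif c == "-":
            choices.append((-1.0,))
        elif c == "unknown":
            choices.append((1.0, -1.0))
        else:
            raise ValueError(f"sign constraint must be '+', '-' or 'unknown', got {c!r}")
    out = []
    for signs in itertools.product(*choices):
        signed = tuple(s * m for s, m in zip(signs, magnitudes))
        out.append((signed, isotropic_average(*signed)))
    return out


def resonance_field(g_eff: float, frequency_ghz: float) -> float:
    """Resonance field hν/(g·μB) in mT for an effective g at ν in GHz."""
    _check_finite(g_eff, frequency_ghz)
    if g_eff <= 0 or frequency_ghz <= 0:
        raise ValueError("g_eff and frequency must be positive")
    return frequency_ghz * 1.0e3 / (g_eff * MHZ_PER_MT)


def rescale_nitrogen_coupling(value_mhz: float, from_isotope: str,
                              to_isotope: str) -> float:
    """Rescale a nitrogen hyperfine coupling between isotopologues.

    Multiplies by |γ(to)/γ(from)|; the ¹⁵N/¹⁴N ratio is 1.4027.
    """
    ratios = {"14N": 1.0, "15N": N15_OVER_N14}
    if from_isotope not in ratios or to_isotope not in ratios:
        raise ValueError(f"isotopes must be 14N or 15N, got "
                         f"{from_isotope!r} -> {to_isotope!r}")
    return value_mhz * ratios[to_isotope] / ratios[from_isotope]


@dataclass(frozen=True)
class CuHyperfine:
    """Copper hyperfine principal values as magnitudes plus per-axis signs.

    ``signs`` entries are '+', '-' or 'unknown'; ``aiso`` is defined only
    when all three signs are resolved, otherwise the possible values are
    available through :func:`enumerate_hyperfine_signs`.
    """

    absA1: float
    absA2: float
    absA3: float
    signs: tuple[str, str, str] = ("unknown", "unknown", "unknown")

    def __post_init__(self):
        for m in (self.absA1, self.absA2, self.absA3):
            _check_finite(m)
            if m < 0:
                raise ValueError("|A| values must be >= 0")
        for s in self.signs:
            if s not in ("+", "-", "unknown"):
                raise ValueError(f"bad sign {s!r}")

    @property
    def magnitudes(self) -> tuple[float, float, float]:
        return (self.absA1, self.absA2, self.absA3)

    @property
    def resolved(self) -> bool:
        return all(s != "unknown" for s in self.signs)

    @property
    def signed(self) -> tuple[float, float, float]:
        if not self.resolved:
            raise ValueError("signs not fully resolved")
        return tuple(m if s == "+" else -m
                     for m, s in zip(self.magnitudes, self.signs))

    @property
    def aiso(self) -> float:
        return isotropic_average(*self.signed)

    def aiso_candidates(self) -> list[float]:
        """All Aiso values compatible with the current sign constraints."""
        return [a for _, a in enumerate_hyperfine_signs(self.magnitudes, self.signs)]


@dataclass(frozen=True)
class NitrogenSHF:
    """One ligand-nitrogen superhyperfine coupling.

    CW spectra resolve only the coupling along the Cu–N bond, so a single
    principal value per nucleus is stored; the forward simulator fills in
    the two minor tensor components as a configurable fraction.
    """

    principal_value: float  # MHz
    isotope: str = "14N"
    assignment: str = "unknown"  # His / NH2 / unknown

    def __post_init__(self):
        _check_finite(self.principal_value)
        if self.principal_value < 0:
            raise ValueError("SHF principal value must be >= 0")
        if self.isotope not in ("14N", "15N"):
            raise ValueError(f"isotope must be 14N or 15N, got {self.isotope!r}")

    def rescaled(self, to_isotope: str) -> "NitrogenSHF":
        return NitrogenSHF(
            rescale_nitrogen_coupling(self.principal_value, self.isotope, to_isotope),
            to_isotope, self.assignment)


@dataclass(frozen=True)
class SpinSystem:
    """Complete CW-EPR model of one Cu(II) species.

    S = 1/2 coupled to ⁶³Cu (I = 3/2) plus ligand nitrogens; Gaussian
    strain widths on g and A, residual pseudo-Voigt linewidths (mT
    peak-to-peak Gaussian, Lorentzian) and the microwave frequency in GHz.
    """

    g: GTensor
    cuA: CuHyperfine
    nitrogens: tuple[NitrogenSHF, ...] = ()
    g_strain: tuple[float, float, float] = (0.0, 0.0, 0.0)
    A_strain: tuple[float, float, float] = (0.0, 0.0, 0.0)  # MHz
    linewidths: tuple[float, float] = (0.3, 0.0)  # mT pp (Gaussian, Lorentzian)
    mw_frequency: float = 9.3  # GHz
    cu_isotope: str = "63Cu"
    label: str = ""

    def __post_init__(self):
        if any(s < 0 for s in self.g_strain + self.A_strain):
            raise ValueError("strains must be >= 0")
        if any(w < 0 for w in self.linewidths):
            raise ValueError("linewidths must be >= 0")
        if self.mw_frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.cu_isotope != "63Cu":
            raise ValueError("only pure 63Cu supported")
        object.__setattr__(self, "nitrogens", tuple(self.nitrogens))

    electron_spin: float = 0.5

    def with_frequency(self, freq_ghz: float) -> "SpinSystem":
        return replace(self, mw_frequency=freq_ghz)


# ---------------------------------------------------------------------------
# Table I/O — columns mirror the published spin-Hamiltonian table layout


_COLUMNS = ["label", "g1", "g2", "g3", "absA1", "absA2", "absA3", "signs",
            "shf_values", "shf_isotope", "g_strain", "A_strain",
            "lw_gauss", "lw_lorentz", "freq_GHz", "isotope"]


def _system_to_row(sys: SpinSystem) -> dict:
    return {
        "label": sys.label,
        "g1": sys.g.g1, "g2": sys.g.g2, "g3": sys.g.g3,
        "absA1": sys.cuA.absA1, "absA2": sys.cuA.absA2, "absA3": sys.cuA.absA3,
        "signs": ",".join(sys.cuA.signs),
        "shf_values": ",".join(str(n.principal_value) for n in sys.nitrogens),
        "shf_isotope": sys.nitrogens[0].isotope if sys.nitrogens else "14N",
        "g_strain": ",".join(str(v) for v in sys.g_strain),
        "A_strain": ",".join(str(v) for v in sys.A_strain),
        "lw_gauss": sys.linewidths[0], "lw_lorentz": sys.linewidths[1],
        "freq_GHz": sys.mw_frequency,
        "isotope": sys.cu_isotope,
    }


def _row_to_system(row: dict) -> SpinSystem:
    def triple(s, cast=float):
        parts = str(s).split(",")
        return tuple(cast(p) for p in parts)

    shf_iso = str(row.get("shf_isotope", "14N"))
    shf_raw = str(row.get("shf_values", "") or "")
    nitrogens = tuple(
        NitrogenSHF(float(v), shf_iso)
        for v in shf_raw.split(",") if str(v).strip())
    signs = tuple(str(row.get("signs", "unknown,unknown,unknown")).split(","))
    return SpinSystem(
        g=GTensor(float(row["g1"]), float(row["g2"]), float(row["g3"])),
        cuA=CuHyperfine(float(row["absA1"]), float(row["absA2"]),
                        float(row["absA3"]), signs),
        nitrogens=nitrogens,
        g_strain=triple(row.get("g_strain", "0,0,0")),
        A_strain=triple(row.get("A_strain", "0,0,0")),
        linewidths=(float(row.get("lw_gauss", 0.3)),
                    float(row.get("lw_lorentz", 0.0))),
        mw_frequency=float(row["freq_GHz"]),
        cu_isotope=str(row.get("isotope", "63Cu")),
        label=str(row.get("label", "")),
    )


def read_spin_systems(path) -> list[SpinSystem]:
    """Read spin systems from a CSV or JSON table (auto-detected by suffix)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
        if isinstance(rows, dict):
            rows = [rows]
    else:
        rows = pd.read_csv(path, dtype=str).to_dict("records")
    return [_row_to_system(r) for r in rows]


def write_spin_systems(systems: list[SpinSystem], path) -> None:
    path = str(path)
    rows = [_system_to_row(s) for s in systems]
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
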