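"""Paramagnetic relaxation enhancement from structural ensembles.

A Cu(II) centre broadens nearby amide resonances through the electron–
nucleus dipolar interaction.  Given a multi-model structure with a
paramagnetic centre, the transverse PRE rate for each amide proton is
the Solomon–Bloembergen dipolar term

    Γ2 = (1/15) (μ0/4π)² γH² g² μB² S(S+1) r⁻⁶ [4τc + 3τc/(1+ωH²τc²)]

with S = 1/2, g the isotropic electron g value, r the electron–proton
distance and τc the effective electron–nucleus correlation time
(τc⁻¹ = τr⁻¹ + τs⁻¹; electron relaxation τs defaults to ∞ so rotational
tumbling dominates, as appropriate when τc is taken from ¹⁵N T1/T2).
Distances are ensemble-averaged as ⟨r⁻⁶⟩^(−1/6), the PRE-appropriate
convention.  Predicted HSQC intensity ratios use the Battiste–Wagner
form R2·exp(−Γ2·t)/(R2+Γ2) with t the total INEPT evolution period.

Also here: rotational correlation time estimation from the average
¹⁵N T1/T2 ratio, τc = √(6⟨T1/T2⟩−7)/(4π·νN), with hetNOE and outlier
filters on the records entering the average.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .constants import BOHR_MAGNETON, GAMMA_H_RAD, MU0_OVER_4PI

__all__ = [
    "CenterSpec",
    "StructureEnsemble",
    "RelaxationRecord",
    "PREProfile",
    "read_ensemble",
    "read_relaxation_table",
    "effective_distances",
    "gamma2_sb",
    "intensity_ratio",
    "predict_pre_profile",
    "estimate_tauc",
]


@dataclass(frozen=True)
class CenterSpec:
    """Rule locating the paramagnetic centre in each conformer.

    mode='cu': explicit Cu atom (ATOM/HETATM named CU).
    mode='midpoint': geometric midpoint of the named (residue, atom)
    pairs, e.g. the two histidine ring nitrogens of the brace.
    """

    mode: str = "cu"
    atoms: tuple[tuple[int, str], ...] = ()  # (residue number, atom name)

    def __post_init__(self):
        if self.mode not in ("cu", "midpoint"):
            raise ValueError("center mode must be 'cu' or 'midpoint'")
        if self.mode == "midpoint" and not self.atoms:
            raise ValueError("midpoint centre needs at least one atom spec")


@dataclass
class StructureEnsemble:
    """Multi-model coordinates with a resolvable paramagnetic centre.

    ``models`` maps, per conformer, residue number -> {atom name: xyz (Å)};
    ``centers`` holds the paramagnetic-centre coordinates per conformer.
    """

    models: list[dict[int, dict[str, np.ndarray]]]
    centers: list[np.ndarray]
    residue_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        if len(self.centers) != len(self.models):
            raise ValueError("one paramagnetic centre required per model")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residues(self) -> list[int]:
        common = set(self.models[0])
        for m in self.models[1:]:
            common &= set(m)
        return sorted(common)


#: atom names retained from the PDB: backbone amides and the copper
_KEEP_ATOMS = {"N", "H", "HN", "CA", "CU"}


def read_ensemble(pdb_source, center: CenterSpec = CenterSpec()) -> StructureEnsemble:
    """Parse a multi-MODEL PDB (text or path) into a StructureEnsemble.

    Retains backbone amide N/H (and CA, CU) atoms; residue numbering is
    kept verbatim from the file.  The paramagnetic centre is resolved in
    every model according to ``center`` or parsing fails.
    """
    text = str(pdb_source)
    if "\n" not in text and not text.lstrip().startswith(("ATOM", "HETATM", "MODEL")):
        with open(text) as fh:
            text = fh.read()
    structure = gemmi.read_pdb_string(text)
    if len(structure) == 0:
        raise ValueError("PDB contains no models")

    models, centers = [], []
    residue_names: dict[int, str] = {}
    for model in structure:
        res_map: dict[int, dict[str, np.ndarray]] = {}
        cu_pos = None
        for chain in model:
            for res in chain:
                num = res.seqid.num
                for atom in res:
                    name = atom.name.upper()
                    if name not in _KEEP_ATOMS and atom.element.name != "Cu":
                        continue
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if name == "CU" or atom.element.name == "Cu":
                        cu_pos = pos
                        continue
                    res_map.setdefault(num, {})[name] = pos
                    residue_names.setdefault(num, res.name)
        if center.mode == "cu":
            if cu_pos is None:
                raise ValueError("no Cu atom found and centre mode is 'cu'")
            centers.append(cu_pos)
        else:
            pts = []
            for resnum, atname in center.atoms:
                try:
                    pts.append(res_map[resnum][atname.upper()])
                except KeyError:
                    raise ValueError(
                        f"centre atom {atname} of residue {resnum} missing")
            centers.append(np.mean(pts, axis=0))
        models.append(res_map)
    return StructureEnsemble(models, centers, residue_names)


@dataclass(frozen=True)
class RelaxationRecord:
    """Per-residue ¹⁵N relaxation data: T1, T2 in s, {¹H}-¹⁵N NOE."""

    residue: int
    T1: float
    T2: float
    hetNOE: float

    def __post_init__(self):
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("T1 and T2 must be > 0")
        if self.hetNOE > 1.2:
            raise ValueError("hetNOE above the theoretical ceiling (~1.2)")


def read_relaxation_table(path) -> list[RelaxationRecord]:
    """Read a CSV with columns residue, T1, T2, hetNOE (T1/T2 in s)."""
    df = pd.read_csv(path)
    return [RelaxationRecord(int(r.residue), float(r.T1), float(r.T2),
                             float(r.hetNOE))
            for r in df.itertuples()]


def effective_distances(e: StructureEnsemble, atom: str = "H") -> pd.Series:
    """PRE effective distance ⟨r⁻⁶⟩^(−1/6) (Å) per residue.

    r is the distance from the chosen atom (default backbone amide H) to
    the paramagnetic centre; the inverse-sixth-power average over models
    is the convention appropriate for an r⁻⁶ observable.  Residues
    missing the atom in any model are skipped with a warning.
    """
    atom = atom.upper()
    out = {}
    skipped = []
    for resnum in e.residues():
        r6 = []
        ok = True
        for model, center in zip(e.models, e.centers):
            pos = model.get(resnum, {}).get(atom)
            if pos is None:
                ok = False
                break
            r6.append(float(np.sum((pos - center) ** 2)) ** -3)
        if ok:
            out[resnum] = (np.mean(r6)) ** (-1.0 / 6.0)
        else:
            skipped.append(resnum)
    if skipped:
        warnings.warn(f"residues missing atom {atom!r} skipped: {skipped}")
    return pd.Series(out, name="r_eff")


def gamma2_sb(r_eff: float, tau_c: float, proton_frequency: float = 600.0,
              g_iso: float = 2.128, tau_s: float = math.inf) -> float:
    """Solomon–Bloembergen transverse PRE rate Γ2 in s⁻¹.

    Parameters: r_eff in Å, rotational τc in ns, proton Larmor frequency
    in MHz, isotropic electron g, optional electron relaxation time τs
    in ns (combined as τ_eff⁻¹ = τc⁻¹ + τs⁻¹).
    """
    if r_eff <= 0 or tau_c <= 0 or proton_frequency <= 0 or g_iso <= 0:
        raise ValueError("all inputs must be > 0")
    tau = 1.0 / (1.0 / tau_c + (0.0 if math.isinf(tau_s) else 1.0 / tau_s))
    tau_s_si = tau * 1e-9
    r_m = r_eff * 1e-10
    omega_h = 2.0 * math.pi * proton_frequency * 1e6
    s = 0.5
    prefactor = (MU0_OVER_4PI ** 2 * GAMMA_H_RAD ** 2 * g_iso ** 2
                 * BOHR_MAGNETON ** 2 * s * (s + 1.0)) / 15.0
    spectral = 4.0 * tau_s_si + 3.0 * tau_s_si / (1.0 + (omega_h * tau_s_si) ** 2)
    return prefactor * r_m ** -6 * spectral


def intensity_ratio(gamma2: float, R2_dia: float, t_evolution: float = 0.010
                    ) -> float:
    """Predicted paramagnetic/diamagnetic HSQC intensity ratio.

    Battiste–Wagner form R2·exp(−Γ2·t)/(R2+Γ2) with R2 the diamagnetic
    transverse rate (s⁻¹) and t the total INEPT evolution period (s);
    clipped to [0, 1].
    """
    if R2_dia <= 0:
        raise ValueError("R2_dia must be > 0")
    if t_evolution < 0:
        raise ValueError("t_evolution must be >= 0")
    ratio = R2_dia * math.exp(-gamma2 * t_evolution) / (R2_dia + gamma2)
    return min(max(ratio, 0.0), 1.0)


@dataclass
class PREProfile:
    """Per-residue PRE prediction (and optional observation)."""

    table: pd.DataFrame  # residue, r_eff, gamma2, predicted_ratio[, observed...]
    settings: dict = field(default_factory=dict)

    def merged_with_observed(self, observed: pd.DataFrame) -> "PREProfile":
        merged = self.table.merge(observed, on="residue", how="left")
        return PREProfile(merged, dict(self.settings))


def predict_pre_profile(e: StructureEnsemble,
                        relax: list[RelaxationRecord] | None = None,
                        tau_c: float = 10.2,
                        proton_frequency: float = 600.0,
                        g_iso: float = 2.128,
                        tau_s: float = math.inf,
                        t_evolution: float = 0.010,
                        default_R2: float = 20.0,
                        atom: str = "H") -> PREProfile:
    """Forward PRE profile: distances → Γ2 → intensity ratios per residue.

    Per-residue diamagnetic R2 = 1/T2 is taken from the relaxation table
    where available, else ``default_R2`` (s⁻¹) is used.
    """
    r_eff = effective_distances(e, atom=atom)
    if len(r_eff) == 0:
        raise ValueError("no residues with the requested atom in all models")
    r2_map = {r.residue: 1.0 / r.T2 for r in relax} if relax else {}
    if relax and not (set(r2_map) & set(r_eff.index)):
        raise ValueError("no residue overlap between ensemble and relaxation table")
    rows = []
    for resnum, r in r_eff.items():
        g2 = gamma2_sb(r, tau_c, proton_frequency, g_iso, tau_s)
        r2 = r2_map.get(resnum, default_R2)
        rows.append({"residue": resnum, "r_eff": r, "gamma2": g2,
                     "predicted_ratio": intensity_ratio(g2, r2, t_evolution)})
    settings = {"tau_c_ns": tau_c, "proton_frequency_MHz": proton_frequency,
                "g_iso": g_iso, "tau_s_ns": tau_s,
                "t_evolution_s": t_evolution, "default_R2_s": default_R2,
                "ratio_model": "R2*exp(-Gamma2*t)/(R2+Gamma2)"}
    return PREProfile(pd.DataFrame(rows), settings)


def estimate_tauc(relax: list[RelaxationRecord], n15_frequency: float,
                  noe_min: float = 0.65, sd_window: float = 1.5
                  ) -> tuple[float, float]:
    """Rotational correlation time from the average ¹⁵N T1/T2 ratio.

    τc = √(6⟨T1/T2⟩ − 7)/(4π·νN) in ns with νN in MHz.  Records with
    hetNOE below ``noe_min`` (flexible residues) are excluded, then a
    trimmed mean keeps ratios within ``sd_window`` standard deviations
    of the median.  The uncertainty propagates the SD of the surviving
    ratios through the closed form.
    """
    ratios = np.array([r.T1 / r.T2 for r in relax if r.hetNOE >= noe_min])
    if len(ratios) < 3:
        raise ValueError("fewer than 3 records survive the NOE filter")
    med = np.median(ratios)
    sd = np.std(ratios)
    if sd > 0:
        ratios = ratios[np.abs(ratios - med) <= sd_window * sd]
    mean_ratio = float(np.mean(ratios))
    if mean_ratio < 7.0 / 6.0:
        raise ValueError("mean T1/T2 below 7/6; the estimator is undefined")
    nu_n_hz = n15_frequency * 1e6
    root = math.sqrt(6.0 * mean_ratio - 7.0)
    tau_c = root / (4.0 * math.pi * nu_n_hz) * 1e9  # ns
    sd_surv = float(np.std(ratios))
    if root > 0:
        sigma = 3.0 * sd_surv / root / (4.0 * math.pi * nu_n_hz) * 1e9
    else:
        sigma = math.inf
    return tau_c, sigma
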