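"""Synthetic-data generators with known ground truth.

Every pipeline stage can be exercised without external downloads: a
multi-model protein-like ensemble with a copper centre (stand-in for a
solution-NMR conformer bundle), ¹⁵N relaxation tables from rigid
isotropic tumbling at a known τc, noisy derivative CW-EPR spectra from
known spin-Hamiltonian parameters, and PRE intensity-ratio profiles
with Gaussian noise.  All generators are pure functions of their
configuration: a fixed seed gives bit-identical output, and each data
channel draws from its own named generator derived from the master seed
so adding one channel never perturbs another.  Ground-truth parameters
are emitted alongside the data as JSON sidecars.

The ensemble backbone is a schematic extended chain — sufficient for
distance/PRE physics, with no attempt at a realistic fold.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GAMMA_H_RAD, GAMMA_MHZ_PER_T, MU0_OVER_4PI, PLANCK_H
from .epr_forward import Spectrum, simulate_powder
from .pre import PREProfile, RelaxationRecord, StructureEnsemble, read_ensemble
from .spin_core import SpinSystem

__all__ = [
    "SynthConfig",
    "synth_ensemble",
    "synth_relaxation",
    "synth_spectrum",
    "synth_intensity_table",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shared knobs for the generators (seed-deterministic)."""

    seed: int = 0
    n_models: int = 10
    n_residues: int = 60
    cu_attach_residue: int = 10
    coordinate_jitter: float = 0.8  # Å, per-model Gaussian
    relaxation_noise: float = 0.05  # multiplicative lognormal sd
    spectrum_snr: float = 50.0  # peak-to-peak signal / noise sd
    intensity_sd: float = 0.05  # observed-ratio Gaussian sd

    def __post_init__(self):
        for name in ("coordinate_jitter", "relaxation_noise", "intensity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, channel: str) -> np.random.Generator:
        """A named per-channel generator derived from the master seed."""
        tag = zlib.crc32(channel.encode()) % 2**31
        return np.random.default_rng([self.seed, tag])


# ---------------------------------------------------------------------------
# structural ensemble


_PDB_ATOM = ("ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}"
             "{resnum:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
             "{b:6.2f}          {element:>2s}\n")


def _chain_coords(n_residues: int, spacing: float = 3.5) -> dict:
    """Idealized extended chain: N, H, CA per residue along +x, with the
    amide H offset so H–Cu distances differ from N–Cu ones."""
    coords = {}
    for i in range(n_residues):
        resnum = i + 1
        x = i * spacing
        coords[resnum] = {
            "N": np.array([x, 0.0, 0.0]),
            "H": np.array([x, -0.98, 0.0]),
            "CA": np.array([x + 1.46, 0.8, 0.0]),
        }
    return coords


def synth_ensemble(cfg: SynthConfig) -> tuple[StructureEnsemble, str]:
    """Multi-model PDB ensemble with a paramagnetic copper centre.

    Per-model Gaussian coordinate jitter emulates conformer spread; one
    Cu atom sits a fixed 2.2 Å from the attachment residue's amide
    nitrogen in every model.  Returns the parsed ensemble and the PDB
    text (which round-trips through :func:`histbrace.pre.read_ensemble`).
    """
    if cfg.n_residues < 10:
        raise ValueError("need at least 10 residues")
    if not (1 <= cfg.cu_attach_residue <= cfg.n_residues):
        raise ValueError("cu_attach_residue outside the chain")
    rng = cfg.rng("ensemble")
    base = _chain_coords(cfg.n_residues)
    lines = []
    for m in range(cfg.n_models):
        lines.append(f"MODEL     {m + 1:4d}\n")
        serial = 1
        jitter = {rn: rng.normal(0.0, cfg.coordinate_jitter, size=3)
                  for rn in base}
        for rn in sorted(base):
            for name in ("N", "H", "CA"):
                xyz = base[rn][name] + jitter[rn]
                lines.append(_PDB_ATOM.format(
                    serial=serial, name=name, alt=" ", res="ALA", chain="A",
                    resnum=rn, icode=" ", x=xyz[0], y=xyz[1], z=xyz[2],
                    occ=1.0, b=0.0, element=name[0]))
                serial += 1
        cu = base[cfg.cu_attach_residue]["N"] + jitter[cfg.cu_attach_residue] \
            + np.array([0.0, 2.2, 0.0])
        lines.append(_PDB_ATOM.format(
            serial=serial, name="CU", alt=" ", res="CU", chain="A",
            resnum=cfg.n_residues + 1, icode=" ", x=cu[0], y=cu[1], z=cu[2],
            occ=1.0, b=0.0, element="CU"))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    pdb_text = "".join(lines)
    return read_ensemble(pdb_text), pdb_text


# ---------------------------------------------------------------------------
# relaxation table


def _n15_rates(tau_c_ns: float, proton_frequency: float = 600.0
               ) -> tuple[float, float, float]:
    """Rigid isotropic-tumbling ¹⁵N R1, R2 (s⁻¹) and {¹H}-¹⁵N NOE.

    Dipolar (N–H, 1.02 Å) + CSA (−160 ppm) with Lorentzian spectral
    densities J(ω) = 0.4·τc/(1+(ωτc)²).  R1 and R2 keep the J(0) and
    J(ωN) terms that dominate slow tumbling — making the T1/T2 → τc
    estimator its exact inverse in the noiseless limit — while the NOE
    uses the full cross-relaxation term (it vanishes otherwise).
    """
    tau = tau_c_ns * 1e-9
    omega_h = 2.0 * math.pi * proton_frequency * 1e6
    gamma_ratio = GAMMA_MHZ_PER_T["15N"] / GAMMA_MHZ_PER_T["1H"]
    omega_n = omega_h * gamma_ratio
    j = lambda w: 0.4 * tau / (1.0 + (w * tau) ** 2)
    # dipolar constant d = (mu0/4pi) * hbar * gammaH * gammaN / r^3
    gamma_n_rad = GAMMA_H_RAD * gamma_ratio
    hbar = PLANCK_H / (2.0 * math.pi)
    d = MU0_OVER_4PI * hbar * GAMMA_H_RAD * gamma_n_rad / (1.02e-10) ** 3
    c = omega_n * 160e-6 / math.sqrt(3.0)
    r1 = (d * d / 4.0) * 3.0 * j(omega_n) + c * c * j(omega_n)
    r2 = (d * d / 8.0) * (4.0 * j(0.0) + 3.0 * j(omega_n)) \
        + (c * c / 6.0) * (4.0 * j(0.0) + 3.0 * j(omega_n))
    # gamma(15N) < 0: the sum/difference frequencies are |ωH|−|ωN| and
    # |ωH|+|ωN|, and the NOE enhancement carries the negative sign of γN
    sigma = (d * d / 4.0) * (6.0 * j(omega_h - omega_n) - j(omega_h + omega_n))
    noe = 1.0 - (1.0 / gamma_ratio) * sigma / r1
    return r1, r2, noe


def synth_relaxation(tau_c: float, cfg: SynthConfig,
                     proton_frequency: float = 600.0,
                     flexible_fraction: float = 0.15
                     ) -> tuple[list[RelaxationRecord], dict]:
    """Per-residue T1/T2/NOE table generated at a known τc (ns).

    Core residues follow the rigid-tumbling rates with multiplicative
    lognormal noise; a flexible C-terminal tail gets longer T2 and
    hetNOE < 0.65 so that the default filters of the τc estimator are
    exercised.  Returns (records, truth sidecar dict).
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be > 0")
    rng = cfg.rng("relaxation")
    r1, r2, noe = _n15_rates(tau_c, proton_frequency)
    n_flex = int(round(flexible_fraction * cfg.n_residues))
    records = []
    for resnum in range(1, cfg.n_residues + 1):
        flexible = resnum > cfg.n_residues - n_flex
        noise = lambda: math.exp(rng.normal(0.0, cfg.relaxation_noise)) \
            if cfg.relaxation_noise > 0 else 1.0
        if flexible:
            # mobile tail: shorter effective tau -> longer T2, low NOE
            t1 = (1.0 / r1) * 0.8 * noise()
            t2 = (1.0 / r2) * 3.0 * noise()
            het = float(rng.uniform(0.1, 0.55))
        else:
            t1 = (1.0 / r1) * noise()
            t2 = (1.0 / r2) * noise()
            het = noe + float(rng.normal(0.0, 0.02))
        records.append(RelaxationRecord(resnum, t1, t2, min(het, 1.2)))
    truth = {"tau_c_ns": tau_c, "proton_frequency_MHz": proton_frequency,
             "R1_s": r1, "R2_s": r2, "NOE_rigid": noe,
             "n_flexible": n_flex, "seed": cfg.seed}
    return records, truth


# ---------------------------------------------------------------------------
# spectra and intensity tables


def synth_spectrum(sys: SpinSystem, snr: float | None = 50.0,
                   seed: int = 0, **powder_kwargs) -> Spectrum:
    """Powder spectrum plus white Gaussian noise at a target SNR.

    SNR is peak-to-peak signal over noise standard deviation;
    ``snr=None`` (or inf) returns the noiseless simulation.
    """
    spec = simulate_powder(sys, **powder_kwargs)
    if snr is None or math.isinf(snr):
        return spec
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = np.random.default_rng([seed, 71])
    pp = spec.intensity.max() - spec.intensity.min()
    noisy = spec.intensity + rng.normal(0.0, pp / snr, size=spec.intensity.shape)
    meta = dict(spec.metadata, snr=snr, seed=seed)
    return Spectrum(spec.field_mt, noisy, spec.mw_frequency, meta)


def synth_intensity_table(profile: PREProfile, sd: float = 0.05,
                          seed: int = 0) -> pd.DataFrame:
    """Observed-ratio table: predicted ratios + truncated-Gaussian noise.

    Noise is clipped to [0, 1.2] (ratios slightly above 1 occur in real
    data); the per-residue error column carries the generating sd.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng([seed, 72])
    pred = profile.table["predicted_ratio"].to_numpy()
    observed = np.clip(pred + rng.normal(0.0, sd, size=pred.shape), 0.0, 1.2)
    return pd.DataFrame({
        "residue": profile.table["residue"],
        "observed_ratio": observed,
        "error": sd,
    })


def write_truth_sidecar(path, truth: dict) -> None:
    with open(str(path), "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
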