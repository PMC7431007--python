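# histbrace

Integrated NMR/EPR analysis of histidine-brace Cu(II) sites in lytic
polysaccharide monooxygenases (LPMOs) — copper enzymes that oxidatively
cleave crystalline polysaccharides such as chitin.  The package is for
spectroscopists and structural biologists who want to go from measured
spin-Hamiltonian parameters, HYSCORE couplings and relaxation data to
electronic-structure statements about the copper site, without
hand-assembled spreadsheets.

## What it computes

**Sign-constrained hyperfine analysis.**  CW-EPR gives |A₁|, |A₂|, |A₃|;
signs come from theory.  With per-axis constraints the package
enumerates the compatible branches and their isotropic averages
A_iso = (A₁+A₂+A₃)/3.

**Ligand-field decomposition.**  For a d(x²−y²) SOMO with orbital
coefficients a, b (a² + b² = 1) and spin density α² on copper,

    A_iso = P_d[−κ + (Δg₁+Δg₂+Δg₃)/3]
    A₃ = −P_d[κ + (4/7)α²(a²−b²) − (3a−3b)Δg₂/(14(a+3b))
              − (3a+3b)Δg₁/(14(a−3b)) − Δg₃]

yield the Fermi contact (−P_d·κ), the spin density, and the
Fermi/dipolar/orbital breakdown of the copper hyperfine coupling.

**CW powder EPR simulation and fitting.**  S = 1/2 ⊗ ⁶³Cu (I = 3/2)
with g/A strain and nitrogen superhyperfine; a third-order perturbative
engine validated against an exact-diagonalization oracle; joint
multi-frequency least-squares refinement.

**HYSCORE couplings and H bonds.**  Axial couplings A + 2T of the
remote imidazole nitrogens, first-order cross-peak positions
ν± = |ν_I ± A_eff/2|, and hydrogen-bond classification from the ¹⁴N
quadrupole asymmetry η.

**PRE and τc.**  Solomon–Bloembergen Γ₂ from a multi-model structure
with ⟨r⁻⁶⟩ ensemble averaging, HSQC intensity-ratio prediction, and
rotational correlation time τc = √(6⟨T₁/T₂⟩−7)/(4π ν_N).

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
from histbrace import decompose_hyperfine, enumerate_hyperfine_signs
from histbrace.pipeline import load_reference_systems

systems = load_reference_systems()          # bundled parameter table

free = systems["free_X_14N"]                # substrate-free, X band
d = decompose_hyperfine(free.g, free.cuA.aiso, free.cuA.signed[2], b2=0.02)
print(round(free.cuA.aiso), round(d.fermi), round(d.alpha2, 2))
# 10 -138 0.82

bound = systems["chitin_X_14N"]             # chitin-bound: A1 sign open
for signed, aiso in enumerate_hyperfine_signs(bound.cuA.magnitudes,
                                              bound.cuA.signs):
    d = decompose_hyperfine(bound.g, aiso, signed[2], b2=0.005)
    print(round(aiso), round(d.fermi), round(d.alpha2, 2))
# -208 -324 0.84
# -262 -377 0.76
```

Reading: the substrate-free site has A_iso ≈ +10 MHz, a Fermi contact
of about −138 MHz and 82% of the unpaired spin on copper.  Chitin
binding flips A_iso to −208 (or −262) MHz; the Fermi contact jumps to
−324 MHz — the electronic fingerprint of the five- to four-coordinate
rearrangement that stabilizes the Cu(II)–superoxide intermediate (the
binding-energy difference of 8.2 kcal/mol corresponds to a ~10⁶
stabilization at 298 K, `stability_ratio`).

The `examples/` directory has one short script per capability
(ligand-field decomposition, powder simulation with the high-field
"overshoot", spectrum fitting, HYSCORE shifts and H bonds, PRE + τc).
A thin CLI wraps the same functions:

```sh
histbrace-spect run --out results_dir     # full pipeline
histbrace-spect lft                       # ligand-field stage only
histbrace-spect synth --what relaxation   # synthetic data + truth sidecar
```

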