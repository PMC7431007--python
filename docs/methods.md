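# Methods

`histbrace` analyses the Cu(II) active site of a chitin-active lytic
polysaccharide monooxygenase (LPMO) — a histidine-brace copper enzyme —
by combining CW-EPR spin-Hamiltonian analysis, ligand-field theory,
HYSCORE-derived nitrogen couplings, and NMR paramagnetic relaxation
enhancement (PRE).  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Spin-Hamiltonian conventions

Principal values are labelled 1–3 with g1 ≤ g2 ≤ g3; the copper
hyperfine tensor shares axes with g (inputs violating the ordering are
re-sorted with a warning).  Δg_n = g_n − g_e uses the free-electron
value g_e = 2.0023 throughout.  Couplings are stored in MHz, fields in
mT, frequencies in GHz; physical constants are CODATA 2018.  CW-EPR
determines only |A_n|; signs come from elsewhere (in practice DFT), so
`CuHyperfine` carries per-axis sign constraints and
`enumerate_hyperfine_signs` expands the compatible branches, each with
its Aiso.  Presentation layers round Aiso to integer MHz and g to three
decimals; the core keeps full precision.

Nitrogen superhyperfine couplings are single principal values (the
coupling along the Cu–N bond, the only component CW spectra resolve);
¹⁴N ↔ ¹⁵N rescaling multiplies by the gyromagnetic ratio
|γ(¹⁵N)/γ(¹⁴N)| = 1.4027.

## Ligand-field (DELFT-style) hyperfine decomposition

For a d(x²−y²)-dominated SOMO with orbital coefficients a (d(x²−y²))
and b (d(z²)), a² + b² = 1:

    Aiso = Pd[−K + (Δg1 + Δg2 + Δg3)/3]
    A3   = −Pd[K + (4/7)α²(a²−b²)
               − (3a−3b)Δg2/(14(a+3b))
               − (3a+3b)Δg1/(14(a−3b)) − Δg3]

* **Pd** — free-ion dipolar parameter.  The default is 1180 **MHz**:
  this is the only reading that is dimensionally consistent with the
  other MHz-valued terms and it reproduces the anchor Fermi contacts
  (−139 / −324 MHz) from the tabulated g values, so the package treats
  Pd as an MHz quantity (configurable).
* **K** — dimensionless Fermi-contact parameter; Fermi contact = −Pd·K
  from the Aiso relation.
* **α²** — ground-state Cu spin density, solved from the A3 equation by
  bracketed root finding on [0, 1.2] (the equation is linear in α², but
  bracketing makes inconsistent inputs fail loudly).
* **b²** — d(z²) admixture.  Five-coordinate (substrate-free) default
  0.02, the value implied by the in-plane g splitting g2 − g1 ≈ 0.07;
  four-coordinate (substrate-bound) default 0.005, the post-binding
  d(z²) content indicated by electronic-structure calculations.  With
  these two defaults the full published decomposition table is
  reproduced: every sign, and all parallel-direction magnitudes within
  5 MHz.  Using b² = 0.02 for the bound state instead shifts the bound
  dipolar term by ~5 MHz and α² by ~0.03; both options are exposed.
  A linear surrogate b² = c·(g2 − g1) (mode `estimate`, calibrated on
  the five-coordinate anchor) is provided for exploration; the exact
  literature mapping is not reproduced here.

The decomposition solves the parallel direction exactly: Fermi from
Aiso, dipolar_para = −Pd·(4/7)·α²(a²−b²), orbital_para as the remainder,
so `recompose_parallel` returns the signed A3 to machine precision.
The perpendicular entries use the leading-order expressions
(+Pd·(2/7)·α²(a²−b²); Pd·(Δg1+Δg2)/2) and are flagged *approximate*:
the cross terms they omit are not defined by the parallel-direction
data, and tests assert only sign and 20% agreement for them.

The substrate-coupling conversion exp(ΔΔE/RT) (R in kcal mol⁻¹ K⁻¹,
default T = 298 K) turns the copper–superoxide binding-energy
difference between the five- and four-coordinate sites into an
equilibrium stabilization ratio; ΔΔE = 8.2 kcal/mol gives ≈ 1.04 × 10⁶.

## CW powder EPR simulation

The model is S = 1/2 coupled to one ⁶³Cu (I = 3/2) with collinear
orthorhombic g and A, plus ligand nitrogens at first order.  Two
engines:

* **Exact oracle** — full 8×8 Zeeman + hyperfine matrix; resonance
  fields by Brent bisection on the sorted eigen-energy differences over
  a scan window, amplitudes from perpendicular transition moments.
* **Perturbative engine** — numeric degenerate perturbation theory to
  third order in A/(gμB B) within each electron manifold, with a
  self-consistent resonance-field iteration (two passes).  The two
  engines agree to better than 0.01 mT on the tabulated parameter sets
  (the tests require 0.1 mT).  Second-order terms are what place the
  high-field "overshoot" line of the substrate-bound spectrum beyond
  the g1 resonance field.

Nitrogen superhyperfine enters as first-order equal-splitting
multiplets (1:1:1 per ¹⁴N, 1:1 per ¹⁵N).  Only the principal Cu–N value
is known; the two minor tensor components default to 2/3 of it (placed
with the principal component on axis 1, i.e. equatorial).  This choice
broadens and substructures, but never shifts, the copper comb.

Powder integration uses a product quadrature — Gauss–Legendre in cosθ,
trapezoid in φ — over one octant (collinear orthorhombic symmetry;
hemisphere available for rotated-frame work).  Default spacing is 1° in
θ and 3° in φ: line positions sweep fastest in θ, and halving the
spacing changes the spectrum by < 1%.  Each line is deposited as a
linearly interpolated stick and convolved, in buckets of similar width,
with a pseudo-Voigt kernel combining

* strain broadening: Gaussian distributions of g_i and A_i (table
  entries read as FWHM), propagated to field width through first-order
  derivatives ∂B/∂g_i = −B·g_i n_i²/g² and ∂B/∂A_i = −m_I·∂K/∂A_i/(gμB);
  no correlated g–A strain;
* residual lineshape: the two linewidth entries interpreted as mT
  peak-to-peak Gaussian and Lorentzian widths (σ = pp/2,
  HWHM = √3·pp/2) — the source table does not state units, so this
  interpretation is a documented assumption.

The output is the field derivative of the accumulated absorption;
spectra are deterministic for fixed inputs and the absorption integral
is conserved under broadening and linear in the spin-count scale.

Fitting is bounded, derivative-free (Powell) and local: default bounds
bracket the starting guess (±0.03 on g, ±15% or 20 MHz on |A|), since a
wide-open search can tunnel between comb assignments.  Several spectra
at different microwave frequencies can be fitted jointly with shared
parameters — the two-frequency strategy that makes the g values
reliable.  The residual is scale-invariant (per-spectrum amplitude
solved analytically).  Deterministic from a given start;
non-convergence returns the best iterate, flagged.

## HYSCORE-derived quantities

Remote imidazole nitrogens are described by (aiso, T, Euler angles) and
for ¹⁴N the quadrupole pair (Κ = e²qQ/h, η).  The axial coupling
A + 2T tracks the N–Cu axial interaction; first-order cross peaks sit
at ν± = |νI ± A_eff/2| with A_eff = aiso + 2T (parallel) or aiso − T
(perpendicular).  Time-domain HYSCORE simulation is out of scope:
¹⁴N frequencies are computed without the quadrupole and flagged, and
Euler angles are metadata.

The H-bond classification from η uses weak = [0.45, 0.75] and
strong ≥ 0.85, with `intermediate` and `below-range` classes added so
the map is total on [0, 1]; all thresholds are configurable and the
buffer classes are never silently folded into scientific conclusions.

## PRE and rotational correlation time

Γ2 is the Solomon–Bloembergen dipolar rate with S = 1/2, g = g_iso from
EPR, and effective correlation time τ_eff⁻¹ = τ_r⁻¹ + τ_s⁻¹; electron
relaxation τ_s defaults to ∞ (rotation-dominated), matching the use of
τc from ¹⁵N T1/T2, but is configurable because Cu(II) τ_s can be
comparable.  Distances from a multi-model ensemble are averaged as
⟨r⁻⁶⟩^(−1/6) — the convention appropriate for an r⁻⁶ observable — and
residue numbering follows the PDB file verbatim.  Curie-spin and
cross-correlated contributions are neglected (small for a ~20 kDa
protein at these fields).

Intensity ratios use the Battiste–Wagner form
R2·exp(−Γ2·t)/(R2 + Γ2), with per-residue diamagnetic R2 = 1/T2 when
relaxation data are supplied, t defaulting to 10 ms (total HSQC INEPT
evolution), and clipping to [0, 1].  The functional form is a modelling
choice (the experimental papers rarely state theirs) and is echoed into
every report.

τc comes from τc = √(6⟨T1/T2⟩ − 7)/(4π νN), the rigid-isotropic-tumbling
inversion of the T1/T2 ratio with high-frequency spectral densities
neglected.  Records with hetNOE < 0.65 are excluded and a trimmed mean
keeps ratios within 1.5 SD of the median; the uncertainty propagates
the SD of the surviving ratios.

## Synthetic data: what it shows and what it does not

Generators are pure functions of (config, seed), with one named RNG
stream per channel and ground truth emitted as JSON sidecars.

* **Ensemble** — an idealized extended chain (3.5 Å/residue) with
  per-model Gaussian jitter (default 0.8 Å, 10 models, 60 residues) and
  a Cu placed 2.2 Å from the attachment residue's amide nitrogen.  It
  reproduces the *distance physics* of a conformer bundle, not a
  protein fold: passing PRE tests demonstrates correct r⁻⁶ averaging
  and rate assembly, not structural realism.
* **Relaxation** — T1/T2 from dipolar (N–H, 1.02 Å) + CSA (−160 ppm)
  spectral densities keeping the J(0) and J(ωN) terms that dominate
  slow tumbling; this makes the τc estimator the exact inverse of the
  generator in the noiseless limit, so the noiseless round-trip tests
  the plumbing, while the 5%-noise recovery at τc = 10.2 ns tests the
  filters in the regime of a well-packed ~20 kDa protein.  The NOE uses
  the full cross-relaxation term (it vanishes in the truncated model);
  a flexible C-terminal tail (15% of residues) gets hetNOE < 0.65 to
  exercise the filters.  Real data add exchange contributions,
  anisotropic tumbling and per-residue order parameters that this
  generator does not emulate.
* **Spectra** — powder simulation plus white Gaussian noise scaled to a
  peak-to-peak SNR (default 50).  Real CW spectra add baseline drift
  and modulation distortion, so parameter-recovery results here bound
  the statistical, not the systematic, error.
* **Intensity ratios** — predicted ratios + truncated Gaussian noise
  clipped to [0, 1.2].  Residues far from the copper saturate at 1.0
  and carry no ranking information; concordance statements are
  therefore made over the PRE-affected residues.

## Degenerate inputs, ties, tolerances

Non-finite inputs raise; g values outside (1.8, 2.6) warn but pass
(plausibility only).  A perturbation parameter max|A|/(gμB B) > 0.15
attaches a warning to perturbative output.  Sign-enumeration output is
ordered lexicographically with + before −.  The powder field axis must
span all resonances (± a 1 mT grace) unless `allow_outside=True`, in
which case off-axis lines are dropped — the mode the fitter uses while
exploring.  Strain-width bucketing quantizes Gaussian widths to ≤ 0.05
grid steps; quadrature weights are renormalized to 1.

## Problem sizes used in the shipped tests

Engine cross-checks run 16 random orientations on four parameter sets;
powder-convergence tests compare 1°/0.75° θ grids; the
parameter-recovery experiment fits six parameters on a 4° grid against
one SNR-50 X-band spectrum; PRE tests use the default 60-residue,
10-model ensemble.  These sizes keep the full suite at a few minutes on
one CPU while exercising every code path at the study's parameter
values.

## Known limitations

No Cu isotope mixtures or S > 1/2; no time-domain ESEEM/ENDOR
simulation; no quadrupole-perturbed ¹⁴N cross-peak placement; the
perpendicular hyperfine decomposition is leading-order; no
PRE-restrained structure refinement or τ_s fitting; EasySpin-level
features (modulation effects, frequency sweeps, Bruker file formats)
are out of scope, with the plain-text spectrum format as the exchange
point.
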