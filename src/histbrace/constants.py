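"""Physical constants (CODATA 2018) and nuclear data used across the package.

Internal unit conventions: couplings in MHz, magnetic fields in mT,
microwave frequencies in GHz, distances in Å, correlation times in ns.
"""

# CODATA 2018
PLANCK_H = 6.62607015e-34  # J s (exact)
BOHR_MAGNETON = 9.2740100783e-24  # J/T
MU0_OVER_4PI = 1.0e-7  # T^2 m^3 / J (exact in SI 2019 to ~1e-10)
BOLTZMANN_KCAL = 1.98720425864083e-3  # kcal mol^-1 K^-1 (R in kcal units)

G_ELECTRON = 2.0023  # free-electron g reference used for all Delta-g

# mu_B / h in MHz/mT: how many MHz one mT of field is worth at g = 1
MHZ_PER_MT = BOHR_MAGNETON / PLANCK_H / 1.0e9  # = 13.9962449...

# Nuclear gyromagnetic ratios, gamma/2pi in MHz/T (magnitudes)
GAMMA_MHZ_PER_T = {
    "1H": 42.577478518,
    "14N": 3.07770646,
    "15N": 4.31726882,
}

#: |gamma(15N)/gamma(14N)| — isotopologue rescaling factor for N couplings
N15_OVER_N14 = GAMMA_MHZ_PER_T["15N"] / GAMMA_MHZ_PER_T["14N"]  # 1.40275...

# proton gamma in rad s^-1 T^-1 (for PRE rate assembly)
GAMMA_H_RAD = 2.6752218744e8

NUCLEAR_SPIN = {"1H": 0.5, "14N": 1.0, "15N": 0.5, "63Cu": 1.5}
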