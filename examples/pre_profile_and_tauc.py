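"""Predict a PRE intensity-ratio profile and estimate τc.

Builds a synthetic conformer ensemble with a Cu(II) centre, generates a
¹⁵N relaxation table at τc = 10.2 ns, estimates τc back from <T1/T2>,
and forward-calculates the per-residue HSQC intensity ratios.
"""

from histbrace import estimate_tauc, predict_pre_profile
from histbrace.synthetic import SynthConfig, synth_ensemble, synth_relaxation

cfg = SynthConfig(seed=1)
ensemble, _ = synth_ensemble(cfg)
relax, truth = synth_relaxation(10.2, cfg)

nu_n = 600.0 * 4.31726882 / 42.577478518  # 15N frequency at 600 MHz, ~60.8
tau_c, tau_sd = estimate_tauc(relax, nu_n)
print(f"tau_c = {tau_c:.1f} +- {tau_sd:.1f} ns "
      f"(generated at {truth['tau_c_ns']} ns)")

profile = predict_pre_profile(ensemble, relax, tau_c=tau_c)
table = profile.table
near = table[table.r_eff <= 12.0]
print(f"\n{len(near)} residues lie within 12 A of the Cu; "
      f"max predicted ratio there = {near.predicted_ratio.max():.3f}")
print("(all < 0.2, i.e. > 80% signal loss — the PRE fingerprint of the"
      " copper site)")
print("\nclosest five residues:")
print(table.nsmallest(5, "r_eff").round(3).to_string(index=False))
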