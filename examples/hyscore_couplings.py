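"""Remote-nitrogen couplings: substrate-induced shifts and H bonds.

The two remote imidazole nitrogens of the histidine brace report on
Cu–His covalency (aiso, T) and on their N–H hydrogen bonds (quadrupole
asymmetry η from the ¹⁴N data).
"""

from importlib import resources

import pandas as pd

from histbrace import (RemoteNitrogen, classify_hbond,
                       cross_peak_frequencies, substrate_shift_report)

data = resources.files("histbrace.data")
df15 = pd.read_csv(data / "hyscore_15N.csv")
df14 = pd.read_csv(data / "hyscore_14N.csv")

par = df15[df15.orientation == "parallel"]
mk = lambda r: RemoteNitrogen(r.aiso, r.T, r.label, "15N")
before = [mk(r) for r in par[par["sample"] == "free"].itertuples()]
after = [mk(r) for r in par[par["sample"] == "chitin"].itertuples()]

print(substrate_shift_report(before, after).to_string(index=False))

na, nb = cross_peak_frequencies(before[0], 339.5, "parallel")
print(f"\nfirst-order cross peaks of N(A) at 339.5 mT (parallel): "
      f"{na:.2f} / {nb:.3f} MHz")

print("\nH-bond classification from the quadrupole asymmetry eta:")
for r in df14.itertuples():
    print(f"  {r.sample:6s} {r.label}: eta = {r.eta} -> "
          f"{classify_hbond(r.eta)}")
print("\nN(A)'s eta rises 0.7 -> 0.9 with chitin: the substrate drives a"
      "\nstrong H bond at that N-H, while N(B) is essentially unperturbed.")
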