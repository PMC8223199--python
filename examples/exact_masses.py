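"""Exact-mass arithmetic: the adduct registry and some well-known MALDI ions.

Every Δmass the pipeline matches against is derived from a molecular formula
and the bundled monoisotopic isotope-mass table — nothing is hand-entered.
"""

from msiadducts import default_registry, ion_mz, monoisotopic_mass

print("Default adduct registry (DHB + CHCA matrices):")
for entry in default_registry("all"):
    print(f"  {entry.name:12s} {entry.category:8s} Δmass = {entry.delta_mass:10.5f} Da"
          f"   (net change {entry.net_change})")

print()
print("Some reference ions (singly protonated, positive mode):")
pc36_1 = ion_mz("C44H86NO8P")
print(f"  [PC(36:1)+H]+              m/z {pc36_1:.3f}")
print(f"  its DHB-H2O matrix adduct  m/z {pc36_1 + monoisotopic_mass('C7H4O3'):.3f}")
print(f"  protonated DHB-H2O         m/z {ion_mz('C7H4O3'):.2f}")
print()
print("The 136.016 Da offset between a protonated metabolite and its")
print("[M+(DHB-H2O)+H]+ adduct is the dominant matrix-adduct signature in")
print("DHB-prepared MALDI imaging data.")
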