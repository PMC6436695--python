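"""Parse Nod-factor names, derive formulas and predict ion masses.

Run: python examples/01_structures_and_masses.py
"""

from lcoscreen import (
    M_PLUS_H,
    adduct_mz,
    average_mass,
    elemental_formula,
    fragment_ions,
    monoisotopic_mass,
    parse_structure,
)

# A sulfated, N-methylated pentameric LCO in Spaink nomenclature.
s = parse_structure("V (C18:1, NMe, S)")
f = elemental_formula(s)

print(f"structure      {s}")
print(f"formula        {f.hill()}")
print(f"monoisotopic   {monoisotopic_mass(f):.5f} Da")
print(f"average        {average_mass(f):.3f} Da")
print(f"[M+H]+ m/z     {adduct_mz(f, M_PLUS_H):.5f}")

print("\nB/Y glycosidic fragment ions (protonated):")
for ion in fragment_ions(s):
    print(f"  {ion.series}{ion.index}  m/z {ion.mz:10.4f}  (cleavage site {ion.cleavage_site})")

# The four B/Y pairs are the diagnostic ladder a targeted MS/MS screen
# compares against: each pair sums to the precursor mass plus two protons.
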