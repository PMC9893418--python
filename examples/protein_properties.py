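"""Physico-chemical profile grid of the translated ortholog family.

Prints the classic parameter bundle (molecular weight, pI, aliphatic
index, sulfur atoms, charge fractions, instability index, GRAVY) per
sequence.
"""

from orthostats import SimConfig, simulate_family, translate_set
from orthostats.protstats import physchem_grid, physchem_profile

seqs, _ = simulate_family(SimConfig(seed=11))
prots = translate_set(seqs)

print(physchem_grid(prots).to_string())

prof = physchem_profile(prots[0])
print(f"\n{prof.id}: {prof.stability_label} "
      f"(instability index {prof.instability_index:.2f}; < 40 is stable); "
      f"GRAVY {prof.gravy:.3f} "
      f"({'net hydrophobic' if prof.gravy > 0 else 'net hydrophilic'})")
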