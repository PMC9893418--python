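"""Kyte-Doolittle hydropathy profile and membrane-topology calling.

Builds a synthetic six-helix carrier protein and recovers its layout: six
transmembrane segments with four extracellular and three cytoplasmic
regions (both termini extracellular, as in mitochondrial carriers).
"""

from orthostats import kd_profile, make_membrane_protein, predict_topology

protein = make_membrane_protein(n_tm=6, seed=3)
profile = kd_profile(protein, window=19)
print(f"{protein.id}: {len(protein)} residues, "
      f"hydropathy range {min(profile.values):.2f} to {max(profile.values):.2f}")

model = predict_topology(protein, window=19, threshold=1.6, min_len=15, min_gap=5)
print(model.to_frame().to_string(index=False))
print("counts:", model.counts())
print("runs of windowed hydropathy above 1.6 are helix candidates; loops "
      "alternate sides starting extracellular at the N-terminus.")
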