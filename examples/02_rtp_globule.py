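"""Derive a residue transition pattern (RTP) from a peeled structure.

A pseudo-globule (random minimum-distance packing decorated with
pseudo-residues) stands in for a protein chain.  Each residue takes the
deepest layer any of its atoms reaches; read along the sequence this gives
a 1D fingerprint of how the chain weaves between surface and core.
"""

import mol_layers as ml
from mol_layers import fixtures as fx

globule = fx.generate_pseudo_globule(300, radius=12.0, min_dist=2.0, seed=7)
assignment = ml.peel(globule, ml.PeelingParams(sr=3.0))
pattern = ml.residue_layers(globule, assignment)

print(f"residues: {len(pattern)}, layers: {pattern.n_layers}")
print("1D pattern (S=surface, digits=sandwich depth, I=innermost):")
print(ml.render_rtp(pattern, "oneD"))
print()
print("2D block (sequence / hydrophobicity class / layer):")
print(ml.render_rtp(pattern, "twoD"))
print()
comp = ml.class_composition(pattern)
print("class composition (% of classified residues):", comp["percent"])
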