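"""Layer composition and residue propensity of a peeled structure.

Residue tallies use the RTP (deepest-layer) label; backbone vs side-chain
splits use the raw atom layers, since one residue's atoms often straddle
layers.  Propensity divides a residue type's occurrence fraction in a layer
by the layer's share of all residues: 1 means no preference.
"""

import mol_layers as ml
from mol_layers import fixtures as fx

globule = fx.generate_pseudo_globule(400, radius=14.0, min_dist=1.8, seed=3)
assignment = ml.merge_single_residue_im(globule, ml.peel(globule, ml.PeelingParams(sr=3.0)))
pattern = ml.residue_layers(globule, assignment, merge_single_im=False)
comp = ml.layer_composition(globule, pattern, assignment)

print("per-layer composition:")
print(comp.to_frame().to_string(index=False))
print()
print("backbone / side-chain split (% of heavy atoms per layer):")
print(ml.backbone_sidechain_fractions(comp).to_string(index=False))
print()
prop = ml.residue_propensity(comp)
print("five most surface-enriched residue types:")
surface = prop.query("layer_label == 'SURFACE'").dropna().nlargest(5, "propensity")
print(surface[["res_name", "count", "propensity"]].to_string(index=False))
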