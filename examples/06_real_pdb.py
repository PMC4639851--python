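"""Run the full pipeline on a real PDB file.

Usage:  python examples/06_real_pdb.py STRUCTURE.pdb [CHAIN]

Downloads are not performed here; point the script at any local PDB file
(e.g. barnase 1A2P, chain A).  Equivalent shell commands:

    mol-layers peel  STRUCTURE.pdb --chain A --out out/
    mol-layers rtp   STRUCTURE.pdb --chain A --out out/
    mol-layers sample STRUCTURE.pdb --sr-list 1.52,7,16 --out out/
"""

import sys

import mol_layers as ml

if len(sys.argv) < 2:
    print(__doc__)
    raise SystemExit(1)

path = sys.argv[1]
chain = sys.argv[2] if len(sys.argv) > 2 else None
policy = ml.SelectionPolicy(chain_filter=frozenset(chain) if chain else None)
structure = ml.read_structure(path, policy)

assignment = ml.peel(structure)
pattern = ml.residue_layers(structure, assignment)
comp = ml.class_composition(pattern)

print(f"{structure.source_id}: {structure.atom_count} atoms, "
      f"{len(pattern)} residues, {assignment.n_layers} layers "
      f"{assignment.layer_sizes}")
print("class composition (%):", comp["percent"])
surface_frac = sum(lab == "SURFACE" for lab in pattern.labels) / len(pattern)
print(f"surface-residue fraction: {100 * surface_frac:.0f}%")
print("RTP:", ml.render_rtp(pattern, "oneD"))
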