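# mol-layers

Peel protein structures into concentric atom layers, derive residue
transition patterns, and build coarse surface models by non-random
sampling.

## The problem and who this is for

Comparing protein folds with full sequence or structure alignment is
expensive at scale, and sequence methods miss structurally similar proteins
with low identity.  `mol-layers` implements a cheap geometric alternative
for structural bioinformaticians: strip a molecule's heavy atoms from the
periphery inward into **layers**, then read along the sequence which layer
each residue reaches.  The resulting 1D string — the **residue transition
pattern (RTP)** — is independent of molecular orientation, diffable as
plain text, and summarizes how the polypeptide weaves between surface and
core.  The same machinery yields tunable coarse-grained surface models for
shape comparison, and per-layer composition statistics (who lives in the
core, backbone vs side chain exposure).

## The algorithm

For every atom *A* of the active set, three unbounded cylinders of radius
*S<sub>r</sub>* are drawn through *A*, one along each Cartesian axis.  An
atom *B* belongs to the x-cylinder of *A* when its perpendicular distance

&nbsp;&nbsp;&nbsp;&nbsp;√((y<sub>B</sub> − y<sub>A</sub>)² + (z<sub>B</sub> − z<sub>A</sub>)²) &lt; *S<sub>r</sub>*

(and analogously for y and z).  Within each cylinder the atoms attaining
the maximum and minimum coordinate along the cylinder axis are marked as
layer members.  One pass over all active atoms and all three axes extracts
one layer; unmarked atoms are peeled in later passes until none remain.
Layer 1 is the **surface**, the last layer is the **innermost (IM)** core,
layers between are **sandwich** layers.  The default *S<sub>r</sub>* =
1.52 Å is the smallest heavy-atom radius in protein crystals; raising it
performs deterministic ("non-random") surface sampling at coarser fineness.

A residue's RTP label is the deepest layer any of its atoms reaches
(equivalently: its first occurrence when traversing from the IM layer
outward).  If the IM layer holds atoms of a single residue it is merged
into the layer above before labeling.

## Worked example

A 5×5×5 cubic lattice at 1.5 Å spacing is the exactly-enumerable case —
each pass strips the bounding-box faces of the remaining cube:

```sh
$ python examples/01_peel_lattice.py
atoms: 125
layers: 3
layer sizes (surface -> innermost): [98, 26, 1]
first ATOM record:
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  1.00           N
```

98 face atoms form the surface layer, the 26 face atoms of the inner 3×3×3
cube the sandwich layer, and the single central atom the IM layer.  The
layer number is written into the B-factor column (here `1.00`), so any
viewer can color a structure by layer.  Sampling the same lattice surface
retains 98 of 125 atoms — a 21.6 % reduction.

The other examples peel a random pseudo-globule and print its RTP, a
reduction profile across radii, layer composition/propensity tables, and a
stacked multi-structure consensus:

```sh
$ python examples/03_surface_sampling.py
total atoms: 400
   sr  atoms_retained  percent_reduction
 1.52             344              14.00
 3.00             194              51.50
 7.00             123              69.25
16.00              11              97.25
```

Retention falls as the cylinders widen, while the protruding bounding-box
atoms that define the molecular shape always survive.

## Command line

```sh
mol-layers peel   structure.pdb --chain A --out out/     # layers TSV + annotated PDB
mol-layers rtp    structure.pdb --chain A --out out/     # RTP TSV + 1D/2D text
mol-layers sample structure.pdb --sr-list 1.52,7,16      # surface sampling profile
mol-layers stats  structure.pdb                          # composition, propensity
mol-layers stack  a.pdb b.pdb --bins 100                 # RTP consensus matrix
mol-layers fixtures --kind lattice --n 5 --out lattice.pdb
```

Every run prints a JSON-lines summary and writes its resolved configuration
next to the outputs.

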