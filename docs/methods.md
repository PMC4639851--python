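# Methods

## The peeling model

The peeler operates on the heavy-atom point cloud of a polypeptide chain.
For a reference atom and an axis (x, y or z), the axis-aligned cylinder of
radius `sr` through the atom collects every active atom whose distance to
the reference, measured in the plane perpendicular to the axis, is
**strictly** less than `sr`; the cylinder is unbounded along its axis, so
the reference is always a member.  Within a cylinder, the atoms attaining
the maximum and the minimum coordinate along the axis are the cylinder's
periphery and are marked as layer members.  One pass — the union of these
extrema over every active atom and all three axes — extracts one layer.
Marked atoms are removed and passes repeat on the remainder until no atom
is left.  Layer 1 is the surface, the final layer the innermost (IM)
layer, and intermediate layers are sandwich layers.  Inner passes see only
the unassigned remainder: each inner layer is the surface of the core left
after removing the layers above it.

Because every pass is a set union over reference atoms, the result does not
depend on atom iteration order.  Two consequences used throughout the
tests: the atoms attaining the global min/max of each coordinate are always
in layer 1 (each is the extremum of its own cylinder), and any structure of
one or two atoms exhausts in a single layer.

## Parameters

- `sr` (Å, default **1.52**) — cylinder radius.  The default corresponds to
  the smallest heavy-atom radius in protein crystal structures, which makes
  the first layer a tight molecular surface.  Larger radii let atoms shadow
  each other inside wider cylinders, thinning the extracted surface: this
  is the non-random sampling mode.  Membership uses the squared comparison
  `d² < sr²`, mathematically identical to the strict distance comparison
  for positive radii.
- `tie_tolerance` (Å, default **1e-6**) — absolute tolerance for declaring
  atoms tied at a cylinder extremum; all tied atoms are selected.  Exact
  ties essentially never occur in refined crystal coordinates but dominate
  degenerate synthetic inputs (lattices, collinear chains); selecting all
  tied atoms keeps the algorithm deterministic and order-free.  No epsilon
  is applied to cylinder membership itself.

## Implementation and its oracle

`peel` accelerates each pass with a 2D k-d tree per axis on the projected
coordinates (scipy `cKDTree`); since the tree query is inclusive (d ≤ r),
hits are post-filtered with the strict `d² < sr²` test.  `peel_bruteforce`
is the direct all-pairs transcription of the same definition with no
acceleration structure.  The two are contract-identical, and the test suite
asserts bit-identical layer assignments across an ensemble of random
packings and radii {1.52, 3, 7, 16} Å.

## Residue transition pattern

A residue's label is the deepest (largest-numbered) layer containing any of
its atoms.  This is the order-free equivalent of "first occurrence when
traversing from the IM layer toward the surface".  Labels are `SURFACE`,
`SANDWICH_k` (k = 2..L−1) and `IM`; the 1D rendering uses the alphabet
`S`, `2`–`9`, `I` so patterns are diffable and alignable as strings, with
terminal colors (surface cyan, sandwich pink, IM yellow) as an optional
presentation layer.  A structure that peels into a single layer is labeled
all-`SURFACE`.

If the IM layer's atoms all belong to one residue, the layer is merged into
the one above before labeling (`merge_single_residue_im`, on by default in
the CLI): a one-residue core is insignificant for interactions.  The merge
never increases the layer count and only changes atoms previously in the
IM layer.

Residues are classified on a fixed four-class hydrophobicity scale —
hydrophilic (Gly, Thr, Ser, Trp, Tyr, Pro, His, Asn, Gln), hydrophobic
(Ile, Val, Leu, Phe, Cys, Met, Ala), positive (Lys, Arg), negative (Glu,
Asp) — partitioning the 20 standard residues 9/7/2/2.  Non-standard
residues get an explicit `X` marker (never dropped; they still carry a
layer label) unless the alias table (MSE→MET etc.) is enabled.

Stacking resamples each pattern onto `n_bins` (default 100) half-open
equal-width bins of relative sequence position — residue *i* of *n* maps to
bin `(i−1)·n_bins // n` — taking the majority label per bin with ties going
to the deeper layer.  Bins narrower than one residue inherit the previous
bin's label.  Patterns with different layer counts keep their depth labels
verbatim in the consensus summary; no cross-depth equivalence is imposed.

## Surface sampling

`sample_surface` is a single pass at the requested radius over the whole
molecule — not a re-peel of a previously extracted surface — and equals
layer 1 of a full peel at the same radius (asserted exactly in the tests).
The reduction profile evaluates each radius independently;
`percent_reduction = 100·(1 − retained/total)`.  Retention is empirically
non-increasing in `sr` on average over an ensemble; per-structure strict
monotonicity is not asserted, as tie geometry can locally violate it.

## Layer statistics

Residue-level tallies use the RTP label (one layer per residue); atom-level
backbone/side-chain tallies use the raw atom assignment, since residues
straddle layers.  Both granularities appear explicitly in the outputs, and
the composition function requires the RTP and the atom assignment to
describe the same (merged or unmerged) peel.  Backbone is {N, CA, C, O}
plus OXT, read as the terminal completion of the repeating backbone unit;
all other heavy atoms are side chain.  Propensity of residue type *r* in
layer *l* is `(c_rl / c_r) / (c_l / T)`; the count-weighted average across
layers is identically 1, which the tests assert to 1e-9.  Residues absent
from a layer get propensity 0 there; an empty layer yields an undefined
(NaN) propensity rather than a number.

## Structure I/O conventions

Parsing is backed by gemmi.  Defaults: heavy atoms only, first model only,
no HETATM, no waters; alternate locations collapse to the highest-occupancy
conformer (ties: first in file order).  These defaults reflect the
hydrogen-free X-ray models the 1.52 Å default radius presumes; flags admit
hydrogens, HETATM and waters for ligand-context use.  Residue identity is
the triple (chain, author number, insertion code); RTP positions renumber
observed residues contiguously from 1, keeping the author-numbering map in
the outputs.  Missing residues are not reconstructed — patterns are over
observed residues only.  Writing stores the layer number in the B-factor
column ("%6.2f"); a round trip through the parser reproduces coordinates at
PDB precision (1e-3 Å), and a second round trip is bit-exact.

## Synthetic data

Three generators exercise the geometry without downloads:

- **Cubic lattices** maximize coordinate ties and are exactly enumerable:
  the 5×5×5 lattice at 1.5 Å spacing peels to layers [98, 26, 1] (cube
  faces, inner-cube faces, center), a value derived with the brute-force
  oracle and frozen as a regression test.
- **Pseudo-globules**: rejection-sampled uniform points in a ball with a
  minimum inter-point distance (default 1.8–2.0 Å, emulating heavy-atom
  packing), then ordered along a greedy nearest-neighbor walk so that the
  pseudo-residues decorated onto consecutive atoms (4–8 atoms each, cycling
  the 20 standard names with backbone-style atom names) are spatially
  local, as in a real chain.  Deterministic per seed.
- **Collinear chains**: the 1D degenerate case, where shared-coordinate
  ties collapse everything into one layer.

What the fixtures do **not** emulate: covalent geometry, Ramachandran
statistics, secondary structure, or realistic packing density.  Passing
tests therefore demonstrate the geometric contracts (partition,
invariances, oracle equivalence, statistic identities), not biophysical
realism; the published per-protein numbers (e.g. a 63 % surface reduction
for an 18,119-atom metalloprotease) are checked in integration tests that
fetch the real structures and require network access.

## Numerical and design choices

- Exact invariances: translation and signed axis permutation (90°
  rotations/mirrors) leave assignments bit-identical, because the same
  squared differences are summed (IEEE addition is commutative).  General
  rotation is **not** an exact invariance of an axis-aligned algorithm; the
  orientation robustness of the RTP is treated as an empirical property.
  Measured on a 300-atom globule over 20 random proper rotations,
  per-residue label agreement averages ≈ 0.75 (range ≈ 0.60–0.85); the
  acceptance test declares a conservative mean ≥ 0.60.
- Problem sizes: the test ensemble uses 200 random globules of 30–500
  atoms and the acceptance script 120, sizes at which the brute-force
  oracle remains fast enough to cross-check every run.
- Degenerate inputs: empty selections raise a policy-naming error; an
  empty active set is a programming error and raises; a single atom peels
  to one layer labeled SURFACE.

## Known limitations

- Multi-chain assemblies peel mechanically as a unit but the published
  behavior is only characterized for single chains/domains.
- mmCIF input and NMR multi-model handling (beyond first-model) are not
  implemented.
- No RTP-based classifier is provided; patterns are compared as strings or
  stacked matrices.
- Synthetic globules are sparser than real proteins, so their surface
  reduction at the default radius (a few percent) is much smaller than the
  ~25 % average reported for real protein datasets; the package makes no
  claim of reproducing dataset-scale averages from synthetic inputs.
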