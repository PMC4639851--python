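"""The surface-peeling algorithm: concentric atom layers from cylinder extrema.

For every atom three unbounded cylinders of radius ``sr`` are drawn, one
along each Cartesian axis.  An atom belongs to a cylinder when its distance
to the reference atom, measured in the plane perpendicular to the cylinder
axis, is strictly less than ``sr``.  Within each cylinder the atoms
attaining the maximum and minimum coordinate along the axis — the cylinder's
periphery — are marked as layer members.  One full pass over all active
atoms and all three axes extracts one layer; atoms left unmarked are peeled
in subsequent passes until none remain.  Layer 1 is the surface, the final
layer is the innermost (IM) layer, intermediate layers are sandwich layers.

The default radius of 1.52 Å corresponds to the smallest heavy-atom radius
in protein crystal structures; larger radii coarsen the extracted surface
(see :mod:`mol_layers.sampling`).

Two implementations are provided with a bit-identical contract:
:func:`peel` (per-axis 2D k-d tree neighbor search) and
:func:`peel_bruteforce` (direct all-pairs transcription), the latter kept
as an independent oracle for the former.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "PeelingParams",
    "LayerAssignment",
    "cylinder_members",
    "extreme_members",
    "extract_one_layer",
    "extract_one_layer_bruteforce",
    "peel",
    "peel_bruteforce",
]

_AXES = {"x": 0, "y": 1, "z": 2}
DEFAULT_SR = 1.52


@dataclass(frozen=True)
class PeelingParams:
    """Tunable knobs of the peeler.

    sr : cylinder radius in Å (> 0). Default 1.52 Å, the smallest
        heavy-atom radius in protein crystals.
    tie_tolerance : absolute tolerance in Å for declaring two atoms tied at
        a cylinder extremum.  Exact ties never occur in refined crystal
        coordinates but dominate degenerate synthetic lattices; all tied
        atoms are selected, keeping the algorithm order-independent.
    """

    sr: float = DEFAULT_SR
    tie_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not self.sr > 0:
            raise ValueError(f"sr must be > 0, got {self.sr}")
        if self.tie_tolerance < 0:
            raise ValueError("tie_tolerance must be >= 0")


@dataclass
class LayerAssignment:
    """A complete partition of atoms into layers 1 (surface) .. L (innermost)."""

    layer_of: np.ndarray  # (N,) int, values 1..n_layers
    n_layers: int

    @property
    def members(self) -> list[np.ndarray]:
        """Per-layer atom index arrays, ordered layer 1..L."""
        return [np.flatnonzero(self.layer_of == k) for k in range(1, self.n_layers + 1)]

    @property
    def layer_sizes(self) -> list[int]:
        return [int((self.layer_of == k).sum()) for k in range(1, self.n_layers + 1)]

    def validate(self) -> None:
        """Assert the partition invariants: all atoms assigned, no empty layer."""
        if self.layer_of.min(initial=1) < 1 or self.layer_of.max(initial=1) > self.n_layers:
            raise ValueError("layer numbers out of range")
        present = np.unique(self.layer_of)
        if len(present) != self.n_layers:
            raise ValueError("empty layer in assignment")


def _as_index_array(active) -> np.ndarray:
    idx = np.asarray(sorted(active) if isinstance(active, (set, frozenset)) else active,
                     dtype=np.intp)
    return idx


def cylinder_members(
    coords: np.ndarray,
    active,
    ref: int,
    axis: str,
    params: PeelingParams | None = None,
) -> np.ndarray:
    """Atoms of ``active`` inside the axis-aligned cylinder through ``ref``.

    Membership is strict: perpendicular distance to ``ref`` < ``sr``.  The
    cylinder is unbounded along ``axis``, so the reference atom itself is
    always a member (distance 0).
    """
    params = params or PeelingParams()
    coords = np.asarray(coords, dtype=np.float64)
    idx = _as_index_array(active)
    if ref not in idx:
        raise ValueError(f"reference atom {ref} is not in the active set")
    keep = [i for i in range(3) if i != _AXES[axis]]
    d2 = ((coords[idx][:, keep] - coords[ref, keep]) ** 2).sum(axis=1)
    return idx[d2 < params.sr * params.sr]


def extreme_members(
    members,
    coords: np.ndarray,
    axis: str,
    params: PeelingParams | None = None,
) -> np.ndarray:
    """Members attaining the cylinder's axial maximum or minimum.

    All atoms within ``tie_tolerance`` of either extreme are returned; a
    single-member set returns that member.
    """
    params = params or PeelingParams()
    idx = _as_index_array(members)
    if len(idx) == 0:
        raise ValueError("empty member set")
    vals = np.asarray(coords, dtype=np.float64)[idx, _AXES[axis]]
    tol = params.tie_tolerance
    mask = (vals >= vals.max() - tol) | (vals <= vals.min() + tol)
    return idx[mask]


def extract_one_layer_bruteforce(
    coords: np.ndarray,
    active,
    params: PeelingParams | None = None,
) -> np.ndarray:
    """One peeling pass by direct enumeration over every (atom, axis) pair.

    O(N^2) per pass; the reference oracle for :func:`extract_one_layer`.
    """
    params = params or PeelingParams()
    coords = np.asarray(coords, dtype=np.float64)
    idx = _as_index_array(active)
    if len(idx) == 0:
        raise ValueError("empty active set")
    selected = np.zeros(len(idx), dtype=bool)
    sr2 = params.sr * params.sr
    tol = params.tie_tolerance
    for ax in range(3):
        keep = [i for i in range(3) if i != ax]
        plane = coords[idx][:, keep]
        along = coords[idx][:, ax]
        for i in range(len(idx)):
            d2 = ((plane - plane[i]) ** 2).sum(axis=1)
            in_cyl = d2 < sr2
            vals = along[in_cyl]
            hit = (vals >= vals.max() - tol) | (vals <= vals.min() + tol)
            where = np.flatnonzero(in_cyl)
            selected[where[hit]] = True
    return idx[selected]


def extract_one_layer(
    coords: np.ndarray,
    active,
    params: PeelingParams | None = None,
) -> np.ndarray:
    """One peeling pass, accelerated with a 2D k-d tree per axis.

    The tree query is inclusive (d <= r), so hits are post-filtered with the
    strict ``d^2 < sr^2`` comparison to stay bit-identical to
    :func:`extract_one_layer_bruteforce`.
    """
    params = params or PeelingParams()
    coords = np.asarray(coords, dtype=np.float64)
    idx = _as_index_array(active)
    if len(idx) == 0:
        raise ValueError("empty active set")
    selected = np.zeros(len(idx), dtype=bool)
    sr = params.sr
    sr2 = sr * sr
    tol = params.tie_tolerance
    for ax in range(3):
        keep = [i for i in range(3) if i != ax]
        plane = coords[idx][:, keep]
        along = coords[idx][:, ax]
        tree = cKDTree(plane)
        hits = tree.query_ball_point(plane, sr)
        for i, raw in enumerate(hits):
            raw = np.asarray(raw, dtype=np.intp)
            d2 = ((plane[raw] - plane[i]) ** 2).sum(axis=1)
            members = raw[d2 < sr2]
            vals = along[members]
            hit = (vals >= vals.max() - tol) | (vals <= vals.min() + tol)
            selected[members[hit]] = True
    return idx[selected]


def _peel_with(extract, structure: Structure, params: PeelingParams) -> LayerAssignment:
    coords = structure.coords
    n = len(coords)
    if n == 0:
        raise ValueError("empty structure")
    layer_of = np.zeros(n, dtype=np.intp)
    active = np.arange(n, dtype=np.intp)
    layer = 0
    while len(active):
        layer += 1
        chosen = extract(coords, active, params)
        layer_of[chosen] = layer
        mask = np.ones(len(active), dtype=bool)
        mask[np.searchsorted(active, chosen)] = False
        active = active[mask]
    out = LayerAssignment(layer_of=layer_of, n_layers=layer)
    out.validate()
    return out


def peel(structure: Structure, params: PeelingParams | None = None) -> LayerAssignment:
    """Peel a structure to exhaustion: layer 1 = surface, layer L = IM.

    Each pass operates on the atoms left unassigned by previous passes, so
    cylinders in inner passes see only the remaining core.  Deterministic
    for fixed input and parameters.
    """
    return _peel_with(extract_one_layer, structure, params or PeelingParams())


def peel_bruteforce(
    structure: Structure, params: PeelingParams | None = None
) -> LayerAssignment:
    """Identical contract to :func:`peel`, via the all-pairs oracle."""
    return _peel_with(extract_one_layer_bruteforce, structure, params or PeelingParams())
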