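"""Deterministic synthetic structures for exercising the peeling geometry.

Three generators cover the degenerate and the realistic ends of the input
space: cubic lattices (maximal coordinate ties, exactly enumerable layers),
minimum-distance-packed random points in a ball ("pseudo-globules", which
emulate the ~1.5-4 Å heavy-atom spacing of packed protein interiors without
any ties), and collinear chains (the 1D degenerate case).

Atoms are decorated into pseudo-residues — consecutive runs named after the
20 standard amino acids with backbone-style atom names — purely so that the
residue-level machinery (transition patterns, composition statistics) can
run on synthetic geometry.  The decoration is synthetic, not biophysical.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .structure_io import AtomRecord, Structure

__all__ = [
    "generate_lattice",
    "generate_pseudo_globule",
    "generate_collinear_chain",
    "STANDARD_RESIDUES",
]

STANDARD_RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# backbone unit first, then generic side-chain names
_ATOM_NAME_CYCLE = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]

_ELEMENT_OF = {"N": "N", "O": "O"}


def _decorate(coords: np.ndarray, source_id: str, residue_sizes) -> Structure:
    """Wrap raw coordinates into pseudo-residues of the given sizes."""
    atoms: list[AtomRecord] = []
    i = 0
    res_seq = 0
    for size in residue_sizes:
        res_seq += 1
        res_name = STANDARD_RESIDUES[(res_seq - 1) % len(STANDARD_RESIDUES)]
        for j in range(size):
            if i >= len(coords):
                break
            name = _ATOM_NAME_CYCLE[j % len(_ATOM_NAME_CYCLE)]
            atoms.append(
                AtomRecord(
                    serial=i + 1,
                    atom_name=name,
                    element=_ELEMENT_OF.get(name, "C"),
                    res_name=res_name,
                    chain_id="A",
                    res_seq=res_seq,
                    insertion_code="",
                    altloc="",
                    occupancy=1.0,
                    coords=(float(coords[i, 0]), float(coords[i, 1]), float(coords[i, 2])),
                )
            )
            i += 1
        if i >= len(coords):
            break
    return Structure(atoms=atoms, source_id=source_id)


def _constant_residue_sizes(n_atoms: int, size: int = 4):
    full, rem = divmod(n_atoms, size)
    sizes = [size] * full
    if rem:
        sizes.append(rem)
    return sizes


def generate_lattice(n: int, spacing: float = 1.5) -> Structure:
    """``n^3`` atoms on a cubic grid with the given spacing (Å).

    Decorated as consecutive 4-atom pseudo-residues.  Deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    pts = np.array(list(product(range(n), repeat=3)), dtype=np.float64) * spacing
    return _decorate(pts, f"lattice-{n}x{n}x{n}", _constant_residue_sizes(len(pts)))


def generate_pseudo_globule(
    n_atoms: int,
    radius: float = 12.0,
    min_dist: float = 2.0,
    seed: int = 0,
    max_attempts_per_atom: int = 2000,
) -> Structure:
    """Minimum-distance random packing of ``n_atoms`` points in a ball.

    Rejection sampling: uniform proposals in the ball of the given radius
    (Å) are accepted when at least ``min_dist`` from every accepted point.
    Accepted points are then ordered along a greedy nearest-neighbor chain
    so that consecutive atoms — and hence the pseudo-residues of 4-8 atoms
    they are decorated into — are spatially local, as residues of a real
    chain are.  The same seed always reproduces the same coordinates.

    Raises
    ------
    RuntimeError
        If the packing cannot be completed within the attempt budget
        (infeasible density).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    accepted = np.empty((n_atoms, 3), dtype=np.float64)
    count = 0
    budget = max_attempts_per_atom * n_atoms
    attempts = 0
    min2 = min_dist * min_dist
    while count < n_atoms:
        if attempts >= budget:
            raise RuntimeError(
                f"could not pack {n_atoms} atoms at min_dist {min_dist} Å within "
                f"radius {radius} Å after {budget} attempts"
            )
        attempts += 1
        p = rng.uniform(-radius, radius, size=3)
        if (p @ p) > radius * radius:
            continue
        if count and (((accepted[:count] - p) ** 2).sum(axis=1) < min2).any():
            continue
        accepted[count] = p
        count += 1

    # order points as a greedy nearest-neighbor walk: a crude polymer path
    # that keeps consecutive atoms (and residues) spatially local
    if n_atoms > 2:
        remaining = np.ones(n_atoms, dtype=bool)
        order = [0]
        remaining[0] = False
        for _ in range(n_atoms - 1):
            d2 = ((accepted - accepted[order[-1]]) ** 2).sum(axis=1)
            d2[~remaining] = np.inf
            nxt = int(np.argmin(d2))
            order.append(nxt)
            remaining[nxt] = False
        accepted = accepted[order]

    sizes: list[int] = []
    total = 0
    while total < n_atoms:
        s = int(rng.integers(4, 9))
        sizes.append(s)
        total += s
    return _decorate(
        accepted, f"globule-n{n_atoms}-seed{seed}", sizes
    )


def generate_collinear_chain(
    n: int, spacing: float = 1.0, axis: str = "x"
) -> Structure:
    """``n`` atoms evenly spaced on an axis-parallel line (degeneracy stressor)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    pts = np.zeros((n, 3), dtype=np.float64)
    pts[:, ax] = np.arange(n, dtype=np.float64) * spacing
    return _decorate(pts, f"chain-{axis}-{n}", _constant_residue_sizes(n))
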