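"""Non-random surface sampling: tunable coarse models of molecular shape.

A single peeling pass at the default cylinder radius extracts the molecular
surface.  Raising the radius beyond the default coarsens that surface
deterministically — nearby atoms shadow each other inside wider cylinders,
so fewer survive, but the atoms attaining the bounding-box extrema (the
protruding parts that define the molecule's shape) always do.  Unlike full
peeling, sampling never iterates: it is a one-pass operation on the whole
molecule at the requested radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peel import PeelingParams, extract_one_layer
from .structure_io import Structure

__all__ = ["SamplingProfile", "sample_surface", "reduction_profile"]


@dataclass
class SamplingProfile:
    """Atoms retained vs cylinder radius: the surface-reduction curve."""

    entries: list[tuple[float, int, float]]  # (sr, atoms_retained, percent_reduction)
    total_atoms: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["sr", "atoms_retained", "percent_reduction"]
        )


def sample_surface(
    structure: Structure, sr: float, tie_tolerance: float = 1e-6
) -> np.ndarray:
    """Surface atom indices at radius ``sr``: one peeling pass, no iteration.

    Equals layer 1 of a full peel at the same radius.  The six bounding-box
    extreme atoms survive at every radius, so the result is never empty.
    """
    params = PeelingParams(sr=sr, tie_tolerance=tie_tolerance)
    return extract_one_layer(structure.coords, np.arange(structure.atom_count), params)


def reduction_profile(structure: Structure, sr_values) -> SamplingProfile:
    """Sample the surface at each radius and tabulate the reduction.

    Radii are evaluated independently; ``percent_reduction`` is
    ``100 * (1 - retained / total)``.
    """
    sr_values = list(sr_values)
    if any(not sr > 0 for sr in sr_values):
        raise ValueError("all sr values must be > 0")
    total = structure.atom_count
    entries = []
    for sr in sr_values:
        kept = len(sample_surface(structure, sr))
        entries.append((float(sr), kept, 100.0 * (1.0 - kept / total)))
    return SamplingProfile(entries=entries, total_atoms=total)
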