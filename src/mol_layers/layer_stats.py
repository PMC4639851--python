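"""Composition and propensity analytics over peeled layers.

Residue-level tallies (who lives in which layer) use the residue transition
pattern, where each residue carries its deepest layer.  Atom-level tallies
(backbone vs side chain) use the raw atom assignment, since a residue's
atoms routinely straddle layers.  Backbone atoms are the repeating unit
N, CA, C, O — plus the terminal OXT, read as the completion of that unit;
every other heavy atom is side chain.

Propensity normalizes layer occupancy for sequence composition: a residue
type's occurrence fraction in a layer divided by the layer's share of all
residues.  1 means no preference; >1 enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .peel import LayerAssignment
from .rtp import RTP
from .structure_io import Structure

__all__ = [
    "BACKBONE_ATOMS",
    "LayerComposition",
    "CompositionTable",
    "layer_composition",
    "residue_propensity",
    "backbone_sidechain_fractions",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class LayerComposition:
    """Counts for a single layer label."""

    residue_counts: dict[str, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)
    backbone_atoms: int = 0
    sidechain_atoms: int = 0
    total_atoms: int = 0
    total_residues: int = 0


@dataclass
class CompositionTable:
    """Per-layer-label composition of a peeled structure."""

    layers: dict[str, LayerComposition]  # keyed by layer label, surface..IM order
    structure_atoms: int
    structure_residues: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, c in self.layers.items():
            rows.append(
                {
                    "layer_label": label,
                    "total_residues": c.total_residues,
                    "total_atoms": c.total_atoms,
                    "backbone_atoms": c.backbone_atoms,
                    "sidechain_atoms": c.sidechain_atoms,
                    **{f"class_{k}": v for k, v in sorted(c.class_counts.items())},
                }
            )
        return pd.DataFrame(rows)


def _label_for(layer: int, n_layers: int) -> str:
    if layer == 1:
        return "SURFACE"
    if layer == n_layers:
        return "IM"
    return f"SANDWICH_{layer}"


def layer_composition(
    structure: Structure, rtp: RTP, layers: LayerAssignment
) -> CompositionTable:
    """Tally residues (by RTP label) and atoms (by atom layer) per layer.

    ``rtp`` and ``layers`` must describe the same peel: pass the merged
    assignment when the RTP was derived with the single-residue-IM merge.
    """
    if len(layers.layer_of) != structure.atom_count:
        raise ValueError("layer assignment does not match structure")
    if rtp.n_layers != layers.n_layers:
        raise ValueError(
            f"RTP has {rtp.n_layers} layers but assignment has {layers.n_layers}; "
            "pass the same (merged or unmerged) assignment used to build the RTP"
        )

    labels = [_label_for(k, layers.n_layers) for k in range(1, layers.n_layers + 1)]
    table = {
        lab: LayerComposition(class_counts={"HPL": 0, "HPB": 0, "POS": 0, "NEG": 0})
        for lab in labels
    }

    for rec in rtp.records:
        c = table[rec.layer_label]
        c.total_residues += 1
        c.residue_counts[rec.res_name] = c.residue_counts.get(rec.res_name, 0) + 1
        c.class_counts[rec.residue_class] = c.class_counts.get(rec.residue_class, 0) + 1

    for i, atom in enumerate(structure.atoms):
        c = table[_label_for(int(layers.layer_of[i]), layers.n_layers)]
        c.total_atoms += 1
        if atom.atom_name.strip().upper() in BACKBONE_ATOMS:
            c.backbone_atoms += 1
        else:
            c.sidechain_atoms += 1

    return CompositionTable(
        layers=table,
        structure_atoms=structure.atom_count,
        structure_residues=len(rtp),
    )


def residue_propensity(composition: CompositionTable) -> pd.DataFrame:
    """Per (residue, layer) propensity: occurrence ratio over layer share.

    ``propensity = (count_{r,l} / count_r) / (count_l / total)``.  Residues
    absent from the structure are simply absent from the table; a residue
    present overall but absent from a layer gets propensity 0 there.  The
    count-weighted average of a residue's propensities across layers is 1.
    """
    total = composition.structure_residues
    if total == 0:
        raise ValueError("composition has no residues")
    layer_tot = {lab: c.total_residues for lab, c in composition.layers.items()}
    res_tot: dict[str, int] = {}
    for c in composition.layers.values():
        for res, n in c.residue_counts.items():
            res_tot[res] = res_tot.get(res, 0) + n

    rows = []
    for res, n_res in sorted(res_tot.items()):
        for lab, c in composition.layers.items():
            n_rl = c.residue_counts.get(res, 0)
            if layer_tot[lab] == 0:
                prop = math.nan  # undefined for an empty layer
            else:
                prop = (n_rl / n_res) / (layer_tot[lab] / total)
            rows.append(
                {
                    "res_name": res,
                    "layer_label": lab,
                    "count": n_rl,
                    "residue_total": n_res,
                    "layer_total": layer_tot[lab],
                    "propensity": prop,
                }
            )
    return pd.DataFrame(rows)


def backbone_sidechain_fractions(composition: CompositionTable) -> pd.DataFrame:
    """Per-layer backbone / side-chain percentages of heavy atoms (sum 100)."""
    rows = []
    for lab, c in composition.layers.items():
        if c.total_atoms == 0:
            bb = sc = math.nan
        else:
            bb = 100.0 * c.backbone_atoms / c.total_atoms
            sc = 100.0 * c.sidechain_atoms / c.total_atoms
        rows.append({"layer_label": lab, "backbone_pct": bb, "sidechain_pct": sc})
    return pd.DataFrame(rows)
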