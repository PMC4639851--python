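"""Residue transition patterns (RTP): the 1D fingerprint of a peeled fold.

A peeled structure assigns every atom to a layer; the RTP lifts this to
residues.  Traversing from the innermost (IM) layer outward, a residue is
labeled with the first layer in which any of its atoms appears — i.e. the
deepest layer touched by the residue.  Read along the sequence, the
resulting string of layer labels summarizes how the polypeptide weaves in
and out of the molecular interior: a final snapshot of the folding pattern
that is independent of molecular orientation, cheap to compare across
structures, and alignable as plain text.

Residues are also classified on a four-class hydrophobicity scale
(hydrophilic / hydrophobic / positively / negatively charged) so patterns
can be read jointly with chemistry.

If the IM layer consists of atoms from a single residue it is merged into
the layer above before labeling — one residue is too small to constitute a
meaningful core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peel import LayerAssignment
from .structure_io import Structure

__all__ = [
    "RESIDUE_CLASSES",
    "RTPRecord",
    "RTP",
    "classify_residue",
    "merge_single_residue_im",
    "residue_layers",
    "class_composition",
    "render_rtp",
    "stack_rtp",
]

# Four-class hydrophobicity scale partitioning the 20 standard residues.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "HPL": frozenset({"GLY", "THR", "SER", "TRP", "TYR", "PRO", "HIS", "ASN", "GLN"}),
    "HPB": frozenset({"ILE", "VAL", "LEU", "PHE", "CYS", "MET", "ALA"}),
    "POS": frozenset({"LYS", "ARG"}),
    "NEG": frozenset({"GLU", "ASP"}),
}

UNCLASSIFIED = "X"

# common non-standard residue aliases, applied only on request
NONSTANDARD_ALIASES = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_CLASS_SYMBOL = {"HPL": "L", "HPB": "B", "POS": "+", "NEG": "-", UNCLASSIFIED: "X"}

# terminal color codes used by the optional colored 1D rendering:
# IM yellow, sandwich pink, surface cyan
_ANSI = {"IM": "\x1b[43m", "SANDWICH": "\x1b[45m", "SURFACE": "\x1b[46m"}
_ANSI_RESET = "\x1b[0m"


def classify_residue(res_name: str, map_nonstandard: bool = False) -> str:
    """Classify a three-letter residue code on the four-class scale.

    Returns ``"HPL"``, ``"HPB"``, ``"POS"`` or ``"NEG"``; non-standard
    residues return the explicit unclassified marker ``"X"`` (never silently
    dropped) unless ``map_nonstandard`` enables the alias table
    (e.g. MSE -> MET).
    """
    code = res_name.strip().upper()
    if map_nonstandard:
        code = NONSTANDARD_ALIASES.get(code, code)
    for cls, members in RESIDUE_CLASSES.items():
        if code in members:
            return cls
    return UNCLASSIFIED


@dataclass(frozen=True)
class RTPRecord:
    """One residue of a transition pattern."""

    sequential_index: int
    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    residue_class: str
    layer: int  # 1 = surface .. n_layers = IM
    layer_label: str  # SURFACE | SANDWICH_k | IM


@dataclass
class RTP:
    """Per-residue layer labels in sequence order for one structure."""

    records: list[RTPRecord]
    n_layers: int
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.layer_label for r in self.records]

    @property
    def layers(self) -> np.ndarray:
        return np.array([r.layer for r in self.records], dtype=np.intp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.sequential_index for r in self.records],
                "chain": [r.chain_id for r in self.records],
                "res_seq": [r.res_seq for r in self.records],
                "icode": [r.insertion_code for r in self.records],
                "res_name": [r.res_name for r in self.records],
                "class": [r.residue_class for r in self.records],
                "layer_label": [r.layer_label for r in self.records],
            }
        )


def _label_for(layer: int, n_layers: int) -> str:
    if layer == 1:
        return "SURFACE"
    if layer == n_layers:
        return "IM"
    return f"SANDWICH_{layer}"


def _layer_symbol(layer: int, n_layers: int) -> str:
    if layer == 1:
        return "S"
    if layer == n_layers:
        return "I"
    return str(layer) if layer <= 9 else "*"


def merge_single_residue_im(
    structure: Structure, layers: LayerAssignment
) -> LayerAssignment:
    """Merge the IM layer into the layer above if it holds a single residue.

    A one-residue core is insignificant for interactions, so its atoms are
    reassigned to layer L-1 and the layer count drops by one.  Returns the
    input unchanged when the rule does not apply (L == 1 or a multi-residue
    IM layer).
    """
    if layers.n_layers < 2:
        return layers
    im_atoms = np.flatnonzero(layers.layer_of == layers.n_layers)
    im_residues = {structure.atoms[i].residue_key for i in im_atoms}
    if len(im_residues) != 1:
        return layers
    new_layer_of = layers.layer_of.copy()
    new_layer_of[im_atoms] = layers.n_layers - 1
    return LayerAssignment(layer_of=new_layer_of, n_layers=layers.n_layers - 1)


def residue_layers(
    structure: Structure,
    layers: LayerAssignment,
    merge_single_im: bool = True,
    map_nonstandard: bool = False,
) -> RTP:
    """Derive the residue transition pattern from an atom-level assignment.

    Each residue takes the deepest (largest-numbered) layer containing any
    of its atoms — equivalent to first occurrence when traversing from the
    IM layer toward the surface.  With ``merge_single_im`` a single-residue
    IM layer is folded into the layer above before labeling.
    """
    if len(layers.layer_of) != structure.atom_count:
        raise ValueError(
            f"assignment covers {len(layers.layer_of)} atoms, structure has "
            f"{structure.atom_count}"
        )
    if merge_single_im:
        layers = merge_single_residue_im(structure, layers)

    deepest: dict[tuple, int] = {}
    names: dict[tuple, str] = {}
    order: list[tuple] = []
    for i, atom in enumerate(structure.atoms):
        key = atom.residue_key
        lay = int(layers.layer_of[i])
        if key not in deepest:
            deepest[key] = lay
            names[key] = atom.res_name
            order.append(key)
        elif lay > deepest[key]:
            deepest[key] = lay

    records = [
        RTPRecord(
            sequential_index=i + 1,
            chain_id=key[0],
            res_seq=key[1],
            insertion_code=key[2],
            res_name=names[key],
            residue_class=classify_residue(names[key], map_nonstandard),
            layer=deepest[key],
            layer_label=_label_for(deepest[key], layers.n_layers),
        )
        for i, key in enumerate(order)
    ]
    return RTP(records=records, n_layers=layers.n_layers, source_id=structure.source_id)


def class_composition(rtp: RTP) -> dict:
    """Residue-class composition over classifiable residues.

    Returns raw fractions (summing to 1 over the four classes), rounded
    integer percentages for reporting, and counts (including unclassified).
    """
    if len(rtp) == 0:
        raise ValueError("empty RTP")
    counts = {c: 0 for c in RESIDUE_CLASSES}
    counts[UNCLASSIFIED] = 0
    for r in rtp.records:
        counts[r.residue_class] += 1
    n_classified = sum(counts[c] for c in RESIDUE_CLASSES)
    fractions = {
        c: (counts[c] / n_classified if n_classified else float("nan"))
        for c in RESIDUE_CLASSES
    }
    percents = {c: round(100 * fractions[c]) if n_classified else None for c in RESIDUE_CLASSES}
    return {"counts": counts, "fractions": fractions, "percent": percents}


def render_rtp(rtp: RTP, mode: str = "oneD", color: bool = False) -> str:
    """Render an RTP as text.

    ``oneD``: one symbol per residue — ``S`` surface, ``2``..``9`` sandwich
    depth, ``I`` innermost — optionally wrapped in terminal colors
    (IM yellow, sandwich pink, surface cyan).  ``twoD``: a multi-line block
    pairing the one-letter sequence with per-residue class and layer rows.
    """
    symbols = [_layer_symbol(r.layer, rtp.n_layers) for r in rtp.records]
    if mode == "oneD":
        if not color:
            return "".join(symbols)
        out = []
        for r, sym in zip(rtp.records, symbols):
            kind = "IM" if sym == "I" else ("SURFACE" if sym == "S" else "SANDWICH")
            out.append(f"{_ANSI[kind]}{sym}{_ANSI_RESET}")
        return "".join(out)
    if mode == "twoD":
        seq = "".join(_THREE_TO_ONE.get(r.res_name.upper(), "X") for r in rtp.records)
        cls = "".join(_CLASS_SYMBOL[r.residue_class] for r in rtp.records)
        lay = "".join(symbols)
        return f"seq   {seq}\nclass {cls}\nlayer {lay}"
    raise ValueError(f"unknown mode {mode!r}")


def stack_rtp(rtps: list[RTP], n_bins: int = 100) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack RTPs on a common relative-position axis for consensus plots.

    Each pattern is resampled onto ``n_bins`` equal-width bins of relative
    sequence position (residue ``i`` of a length-``n`` pattern falls in bin
    ``(i-1)*n_bins // n``).  A bin takes the majority layer label of its
    residues, ties resolving to the deeper layer; bins narrower than one
    residue inherit the previous bin's label.

    Returns the (structures x bins) label matrix, rows in input order, and a
    long-format frequency table (bin, layer_label, count) for consensus
    summaries.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not rtps:
        raise ValueError("no RTPs to stack")
    for r in rtps:
        if len(r) == 0:
            raise ValueError("empty RTP in stack")

    matrix = np.empty((len(rtps), n_bins), dtype=object)
    for row, rtp in enumerate(rtps):
        n = len(rtp)
        per_bin: list[list[RTPRecord]] = [[] for _ in range(n_bins)]
        for i, rec in enumerate(rtp.records):
            per_bin[(i * n_bins) // n].append(rec)
        prev = None
        for b in range(n_bins):
            if per_bin[b]:
                votes: dict[str, int] = {}
                depth: dict[str, int] = {}
                for rec in per_bin[b]:
                    votes[rec.layer_label] = votes.get(rec.layer_label, 0) + 1
                    depth[rec.layer_label] = rec.layer
                best = max(votes, key=lambda lab: (votes[lab], depth[lab]))
                matrix[row, b] = best
                prev = best
            else:
                matrix[row, b] = prev
    freq = (
        pd.DataFrame(
            [
                {"bin": b, "layer_label": matrix[row, b]}
                for row in range(len(rtps))
                for b in range(n_bins)
            ]
        )
        .groupby(["bin", "layer_label"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return matrix, freq
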