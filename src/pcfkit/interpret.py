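"""Attention-based attribution of carbon-footprint predictions to atoms and
substructures.

The decoder's self-attention maps are row-stochastic over atoms; the
attention an atom *receives* (column mass), averaged over decoder blocks and
heads and renormalized, gives a per-atom weight vector summing to 1.
Summing those weights over user-supplied atom subsets (functional groups, or
atoms mapped to synthesis precursors) yields relative substructure
contributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .abt_model import TrainedModel

__all__ = ["AttributionMap", "attribute", "substructure_contribution", "render"]


@dataclass
class AttributionMap:
    smiles: str
    atom_weights: np.ndarray           # (n_atoms,) non-negative, sums to 1
    block_head_raw: list[np.ndarray]   # per decoder block: (heads, n, n)


def attribute(model: TrainedModel, smiles: str, aggregation: str = "mean",
              direction: str = "received") -> AttributionMap:
    """Collapse decoder attention into per-atom weights.

    `aggregation`: "mean" (default) or "max" over blocks and heads.
    `direction`: "received" pools each atom's incoming attention (column
    means of the row-stochastic maps); "emitted" pools outgoing rows.
    """
    attn = model.attention(smiles)  # list of (heads, n, n)
    stacked = np.concatenate(attn, axis=0)  # (blocks*heads, n, n)
    axis = 1 if direction == "received" else 2
    if direction not in ("received", "emitted"):
        raise ValueError(f"unknown direction: {direction!r}")
    per_map = stacked.mean(axis=axis)  # (blocks*heads, n)
    if aggregation == "mean":
        raw = per_map.mean(axis=0)
    elif aggregation == "max":
        raw = per_map.max(axis=0)
    else:
        raise ValueError(f"unknown aggregation: {aggregation!r}")
    weights = raw / raw.sum()
    return AttributionMap(smiles=smiles, atom_weights=weights, block_head_raw=attn)


def substructure_contribution(a: AttributionMap,
                              atom_subsets: dict[str, set[int] | list[int]]) -> dict[str, float]:
    """share(S) = sum of atom weights over S; shares of a partition sum to 1."""
    n = len(a.atom_weights)
    shares: dict[str, float] = {}
    for name, subset in atom_subsets.items():
        idx = sorted(set(int(i) for i in subset))
        if idx and (idx[0] < 0 or idx[-1] >= n):
            raise IndexError(f"atom index out of range for subset {name!r}")
        shares[name] = float(a.atom_weights[idx].sum()) if idx else 0.0
    return shares


def _ramp(t: float) -> tuple[float, float, float]:
    # green (low) -> yellow -> red (high)
    return (min(1.0, 2 * t), min(1.0, 2 * (1 - t)), 0.2)


def render(smiles: str, a: AttributionMap, path) -> Path:
    """Write a 2-D depiction with atoms shaded green (low weight) to red
    (high), plus a JSON sidecar with the weights and the color-scale anchors.

    The ramp is anchored per molecule (min weight -> green, max -> red).
    Output format follows the file extension: .svg (default) or .png.
    """
    path = Path(path)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    if mol.GetNumAtoms() != len(a.atom_weights):
        raise ValueError("attribution map does not match molecule size")
    rdDepictor.Compute2DCoords(mol)
    w = a.atom_weights
    lo, hi = float(w.min()), float(w.max())
    scaled = np.zeros_like(w) if hi <= lo else (w - lo) / (hi - lo)
    colors = {i: _ramp(float(t)) for i, t in enumerate(scaled)}
    if path.suffix.lower() == ".png":
        drawer = rdMolDraw2D.MolDraw2DCairo(500, 400)
    else:
        drawer = rdMolDraw2D.MolDraw2DSVG(500, 400)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol,
        highlightAtoms=list(range(mol.GetNumAtoms())),
        highlightAtomColors=colors,
    )
    drawer.FinishDrawing()
    data = drawer.GetDrawingText()
    if isinstance(data, str):
        path.write_text(data)
    else:
        path.write_bytes(data)
    sidecar = {
        "smiles": smiles,
        "atom_weights": [float(x) for x in w],
        "elements": [atom.GetSymbol() for atom in mol.GetAtoms()],
        "legend": {"min_weight": lo, "max_weight": hi,
                   "low_color": "green", "high_color": "red"},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path
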