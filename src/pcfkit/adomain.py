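"""Applicability domain (AD) via k-nearest-neighbor Euclidean distance on
extended-connectivity fingerprints.

A query chemical is inside the domain when its mean Euclidean distance to the
k most similar training chemicals does not exceed a threshold T fitted on the
training set: T = Ybar + Z * sigma, where Ybar and sigma are the mean and
standard deviation of the training molecules' own k-NN distances.  Defaults
k = 5 and Z = 0.5 follow the conventional QSAR recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .datakit import Dataset
from .featurize import InvalidStructureError, compute_fingerprint

__all__ = [
    "ADModel",
    "ADResult",
    "euclidean_distance",
    "fit_ad",
    "classify",
    "screen_inventory",
    "coverage_summary",
    "normalize_inventory",
]

_METAL_FREE = {
    "H", "He", "B", "C", "N", "O", "F", "Ne", "Si", "P", "S", "Cl", "Ar",
    "Ge", "As", "Se", "Br", "Kr", "Sb", "Te", "I", "Xe", "At", "Rn",
}


def euclidean_distance(a, b) -> float:
    """sqrt(sum (a_i - b_i)^2); for bit vectors this equals
    sqrt(Hamming distance)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


@dataclass
class ADModel:
    reference_fps: np.ndarray      # (n_ref, n_bits)
    reference_smiles: list[str]
    k: int
    Z: float
    Ybar: float
    sigma: float
    T: float


@dataclass
class ADResult:
    smiles: str
    mean_knn_distance: float
    within_ad: bool
    nearest_neighbors: list[tuple[int, float]]


def _fp_matrix(smiles: list[str]) -> np.ndarray:
    return np.vstack([compute_fingerprint(s, "ECFP4").bits for s in smiles]).astype(np.float64)


def _pairwise_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # exact squared Euclidean distances; no approximate shortcuts
    d2 = (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :] - 2.0 * a @ b.T
    return np.maximum(d2, 0.0)


def fit_ad(train: Dataset | list[str], k: int = 5, Z: float = 0.5,
           population_sigma: bool = True) -> ADModel:
    """Fit the distance threshold on the training set.

    Each training molecule's mean distance to its k nearest *other* training
    molecules (self excluded) feeds Ybar and sigma; by default sigma uses the
    population divisor n.
    """
    smiles = train.smiles if isinstance(train, Dataset) else list(train)
    n = len(smiles)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of reference molecules ({n})")
    fps = _fp_matrix(smiles)
    d = np.sqrt(_pairwise_sq(fps, fps))
    np.fill_diagonal(d, np.inf)  # exclude self-matches
    knn_means = np.sort(d, axis=1)[:, :k].mean(axis=1)
    ybar = float(knn_means.mean())
    sigma = float(knn_means.std(ddof=0 if population_sigma else 1))
    return ADModel(reference_fps=fps, reference_smiles=smiles, k=k, Z=Z,
                   Ybar=ybar, sigma=sigma, T=ybar + Z * sigma)


def classify(ad: ADModel, smiles: str) -> ADResult:
    """Mean distance to the k nearest references, compared to T.

    A distance exactly equal to T counts as within the domain (only distances
    strictly above the threshold fall outside).
    """
    fp = compute_fingerprint(smiles, "ECFP4").bits.astype(np.float64)
    d = np.sqrt(_pairwise_sq(fp[None, :], ad.reference_fps))[0]
    order = np.argsort(d, kind="stable")[: ad.k]
    mean_d = float(d[order].mean())
    return ADResult(
        smiles=smiles,
        mean_knn_distance=mean_d,
        within_ad=mean_d <= ad.T,
        nearest_neighbors=[(int(i), float(d[i])) for i in order],
    )


def normalize_inventory(smiles_list: list[str]) -> list[str]:
    """Prepare an external chemical inventory for AD screening.

    Detachable metal counterions are stripped (the organic component is
    kept); multi-organic mixtures, polymers and inorganic entries are
    dropped; survivors are deduplicated by canonical SMILES, preserving
    first-seen order.
    """
    seen: set[str] = set()
    out: list[str] = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
            continue  # polymer attachment points
        frags = Chem.GetMolFrags(mol, asMols=True)
        organic = [f for f in frags
                   if all(a.GetSymbol() in _METAL_FREE for a in f.GetAtoms())]
        if len(organic) != 1:
            continue  # pure salt, or a multi-organic mixture
        keep = organic[0]
        if not any(a.GetSymbol() == "C" and
                   (a.GetTotalNumHs() > 0 or
                    any(nb.GetSymbol() == "C" for nb in a.GetNeighbors()))
                   for a in keep.GetAtoms()):
            continue  # inorganic
        canonical = Chem.MolToSmiles(keep)
        if canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
    return out


def screen_inventory(ad: ADModel, inventory: Dataset | list[str]) -> tuple[pd.DataFrame, float]:
    """Classify every inventory chemical; return the per-record table and the
    within-AD percentage.

    The table also carries molecular weight, heteroatom count and ring count
    so coverage can be summarized inside vs outside the domain.
    """
    smiles = inventory.smiles if isinstance(inventory, Dataset) else list(inventory)
    if len(smiles) == 0:
        raise ValueError("empty inventory")
    rows = []
    for smi in smiles:
        res = classify(ad, smi)
        mol = Chem.MolFromSmiles(smi)
        rows.append(
            {
                "smiles": smi,
                "mean_knn_distance": res.mean_knn_distance,
                "within_ad": res.within_ad,
                "mol_weight": Descriptors.MolWt(mol),
                "n_heteroatoms": sum(1 for a in mol.GetAtoms()
                                     if a.GetSymbol() not in ("C", "H")),
                "n_rings": rdMolDescriptors.CalcNumRings(mol),
            }
        )
    table = pd.DataFrame(rows)
    pct = float(100.0 * table["within_ad"].mean())
    return table, pct


def coverage_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Distribution of molecular weight, heteroatom count and ring count for
    chemicals inside vs outside the domain (median and quartiles)."""
    props = ["mol_weight", "n_heteroatoms", "n_rings"]
    return table.groupby("within_ad")[props].describe(percentiles=[0.25, 0.5, 0.75])
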