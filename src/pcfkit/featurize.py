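"""Molecular featurization: graph features, interatomic matrices, descriptors,
and the three baseline fingerprints.

Atom and bond features are one-hot blocks (each block sums to exactly 1), so
downstream models never interpret category indices as magnitudes.  Interatomic
matrices (adjacency, topological distance, Coulomb) carry the pairwise
structural/electrostatic signal used as attention bias by the regressor.

Molecules are featurized in the atom order of the *input* SMILES (no internal
canonicalization), which keeps permutation-covariance properties testable.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, MACCSkeys, rdFingerprintGenerator

logger = logging.getLogger(__name__)

__all__ = [
    "MolGraph",
    "DescriptorVector",
    "Fingerprint",
    "InvalidStructureError",
    "featurize_graph",
    "coulomb_matrix",
    "compute_descriptors",
    "compute_fingerprint",
    "descriptor_manifest",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
]


class InvalidStructureError(ValueError):
    """Raised when a SMILES string does not parse to a usable molecule."""


# ----------------------------------------------------------------- vocabulary
ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si")  # + other
DEGREES = tuple(range(6))  # + ">=6"
CHIRALITY = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)  # + other
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)  # + other
NUM_HS = tuple(range(5))  # + ">=5"
BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
)

ATOM_FEATURE_DIM = (len(ELEMENTS) + 1) + (len(DEGREES) + 1) + (len(CHIRALITY) + 1) \
    + (len(HYBRIDIZATIONS) + 1) + (len(NUM_HS) + 1) + 2
BOND_FEATURE_DIM = len(BOND_ORDERS) + len(BOND_STEREO) + 2 + 2

_SURROGATE_BOND_LENGTH = 1.5  # Angstrom per topological bond step


def _one_hot(value, choices) -> list[float]:
    """One-hot over `choices` with a trailing catch-all slot."""
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _flag(value: bool) -> list[float]:
    return [0.0, 1.0] if value else [1.0, 0.0]


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"SMILES does not parse: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise InvalidStructureError(f"empty molecule: {smiles!r}")
    return mol


# ------------------------------------------------------------------ MolGraph
@dataclass
class MolGraph:
    """Per-molecule feature bundle consumed by the regressor.

    `bond_feats`/`bond_index` list each bond once per direction; the matrices
    are indexed by the atom order of the parsed SMILES.
    """

    smiles: str
    n_atoms: int
    atom_feats: np.ndarray          # (n_atoms, ATOM_FEATURE_DIM) {0,1}
    bond_feats: np.ndarray          # (n_directed_bonds, BOND_FEATURE_DIM) {0,1}
    bond_index: np.ndarray          # (n_directed_bonds, 2) int, (source, target)
    adjacency: np.ndarray           # (n, n) {0,1}
    topo_dist: np.ndarray           # (n, n) shortest-path bond counts
    coulomb: np.ndarray             # (n, n) real

    @property
    def n_bonds(self) -> int:
        return self.bond_index.shape[0]


def featurize_graph(smiles: str, coulomb_mode: str = "topological3d",
                    seed: int = 0) -> MolGraph:
    """Build the atom/bond one-hot matrices and interatomic matrices.

    Hydrogens stay implicit; a single-atom molecule yields an empty bond list
    and 1x1 matrices.
    """
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumAtoms()

    atom_rows = []
    for atom in mol.GetAtoms():
        atom_rows.append(
            _one_hot(atom.GetSymbol(), ELEMENTS)
            + _one_hot(atom.GetDegree(), DEGREES)
            + _one_hot(atom.GetChiralTag(), CHIRALITY)
            + _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
            + _one_hot(atom.GetTotalNumHs(), NUM_HS)
            + _flag(atom.GetIsAromatic())
        )
    atom_feats = np.asarray(atom_rows, dtype=np.float64).reshape(n, ATOM_FEATURE_DIM)

    bond_rows, index_rows = [], []
    for bond in mol.GetBonds():
        feats = (
            _one_hot(bond.GetBondType(), BOND_ORDERS)[:len(BOND_ORDERS)]
            + _one_hot(bond.GetStereo(), BOND_STEREO)[:len(BOND_STEREO)]
            + _flag(bond.GetIsConjugated())
            + _flag(bond.IsInRing())
        )
        # exotic bond orders (dative etc.) do not survive curation; map to single
        if sum(feats[:len(BOND_ORDERS)]) == 0:
            feats[0] = 1.0
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bond_rows.append(feats)
        index_rows.append((i, j))
        bond_rows.append(list(feats))
        index_rows.append((j, i))
    bond_feats = np.asarray(bond_rows, dtype=np.float64).reshape(len(bond_rows), BOND_FEATURE_DIM)
    bond_index = np.asarray(index_rows, dtype=np.int64).reshape(len(index_rows), 2)

    adjacency = Chem.GetAdjacencyMatrix(mol).astype(np.float64)
    topo = Chem.GetDistanceMatrix(mol).astype(np.float64)
    coul = _coulomb_from_mol(mol, topo, coulomb_mode, seed)
    return MolGraph(smiles, n, atom_feats, bond_feats, bond_index, adjacency, topo, coul)


def _coulomb_from_mol(mol: Chem.Mol, topo: np.ndarray, mode: str, seed: int) -> np.ndarray:
    z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=np.float64)
    n = len(z)
    if mode == "embedded3d":
        try:
            molh = Chem.AddHs(mol)
            ok = AllChem.EmbedMolecule(molh, randomSeed=seed)
            if ok != 0:
                raise RuntimeError("embedding failed")
            conf = molh.GetConformer()
            pos = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
            diff = pos[:, None, :] - pos[None, :, :]
            r = np.sqrt((diff ** 2).sum(axis=-1))
        except Exception:
            warnings.warn("3-D embedding failed; falling back to topological distances")
            mode = "topological3d"
    if mode == "topological3d":
        r = topo * _SURROGATE_BOND_LENGTH
    elif mode != "embedded3d":
        raise ValueError(f"unknown coulomb mode: {mode!r}")
    m = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        off = np.outer(z, z) / r
    iu = ~np.eye(n, dtype=bool)
    m[iu] = off[iu]
    np.fill_diagonal(m, 0.5 * z ** 2.4)
    return m


def coulomb_matrix(smiles: str, mode: str = "topological3d", seed: int = 0) -> np.ndarray:
    """Pairwise nuclear-charge matrix over heavy atoms.

    Diagonal 0.5*Z^2.4; off-diagonal Z_i*Z_j / r_ij.  In `topological3d` mode
    r_ij is the topological distance times 1.5 Angstrom (deterministic
    surrogate); `embedded3d` uses a seeded 3-D conformer and falls back to the
    surrogate if embedding fails.  Rows stay index-aligned with atom order.
    """
    mol = _mol_from_smiles(smiles)
    topo = Chem.GetDistanceMatrix(mol).astype(np.float64)
    return _coulomb_from_mol(mol, topo, mode, seed)


# --------------------------------------------------------------- descriptors
MANIFEST_VERSION = "descriptor_manifest_v1"


def descriptor_manifest() -> list[str]:
    """The frozen, ordered list of descriptor names."""
    text = importlib.resources.files("pcfkit.data").joinpath(
        f"{MANIFEST_VERSION}.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


_DESC_FUNCS = dict(Descriptors.descList)


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: list[str] = field(repr=False)


def compute_descriptors(smiles: str) -> DescriptorVector:
    """~200 two-dimensional physicochemical and fragment-count descriptors.

    Order is frozen by the packaged manifest; non-finite entries are imputed
    to 0 with a log entry.
    """
    mol = _mol_from_smiles(smiles)
    names = descriptor_manifest()
    values = np.empty(len(names), dtype=np.float64)
    for k, name in enumerate(names):
        try:
            v = float(_DESC_FUNCS[name](mol))
        except Exception:
            v = np.nan
        if not np.isfinite(v):
            logger.info("descriptor %s non-finite for %s; imputed to 0", name, smiles)
            v = 0.0
        values[k] = v
    return DescriptorVector(values=values, names=names)


# -------------------------------------------------------------- fingerprints
FINGERPRINT_KINDS = ("MACCS", "PATH", "ECFP4")
_N_BITS = 2048
_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_N_BITS)


@dataclass
class Fingerprint:
    kind: str
    bits: np.ndarray  # uint8 {0,1}

    def __len__(self) -> int:
        return self.bits.shape[0]


def compute_fingerprint(smiles: str, kind: str = "ECFP4") -> Fingerprint:
    """Deterministic substructure bit vector.

    ECFP4 = circular environments of radius 2 folded to 2048 bits; PATH =
    linear-path enumeration folded to 2048 bits; MACCS = the standard public
    166-key set (167 bits as emitted, bit 0 unused).
    """
    mol = _mol_from_smiles(smiles)
    if kind == "ECFP4":
        fp = _morgan_gen.GetFingerprint(mol)
    elif kind == "PATH":
        fp = Chem.RDKFingerprint(mol, fpSize=_N_BITS)
    elif kind == "MACCS":
        fp = MACCSkeys.GenMACCSKeys(mol)
    else:
        raise ValueError(f"unknown fingerprint kind: {kind!r}")
    bits = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(kind=kind, bits=bits)
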