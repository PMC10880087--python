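"""Dataset ingestion, curation, deduplication, scaffold analysis and splits.

The atomic unit is the ChemicalRecord: a canonical SMILES plus its product
carbon footprint (PCF, kg CO2-equiv per kg of chemical).  Curation keeps only
single-component organic molecules of adequate purity, mirroring the scope of
structure-based PCF models (pure organics; no salts, polymers, mixtures or
inorganics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .featurize import InvalidStructureError

__all__ = [
    "ChemicalRecord",
    "Dataset",
    "SplitSpec",
    "CurationResult",
    "curate",
    "merge_duplicates",
    "murcko_scaffold",
    "count_unique_scaffolds",
    "split",
    "read_table",
    "write_table",
    "read_sdf",
]

# elements regarded as non-metals for the curation metal test
_NONMETALS = {
    "H", "He", "B", "C", "N", "O", "F", "Ne", "Si", "P", "S", "Cl", "Ar",
    "Ge", "As", "Se", "Br", "Kr", "Sb", "Te", "I", "Xe", "At", "Rn",
}


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical with its per-kilogram carbon footprint."""

    smiles: str
    pcf: float
    source: str = ""
    purity: float | None = None
    name: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.pcf) or self.pcf < 0:
            raise ValueError(f"pcf must be finite and >= 0, got {self.pcf}")
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity must lie in [0, 1], got {self.purity}")


@dataclass
class Dataset:
    records: list[ChemicalRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def targets(self) -> np.ndarray:
        return np.array([r.pcf for r in self.records], dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": [r.smiles for r in self.records],
                "pcf": [r.pcf for r in self.records],
                "source": [r.source for r in self.records],
                "purity": [r.purity for r in self.records],
                "name": [r.name for r in self.records],
            }
        )


@dataclass(frozen=True)
class SplitSpec:
    """How to partition a dataset into train/validation/test."""

    method: str = "random"  # or "scaffold"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    repeat_index: int = 0

    def __post_init__(self):
        if self.method not in ("random", "scaffold"):
            raise ValueError(f"unknown split method: {self.method!r}")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not 0 <= self.repeat_index <= 4:
            raise ValueError("repeat_index must lie in [0, 4]")


# ------------------------------------------------------------------ curation
@dataclass
class CurationResult:
    dataset: Dataset
    exclusions: list[tuple[str, str]]  # (input smiles, rule id)

    def exclusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["smiles", "rule"])


def _contains_metal(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() not in _NONMETALS for a in mol.GetAtoms())


def _is_organic(mol: Chem.Mol) -> bool:
    """At least one carbon bonded to hydrogen or to another carbon."""
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        if atom.GetTotalNumHs() > 0:
            return True
        if any(nb.GetSymbol() == "C" for nb in atom.GetNeighbors()):
            return True
    return False


def _curation_rule(record: ChemicalRecord) -> str | None:
    """Return the id of the first violated rule, or None if the record passes."""
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return "parse_failure"
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        return "polymer"  # wildcard/repeat-unit attachment points
    if record.purity is not None and record.purity < 0.80:
        return "low_purity"
    if _contains_metal(mol):
        return "metal"
    if len(Chem.GetMolFrags(mol)) > 1:
        return "mixture"
    if not _is_organic(mol):
        return "inorganic"
    return None


def curate(records: list[ChemicalRecord]) -> CurationResult:
    """Keep parseable, single-component, metal-free organic records of
    purity >= 0.80 (unset purity passes); canonicalize surviving SMILES.

    Each exclusion is logged as (input smiles, rule id).  Empty input yields
    an empty dataset, not an error.
    """
    kept: list[ChemicalRecord] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        rule = _curation_rule(rec)
        if rule is not None:
            excluded.append((rec.smiles, rule))
            continue
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(rec.smiles))
        kept.append(replace(rec, smiles=canonical))
    return CurationResult(Dataset(kept, provenance="curated"), excluded)


def merge_duplicates(ds: Dataset) -> Dataset:
    """One record per canonical SMILES; PCF is the unweighted mean of the
    merged records, sources are concatenated."""
    order: list[str] = []
    groups: dict[str, list[ChemicalRecord]] = {}
    for rec in ds.records:
        if rec.smiles not in groups:
            groups[rec.smiles] = []
            order.append(rec.smiles)
        groups[rec.smiles].append(rec)
    merged = []
    for smi in order:
        recs = groups[smi]
        merged.append(
            ChemicalRecord(
                smiles=smi,
                pcf=float(np.mean([r.pcf for r in recs])),
                source=";".join(r.source for r in recs if r.source),
                purity=recs[0].purity,
                name=recs[0].name,
            )
        )
    return Dataset(merged, provenance=ds.provenance or "merged")


# ----------------------------------------------------------------- scaffolds
def murcko_scaffold(smiles: str) -> str:
    """Ring systems plus linkers with side chains pruned; acyclic molecules
    return the empty-scaffold sentinel ''."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"SMILES does not parse: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def count_unique_scaffolds(ds: Dataset) -> int:
    """Cardinality of the scaffold set (the empty scaffold counts once)."""
    return len({murcko_scaffold(s) for s in ds.smiles})


# -------------------------------------------------------------------- splits
def _largest_remainder_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    remainders = [x - s for x, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        k = int(np.argmax(remainders))
        sizes[k] += 1
        remainders[k] = -1.0
    return sizes


def split(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset, Dataset]:
    """Partition into train/validation/test.

    Random mode permutes records with a generator seeded by
    (seed, repeat_index).  Scaffold mode assigns whole Murcko-scaffold groups
    (largest first; equal-size groups ordered by a seeded shuffle) to the
    partition with the largest remaining deficit, so no scaffold spans two
    partitions.  Sizes follow largest-remainder rounding of the fractions.
    """
    n = len(ds)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    sizes = _largest_remainder_sizes(n, spec.fractions)
    rng = np.random.default_rng([spec.seed, spec.repeat_index])

    if spec.method == "random":
        perm = rng.permutation(n)
        bounds = np.cumsum([0] + sizes)
        parts = [
            [ds.records[i] for i in perm[lo:hi]]
            for lo, hi in zip(bounds[:-1], bounds[1:])
        ]
    else:
        groups: dict[str, list[int]] = {}
        for idx, smi in enumerate(ds.smiles):
            groups.setdefault(murcko_scaffold(smi), []).append(idx)
        shuffle_key = {s: rng.random() for s in sorted(groups)}
        ordered = sorted(groups.items(),
                         key=lambda kv: (-len(kv[1]), shuffle_key[kv[0]], kv[0]))
        if ordered and len(ordered[0][1]) > sizes[0]:
            warnings.warn(
                f"scaffold group of size {len(ordered[0][1])} exceeds the "
                f"training partition ({sizes[0]}); placing it in training")
        assigned: list[list[int]] = [[], [], []]
        for _, members in ordered:
            deficits = np.array([sizes[k] - len(assigned[k]) for k in range(3)], dtype=float)
            fits = np.flatnonzero(deficits >= len(members))
            if len(fits) == 0:
                k = int(np.argmax(deficits))  # overflow: least-full partition
            elif len(fits) == 1:
                k = int(fits[0])
            else:
                # sample among fitting partitions, weighted by remaining need,
                # so repeated splits explore different scaffold placements
                w = deficits[fits] / deficits[fits].sum()
                k = int(rng.choice(fits, p=w))
            assigned[k].extend(members)
        parts = [[ds.records[i] for i in idxs] for idxs in assigned]

    tags = ("train", "validation", "test")
    return tuple(
        Dataset(p, provenance=f"{ds.provenance}/{t}" if ds.provenance else t)
        for p, t in zip(parts, tags)
    )


# ----------------------------------------------------------------------- I/O
def read_table(path) -> Dataset:
    """Read a comma-separated table with columns smiles, pcf and optional
    source, purity, name."""
    df = pd.read_csv(path)
    if "smiles" not in df.columns or "pcf" not in df.columns:
        raise ValueError("table must contain 'smiles' and 'pcf' columns")
    records = []
    for _, row in df.iterrows():
        purity = row.get("purity")
        records.append(
            ChemicalRecord(
                smiles=str(row["smiles"]),
                pcf=float(row["pcf"]),
                source=str(row.get("source", "") or ""),
                purity=None if purity is None or pd.isna(purity) else float(purity),
                name=None if pd.isna(row.get("name")) else str(row.get("name")),
            )
        )
    return Dataset(records, provenance=str(path))


def write_table(ds: Dataset, path) -> None:
    ds.to_frame().to_csv(path, index=False)


def read_sdf(path, target_property: str = "pcf") -> Dataset:
    """Read an SDF structure file; the target is a named property field."""
    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None or not mol.HasProp(target_property):
            continue
        records.append(
            ChemicalRecord(
                smiles=Chem.MolToSmiles(mol),
                pcf=float(mol.GetProp(target_property)),
                source="sdf",
                name=mol.GetProp("_Name") if mol.HasProp("_Name") else None,
            )
        )
    return Dataset(records, provenance=str(path))
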