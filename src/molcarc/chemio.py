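"""Reading, curating and splitting labelled molecule datasets.

Curation mirrors the conventions of rodent-carcinogenicity QSAR datasets:
compounds with fewer than three carbon atoms, heavy-metal-containing
compounds, polymers (wildcard/attachment-point atoms) and mixtures
(multi-fragment SMILES) are excluded, and the survivors are deduplicated by
canonical SMILES. Labels are binary: 1 = carcinogen, 0 = non-carcinogen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors
from sklearn.model_selection import train_test_split

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord", "CurationReport", "DatasetError", "SchemaError",
    "InvalidMoleculeError", "read_dataset", "curate", "split_train_external",
    "descriptors_mw_alogp", "HEAVY_METALS",
]


class DatasetError(ValueError):
    """Empty dataset or unusable split sizes."""


class SchemaError(ValueError):
    """Input table lacks required columns or matching feature names."""


class InvalidMoleculeError(ValueError):
    """A SMILES string that RDKit cannot parse."""


#: Elements whose presence excludes a compound under the heavy-metal rule:
#: all transition metals, lanthanides and actinides, plus the classic
#: heavy main-group toxicants. Configurable via ``curate(metals=...)``.
_TRANSITION = list(range(21, 31)) + list(range(39, 49)) + list(range(72, 81))
_LANTH_ACT = list(range(57, 72)) + list(range(89, 104))
_MAIN_GROUP = [82, 80, 48, 50, 51, 83, 81, 33]  # Pb Hg Cd Sn Sb Bi Tl As
HEAVY_METALS: frozenset[int] = frozenset(_TRANSITION + _LANTH_ACT + _MAIN_GROUP)


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated compound with a canonical-SMILES identity."""

    id: str
    smiles: str
    label: int
    source: str = "unknown"

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise InvalidMoleculeError(f"unparseable SMILES for {self.id!r}: {self.smiles!r}")
        return m


@dataclass
class CurationReport:
    n_input: int = 0
    n_removed_small: int = 0
    n_removed_metal: int = 0
    n_removed_polymer: int = 0
    n_removed_mixture: int = 0
    n_removed_invalid: int = 0
    n_dedup: int = 0
    n_output: int = 0
    rejected_ids: dict[str, list[str]] = field(default_factory=dict)

    def check_identity(self) -> bool:
        removed = (self.n_removed_small + self.n_removed_metal +
                   self.n_removed_polymer + self.n_removed_mixture +
                   self.n_removed_invalid)
        return self.n_output == self.n_input - removed - self.n_dedup

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def read_dataset(path: str | Path, format: Literal["csv", "sdf"] = "csv",
                 source: str | None = None) -> tuple[list[MoleculeRecord], list[str]]:
    """Read a labelled molecule table.

    Returns ``(records, rejected_ids)`` where rejects are rows whose SMILES
    failed to parse — reported, never silently dropped. CSV requires columns
    ``id, smiles, label``; SDF requires a ``label`` property per molecule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    rejects: list[str] = []
    if format == "csv":
        df = pd.read_csv(path, dtype={"id": str})
        missing = {"id", "smiles", "label"} - set(df.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        tag = source or "csv"
        for row in df.itertuples(index=False):
            mol = Chem.MolFromSmiles(str(row.smiles))
            if mol is None:
                rejects.append(str(row.id))
                continue
            records.append(MoleculeRecord(str(row.id), str(row.smiles),
                                          int(row.label), tag))
    elif format == "sdf":
        tag = source or "sdf"
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                rejects.append(f"sdf:{i}")
                continue
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf:{i}"
            if not mol.HasProp("label"):
                rejects.append(mid)
                continue
            records.append(MoleculeRecord(mid, Chem.MolToSmiles(mol),
                                          int(mol.GetProp("label")), tag))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise DatasetError(f"no valid molecule rows in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate ids in dataset")
    return records, rejects


def _exclusion_reason(mol: Chem.Mol, smiles: str,
                      metals: frozenset[int]) -> str | None:
    """First matching exclusion rule, in the documented order."""
    if sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6) < 3:
        return "small"
    if any(a.GetAtomicNum() in metals for a in mol.GetAtoms()):
        return "metal"
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        return "polymer"
    if len(Chem.GetMolFrags(mol)) > 1:
        return "mixture"
    return None


def curate(records: Sequence[MoleculeRecord],
           metals: Iterable[int] | None = None,
           conflict_policy: Literal["drop_conflicts", "first"] = "drop_conflicts",
           ) -> tuple[list[MoleculeRecord], CurationReport]:
    """Apply the exclusion rules, canonicalize, and deduplicate.

    Rules, in order: (1) fewer than three carbon atoms; (2) any heavy-metal
    atom; (3) polymers, detected as wildcard/attachment-point atoms; (4)
    mixtures, i.e. multi-fragment SMILES. Survivors are deduplicated by
    canonical SMILES, first occurrence winning; duplicate groups with
    conflicting labels are dropped entirely under the default
    ``conflict_policy="drop_conflicts"`` (use ``"first"`` to keep the first
    label instead). Curation is idempotent.
    """
    metal_set = frozenset(metals) if metals is not None else HEAVY_METALS
    report = CurationReport(n_input=len(records))
    rej: dict[str, list[str]] = {"small": [], "metal": [], "polymer": [],
                                 "mixture": [], "invalid": []}
    canonical: list[tuple[MoleculeRecord, str]] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            rej["invalid"].append(rec.id)
            continue
        reason = _exclusion_reason(mol, rec.smiles, metal_set)
        if reason is not None:
            rej[reason].append(rec.id)
            continue
        canonical.append((rec, Chem.MolToSmiles(mol)))

    # dedup by canonical SMILES, preserving input order
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec, can in canonical:
        if can not in groups:
            groups[can] = []
            order.append(can)
        groups[can].append(rec)

    out: list[MoleculeRecord] = []
    n_dedup = 0
    for can in order:
        grp = groups[can]
        labels = {r.label for r in grp}
        if len(labels) > 1 and conflict_policy == "drop_conflicts":
            n_dedup += len(grp)
            continue
        first = grp[0]
        out.append(MoleculeRecord(first.id, can, first.label, first.source))
        n_dedup += len(grp) - 1

    report.n_removed_small = len(rej["small"])
    report.n_removed_metal = len(rej["metal"])
    report.n_removed_polymer = len(rej["polymer"])
    report.n_removed_mixture = len(rej["mixture"])
    report.n_removed_invalid = len(rej["invalid"])
    report.n_dedup = n_dedup
    report.n_output = len(out)
    report.rejected_ids = rej
    assert report.check_identity()
    return out, report


def split_train_external(records: Sequence[MoleculeRecord], n_external: int,
                         seed: int) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Reproducible stratified split into a training and an external set."""
    if n_external >= len(records):
        raise DatasetError(
            f"n_external={n_external} must be smaller than the dataset ({len(records)})")
    labels = [r.label for r in records]
    idx = np.arange(len(records))
    train_idx, ext_idx = train_test_split(
        idx, test_size=n_external, random_state=seed, stratify=labels)
    train_idx, ext_idx = np.sort(train_idx), np.sort(ext_idx)
    return [records[i] for i in train_idx], [records[i] for i in ext_idx]


def descriptors_mw_alogp(record: MoleculeRecord) -> tuple[float, float]:
    """Molecular weight (Da) and Crippen ALogP for chemical-space plots."""
    mol = record.mol()
    return float(Descriptors.MolWt(mol)), float(Crippen.MolLogP(mol))


def records_to_dataframe(records: Sequence[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame({"id": [r.id for r in records],
                         "smiles": [r.smiles for r in records],
                         "label": [r.label for r in records],
                         "source": [r.source for r in records]})


def write_dataset(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)
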