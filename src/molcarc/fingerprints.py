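"""The 12 molecular fingerprint families used for carcinogenicity modelling.

Three hashed-path families (CDK-style, CDK-extended-style, CDK-graph-style,
1024 bits each) enumerate all simple atom-bond paths up to seven bonds and
hash each canonical path string to a bit position. Keyed families (MACCS,
PubChem, Klekota-Roth, substructure/FP4, E-state, plus the count variants)
set position i from the match indicator or match count of key i. The 2D
atom-pair family encodes (atom type, atom type, topological distance)
triples over distances 1-10.

Lengths follow the published family sizes exactly; see
:data:`FINGERPRINT_REGISTRY`.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter

from . import keysets
from .chemio import InvalidMoleculeError, MoleculeRecord

__all__ = ["FingerprintSpec", "FeatureMatrix", "FINGERPRINT_REGISTRY",
           "hashed_path_fingerprint", "keyed_fingerprint",
           "atom_pair_fingerprint", "compute_fingerprint", "featurize_dataset"]

Kind = Literal["hash", "structural", "structural-count"]


@dataclass(frozen=True)
class FingerprintSpec:
    """Name, kind and length contract of one fingerprint family."""

    name: str
    kind: Kind
    length: int

    def __post_init__(self):
        assert self.length > 0


FINGERPRINT_REGISTRY: dict[str, FingerprintSpec] = {
    "CDK": FingerprintSpec("CDK", "hash", 1024),
    "CDKExt": FingerprintSpec("CDKExt", "hash", 1024),
    "CDKGraph": FingerprintSpec("CDKGraph", "hash", 1024),
    "MACCS": FingerprintSpec("MACCS", "structural", 166),
    "PubChem": FingerprintSpec("PubChem", "structural", 881),
    "KR": FingerprintSpec("KR", "structural", 4860),
    "KRC": FingerprintSpec("KRC", "structural-count", 4860),
    "AP2D": FingerprintSpec("AP2D", "structural", 780),
    "AP2DC": FingerprintSpec("AP2DC", "structural-count", 780),
    "FP4": FingerprintSpec("FP4", "structural", 307),
    "FP4C": FingerprintSpec("FP4C", "structural-count", 307),
    "Estate": FingerprintSpec("Estate", "structural", 79),
}


@dataclass
class FeatureMatrix:
    """Molecules x named features, the exchange container of the pipeline."""

    values: np.ndarray
    feature_names: list[str]
    molecule_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        assert self.values.ndim == 2
        assert self.values.shape[1] == len(self.feature_names)
        assert self.values.shape[0] == len(self.molecule_ids)
        assert np.isfinite(self.values).all(), "feature matrix contains non-finite values"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids,
                            columns=self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="id")
        return cls(df.to_numpy(), list(df.columns), [str(i) for i in df.index])

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(self.values[:, idx],
                             [self.feature_names[i] for i in idx],
                             list(self.molecule_ids))


# -- hashed path families ---------------------------------------------------

_BOND_SYMBOL = {
    Chem.rdchem.BondType.SINGLE: "-",
    Chem.rdchem.BondType.DOUBLE: "=",
    Chem.rdchem.BondType.TRIPLE: "#",
    Chem.rdchem.BondType.AROMATIC: ":",
}

_HASH_SALT = b"molcarc/v1:"  # fixed so bit assignment is stable everywhere


def _stable_hash(s: str) -> int:
    return zlib.crc32(_HASH_SALT + s.encode("utf8")) & 0xFFFFFFFF


def _atom_token(atom: Chem.Atom, style: str) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic() and style != "graph":
        sym = sym.lower()
    if style == "extended":
        if atom.IsInRing():
            sym += "R"
        q = atom.GetFormalCharge()
        if q:
            sym += f"{q:+d}"
    return sym


def _bond_token(bond: Chem.Bond, style: str) -> str:
    if style == "graph":
        return "~"
    return _BOND_SYMBOL.get(bond.GetBondType(), "?")


def _enumerate_paths(mol: Chem.Mol, max_depth: int, style: str) -> set[str]:
    """Canonical strings of all simple paths of 0..max_depth bonds."""
    paths: set[str] = set()

    def dfs(atom: Chem.Atom, visited: set[int], tokens: list[str], depth: int):
        s = "".join(tokens)
        paths.add(min(s, s[::-1]))
        if depth == max_depth:
            return
        for bond in atom.GetBonds():
            nbr = bond.GetOtherAtom(atom)
            if nbr.GetIdx() in visited:
                continue
            visited.add(nbr.GetIdx())
            tokens.append(_bond_token(bond, style))
            tokens.append(_atom_token(nbr, style))
            dfs(nbr, visited, tokens, depth + 1)
            tokens.pop(); tokens.pop()
            visited.remove(nbr.GetIdx())

    for atom in mol.GetAtoms():
        dfs(atom, {atom.GetIdx()}, [_atom_token(atom, style)], 0)
    return paths


def hashed_path_fingerprint(mol: Chem.Mol, length: int = 1024,
                            max_depth: int = 7,
                            style: Literal["plain", "extended", "graph"] = "plain",
                            ) -> np.ndarray:
    """Depth-limited canonical-path hashed fingerprint.

    ``plain`` distinguishes bond orders and aromaticity; ``extended``
    additionally annotates ring membership and formal charge on atoms;
    ``graph`` ignores bond orders entirely (connectivity only).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    vec = np.zeros(length)
    if mol.GetNumAtoms() == 0:
        warnings.warn("empty molecule: zero fingerprint")
        return vec
    for path in _enumerate_paths(mol, max_depth, style):
        vec[_stable_hash(path) % length] = 1.0
    return vec


# -- keyed families ---------------------------------------------------------

def _maccs(mol: Chem.Mol) -> np.ndarray:
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    return np.array([float(bv.GetBit(i)) for i in range(1, 167)])


def _estate(mol: Chem.Mol) -> np.ndarray:
    counts, _sums = EStateFingerprinter.FingerprintMol(mol)
    return (np.asarray(counts) > 0).astype(float)


def keyed_fingerprint(mol: Chem.Mol, spec: FingerprintSpec) -> np.ndarray:
    """Match indicator (or count, for the *C variants) of each key pattern."""
    if mol.GetNumAtoms() == 0:
        warnings.warn("empty molecule: zero fingerprint")
        return np.zeros(spec.length)
    if spec.name == "MACCS":
        return _maccs(mol)
    if spec.name == "Estate":
        return _estate(mol)
    keys = {"KR": keysets.kr_keys, "KRC": keysets.kr_keys,
            "FP4": keysets.fp4_keys, "FP4C": keysets.fp4_keys,
            "PubChem": keysets.pubchem_keys}[spec.name]()
    counts = np.array([float(k.count(mol)) for k in keys])
    if spec.kind == "structural-count":
        return counts
    return (counts > 0).astype(float)


# -- 2D atom pairs ----------------------------------------------------------

_AP2D_TYPES = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se"]
_AP2D_MAX_DIST = 10
_AP2D_PAIRS = [(i, j) for i in range(len(_AP2D_TYPES))
               for j in range(i, len(_AP2D_TYPES))]


def atom_pair_fingerprint(mol: Chem.Mol, counting: bool = False) -> np.ndarray:
    """(atom type, atom type, topological distance) fingerprint, length 780.

    12 element types, unordered pairs (78), shortest-path distances 1-10.
    """
    vec = np.zeros(len(_AP2D_PAIRS) * _AP2D_MAX_DIST)
    if mol.GetNumAtoms() == 0:
        warnings.warn("empty molecule: zero fingerprint")
        return vec
    type_idx = {s: i for i, s in enumerate(_AP2D_TYPES)}
    typed = [(a.GetIdx(), type_idx[a.GetSymbol()]) for a in mol.GetAtoms()
             if a.GetSymbol() in type_idx]
    if len(typed) >= 2:
        dmat = Chem.GetDistanceMatrix(mol)
        pair_pos = {p: k for k, p in enumerate(_AP2D_PAIRS)}
        for ai in range(len(typed)):
            for aj in range(ai + 1, len(typed)):
                (ia, ta), (ja, tb) = typed[ai], typed[aj]
                d = int(dmat[ia, ja])
                if 1 <= d <= _AP2D_MAX_DIST:
                    k = pair_pos[(min(ta, tb), max(ta, tb))]
                    pos = (d - 1) * len(_AP2D_PAIRS) + k
                    vec[pos] += 1.0
    return vec if counting else (vec > 0).astype(float)


def _ap2d_names(counting: bool) -> list[str]:
    prefix = "AP2DC" if counting else "AP2D"
    return [f"{prefix}_d{d}_{_AP2D_TYPES[i]}_{_AP2D_TYPES[j]}"
            for d in range(1, _AP2D_MAX_DIST + 1) for (i, j) in _AP2D_PAIRS]


# -- dispatch ---------------------------------------------------------------

def compute_fingerprint(mol: Chem.Mol, spec: FingerprintSpec | str) -> np.ndarray:
    if isinstance(spec, str):
        spec = FINGERPRINT_REGISTRY[spec]
    if spec.name == "CDK":
        return hashed_path_fingerprint(mol, spec.length, 7, "plain")
    if spec.name == "CDKExt":
        return hashed_path_fingerprint(mol, spec.length, 7, "extended")
    if spec.name == "CDKGraph":
        return hashed_path_fingerprint(mol, spec.length, 7, "graph")
    if spec.name in ("AP2D", "AP2DC"):
        return atom_pair_fingerprint(mol, counting=spec.name == "AP2DC")
    return keyed_fingerprint(mol, spec)


def _feature_names(spec: FingerprintSpec) -> list[str]:
    if spec.name in ("AP2D", "AP2DC"):
        return _ap2d_names(spec.name == "AP2DC")
    if spec.name in ("KR", "KRC", "FP4", "FP4C", "PubChem"):
        keys = {"KR": keysets.kr_keys, "KRC": keysets.kr_keys,
                "FP4": keysets.fp4_keys, "FP4C": keysets.fp4_keys,
                "PubChem": keysets.pubchem_keys}[spec.name]()
        return [f"{spec.name}_{k.name}" for k in keys]
    return [f"{spec.name}_{i}" for i in range(spec.length)]


def featurize_dataset(records: Sequence[MoleculeRecord],
                      spec: FingerprintSpec | str) -> FeatureMatrix:
    """Fingerprint every record; row order follows record order."""
    if isinstance(spec, str):
        spec = FINGERPRINT_REGISTRY[spec]
    rows, failures = [], []
    for rec in records:
        try:
            rows.append(compute_fingerprint(rec.mol(), spec))
        except InvalidMoleculeError:
            failures.append(rec.id)
    if failures:
        raise InvalidMoleculeError(f"featurization failed for ids: {failures}")
    values = np.vstack(rows) if rows else np.zeros((0, spec.length))
    return FeatureMatrix(values, _feature_names(spec), [r.id for r in records])
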