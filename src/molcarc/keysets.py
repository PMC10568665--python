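"""Substructure key-set definitions for the keyed fingerprint families.

The MACCS (166) and E-state (79) families use RDKit's own key definitions.
For the Klekota-Roth-length (4860), PubChem-length (881) and
substructure/FP4-length (307) families the published key-definition files
are not bundled; instead each family is a deterministic *synthetic key set*
of the exact published length, built from a curated functional-group list
(``data/functional_groups.smarts``) extended by a systematic SMARTS grammar
over element/bond chains. Position i of the fingerprint is still, exactly as
for the published sets, the match indicator (or match count) of pattern i —
only the identity of the individual keys differs.

Key objects expose ``name`` and ``count(mol) -> int``; a bit is set when the
count is positive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from rdkit import Chem

__all__ = ["SmartsKey", "ElementCountKey", "RingCountKey",
           "functional_group_keys", "fp4_keys", "kr_keys", "pubchem_keys"]


@dataclass(frozen=True)
class SmartsKey:
    name: str
    smarts: str

    @property
    def pattern(self) -> Chem.Mol:
        return _compile(self.smarts)

    def count(self, mol: Chem.Mol) -> int:
        return len(mol.GetSubstructMatches(self.pattern, uniquify=True))


@dataclass(frozen=True)
class ElementCountKey:
    """Indicator key: molecule contains >= threshold atoms of an element."""

    name: str
    symbol: str
    threshold: int

    def count(self, mol: Chem.Mol) -> int:
        n = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == self.symbol)
        return int(n >= self.threshold)


@dataclass(frozen=True)
class RingCountKey:
    """Indicator key: molecule contains >= threshold rings of a given size."""

    name: str
    size: int          # 0 = any aromatic ring
    threshold: int
    aromatic: bool = False

    def count(self, mol: Chem.Mol) -> int:
        ri = mol.GetRingInfo()
        if self.aromatic:
            n = 0
            for ring in ri.AtomRings():
                if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                    n += 1
        else:
            n = sum(1 for ring in ri.AtomRings() if len(ring) == self.size)
        return int(n >= self.threshold)


@lru_cache(maxsize=None)
def _compile(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    return patt


@lru_cache(maxsize=1)
def functional_group_keys() -> tuple[SmartsKey, ...]:
    """The curated functional-group list bundled with the package."""
    text = (resources.files("molcarc") / "data" / "functional_groups.smarts").read_text()
    keys = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")
        _compile(smarts)  # fail fast on a broken bundled pattern
        keys.append(SmartsKey(name, smarts))
    return tuple(keys)


# -- systematic SMARTS grammar ----------------------------------------------

_CHAIN_ATOMS = ["C", "c", "N", "n", "O", "o", "S", "s", "P", "F", "Cl", "Br", "I"]
_CHAIN_BONDS = ["-", "=", "#", "~"]


def _chain_patterns():
    """Deterministic stream of element-chain SMARTS: pairs, then triples.

    Mirror-image chains describe the same pattern, so only the
    lexicographically smaller spelling of each chain is emitted.
    """
    for (a1, b, a2) in itertools.product(_CHAIN_ATOMS, _CHAIN_BONDS, _CHAIN_ATOMS):
        fwd, rev = f"{a1}{b}{a2}", f"{a2}{b}{a1}"
        if fwd <= rev:
            yield fwd
    for (a1, b1, a2, b2, a3) in itertools.product(
            _CHAIN_ATOMS, _CHAIN_BONDS, _CHAIN_ATOMS, _CHAIN_BONDS, _CHAIN_ATOMS):
        fwd = f"{a1}{b1}{a2}{b2}{a3}"
        rev = f"{a3}{b2}{a2}{b1}{a1}"
        if fwd <= rev:
            yield fwd
    # branched triples, central atom with two substituents
    for (c, b1, a1, b2, a2) in itertools.product(
            _CHAIN_ATOMS, _CHAIN_BONDS, _CHAIN_ATOMS, _CHAIN_BONDS, _CHAIN_ATOMS):
        if (b1, a1) <= (b2, a2):
            yield f"{c}({b1}{a1}){b2}{a2}"


def _grammar_keys(n: int, skip: set[str], prefix: str) -> list[SmartsKey]:
    out: list[SmartsKey] = []
    seen = set(skip)
    for i, patt in enumerate(_chain_patterns()):
        if len(out) == n:
            break
        if patt in seen:
            continue
        seen.add(patt)
        out.append(SmartsKey(f"{prefix}{len(out)}_{patt}", patt))
    if len(out) < n:  # pragma: no cover - grammar yields far more than needed
        raise RuntimeError("SMARTS grammar exhausted")
    return out


@lru_cache(maxsize=1)
def fp4_keys() -> tuple:
    """Synthetic substructure key set of the published FP4 length (307)."""
    base = list(functional_group_keys())
    extra = _grammar_keys(307 - len(base), {k.smarts for k in base}, "sub")
    return tuple(base + extra)


@lru_cache(maxsize=1)
def kr_keys() -> tuple:
    """Synthetic key set of the published Klekota-Roth length (4860)."""
    base = list(functional_group_keys())
    extra = _grammar_keys(4860 - len(base), {k.smarts for k in base}, "kr")
    return tuple(base + extra)


@lru_cache(maxsize=1)
def pubchem_keys() -> tuple:
    """Synthetic key set of the published PubChem length (881).

    Mirrors the sectioned structure of the real set: element-count keys,
    ring-count keys, then substructure keys.
    """
    keys: list = []
    elements = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
                "Si", "Na", "K", "Li", "Ca", "Mg", "Fe", "Zn", "Al", "Se"]
    for sym in elements:
        for thr in (1, 2, 4, 8):
            keys.append(ElementCountKey(f"count_{sym}_ge{thr}", sym, thr))
    for size in range(3, 9):
        for thr in (1, 2):
            keys.append(RingCountKey(f"ring{size}_ge{thr}", size, thr))
    for thr in (1, 2, 3, 4):
        keys.append(RingCountKey(f"aromatic_ring_ge{thr}", 0, thr, aromatic=True))
    n_struct = 881 - len(keys)
    keys.extend(_grammar_keys(n_struct, set(), "pc"))
    return tuple(keys)
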