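"""Molecules as attributed graphs with canonical atom and bond features.

Atoms become nodes carrying a 74-dimensional feature vector and bonds become
bidirected edge pairs carrying a 12-dimensional feature vector, following the
widely used canonical featurization convention for molecular graph networks:

* atom: element one-hot (43 symbols), degree one-hot (0-10), implicit
  valence one-hot (0-6), formal charge, radical electron count,
  hybridization one-hot (SP, SP2, SP3, SP3D, SP3D2), aromatic flag,
  total-hydrogen one-hot (0-4)  ->  43+11+7+1+1+5+1+5 = 74
* bond: bond-type one-hot (single, double, triple, aromatic), conjugation
  flag, ring flag, stereo one-hot (6 states)  ->  4+1+1+6 = 12

Hydrogens are implicit (never nodes). Bond features are computed and exposed
but the attention encoder consumes node features only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chemio import InvalidMoleculeError, MoleculeRecord

__all__ = ["MolecularGraph", "GraphBatch", "atom_featurize", "bond_featurize",
           "mol_to_graph", "batch_graphs", "ATOM_FEATURE_DIM", "BOND_FEATURE_DIM"]

_ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]
_BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]
_STEREO = [
    Chem.rdchem.BondStereo.STEREONONE,
    Chem.rdchem.BondStereo.STEREOANY,
    Chem.rdchem.BondStereo.STEREOZ,
    Chem.rdchem.BondStereo.STEREOE,
    Chem.rdchem.BondStereo.STEREOCIS,
    Chem.rdchem.BondStereo.STEREOTRANS,
]

ATOM_FEATURE_DIM = len(_ATOM_SYMBOLS) + 11 + 7 + 1 + 1 + len(_HYBRIDIZATIONS) + 1 + 5
BOND_FEATURE_DIM = len(_BOND_TYPES) + 1 + 1 + len(_STEREO)


def _one_hot(value, choices) -> list[float]:
    return [1.0 if value == c else 0.0 for c in choices]


def atom_featurize(atom: Chem.Atom) -> np.ndarray:
    """74-d canonical atom feature vector."""
    feats = (
        _one_hot(atom.GetSymbol(), _ATOM_SYMBOLS)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(7)))
        + [float(atom.GetFormalCharge()), float(atom.GetNumRadicalElectrons())]
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [float(atom.GetIsAromatic())]
        + _one_hot(atom.GetTotalNumHs(), list(range(5)))
    )
    return np.asarray(feats)


def bond_featurize(bond: Chem.Bond) -> np.ndarray:
    """12-d canonical bond feature vector (shared by both edge directions)."""
    feats = (
        _one_hot(bond.GetBondType(), _BOND_TYPES)
        + [float(bond.GetIsConjugated()), float(bond.IsInRing())]
        + _one_hot(bond.GetStereo(), _STEREO)
    )
    return np.asarray(feats)


@dataclass
class MolecularGraph:
    """Attributed bidirected molecular graph (heavy atoms only, no self-loops)."""

    node_features: np.ndarray        # (n_nodes, 74)
    edge_list: np.ndarray            # (n_edges, 2) int; both directions present
    edge_features: np.ndarray        # (n_edges, 12)
    n_nodes: int

    def __post_init__(self):
        assert self.node_features.shape == (self.n_nodes, ATOM_FEATURE_DIM)
        if self.edge_list.size:
            assert self.edge_list.max() < self.n_nodes


def mol_to_graph(record: MoleculeRecord | str) -> MolecularGraph:
    """Build the attributed graph for one molecule.

    Atoms are ordered canonically (by the canonical SMILES atom ranking) so
    that any SMILES spelling of the same molecule yields a bit-identical
    graph.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))  # canonical atom order
    n = mol.GetNumAtoms()
    nodes = np.zeros((n, ATOM_FEATURE_DIM))
    for atom in mol.GetAtoms():
        nodes[atom.GetIdx()] = atom_featurize(atom)
    edges, efeats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = bond_featurize(bond)
        edges.append((i, j)); efeats.append(f)
        edges.append((j, i)); efeats.append(f)
    edge_list = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    edge_features = (np.asarray(efeats).reshape(-1, BOND_FEATURE_DIM)
                     if efeats else np.zeros((0, BOND_FEATURE_DIM)))
    return MolecularGraph(nodes, edge_list, edge_features, n)


@dataclass
class GraphBatch:
    """Several graphs stacked into one disjoint-union graph.

    Self-loops are appended so isolated atoms still receive a message, and
    edges are sorted by destination node for segment reductions.
    """

    node_features: np.ndarray   # (N, 74)
    src: np.ndarray             # (E,) int, self-loops included
    dst: np.ndarray             # (E,) int, sorted ascending
    graph_ids: np.ndarray       # (N,) int graph index per node
    n_nodes: int
    n_graphs: int


def batch_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    nodes = np.concatenate([g.node_features for g in graphs], axis=0)
    src_parts, dst_parts, gid_parts = [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        loops = np.arange(g.n_nodes) + offset
        if g.edge_list.size:
            src_parts.append(g.edge_list[:, 0] + offset)
            dst_parts.append(g.edge_list[:, 1] + offset)
        src_parts.append(loops)
        dst_parts.append(loops)
        gid_parts.append(np.full(g.n_nodes, gi, dtype=np.int64))
        offset += g.n_nodes
    src = np.concatenate(src_parts)
    dst = np.concatenate(dst_parts)
    order = np.argsort(dst, kind="stable")
    return GraphBatch(nodes, src[order], dst[order],
                      np.concatenate(gid_parts), offset, len(graphs))
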