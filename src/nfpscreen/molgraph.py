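"""SMILES → three-matrix molecular graph.

A molecule is represented by three arrays consumed by the convolutional
fingerprint: a per-atom feature matrix, a per-bond feature matrix, and the
connectivity (for each atom, its (neighbor, bond) incidences). Hydrogens are
implicit — they appear as an attached-H count in the atom features, never as
graph nodes.

Atom feature layout (d_atom = 23):
    element one-hot over {C, N, O, S, P, F, Cl, Br, I, other}   (10)
    degree one-hot 0–5                                          (6)
    attached-H count one-hot 0–4                                (5)
    formal charge, signed scalar                                (1)
    aromatic flag                                               (1)

Bond feature layout (d_bond = 6):
    order one-hot {single, double, triple, aromatic}            (4)
    conjugated flag                                             (1)
    in-ring flag                                                (1)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
N_ELEMENT_SLOTS = len(ELEMENTS) + 1  # +1 reserved "other" slot
MAX_DEGREE = 5
MAX_NUM_H = 4
D_ATOM = N_ELEMENT_SLOTS + (MAX_DEGREE + 1) + (MAX_NUM_H + 1) + 2
D_BOND = 6

_BOND_ORDER_SLOT = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass
class MoleculeGraph:
    """Three-matrix graph representation of a single molecule.

    ``adjacency[i]`` lists ``(neighbor_atom_index, bond_index)`` pairs for
    atom ``i``; the listing is symmetric, so every bond index appears in
    exactly two atoms' lists.
    """

    atom_features: np.ndarray  # [n_atoms, D_ATOM]
    bond_features: np.ndarray  # [n_bonds, D_BOND]
    adjacency: list[list[tuple[int, int]]]
    n_atoms: int
    n_bonds: int
    source_smiles: str
    # dense helpers used by the convolutional fingerprint; derived, cached
    _adj_matrix: np.ndarray | None = field(default=None, repr=False)
    _incidence: np.ndarray | None = field(default=None, repr=False)

    @property
    def adj_matrix(self) -> np.ndarray:
        """Dense [n_atoms, n_atoms] 0/1 neighbor matrix."""
        if self._adj_matrix is None:
            a = np.zeros((self.n_atoms, self.n_atoms))
            for i, nbrs in enumerate(self.adjacency):
                for j, _ in nbrs:
                    a[i, j] = 1.0
            self._adj_matrix = a
        return self._adj_matrix

    @property
    def incidence(self) -> np.ndarray:
        """Dense [n_atoms, n_bonds] atom–bond incidence matrix."""
        if self._incidence is None:
            m = np.zeros((self.n_atoms, max(self.n_bonds, 1)))
            for i, nbrs in enumerate(self.adjacency):
                for _, b in nbrs:
                    m[i, b] = 1.0
            self._incidence = m
        return self._incidence


def atom_feature_vector(atom: Chem.Atom) -> np.ndarray:
    """Featurize one RDKit atom into a fixed-length vector of length D_ATOM.

    Elements outside the vocabulary map to the reserved "other" slot, never
    an error; degree and H-count saturate at their top bin.
    """
    v = np.zeros(D_ATOM)
    try:
        v[ELEMENTS.index(atom.GetSymbol())] = 1.0
    except ValueError:
        v[N_ELEMENT_SLOTS - 1] = 1.0
    off = N_ELEMENT_SLOTS
    v[off + min(atom.GetDegree(), MAX_DEGREE)] = 1.0
    off += MAX_DEGREE + 1
    v[off + min(atom.GetTotalNumHs(), MAX_NUM_H)] = 1.0
    off += MAX_NUM_H + 1
    v[off] = float(atom.GetFormalCharge())
    v[off + 1] = 1.0 if atom.GetIsAromatic() else 0.0
    return v


def bond_feature_vector(bond: Chem.Bond) -> np.ndarray:
    """Featurize one RDKit bond; undirected, so either endpoint sees the same
    vector. Unknown bond orders raise explicitly."""
    v = np.zeros(D_BOND)
    try:
        v[_BOND_ORDER_SLOT[bond.GetBondType()]] = 1.0
    except KeyError:
        raise ValueError(f"unsupported bond order: {bond.GetBondType()}")
    v[4] = 1.0 if bond.GetIsConjugated() else 0.0
    v[5] = 1.0 if bond.IsInRing() else 0.0
    return v


def mol_to_graph(mol: Chem.Mol, source_smiles: str = "") -> MoleculeGraph:
    """Build the three-matrix graph from an RDKit molecule as-ordered.

    Used directly by tests that permute atom order; normal entry is
    :func:`smiles_to_graph`, which canonicalizes first.
    """
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise ValueError("molecule has zero heavy atoms")
    atom_feats = np.stack([atom_feature_vector(a) for a in mol.GetAtoms()])
    n_bonds = mol.GetNumBonds()
    bond_feats = (
        np.stack([bond_feature_vector(b) for b in mol.GetBonds()])
        if n_bonds
        else np.zeros((0, D_BOND))
    )
    adjacency: list[list[tuple[int, int]]] = [[] for _ in range(n_atoms)]
    for b_idx, bond in enumerate(mol.GetBonds()):
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i].append((j, b_idx))
        adjacency[j].append((i, b_idx))
    return MoleculeGraph(
        atom_features=atom_feats,
        bond_features=bond_feats,
        adjacency=adjacency,
        n_atoms=n_atoms,
        n_bonds=n_bonds,
        source_smiles=source_smiles,
    )


def canonical_smiles(smiles: str) -> str:
    """Canonical form, or raise SmilesParseError naming the offender."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a MoleculeGraph over heavy atoms.

    The SMILES is canonicalized first, so any spelling of the same molecule
    yields an identical graph.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    canon = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canon)
    return mol_to_graph(mol, source_smiles=canon)
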