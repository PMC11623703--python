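"""Molecule data model: fully connected graphs with categorical modalities.

A molecule is a fully connected graph over its atoms. Each atom carries a 3D
position, an atom type (element) and a formal charge; every unordered pair of
atoms carries a bond order, with an explicit ``none`` class so that the edge
representation is total. Atom types, charges and bond orders are categorical
variables drawn from small vocabularies; an optional MASK class (always the
last index) supports the CTMC flow variant.

SDF I/O goes through RDKit so the package reads and writes the field's
standard interchange format.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

logger = logging.getLogger(__name__)

# bond order classes, in vocabulary order; "none" makes the fully connected
# edge set total
BOND_CLASSES = ("none", "single", "double", "triple", "aromatic")
BOND_ORDER_VALUES = {
    "none": 0.0,
    "single": 1.0,
    "double": 2.0,
    "triple": 3.0,
    "aromatic": 1.5,
}
_RDKIT_BOND_TYPES = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_BOND_CLASS_FROM_RDKIT = {v: k for k, v in _RDKIT_BOND_TYPES.items()}

DEFAULT_ELEMENTS = ("H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I")
DEFAULT_CHARGES = (-2, -1, 0, 1, 2, 3)

MASK_NAME = "<MASK>"


@dataclass(frozen=True)
class Vocabulary:
    """Ordered list of class labels, with an optional trailing MASK class."""

    names: tuple[str, ...]
    mask_index: Optional[int] = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("vocabulary names must be unique")
        if self.mask_index is not None and self.mask_index != len(self.names) - 1:
            raise ValueError("mask_index, when present, must be the last index")

    @property
    def size(self) -> int:
        """Total number of classes, including MASK when present."""
        return len(self.names)

    @property
    def n_real(self) -> int:
        """Number of real (non-MASK) classes."""
        return len(self.names) - (1 if self.mask_index is not None else 0)

    def with_mask(self) -> "Vocabulary":
        if self.mask_index is not None:
            return self
        return Vocabulary(names=self.names + (MASK_NAME,), mask_index=len(self.names))

    def without_mask(self) -> "Vocabulary":
        if self.mask_index is None:
            return self
        return Vocabulary(names=self.names[:-1], mask_index=None)

    def index(self, name: str) -> int:
        return self.names.index(name)


def atom_vocabulary(elements: Sequence[str] = DEFAULT_ELEMENTS) -> Vocabulary:
    return Vocabulary(names=tuple(elements))


def charge_vocabulary(charges: Sequence[int] = DEFAULT_CHARGES) -> Vocabulary:
    return Vocabulary(names=tuple(str(c) for c in charges))


def bond_vocabulary() -> Vocabulary:
    return Vocabulary(names=BOND_CLASSES)


@dataclass(frozen=True)
class Vocabularies:
    """The triple of categorical vocabularies describing one molecule set."""

    atoms: Vocabulary = field(default_factory=atom_vocabulary)
    charges: Vocabulary = field(default_factory=charge_vocabulary)
    bonds: Vocabulary = field(default_factory=bond_vocabulary)

    def with_mask(self) -> "Vocabularies":
        return Vocabularies(
            atoms=self.atoms.with_mask(),
            charges=self.charges.with_mask(),
            bonds=self.bonds.with_mask(),
        )

    def charge_value(self, index: int) -> int:
        return int(self.charges.names[index])

    def charge_index(self, value: int) -> int:
        return self.charges.names.index(str(value))


def n_pairs(n_atoms: int) -> int:
    return n_atoms * (n_atoms - 1) // 2


@lru_cache(maxsize=512)
def _pair_list_cached(n_atoms: int) -> np.ndarray:
    idx = np.triu_indices(n_atoms, k=1)
    out = np.stack(idx, axis=1)
    out.setflags(write=False)
    return out


def pair_list(n_atoms: int) -> np.ndarray:
    """All unordered pairs (i, j) with i < j, in row-major order."""
    return _pair_list_cached(n_atoms)


def pair_index(i: int, j: int, n_atoms: int) -> int:
    """Position of unordered pair {i, j} in the canonical pair list."""
    if i == j:
        raise ValueError("no self-pairs in the edge set")
    if i > j:
        i, j = j, i
    return i * n_atoms - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class MoleculeGraph:
    """One molecule: positions plus categorical atom/charge/bond states.

    ``bond_orders`` has one entry per unordered pair {i, j}, i < j, in the
    order produced by :func:`pair_list`.
    """

    positions: np.ndarray  # (N, 3) float, Angstrom
    atom_types: np.ndarray  # (N,) int indices into vocabs.atoms
    charges: np.ndarray  # (N,) int indices into vocabs.charges
    bond_orders: np.ndarray  # (N*(N-1)/2,) int indices into vocabs.bonds
    vocabs: Vocabularies = field(default_factory=Vocabularies)
    name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.atom_types = np.asarray(self.atom_types, dtype=int).reshape(-1)
        self.charges = np.asarray(self.charges, dtype=int).reshape(-1)
        self.bond_orders = np.asarray(self.bond_orders, dtype=int).reshape(-1)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def pairs(self) -> np.ndarray:
        return pair_list(self.n_atoms)

    def bond_order_value(self, i: int, j: int) -> float:
        """Numeric bond order between atoms i and j (none = 0, aromatic = 1.5)."""
        k = self.bond_orders[pair_index(i, j, self.n_atoms)]
        name = self.vocabs.bonds.names[k]
        if name == MASK_NAME:
            raise ValueError("mask bond present; resolve the molecule first")
        return BOND_ORDER_VALUES[name]

    def element(self, i: int) -> str:
        return self.vocabs.atoms.names[self.atom_types[i]]

    def formal_charge(self, i: int) -> int:
        return self.vocabs.charge_value(self.charges[i])

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(
            positions=self.positions.copy(),
            atom_types=self.atom_types.copy(),
            charges=self.charges.copy(),
            bond_orders=self.bond_orders.copy(),
            vocabs=self.vocabs,
            name=self.name,
        )


@dataclass(frozen=True)
class Violation:
    field: str
    index: int
    message: str


def encode_onehot(index: int, size: int) -> np.ndarray:
    """One-hot vector of length ``size`` with a 1 at ``index``."""
    index = int(index)
    if not 0 <= index < size:
        raise ValueError(f"index {index} out of range for vocabulary of size {size}")
    v = np.zeros(size, dtype=float)
    v[index] = 1.0
    return v


def validate_graph(g: MoleculeGraph) -> list[Violation]:
    """Check MoleculeGraph invariants; returns violations instead of raising."""
    out: list[Violation] = []
    n = g.n_atoms
    if g.atom_types.shape[0] != n:
        out.append(Violation("atom_types", -1, f"expected {n} entries"))
    if g.charges.shape[0] != n:
        out.append(Violation("charges", -1, f"expected {n} entries"))
    expected_pairs = n_pairs(n)
    if g.bond_orders.shape[0] != expected_pairs:
        out.append(
            Violation(
                "bond_orders",
                -1,
                f"expected {expected_pairs} unordered pairs, got {g.bond_orders.shape[0]}",
            )
        )
    if not np.all(np.isfinite(g.positions)):
        bad = int(np.argwhere(~np.isfinite(g.positions))[0][0])
        out.append(Violation("positions", bad, "non-finite coordinate"))
    for fname, values, vocab in (
        ("atom_types", g.atom_types, g.vocabs.atoms),
        ("charges", g.charges, g.vocabs.charges),
        ("bond_orders", g.bond_orders, g.vocabs.bonds),
    ):
        bad = np.nonzero((values < 0) | (values >= vocab.size))[0]
        for b in bad[:10]:
            out.append(
                Violation(fname, int(b), f"index {int(values[b])} outside vocabulary of size {vocab.size}")
            )
    return out


# ---------------------------------------------------------------------------
# RDKit conversion and SDF I/O
# ---------------------------------------------------------------------------


def to_rdkit(g: MoleculeGraph, sanitize: bool = False) -> Chem.Mol:
    """Build an RDKit molecule (with conformer) from a MoleculeGraph.

    Aromatic flags are set on atoms incident to aromatic bonds so that RDKit's
    default sanitization can perceive aromatic rings.
    """
    rw = Chem.RWMol()
    aromatic_atoms: set[int] = set()
    for i in range(g.n_atoms):
        sym = g.element(i)
        if sym == MASK_NAME:
            raise ValueError("mask atom present; resolve the molecule first")
        a = Chem.Atom(sym)
        a.SetFormalCharge(g.formal_charge(i))
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for (i, j), k in zip(g.pairs, g.bond_orders):
        name = g.vocabs.bonds.names[k]
        if name == MASK_NAME:
            raise ValueError("mask bond present; resolve the molecule first")
        if name == "none":
            continue
        rw.AddBond(int(i), int(j), _RDKIT_BOND_TYPES[name])
        if name == "aromatic":
            aromatic_atoms.update((int(i), int(j)))
    for i in aromatic_atoms:
        rw.GetAtomWithIdx(i).SetIsAromatic(True)
    for b in rw.GetBonds():
        if b.GetBondType() == Chem.BondType.AROMATIC:
            b.SetIsAromatic(True)
    mol = rw.GetMol()
    conf = Chem.Conformer(g.n_atoms)
    for i, (x, y, z) in enumerate(g.positions):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    if g.name:
        mol.SetProp("_Name", g.name)
    if sanitize:
        Chem.SanitizeMol(mol)
    return mol


def from_rdkit(mol: Chem.Mol, vocabs: Optional[Vocabularies] = None) -> MoleculeGraph:
    """Convert an RDKit molecule (explicit H, 3D conformer) to a MoleculeGraph.

    Formal charges outside the charge vocabulary are clamped to the nearest
    vocabulary value with a logged warning.
    """
    vocabs = vocabs or Vocabularies()
    n = mol.GetNumAtoms()
    conf = mol.GetConformer()
    positions = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z] for i in range(n)]
    )
    atom_types = np.zeros(n, dtype=int)
    charges = np.zeros(n, dtype=int)
    charge_values = [int(c) for c in vocabs.charges.names if c != MASK_NAME]
    for i, atom in enumerate(mol.GetAtoms()):
        sym = atom.GetSymbol()
        try:
            atom_types[i] = vocabs.atoms.index(sym)
        except ValueError as exc:
            raise ValueError(f"element {sym!r} not in atom vocabulary") from exc
        c = atom.GetFormalCharge()
        if c not in charge_values:
            clamped = min(charge_values, key=lambda v: abs(v - c))
            logger.warning("charge %+d on atom %d outside vocabulary; clamped to %+d", c, i, clamped)
            c = clamped
        charges[i] = vocabs.charge_index(c)
    none_idx = vocabs.bonds.index("none")
    bond_orders = np.full(n_pairs(n), none_idx, dtype=int)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        btype = bond.GetBondType()
        name = _BOND_CLASS_FROM_RDKIT.get(btype)
        if name is None:
            raise ValueError(f"unsupported bond type {btype}")
        bond_orders[pair_index(i, j, n)] = vocabs.bonds.index(name)
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return MoleculeGraph(positions, atom_types, charges, bond_orders, vocabs, name=name)


def read_sdf(path, vocabs: Optional[Vocabularies] = None) -> list[MoleculeGraph]:
    """Read molecules from an SDF file (V2000/V3000).

    Unparseable records are skipped with a logged warning rather than failing
    the whole read. Molecules are read without sanitization or hydrogen
    removal so that the graph matches the file exactly.
    """
    if os.path.getsize(path) == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list[MoleculeGraph] = []
    for rec, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparseable SDF record %d in %s", rec, path)
            continue
        try:
            mol.UpdatePropertyCache(strict=False)
            out.append(from_rdkit(mol, vocabs))
        except Exception as exc:  # noqa: BLE001 - per-record robustness
            logger.warning("skipping SDF record %d in %s: %s", rec, path, exc)
    return out


def write_sdf(mols: Iterable[MoleculeGraph], path) -> None:
    """Write molecules to an SDF file (V2000 where possible)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for g in mols:
            writer.write(to_rdkit(g))
    finally:
        writer.close()
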