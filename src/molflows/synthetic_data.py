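"""Deterministic fixture molecules and a stochastic toy molecule distribution.

The toy distribution stands in for a large training corpus at desk scale. A
molecule is drawn by (1) picking a heavy-atom count n, (2) picking a chain or
ring scaffold of single bonds, (3) drawing heavy-atom elements from a
scaffold-conditioned categorical over {C, N, O}, (4) saturating every heavy
atom with hydrogens to its exact allowed valency (C:4, N:3, O:2), and (5)
embedding at idealized bond lengths plus isotropic Gaussian noise. Every
generated molecule is therefore 100% stable and sanitizable by construction,
and the size, atom-type and bond-order marginals are analytically computable
from the configuration — which is what makes total-variation evaluation of
trained models possible without external data.

What this emulates: the coupling between element identity, valency, bonding
topology and local geometry that molecule generators must learn. What it does
not emulate: aromaticity, formal charges, multiple bond orders, conformer
diversity, or drug-like ring systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .molgraph import (
    MoleculeGraph,
    Vocabularies,
    Vocabulary,
    from_rdkit,
    n_pairs,
    pair_index,
)

__all__ = [
    "ToyConfig",
    "toy_vocabularies",
    "fixtures",
    "generate_toy_dataset",
    "size_histogram",
    "empirical_marginals",
    "total_variation_to_reference",
]

HEAVY_VALENCE = {"C": 4, "N": 3, "O": 2}
BOND_LENGTH_HEAVY = 1.5  # Angstrom, idealized single bond
BOND_LENGTH_H = 1.09


def toy_vocabularies() -> Vocabularies:
    """Small vocabularies used by the toy distribution: H/C/N/O, charges, bonds."""
    return Vocabularies(atoms=Vocabulary(names=("H", "C", "N", "O")))


@dataclass(frozen=True)
class ToyConfig:
    """Parameters of the toy molecule distribution.

    ``chain_probs`` / ``ring_probs`` are categoricals over (C, N, O) for the
    heavy atoms of chain and ring scaffolds respectively; ``p_ring`` is the
    probability of a ring scaffold; ``sigma`` is the positional noise in
    Angstrom added to the idealized embedding.
    """

    n_heavy_range: tuple[int, int] = (3, 6)
    p_ring: float = 0.35
    chain_probs: tuple[float, float, float] = (0.60, 0.25, 0.15)
    ring_probs: tuple[float, float, float] = (0.70, 0.15, 0.15)
    sigma: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_heavy_range
        if not (2 <= lo <= hi):
            raise ValueError("n_heavy_range must satisfy 2 <= lo <= hi")
        if self.p_ring > 0 and lo < 3:
            raise ValueError("ring scaffolds need at least 3 heavy atoms")
        for p in (self.chain_probs, self.ring_probs):
            if len(p) != 3 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError("scaffold type probabilities must be a categorical over (C, N, O)")
        if not 0.0 <= self.p_ring <= 1.0:
            raise ValueError("p_ring must be a probability")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    # -- analytically known marginals ------------------------------------

    def _valence_sum_pmf(self, n: int, probs: tuple[float, float, float]) -> dict[int, float]:
        """Exact pmf of the total heavy valency sum over n i.i.d. elements."""
        base = {4: probs[0], 3: probs[1], 2: probs[2]}
        pmf = {0: 1.0}
        for _ in range(n):
            nxt: dict[int, float] = {}
            for s, p in pmf.items():
                for v, q in base.items():
                    nxt[s + v] = nxt.get(s + v, 0.0) + p * q
            pmf = nxt
        return pmf

    def size_pmf(self) -> dict[int, float]:
        """Exact pmf of the total atom count N (heavy + hydrogens)."""
        lo, hi = self.n_heavy_range
        p_n = 1.0 / (hi - lo + 1)
        out: dict[int, float] = {}
        for n in range(lo, hi + 1):
            for is_ring, p_s, probs in (
                (True, self.p_ring, self.ring_probs),
                (False, 1.0 - self.p_ring, self.chain_probs),
            ):
                if p_s == 0.0:
                    continue
                n_bonds = n if is_ring else n - 1
                for vsum, pv in self._valence_sum_pmf(n, probs).items():
                    total = n + vsum - 2 * n_bonds
                    out[total] = out.get(total, 0.0) + p_n * p_s * pv
        return out

    def expected_counts(self) -> dict[str, float]:
        """Expected per-molecule counts of each element and of single bonds."""
        lo, hi = self.n_heavy_range
        p_n = 1.0 / (hi - lo + 1)
        counts = {"H": 0.0, "C": 0.0, "N": 0.0, "O": 0.0, "single": 0.0, "pairs": 0.0}
        for n in range(lo, hi + 1):
            for is_ring, p_s, probs in (
                (True, self.p_ring, self.ring_probs),
                (False, 1.0 - self.p_ring, self.chain_probs),
            ):
                if p_s == 0.0:
                    continue
                w = p_n * p_s
                n_bonds = n if is_ring else n - 1
                counts["C"] += w * n * probs[0]
                counts["N"] += w * n * probs[1]
                counts["O"] += w * n * probs[2]
                e_val = 4 * probs[0] + 3 * probs[1] + 2 * probs[2]
                e_h = n * e_val - 2 * n_bonds
                counts["H"] += w * e_h
                counts["single"] += w * (n_bonds + e_h)
                for vsum, pv in self._valence_sum_pmf(n, probs).items():
                    total = n + vsum - 2 * n_bonds
                    counts["pairs"] += w * pv * n_pairs(total)
        return counts

    def atom_type_marginal(self) -> np.ndarray:
        """Pooled atom-type marginal over the toy vocabulary order (H, C, N, O)."""
        c = self.expected_counts()
        tot = c["H"] + c["C"] + c["N"] + c["O"]
        return np.array([c["H"], c["C"], c["N"], c["O"]]) / tot

    def bond_order_marginal(self) -> np.ndarray:
        """Pooled bond-class marginal over (none, single, double, triple, aromatic)."""
        c = self.expected_counts()
        p_single = c["single"] / c["pairs"]
        return np.array([1.0 - p_single, p_single, 0.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _chain_positions(n: int) -> np.ndarray:
    """Zig-zag chain with tetrahedral-ish angles in the xy plane."""
    half = np.deg2rad(109.5) / 2.0
    step = BOND_LENGTH_HEAVY
    pts = np.zeros((n, 3))
    for i in range(1, n):
        direction = np.array([np.cos(half), np.sin(half) * (1 if i % 2 else -1), 0.0])
        pts[i] = pts[i - 1] + step * direction
    return pts


def _ring_positions(n: int) -> np.ndarray:
    r = BOND_LENGTH_HEAVY / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)], axis=1)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _hydrogen_directions(base: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    out = []
    for _ in range(k):
        u = base + 0.9 * _random_unit(rng)
        nrm = np.linalg.norm(u)
        out.append(u / nrm if nrm > 1e-8 else _random_unit(rng))
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _sample_toy_molecule(cfg: ToyConfig, rng: np.random.Generator, vocabs: Vocabularies) -> MoleculeGraph:
    lo, hi = cfg.n_heavy_range
    n_heavy = int(rng.integers(lo, hi + 1))
    is_ring = bool(rng.random() < cfg.p_ring)
    probs = cfg.ring_probs if is_ring else cfg.chain_probs
    elements = [("C", "N", "O")[i] for i in rng.choice(3, size=n_heavy, p=probs)]

    heavy_pos = _ring_positions(n_heavy) if is_ring else _chain_positions(n_heavy)
    heavy_bonds = [(i, (i + 1) % n_heavy) for i in range(n_heavy)] if is_ring else [
        (i, i + 1) for i in range(n_heavy - 1)
    ]
    degree = np.zeros(n_heavy, dtype=int)
    for i, j in heavy_bonds:
        degree[i] += 1
        degree[j] += 1

    symbols = list(elements)
    positions = [p for p in heavy_pos]
    bonds = list(heavy_bonds)
    for i in range(n_heavy):
        n_h = HEAVY_VALENCE[elements[i]] - degree[i]
        if n_h < 0:
            raise RuntimeError("scaffold degree exceeds valency")  # unreachable by construction
        nb_dirs = np.zeros(3)
        for a, b in heavy_bonds:
            if i in (a, b):
                other = b if a == i else a
                d = heavy_pos[other] - heavy_pos[i]
                nb_dirs += d / np.linalg.norm(d)
        base = -nb_dirs if np.linalg.norm(nb_dirs) > 1e-8 else _random_unit(rng)
        base = base / np.linalg.norm(base)
        for u in _hydrogen_directions(base, n_h, rng):
            bonds.append((i, len(symbols)))
            symbols.append("H")
            positions.append(heavy_pos[i] + BOND_LENGTH_H * u)

    pos = np.asarray(positions) + cfg.sigma * rng.standard_normal((len(symbols), 3))
    pos = pos - pos.mean(axis=0, keepdims=True)
    n = len(symbols)
    atom_types = np.array([vocabs.atoms.index(s) for s in symbols])
    charges = np.full(n, vocabs.charge_index(0), dtype=int)
    bond_orders = np.full(n_pairs(n), vocabs.bonds.index("none"), dtype=int)
    single = vocabs.bonds.index("single")
    for i, j in bonds:
        bond_orders[pair_index(i, j, n)] = single
    return MoleculeGraph(pos, atom_types, charges, bond_orders, vocabs)


def generate_toy_dataset(
    cfg: ToyConfig,
    n: int,
    rng: Union[int, np.random.Generator, None] = None,
) -> list[MoleculeGraph]:
    """Draw n molecules from the toy distribution (centered coordinates)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    vocabs = toy_vocabularies()
    return [_sample_toy_molecule(cfg, rng, vocabs) for _ in range(n)]


def size_histogram(mols: list[MoleculeGraph]) -> dict[int, float]:
    """Counts of molecule sizes (total atoms), for the generation size sampler."""
    out: dict[int, float] = {}
    for g in mols:
        out[g.n_atoms] = out.get(g.n_atoms, 0.0) + 1.0
    return out


def empirical_marginals(mols: list[MoleculeGraph]) -> dict[str, np.ndarray]:
    """Pooled atom-type / bond-order frequencies and the size histogram."""
    if not mols:
        raise ValueError("empty batch")
    da = mols[0].vocabs.atoms.n_real
    de = mols[0].vocabs.bonds.n_real
    type_counts = np.zeros(da)
    bond_counts = np.zeros(de)
    sizes: dict[int, float] = {}
    for g in mols:
        type_counts += np.bincount(g.atom_types, minlength=da)[:da]
        bond_counts += np.bincount(g.bond_orders, minlength=de)[:de]
        sizes[g.n_atoms] = sizes.get(g.n_atoms, 0.0) + 1.0
    total_sizes = sum(sizes.values())
    return {
        "atom_types": type_counts / type_counts.sum(),
        "bond_orders": bond_counts / bond_counts.sum(),
        "sizes": {k: v / total_sizes for k, v in sizes.items()},
    }


def total_variation_to_reference(mols: list[MoleculeGraph], cfg: ToyConfig) -> dict[str, float]:
    """Total variation between a batch's marginals and the analytic toy marginals.

    ``total`` averages the atom-type and bond-order TVs (the size marginal is
    reported separately because generation draws sizes from the data
    histogram, making it variant-independent).
    """
    emp = empirical_marginals(mols)
    tv_types = 0.5 * float(np.abs(emp["atom_types"] - cfg.atom_type_marginal()).sum())
    tv_bonds = 0.5 * float(np.abs(emp["bond_orders"] - cfg.bond_order_marginal()).sum())
    ref_sizes = cfg.size_pmf()
    keys = set(ref_sizes) | set(emp["sizes"])
    tv_sizes = 0.5 * sum(abs(ref_sizes.get(k, 0.0) - emp["sizes"].get(k, 0.0)) for k in keys)
    return {
        "atom_types": tv_types,
        "bond_orders": tv_bonds,
        "sizes": float(tv_sizes),
        "total": 0.5 * (tv_types + tv_bonds),
    }


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_FIXTURE_SMILES = {
    "methane": "C",
    "benzene": "c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "nitrobenzene": "O=[N+]([O-])c1ccccc1",
}


def _embed_from_smiles(smiles: str, seed: int = 20240901) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    return mol


def _pentavalent_carbon(vocabs: Vocabularies) -> MoleculeGraph:
    """Deliberately corrupted CH5: a carbon with five single bonds."""
    dirs = np.array(
        [
            [0, 0, 1.09],
            [0, 0, -1.09],
            [1.09, 0, 0],
            [-0.545, 0.944, 0],
            [-0.545, -0.944, 0],
        ]
    )
    pos = np.vstack([[0.0, 0.0, 0.0], dirs])
    atom_types = np.array([vocabs.atoms.index("C")] + [vocabs.atoms.index("H")] * 5)
    charges = np.full(6, vocabs.charge_index(0), dtype=int)
    bond_orders = np.full(n_pairs(6), vocabs.bonds.index("none"), dtype=int)
    single = vocabs.bonds.index("single")
    for h in range(1, 6):
        bond_orders[pair_index(0, h, 6)] = single
    return MoleculeGraph(pos, atom_types, charges, bond_orders, vocabs, name="pentavalent")


def fixtures(vocabs: Optional[Vocabularies] = None) -> dict[str, MoleculeGraph]:
    """Named fixture molecules with deterministic 3D coordinates.

    Includes clean molecules (methane, benzene, naphthalene, biphenyl,
    nitrobenzene) and a deliberately corrupted pentavalent-carbon molecule
    that must fail both stability and sanitization.
    """
    vocabs = vocabs or Vocabularies()
    out: dict[str, MoleculeGraph] = {}
    for name, smi in _FIXTURE_SMILES.items():
        g = from_rdkit(_embed_from_smiles(smi), vocabs)
        g.name = name
        out[name] = g
    out["pentavalent"] = _pentavalent_carbon(vocabs)
    return out
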