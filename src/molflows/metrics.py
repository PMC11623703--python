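"""Molecule-quality metric suite.

Five complementary views of a generated batch:

* **stability** — an atom is stable iff its (element, formal charge, valency)
  triple appears in a packaged allowed-valency table, where valency is the
  sum of numeric bond orders (aromatic counts 1.5); a molecule is stable iff
  all its atoms are. Computed directly on the graph, with no cheminformatics
  toolkit involved, so it is independent of validity.
* **validity** — fraction of molecules accepted by RDKit's default
  sanitization after reconstruction from the graph.
* **energy JS divergence** — Jensen-Shannon divergence (nats, shared
  equal-width bins) between reference and generated distributions of
  single-point MMFF94 potential energies.
* **structural alerts** — mean number of distinct flagged SMARTS patterns
  (Dundee / Glaxo catalogs) matched per molecule.
* **OOD ring systems** — mean number of ring systems per molecule whose
  canonical key is absent from a reference ring-frequency table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from scipy.spatial.distance import jensenshannon

from .molgraph import MoleculeGraph, to_rdkit

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AlertCatalog",
    "RingReference",
    "MetricsReport",
    "atom_valency",
    "stability",
    "validity",
    "mmff_energy",
    "energy_js",
    "alert_rate",
    "ring_systems",
    "ood_ring_rate",
    "evaluate_batch",
    "load_valency_table",
    "default_alert_catalog",
    "default_ring_reference",
]


# ---------------------------------------------------------------------------
# allowed-valency table
# ---------------------------------------------------------------------------


def load_valency_table() -> dict[tuple[str, int], frozenset[float]]:
    """Packaged (element, charge) -> allowed valency set."""
    table: dict[tuple[str, int], frozenset[float]] = {}
    text = resources.files("molflows.data").joinpath("valency_table.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        elem, charge, vals = line.split("\t")
        table[(elem, int(charge))] = frozenset(float(v) for v in vals.split(","))
    return table


_VALENCY_TABLE: Optional[dict] = None


def _valency_table() -> dict[tuple[str, int], frozenset[float]]:
    global _VALENCY_TABLE
    if _VALENCY_TABLE is None:
        _VALENCY_TABLE = load_valency_table()
    return _VALENCY_TABLE


def atom_valency(g: MoleculeGraph, i: int) -> float:
    """Sum of numeric bond orders incident to atom i (aromatic = 1.5)."""
    if not 0 <= i < g.n_atoms:
        raise IndexError(f"atom index {i} out of range")
    return float(sum(g.bond_order_value(i, j) for j in range(g.n_atoms) if j != i))


_warned_elements: set[str] = set()


def _atom_is_stable(g: MoleculeGraph, i: int) -> bool:
    key = (g.element(i), g.formal_charge(i))
    allowed = _valency_table().get(key)
    if allowed is None:
        if key[0] not in _warned_elements:
            _warned_elements.add(key[0])
            logger.warning("element %s (charge %+d) missing from valency table; counted unstable", *key)
        return False
    return atom_valency(g, i) in allowed


def stability(mols: Sequence[MoleculeGraph]) -> tuple[float, float]:
    """(percent atoms stable, percent molecules stable) over a batch."""
    if not mols:
        raise ValueError("empty batch")
    n_atoms = 0
    n_atoms_stable = 0
    n_mols_stable = 0
    for g in mols:
        flags = [_atom_is_stable(g, i) for i in range(g.n_atoms)]
        n_atoms += len(flags)
        n_atoms_stable += sum(flags)
        n_mols_stable += all(flags)
    return 100.0 * n_atoms_stable / n_atoms, 100.0 * n_mols_stable / len(mols)


def _sanitized(g: MoleculeGraph) -> Optional[Chem.Mol]:
    try:
        return to_rdkit(g, sanitize=True)
    except Exception:  # noqa: BLE001 - any sanitization failure means invalid
        return None


def validity(mols: Sequence[MoleculeGraph]) -> float:
    """Percent of molecules accepted by RDKit default sanitization."""
    if not mols:
        raise ValueError("empty batch")
    return 100.0 * sum(_sanitized(g) is not None for g in mols) / len(mols)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


class EnergyFailure:
    """Token marking a failed force-field evaluation."""

    def __repr__(self) -> str:  # pragma: no cover
        return "EnergyFailure()"


ENERGY_FAILURE = EnergyFailure()


def mmff_energy(g: MoleculeGraph):
    """Single-point MMFF94 energy (kcal/mol) at the stored coordinates.

    No geometry optimization is performed. Returns ENERGY_FAILURE when the
    molecule cannot be sanitized or the force field cannot be set up.
    """
    mol = _sanitized(g)
    if mol is None:
        return ENERGY_FAILURE
    try:
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            return ENERGY_FAILURE
        ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        if ff is None:
            return ENERGY_FAILURE
        return float(ff.CalcEnergy())
    except Exception:  # noqa: BLE001
        return ENERGY_FAILURE


def energy_js(e_ref: Iterable, e_gen: Iterable, n_bins: int = 100) -> float:
    """Jensen-Shannon divergence (nats) between two energy distributions.

    Histograms share ``n_bins`` equal-width bins spanning the pooled finite
    range. Bounded by ln 2; zero iff the histograms coincide.
    """
    ref = np.array([e for e in e_ref if isinstance(e, (int, float)) and math.isfinite(e)], dtype=float)
    gen = np.array([e for e in e_gen if isinstance(e, (int, float)) and math.isfinite(e)], dtype=float)
    if ref.size == 0 or gen.size == 0:
        raise ValueError("both energy lists must be non-empty after dropping failures")
    lo = min(ref.min(), gen.min())
    hi = max(ref.max(), gen.max())
    if hi == lo:
        hi = lo + 1.0
    bins = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(ref, bins=bins)
    q, _ = np.histogram(gen, bins=bins)
    return float(jensenshannon(p, q, base=np.e) ** 2)


# ---------------------------------------------------------------------------
# structural alerts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlertEntry:
    name: str
    smarts: str
    source: str


class AlertCatalog:
    """Named SMARTS alert patterns with provenance tags (Dundee / Glaxo)."""

    def __init__(self, entries: Iterable[tuple[str, str, str]]):
        self.entries: list[AlertEntry] = []
        self._patterns: list[Chem.Mol] = []
        seen: set[tuple[str, str]] = set()
        for name, smarts, source in entries:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"SMARTS does not parse: {name!r}: {smarts}")
            if (source, name) in seen:
                raise ValueError(f"duplicate alert name {name!r} within source {source!r}")
            seen.add((source, name))
            self.entries.append(AlertEntry(name, smarts, source))
            self._patterns.append(patt)

    def __len__(self) -> int:
        return len(self.entries)

    def count_matches(self, mol: Chem.Mol) -> int:
        """Number of distinct catalog patterns with at least one match."""
        return sum(mol.HasSubstructMatch(p) for p in self._patterns)

    @classmethod
    def from_tsv(cls, path) -> "AlertCatalog":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, smarts, source = line.split("\t")
                entries.append((name, smarts, source))
        return cls(entries)


def default_alert_catalog() -> AlertCatalog:
    """Bundled curated subset of the Dundee and Glaxo Wellcome alert sets."""
    entries = []
    for fname in ("alerts_dundee.tsv", "alerts_glaxo.tsv"):
        text = resources.files("molflows.data").joinpath(fname).read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts, source = line.split("\t")
            entries.append((name, smarts, source))
    return AlertCatalog(entries)


def alert_rate(mols: Sequence[MoleculeGraph], catalog: AlertCatalog) -> float:
    """Mean number of distinct alert patterns matched per sanitizable molecule."""
    counts = []
    n_excluded = 0
    for g in mols:
        mol = _sanitized(g)
        if mol is None:
            n_excluded += 1
            continue
        counts.append(catalog.count_matches(mol))
    if n_excluded:
        logger.info("alert_rate: excluded %d unsanitizable molecules", n_excluded)
    if not counts:
        return 0.0
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# ring systems
# ---------------------------------------------------------------------------


def ring_systems(g: MoleculeGraph) -> list[str]:
    """Canonical keys of the molecule's ring systems.

    Rings sharing an atom or a bond (fused and spiro) merge into one system;
    the key is the canonical SMILES of the system's ring atoms and in-ring
    bonds. Acyclic or unsanitizable molecules yield an empty list.
    """
    mol = _sanitized(g)
    if mol is None:
        return []
    return rdkit_ring_systems(mol)


def rdkit_ring_systems(mol: Chem.Mol) -> list[str]:
    info = mol.GetRingInfo()
    rings = [set(r) for r in info.AtomRings()]
    if not rings:
        return []
    # union-find merge of rings sharing atoms (covers fused and spiro)
    parent = list(range(len(rings)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            if rings[a] & rings[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    systems: dict[int, set[int]] = {}
    for idx, ring in enumerate(rings):
        systems.setdefault(find(idx), set()).update(ring)

    keys = []
    for atoms in systems.values():
        bond_ids = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms and b.IsInRing()
        ]
        keys.append(
            Chem.MolFragmentToSmiles(
                mol,
                atomsToUse=sorted(atoms),
                bondsToUse=bond_ids,
                canonical=True,
                isomericSmiles=False,
            )
        )
    return keys


class RingReference:
    """Ring-system key -> occurrence count in a reference corpus."""

    def __init__(self, counts: Mapping[str, int]):
        if not counts:
            raise ValueError("ring reference must be non-empty")
        if any(c < 0 for c in counts.values()):
            raise ValueError("ring reference counts must be >= 0")
        self.counts = dict(counts)

    def __contains__(self, key: str) -> bool:
        return self.counts.get(key, 0) > 0

    @classmethod
    def from_tsv(cls, path) -> "RingReference":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, count = line.split("\t")
                counts[key] = int(count)
        return cls(counts)


def default_ring_reference() -> RingReference:
    """Bundled synthetic ring-frequency table (small stand-in for a corpus census)."""
    text = resources.files("molflows.data").joinpath("ring_reference.tsv").read_text()
    counts: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, count = line.split("\t")
        counts[key] = int(count)
    return RingReference(counts)


def ood_ring_rate(mols: Sequence[MoleculeGraph], ref: RingReference) -> float:
    """Mean number of ring systems per molecule unseen in the reference."""
    if not mols:
        raise ValueError("empty batch")
    counts = [sum(key not in ref for key in ring_systems(g)) for g in mols]
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# batch evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricValue:
    mean: float
    ci95: float  # half-width of the 95% confidence interval

    def as_tuple(self) -> tuple[float, float]:
        return (self.mean, self.ci95)


@dataclass
class MetricsReport:
    """Aggregate quality metrics with 95% confidence intervals over repeats."""

    mols_stable_pct: MetricValue
    mols_valid_pct: MetricValue
    atoms_stable_pct: MetricValue
    js_energy: Optional[MetricValue]
    alerts_per_mol: Optional[MetricValue]
    ood_rings_per_mol: Optional[MetricValue]
    n_molecules: int
    repeats: int

    def as_dict(self) -> dict:
        out = {"n_molecules": self.n_molecules, "repeats": self.repeats}
        for key in (
            "mols_stable_pct",
            "mols_valid_pct",
            "atoms_stable_pct",
            "js_energy",
            "alerts_per_mol",
            "ood_rings_per_mol",
        ):
            v = getattr(self, key)
            out[key] = None if v is None else {"mean": v.mean, "ci95": v.ci95}
        return out


def _summarize(values: list[float]) -> MetricValue:
    arr = np.asarray(values, dtype=float)
    if arr.size <= 1:
        return MetricValue(float(arr.mean()), 0.0)
    sem = arr.std(ddof=1) / math.sqrt(arr.size)
    return MetricValue(float(arr.mean()), float(1.96 * sem))


def evaluate_batch(
    mols: Sequence[MoleculeGraph],
    repeats: int = 1,
    alerts: Optional[AlertCatalog] = None,
    ring_ref: Optional[RingReference] = None,
    ref_energies: Optional[Sequence[float]] = None,
    n_bins: int = 100,
) -> MetricsReport:
    """Evaluate a batch, splitting it into ``repeats`` chunks for CIs.

    Energy JS is computed only when ``ref_energies`` is given; alert and
    OOD-ring rates only when their catalogs are given.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not mols:
        raise ValueError("empty batch")
    chunks = [list(c) for c in np.array_split(np.arange(len(mols)), repeats) if len(c)]
    per: dict[str, list[float]] = {k: [] for k in ("ms", "mv", "as_", "js", "al", "ood")}
    for chunk in chunks:
        sub = [mols[i] for i in chunk]
        atoms_pct, mols_pct = stability(sub)
        per["ms"].append(mols_pct)
        per["as_"].append(atoms_pct)
        per["mv"].append(validity(sub))
        if ref_energies is not None:
            energies = [mmff_energy(g) for g in sub]
            finite = [e for e in energies if not isinstance(e, EnergyFailure)]
            per["js"].append(energy_js(ref_energies, finite, n_bins) if finite else float("nan"))
        if alerts is not None:
            per["al"].append(alert_rate(sub, alerts))
        if ring_ref is not None:
            per["ood"].append(ood_ring_rate(sub, ring_ref))
    return MetricsReport(
        mols_stable_pct=_summarize(per["ms"]),
        mols_valid_pct=_summarize(per["mv"]),
        atoms_stable_pct=_summarize(per["as_"]),
        js_energy=_summarize(per["js"]) if ref_energies is not None else None,
        alerts_per_mol=_summarize(per["al"]) if alerts is not None else None,
        ood_rings_per_mol=_summarize(per["ood"]) if ring_ref is not None else None,
        n_molecules=len(mols),
        repeats=len(chunks),
    )
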