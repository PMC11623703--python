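"""Quality metric suite: valency, stability, validity, energies, alerts, rings."""

import numpy as np
import pytest

from molflows.metrics import (
    ENERGY_FAILURE,
    AlertCatalog,
    EnergyFailure,
    RingReference,
    alert_rate,
    atom_valency,
    default_alert_catalog,
    default_ring_reference,
    energy_js,
    evaluate_batch,
    mmff_energy,
    ood_ring_rate,
    ring_systems,
    stability,
    validity,
)
from molflows.molgraph import MoleculeGraph, Vocabularies, n_pairs


class TestValency:
    def test_methane_carbon(self, fixture_mols):
        g = fixture_mols["methane"]
        carbon = int(np.argmax([g.element(i) == "C" for i in range(g.n_atoms)]))
        assert atom_valency(g, carbon) == 4.0

    def test_benzene_carbon_aromatic_sum(self, fixture_mols):
        # two aromatic (1.5 each) plus one single C-H = 4
        g = fixture_mols["benzene"]
        for i in range(g.n_atoms):
            expected = 4.0 if g.element(i) == "C" else 1.0
            assert atom_valency(g, i) == expected

    def test_isolated_atom(self):
        vocabs = Vocabularies()
        g = MoleculeGraph(
            positions=np.zeros((1, 3)),
            atom_types=[vocabs.atoms.index("O")],
            charges=[vocabs.charge_index(0)],
            bond_orders=np.zeros(0, dtype=int),
            vocabs=vocabs,
        )
        assert atom_valency(g, 0) == 0.0


class TestStabilityValidity:
    def test_clean_fixtures_fully_stable_and_valid(self, fixture_mols):
        clean = [fixture_mols[n] for n in ("methane", "benzene", "naphthalene", "biphenyl", "nitrobenzene")]
        assert stability(clean) == (100.0, 100.0)
        assert validity(clean) == 100.0

    def test_pentavalent_rejected_by_both(self, fixture_mols):
        bad = fixture_mols["pentavalent"]
        atoms_pct, mols_pct = stability([bad])
        assert mols_pct == 0.0
        assert validity([bad]) == 0.0

    def test_mixed_batch_percentage(self, fixture_mols):
        batch = [fixture_mols["methane"], fixture_mols["pentavalent"]]
        assert stability(batch)[1] == 50.0
        assert validity(batch) == 50.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            validity([])
        with pytest.raises(ValueError):
            stability([])


class TestEnergy:
    def test_mmff_finite_on_methane(self, fixture_mols):
        e = mmff_energy(fixture_mols["methane"])
        assert isinstance(e, float) and np.isfinite(e)

    def test_mmff_translation_invariance(self, fixture_mols):
        g = fixture_mols["benzene"].copy()
        e0 = mmff_energy(g)
        g.positions = g.positions + np.array([5.0, -3.0, 1.0])
        assert mmff_energy(g) == pytest.approx(e0, abs=1e-6)

    def test_mmff_failure_token_on_unsanitizable(self, fixture_mols):
        assert isinstance(mmff_energy(fixture_mols["pentavalent"]), EnergyFailure)

    def test_js_identical_zero(self, rng):
        e = rng.standard_normal(500).tolist()
        assert energy_js(e, list(e)) == pytest.approx(0.0, abs=1e-12)

    def test_js_disjoint_supports_ln2(self):
        assert energy_js([0.0, 0.1, 0.2], [10.0, 10.1, 10.2]) == pytest.approx(np.log(2), abs=1e-9)

    def test_js_two_bin_value(self):
        # histograms P=(1/2,1/2) vs Q=(1,0) -> JS = 0.2157 nats
        ref = [0.25, 0.75]
        gen = [0.25, 0.26]
        js = energy_js(ref, gen, n_bins=2)
        expected = 0.25 * np.log(2 / 3) + 0.25 * np.log(2) + 0.5 * np.log(4 / 3)
        assert js == pytest.approx(expected, abs=1e-9)
        assert js == pytest.approx(0.21576, abs=1e-4)

    def test_js_symmetric_and_bounded(self, rng):
        a = rng.standard_normal(300).tolist()
        b = (rng.standard_normal(300) + 1.5).tolist()
        assert energy_js(a, b) == pytest.approx(energy_js(b, a), abs=1e-12)
        assert 0.0 <= energy_js(a, b) <= np.log(2) + 1e-12

    def test_js_all_failures_rejected(self):
        with pytest.raises(ValueError):
            energy_js([ENERGY_FAILURE], [1.0])


class TestAlerts:
    def test_nitrobenzene_one_pattern_catalog(self, fixture_mols):
        catalog = AlertCatalog([("nitro", "[N+](=O)[O-]", "Dundee")])
        assert alert_rate([fixture_mols["nitrobenzene"]], catalog) == 1.0

    def test_methane_no_alerts_full_catalog(self, fixture_mols):
        assert alert_rate([fixture_mols["methane"]], default_alert_catalog()) == 0.0

    def test_additive_over_disjoint_catalogs(self, fixture_mols):
        mols = [fixture_mols["nitrobenzene"], fixture_mols["benzene"]]
        c1 = AlertCatalog([("nitro", "[N+](=O)[O-]", "Dundee")])
        c2 = AlertCatalog([("arene", "c1ccccc1", "Glaxo")])
        both = AlertCatalog([e.name, e.smarts, e.source] for e in c1.entries + c2.entries)
        assert alert_rate(mols, both) == pytest.approx(alert_rate(mols, c1) + alert_rate(mols, c2))

    def test_invalid_smarts_rejected(self):
        with pytest.raises(ValueError):
            AlertCatalog([("bad", "[[[", "Dundee")])

    def test_duplicate_name_within_source_rejected(self):
        with pytest.raises(ValueError):
            AlertCatalog([("x", "C", "Dundee"), ("x", "N", "Dundee")])

    def test_bundled_catalog_parses(self):
        catalog = default_alert_catalog()
        assert len(catalog) >= 20
        assert {e.source for e in catalog.entries} == {"Dundee", "Glaxo"}


class TestRingSystems:
    def test_benzene_single_system(self, fixture_mols):
        assert len(ring_systems(fixture_mols["benzene"])) == 1

    def test_biphenyl_two_identical_systems(self, fixture_mols):
        keys = ring_systems(fixture_mols["biphenyl"])
        assert len(keys) == 2 and keys[0] == keys[1]

    def test_naphthalene_fused_merges(self, fixture_mols):
        assert len(ring_systems(fixture_mols["naphthalene"])) == 1

    def test_acyclic_no_systems(self, fixture_mols):
        assert ring_systems(fixture_mols["methane"]) == []

    def test_ood_rate_known_rings(self, fixture_mols):
        ref = default_ring_reference()
        assert ood_ring_rate([fixture_mols["benzene"]] * 3, ref) == 0.0
        assert ood_ring_rate([fixture_mols["methane"]], ref) == 0.0

    def test_ood_rate_unknown_ring(self, fixture_mols):
        ref = RingReference({"c1ccccc1": 10})
        assert ood_ring_rate([fixture_mols["naphthalene"]], ref) == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            RingReference({})


class TestEvaluateBatch:
    def test_single_repeat_zero_ci(self, fixture_mols):
        report = evaluate_batch([fixture_mols["methane"]] * 4, repeats=1)
        assert report.mols_stable_pct.mean == 100.0
        assert report.mols_stable_pct.ci95 == 0.0

    def test_identical_repeats_zero_ci(self, fixture_mols):
        report = evaluate_batch([fixture_mols["methane"]] * 6, repeats=3)
        assert report.repeats == 3
        assert report.mols_stable_pct.ci95 == 0.0

    def test_heterogeneous_chunks_positive_ci(self, fixture_mols):
        mols = [fixture_mols["methane"]] * 3 + [fixture_mols["pentavalent"]] * 2 + [fixture_mols["benzene"]]
        report = evaluate_batch(mols, repeats=3, ring_ref=default_ring_reference())
        assert report.mols_stable_pct.ci95 > 0.0
        assert report.ood_rings_per_mol is not None

    def test_report_serializable(self, fixture_mols):
        import json

        report = evaluate_batch([fixture_mols["benzene"]], repeats=1, alerts=default_alert_catalog())
        encoded = json.dumps(report.as_dict())
        assert "mols_valid_pct" in encoded
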