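"""Count-based baselines: peptide LCA, NTA, BA, and the 0.5% species filter."""

import numpy as np
import pytest

from metafunc.baselines import (assign_peptide_lca, compute_ba, compute_nta,
                                unipept_species_filter)
from metafunc.em import TAXON_ONLY, build_evidence_graph, estimate_biomass

from conftest import make_bundle, random_taxonomy


@pytest.fixture
def shared_bundle(two_genus_taxonomy):
    # S1 (100) and S2 (101) share genus G1; S3 (102) sits in G2.
    return make_bundle(
        two_genus_taxonomy,
        {
            "A1": (100, 1e-4, ["PEPA", "PEPG"], [("GO:0000001", "BP")]),
            "B1": (101, 1e-4, ["PEPB", "PEPG"], [("GO:0000002", "BP")]),
            "C1": (102, 1e-4, ["PEPC"], [("GO:0000001", "BP"),
                                         ("GO:0000003", "MF")]),
        },
        {
            "PEPA": (3, 1.0, 0.1),
            "PEPB": (1, 1.0, 0.1),
            "PEPC": (2, 1.0, 0.1),
            "PEPG": (4, 1.0, 0.1),
        },
    )


class TestLcaAssignment:
    def test_unique_peptide_maps_to_species(self, shared_bundle,
                                            two_genus_taxonomy):
        lca = assign_peptide_lca(shared_bundle, two_genus_taxonomy)
        assert lca["PEPA"] == 100

    def test_genus_shared_peptide_maps_to_genus(self, shared_bundle,
                                                two_genus_taxonomy):
        lca = assign_peptide_lca(shared_bundle, two_genus_taxonomy)
        assert lca["PEPG"] == 10

    def test_matches_ancestor_intersection_oracle(self, rng):
        tax, species = random_taxonomy(rng, n_species=8)
        prots, peps = {}, {}
        for i in range(15):
            sub = rng.choice(species, size=int(rng.integers(1, 4)),
                             replace=False).tolist()
            pep = f"PEP{i:02d}"
            peps[pep] = (1, 1.0, 0.1)
            for j, tid in enumerate(sub):
                prots.setdefault(f"A{i}_{j}", (int(tid), 1e-4, [pep], []))
        bundle = make_bundle(tax, prots, peps)
        lca = assign_peptide_lca(bundle, tax)
        for pep, got in lca.items():
            sp = {p.species_tax_id for p in bundle.proteins.values()
                  if pep in p.peptides}
            common = set.intersection(*(set(tax.ancestors(t)) for t in sp))
            assert got == max(common, key=lambda t: len(tax.ancestors(t)))


class TestNta:
    def test_unique_counts_normalize(self, shared_bundle, two_genus_taxonomy):
        nta = compute_nta(shared_bundle, two_genus_taxonomy, "species")
        # PEPG is shared across species -> excluded at species rank
        assert nta.rows[100]["ta"] == 3
        assert nta.nta(100) == pytest.approx(0.5)
        assert nta.nta(101) == pytest.approx(1 / 6)
        assert nta.nta(102) == pytest.approx(1 / 3)

    def test_genus_rank_absorbs_shared_peptide(self, shared_bundle,
                                               two_genus_taxonomy):
        nta = compute_nta(shared_bundle, two_genus_taxonomy, "genus")
        # at genus rank PEPG collapses to G1, so G1 gets 3+1+4 = 8 counts
        assert nta.rows[10]["ta"] == 8
        assert nta.nta(10) == pytest.approx(0.8)
        assert nta.nta(11) == pytest.approx(0.2)

    def test_single_taxon_is_one(self, two_genus_taxonomy):
        bundle = make_bundle(
            two_genus_taxonomy,
            {"A1": (100, 1e-4, ["PEPA"], [])},
            {"PEPA": (5, 1.0, 0.1)},
        )
        nta = compute_nta(bundle, two_genus_taxonomy, "species")
        assert nta.nta(100) == pytest.approx(1.0)

    def test_matches_count_based_biomass_without_sharing(
            self, two_genus_taxonomy):
        # cross-module consistency: with only species-unique peptides the EM
        # with count weights reduces to the same count shares as NTA
        bundle = make_bundle(
            two_genus_taxonomy,
            {
                "A1": (100, 1e-4, ["PEPA", "PEPD"], []),
                "B1": (101, 1e-4, ["PEPB"], []),
                "C1": (102, 1e-4, ["PEPC"], []),
            },
            {
                "PEPA": (2, 1.0, 0.1), "PEPD": (3, 2.0, 0.1),
                "PEPB": (4, 1.0, 0.1), "PEPC": (1, 0.5, 0.1),
            },
        )
        nta = compute_nta(bundle, two_genus_taxonomy, "species")
        graph = build_evidence_graph(bundle, list(bundle.proteins.values()),
                                     TAXON_ONLY, weight_mode="count")
        est = estimate_biomass(graph)
        for tid, p in est.p.items():
            assert p == pytest.approx(nta.nta(tid), abs=1e-9)

    def test_matches_brute_force_counting(self, rng):
        tax, species = random_taxonomy(rng, n_species=6)
        prots, peps = {}, {}
        for i in range(20):
            sub = rng.choice(species, size=int(rng.integers(1, 3)),
                             replace=False).tolist()
            pep = f"PEP{i:02d}"
            peps[pep] = (int(rng.integers(1, 5)), 1.0, 0.1)
            for j, tid in enumerate(sub):
                prots[f"A{i}_{j}"] = (int(tid), 1e-4, [pep], [])
        bundle = make_bundle(tax, prots, peps)
        for rank in ("species", "genus", "family"):
            nta = compute_nta(bundle, tax, rank)
            ta = {}
            for pep, (count, _, _) in peps.items():
                sp = {p.species_tax_id for p in bundle.proteins.values()
                      if pep in p.peptides}
                anc = {tax.ancestor_at_rank(t, rank) for t in sp}
                if len(anc) == 1 and None not in anc:
                    (taxon,) = anc
                    ta[taxon] = ta.get(taxon, 0) + count
            total = sum(ta.values())
            for taxon, count in ta.items():
                assert nta.rows[taxon]["ta"] == count
                assert nta.nta(taxon) == pytest.approx(count / total)


class TestBa:
    def test_full_count_to_each_term(self, two_genus_taxonomy):
        bundle = make_bundle(
            two_genus_taxonomy,
            {"A1": (100, 1e-4, ["PEPA"], [("GO:0000001", "BP"),
                                          ("GO:0000002", "BP")])},
            {"PEPA": (2, 1.0, 0.1)},
        )
        ba = compute_ba(bundle)
        assert ba.ba("GO:0000001", "BP") == 2
        assert ba.ba("GO:0000002", "BP") == 2

    def test_no_annotation_empty_table(self, two_genus_taxonomy):
        bundle = make_bundle(
            two_genus_taxonomy,
            {"A1": (100, 1e-4, ["PEPA"], [])},
            {"PEPA": (2, 1.0, 0.1)},
        )
        assert compute_ba(bundle).rows == {}

    def test_matches_brute_force_double_loop(self, shared_bundle):
        ba = compute_ba(shared_bundle)
        expected = {}
        for pep, obs in shared_bundle.peptides.items():
            terms = set()
            for prot in shared_bundle.proteins.values():
                if pep in prot.peptides:
                    terms |= prot.go_terms
            for key in terms:
                expected[key] = expected.get(key, 0) + obs.spectral_count
        assert ba.rows == expected
        # BA totals >= total annotated peptide count
        annotated = sum(o.spectral_count
                        for p, o in shared_bundle.peptides.items()
                        if any(p in pr.peptides and pr.go_terms
                               for pr in shared_bundle.proteins.values()))
        assert sum(ba.rows.values()) >= annotated


class TestUnipeptFilter:
    def test_boundary_inclusive(self):
        assert unipept_species_filter({1: 995, 2: 5}, 0.005) == {1, 2}

    def test_below_threshold_removed(self):
        assert unipept_species_filter({1: 999, 2: 1}, 0.005) == {1}

    def test_fraction_zero_identity(self):
        assert unipept_species_filter({1: 10, 2: 0, 3: 1}, 0.0) == {1, 2, 3}

    def test_empty_counts_warn(self):
        with pytest.warns(UserWarning):
            assert unipept_species_filter({1: 0}) == set()
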