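"""The two-stage EM: evidence graphs, biomass, constrained function EM."""

import numpy as np
import pytest

from metafunc.em import (TAXON_ONLY, UNANNOTATED, Component, EvidenceGraph,
                         build_evidence_graph, estimate_biomass,
                         estimate_function_abundances, loglik)
from metafunc.evidence import ProteinRecord

from conftest import make_bundle


def taxon_graph(weighted_candidates):
    """Graph from {peptide: (weight, {species ids})}."""
    return EvidenceGraph(
        TAXON_ONLY,
        {p: w for p, (w, _) in weighted_candidates.items()},
        {p: frozenset(Component(t, UNANNOTATED, TAXON_ONLY) for t in c)
         for p, (_, c) in weighted_candidates.items()},
    )


def go_graph(weighted_candidates, aspect="BP"):
    """Graph from {peptide: (weight, {(species, go_id)})}."""
    return EvidenceGraph(
        aspect,
        {p: w for p, (w, _) in weighted_candidates.items()},
        {p: frozenset(Component(t, g, aspect) for t, g in c)
         for p, (_, c) in weighted_candidates.items()},
    )


class TestBuildGraph:
    @pytest.fixture
    def bundle(self, two_genus_taxonomy):
        return make_bundle(
            two_genus_taxonomy,
            {
                "A1": (100, 1e-4, ["PEPA", "PEPS"],
                       [("GO:0000001", "BP"), ("GO:0000002", "BP"),
                        ("GO:0000009", "MF")]),
                "B1": (101, 1e-3, ["PEPB", "PEPS"], []),
            },
            {
                "PEPA": (1, 2.0, 0.1),
                "PEPB": (1, 3.0, 0.1),
                "PEPS": (1, 1.0, 0.1),
            },
        )

    def test_bp_candidates_enumerate_terms(self, bundle):
        reps = list(bundle.proteins.values())
        g = build_evidence_graph(bundle, reps, "BP")
        assert g.candidates["PEPA"] == {
            Component(100, "GO:0000001", "BP"),
            Component(100, "GO:0000002", "BP"),
        }
        # B1 has no BP terms -> UNANNOTATED sentinel for its species
        assert g.candidates["PEPB"] == {Component(101, UNANNOTATED, "BP")}

    def test_shared_peptide_taxon_only(self, bundle):
        reps = list(bundle.proteins.values())
        g = build_evidence_graph(bundle, reps, TAXON_ONLY)
        assert {c.species_tax_id for c in g.candidates["PEPS"]} == {100, 101}

    def test_dropped_peptides_warn(self, bundle):
        reps = [bundle.proteins["A1"]]
        with pytest.warns(UserWarning, match="dropped"):
            g = build_evidence_graph(bundle, reps, TAXON_ONLY)
        assert "PEPB" not in g.candidates

    def test_matches_brute_force_scan(self, rng, two_genus_taxonomy):
        species = [100, 101, 102]
        pool = [f"PEP{i:02d}" for i in range(25)]
        prots = {}
        for i in range(9):
            peps = rng.choice(pool, size=int(rng.integers(1, 6)),
                              replace=False).tolist()
            gos = {(f"GO:{1 + int(g):07d}", "BP")
                   for g in rng.integers(0, 6, size=int(rng.integers(0, 3)))}
            prots[f"A{i}"] = (species[i % 3], 1e-4, peps, gos)
        used = sorted({p for (_, _, peps, _) in prots.values() for p in peps})
        bundle = make_bundle(two_genus_taxonomy, prots,
                             {p: (1, 1.0, 0.1) for p in used})
        reps = list(bundle.proteins.values())
        g = build_evidence_graph(bundle, reps, "BP")
        for pep in used:
            expected = set()
            terms_by_sp = {}
            for _, (tid, _, peps, gos) in prots.items():
                if pep in peps:
                    terms_by_sp.setdefault(tid, set()).update(
                        go for go, a in gos if a == "BP")
            for tid, terms in terms_by_sp.items():
                if terms:
                    expected |= {Component(tid, t, "BP") for t in terms}
                else:
                    expected.add(Component(tid, UNANNOTATED, "BP"))
            assert g.candidates[pep] == expected


class TestBiomassEM:
    def test_single_species(self):
        est = estimate_biomass(taxon_graph({"P1": (5.0, {100})}))
        assert est.p == {100: pytest.approx(1.0)}
        assert est.converged

    def test_unique_evidence_closed_form(self):
        g = taxon_graph({"P1": (3.0, {100}), "P2": (1.0, {101})})
        est = estimate_biomass(g)
        assert est.p[100] == pytest.approx(0.75, abs=1e-12)
        assert est.p[101] == pytest.approx(0.25, abs=1e-12)
        # closed form reached in a single EM step
        assert est.n_iter <= 2

    def test_closed_form_matches_grid_search(self):
        # oracle: 1-D likelihood grid over p_A for the 3-vs-1 unique case
        grid = np.linspace(1e-6, 1 - 1e-6, 200001)
        ll = 3.0 * np.log(grid) + 1.0 * np.log(1 - grid)
        assert grid[np.argmax(ll)] == pytest.approx(0.75, abs=1e-4)

    def test_shared_peptide_99_vs_1(self):
        # 99 peptides unique to A plus one shared by {A, B}: all the
        # evidence is consistent with A alone, so B's biomass vanishes.
        cands = {f"P{i:03d}": (1.0, {1001}) for i in range(99)}
        cands["SHARED"] = (1.0, {1001, 1002})
        est = estimate_biomass(taxon_graph(cands))
        assert est.p[1002] < 1e-6
        assert est.p[1001] == pytest.approx(1.0, abs=1e-6)
        # oracle: grid search of 99 log(pA) + log(pA + pB), pB = 1 - pA
        grid = np.linspace(1e-9, 1 - 1e-9, 100001)
        ll = 99 * np.log(grid) + np.log(1.0)  # pA + pB = 1 always
        assert grid[np.argmax(ll)] == pytest.approx(1.0, abs=1e-4)

    def test_loglik_monotone_on_random_instances(self, rng):
        for _ in range(100):
            n_sp = int(rng.integers(2, 6))
            species = list(range(n_sp))
            cands = {}
            for i in range(int(rng.integers(3, 15))):
                k = int(rng.integers(1, n_sp + 1))
                sub = set(rng.choice(species, size=k, replace=False).tolist())
                cands[f"P{i}"] = (float(rng.uniform(0.1, 5.0)), sub)
            est = estimate_biomass(taxon_graph(cands), tol=1e-12,
                                   max_iter=50)
            trace = est.loglik_trace
            for a, b in zip(trace, trace[1:]):
                assert b >= a - 1e-9 * max(1.0, abs(a))

    def test_order_invariance(self, rng):
        items = [(f"P{i}", (float(rng.uniform(0.5, 2.0)),
                            {int(s) for s in
                             rng.choice(5, size=int(rng.integers(1, 4)),
                                        replace=False)}))
                 for i in range(12)]
        est1 = estimate_biomass(taxon_graph(dict(items)))
        est2 = estimate_biomass(taxon_graph(dict(reversed(items))))
        for t in est1.p:
            assert est1.p[t] == pytest.approx(est2.p[t], abs=1e-12)


class TestFunctionEM:
    def test_single_species_single_term(self):
        biomass = estimate_biomass(taxon_graph({"P1": (1.0, {100})}))
        table = estimate_function_abundances(
            go_graph({"P1": (1.0, {(100, "GO:0000001")})}), biomass)
        assert table.species_abundance[(100, "GO:0000001")] == \
            pytest.approx(1.0)

    def test_two_terms_partition_by_unique_weight(self):
        biomass = estimate_biomass(taxon_graph({"P1": (2.0, {100}),
                                                "P2": (1.0, {100})}))
        table = estimate_function_abundances(
            go_graph({"P1": (2.0, {(100, "GO:0000001")}),
                      "P2": (1.0, {(100, "GO:0000002")})}), biomass)
        assert table.species_abundance[(100, "GO:0000001")] == \
            pytest.approx(2 / 3, abs=1e-9)
        assert table.species_abundance[(100, "GO:0000002")] == \
            pytest.approx(1 / 3, abs=1e-9)
        # oracle: grid over the within-species split theta
        grid = np.linspace(1e-6, 1 - 1e-6, 200001)
        ll = 2.0 * np.log(grid) + 1.0 * np.log(1 - grid)
        assert grid[np.argmax(ll)] == pytest.approx(2 / 3, abs=1e-4)

    def test_species_rows_sum_to_biomass(self, rng):
        for _ in range(20):
            n_sp = int(rng.integers(1, 4))
            terms = [f"GO:{i:07d}" for i in range(1, 5)]
            tax_c, go_c = {}, {}
            for i in range(int(rng.integers(3, 12))):
                sp = set(rng.choice(n_sp, size=int(rng.integers(1, n_sp + 1)),
                                    replace=False).tolist())
                w = float(rng.uniform(0.1, 3.0))
                tax_c[f"P{i}"] = (w, sp)
                go_c[f"P{i}"] = (w, {
                    (t, terms[int(rng.integers(len(terms)))]) for t in sp
                })
            biomass = estimate_biomass(taxon_graph(tax_c))
            table = estimate_function_abundances(go_graph(go_c), biomass)
            sums = {}
            for (t, _k), v in table.species_abundance.items():
                assert v >= 0
                sums[t] = sums.get(t, 0.0) + v
            for t, p in biomass.p.items():
                assert sums.get(t, 0.0) == pytest.approx(p, abs=1e-9)

    def test_biomass_without_evidence_goes_unannotated(self):
        biomass = estimate_biomass(
            taxon_graph({"P1": (3.0, {100}), "P2": (1.0, {101})}))
        with pytest.warns(UserWarning, match="UNANNOTATED"):
            table = estimate_function_abundances(
                go_graph({"P1": (3.0, {(100, "GO:0000001")})}), biomass)
        assert table.species_abundance[(101, UNANNOTATED)] == \
            pytest.approx(0.25, abs=1e-9)


class TestLoglik:
    def test_log_one_is_zero(self):
        g = taxon_graph({"P1": (1.0, {100})})
        c = Component(100, UNANNOTATED, TAXON_ONLY)
        assert loglik(g, {c: 1.0}) == pytest.approx(0.0)

    def test_uniform_two_candidates(self):
        g = taxon_graph({"P1": (1.0, {100, 101})})
        c1 = Component(100, UNANNOTATED, TAXON_ONLY)
        c2 = Component(101, UNANNOTATED, TAXON_ONLY)
        assert loglik(g, {c1: 0.5, c2: 0.5}) == pytest.approx(0.0)
        assert loglik(g, {c1: 0.25, c2: 0.25}) == pytest.approx(np.log(0.5))

    def test_zero_mass_is_minus_inf(self):
        g = taxon_graph({"P1": (1.0, {100})})
        assert loglik(g, {}) == float("-inf")

    def test_matches_direct_summation(self, rng):
        cands = {f"P{i}": (float(rng.uniform(0.1, 2.0)),
                           {int(s) for s in
                            rng.choice(4, size=int(rng.integers(1, 4)),
                                       replace=False)})
                 for i in range(10)}
        g = taxon_graph(cands)
        comps = g.components()
        params = {c: float(rng.uniform(0.01, 1.0)) for c in comps}
        expected = sum(
            w * np.log(sum(params[Component(t, UNANNOTATED, TAXON_ONLY)]
                           for t in sp))
            for w, sp in cands.values()
        )
        assert loglik(g, params) == pytest.approx(expected, rel=1e-12)
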