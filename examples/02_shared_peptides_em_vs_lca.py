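"""The shared-peptide problem: why the EM beats LCA-style counting.

Scenario: 99 peptides unique to species A plus one peptide shared between A
and B (same genus).  An LCA assignment pushes the shared peptide's evidence
to the genus, saying nothing about how to divide it; the EM uses all 100
peptides and concludes B's biomass is indistinguishable from zero.
"""

from metafunc import (TAXON_ONLY, UNANNOTATED, Component, EvidenceGraph,
                      estimate_biomass)

SPECIES_A, SPECIES_B = 1001, 1002

weights = {f"pep{i:03d}": 1.0 for i in range(99)}
candidates = {p: frozenset({Component(SPECIES_A, UNANNOTATED, TAXON_ONLY)})
              for p in weights}
weights["shared"] = 1.0
candidates["shared"] = frozenset({
    Component(SPECIES_A, UNANNOTATED, TAXON_ONLY),
    Component(SPECIES_B, UNANNOTATED, TAXON_ONLY),
})

est = estimate_biomass(EvidenceGraph(TAXON_ONLY, weights, candidates))
print(f"p(species A) = {est.p[SPECIES_A]:.9f}")
print(f"p(species B) = {est.p[SPECIES_B]:.2e}")
print(f"converged in {est.n_iter} iterations")

# p(A) -> 1 and p(B) -> 0: the maximizer of 99*log(pA) + log(pA + pB) under
# pA + pB = 1 is pA = 1.  A naive split of the shared peptide would instead
# hand B half a peptide's worth of biomass it has no unique evidence for.
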