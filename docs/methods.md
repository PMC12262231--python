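# Methods

## Model

Evidence consists of confidently identified peptides, each with a
quantitative weight `w_i` — by default its summed MS1 extracted-ion-
chromatogram (XIC) area, falling back to the spectral count when no area is
available (`weight_mode="count"` uses counts throughout). A peptide's
candidate set `C_i` is derived from the representative proteins that contain
it after filtering and grouping (below).

**Stage 1 (biomass).** Candidates are species. The weighted mixture
log-likelihood

    L(p) = Σ_i w_i · log( Σ_{t ∈ C_i} p_t ),   Σ_t p_t = 1,  p_t ≥ 0

is maximized by EM: responsibilities `z_{i,t} = p_t / Σ_{t'∈C_i} p_{t'}`,
then `p_t ← Σ_i w_i z_{i,t} / Σ_i w_i`. This likelihood is concave in `p`
along mixture directions; the EM trace is non-decreasing (asserted to 1e-9
slack in the run report) and no restarts are needed, so initialization is
deterministic-uniform. When no peptide is shared, one iteration reaches the
closed form `p_t = (species t's weight share)` exactly.

**Stage 2 (function abundances).** Candidates are (species, GO term) pairs:
for each species whose representative proteins contain the peptide, the
union of those proteins' terms of the requested aspect, or the sentinel
`UNANNOTATED` when they carry none. The same EM update runs over components
`θ_{t,k}`, followed by a projection that enforces the **biomass
constraint**: `θ_{t,k} ← p_t · θ̃_{t,k} / Σ_k θ̃_{t,k}`. The constraint set
(per-species simplices scaled to `p_t`) contains the uniform-within-species
start, so every iterate satisfies `Σ_k θ_{t,k} = p_t`. The three GO aspects
(BP, MF, CC) are quantified in three independent runs, each a partition of
total biomass. A species with biomass but no peptide in an aspect's graph
keeps all its mass on `UNANNOTATED` (warned).

Species-level results are projected to each of the seven named ranks (root,
phylum, class, order, family, genus, species) by summing over each rank's
lineage ancestors, per GO term. Totals are conserved at every rank and the
set of distinct GO terms is identical across ranks by construction.

## Workflow around the EM

1. **Peptide filter**: keep observations with E-value ≤ 1 (duplicate rows
   merge beforehand: counts and areas sum, E-value takes the minimum).
2. **Species filter**: drop proteins of species with identification E-value
   > 0.01. Species-level scores are an input column (carried in
   `proteins.tsv`); computing them is upstream search-engine territory.
3. **Protein acceptance**: decoy-free PFD control. Reading an E-value as an
   expected false-positive count, the PFD of the top-`r` ranked proteins is
   `E_r / r`; the longest prefix with `E_r / r ≤ α` (default α = 0.01) is
   accepted, capped at E-value ≤ 1. Ties break on accession for determinism.
4. **Clustering / unclustering**: proteins sharing most identified peptides
   (overlap coefficient `|P_a ∩ P_b| / min(|P_a|,|P_b|) ≥ 0.8`, connected
   components) form clusters; within each cluster the best-E-value protein
   per species is retained as that species' representative. The overlap
   coefficient is robust to fragment/isoform proteins whose peptide sets are
   subsets of a longer protein's; the 0.8 default is configurable
   (`--cluster-overlap`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `peptide_evalue` | 1.0 | peptide confidence cutoff (expected false IDs) |
| `species_evalue` | 0.01 | species identification cutoff |
| `protein_pfd` (α) | 0.01 | protein-level proportion of false discoveries |
| `cluster_overlap` | 0.8 | peptide-set overlap coefficient for an edge |
| `weight_mode` | `area` | XIC area, falling back to count per peptide |
| `tol` | 1e-9 | EM stop: max absolute parameter change |
| `max_iter` | 2000 | EM iteration cap per stage |

EM convergence is linear; on near-flat likelihood ridges (see *Limitations*)
the CC aspect occasionally needs more than 2000 iterations to reach 1e-9 —
the run report flags this and the CLI exits with code 4 while still writing
outputs. Raising `--max-iter` resolves it; the estimates move only in the
last few decimal places. Components whose mass converges below 1e-12 are
reported as exact zeros (never pruned mid-run, which could break
monotonicity); this also keeps replicate fold-change comparisons free of
meaningless ratios between numerically dead components.

## Synthetic communities

The simulator emulates evidence-level data for benchmark-style designs:
four species at ratios 1:1:1:1 / 4:2:2:1 / 1:2:2:4 and a 24-species
equimolar mixture, on a seven-rank taxonomy with species grouped two per
genus by default.

- **Areas.** Peptide areas are lognormal with per-species location: a
  species with biomass `b_t` and `n_t` generated peptides draws areas
  `(b_t/n_t)·exp(σZ − σ²/2)`, σ = 0.5 by default (a standard label-free
  intensity model). The normalization by `n_t` makes the *expected total*
  area of each species equal `b_t` exactly, so the σ = 0, no-sharing
  community reproduces the mixing ratios in closed form — the invariant the
  recovery tests lean on.
- **Spectral counts** are `1 + Poisson(rate · n_species · b_t)`: they grow
  with biomass but saturate at one, reproducing the mild bias of
  spectrum-counting estimators relative to area-based ones.
- **Sharing** copies peptide sequences into sibling-species proteomes
  (within genus, default probability 0.05) or random other-genus species
  (0.02), emulating confusable close relatives.
- **Decoys** are absent species grafted onto existing genera whose species-,
  protein- and peptide-level E-values are drawn uniform(0.1, 10), so the
  confidence filters are exercised; a manifest flags them for
  false-positive accounting.
- **Annotation.** Each protein draws `Poisson(1.5)` GO terms per aspect from
  a species-preferred vocabulary (half of a 40-term pool); zero draws leave
  the protein unannotated in that aspect, exercising the `UNANNOTATED`
  mass-conservation path (roughly mirroring the reality that only about
  half of reference proteins carry GO terms).
- **Function ground truth** attributes each peptide's expected area equally
  among its origin protein's terms of an aspect, normalized per species to a
  conditional profile `p(k|t)`.
- **Technical replicates** (`simulate_replicate`) keep the community —
  taxonomy, proteomes, sharing, truth — and redraw only areas and counts.
  **Missingness** (`simulate_missingness`) drops observations i.i.d.

What the simulator does *not* model: spectra, retention time, digestion
efficiency, charge states, protein-level abundance correlation within a
species, or annotation errors. Passing recovery tests therefore shows the
estimator is correct under its own generative assumptions, not that real
communities are this well-behaved; in particular, real XIC noise is heavier
tailed and real peptide detectability depends on abundance, which the
constant-detection design deliberately omits (it would confound the
closed-form checks).

## Numerical and design choices

- Fixed seven-level rank ladder; intermediate ranks are `no_rank`
  pass-throughs. Species lacking a named ancestor at a rank project into an
  explicit `unranked@rank` bucket so totals are conserved rather than
  silently dropped.
- All tie-breaks (protein ranking, representatives, cluster ids) are
  lexicographic; peptide iteration is sorted — outputs are byte-identical
  across re-runs and input orderings.
- Fold-change comparisons exclude pairs with zero abundance on either side
  (missing-data outliers are out of scope); `E[Error]` is the signed mean
  per comparison averaged over comparisons, `E[MALFCE]` its absolute
  counterpart, and `%EV` pools all errors across comparisons before applying
  the ±2 bound.
- Sensitivity/PFD support half-up rounding to a requested printed precision
  so benchmark arithmetic can be compared against published tables digit for
  digit.
- The quasi-gold construction accepts every annotated protein with E-value
  at or below the expected-false-positive budget (default 1) and unions
  terms per aspect without clustering — broad true-positive coverage at the
  cost of some false positives, which is the point of a *quasi* gold
  standard.

## Known limitations

- **Within-species identifiability.** When several GO terms co-occur in the
  same candidate sets (multi-term proteins with no distinguishing
  peptides), the stage-2 likelihood is flat across those terms: the EM
  keeps the uniform-start split along exactly flat directions but can drift
  toward hub terms along nearly flat ones. Conditional profiles `p(k|t)`
  are therefore only partially identifiable; joint abundances remain
  well-behaved because the biomass constraint bounds each species' total.
- Stage-2's projection guarantees feasibility, not a monotone joint
  likelihood; in practice the trace is monotone to numerical precision and
  convergence is checked on parameter change.
- The two-stage formulation fixes `p_t` before fitting `θ_{t,k}`; a joint
  one-stage fit could in principle differ in how cross-species shared
  peptides trade off against function allocation, but the constraints the
  two-stage form satisfies (biomass normalization, per-species partition)
  pin down the reported quantities.
- E-value-based PFD control assumes calibrated E-values; with miscalibrated
  scores the α parameter loses its interpretation.

## Problem sizes

The test suite and the acceptance script use a 24-species equimolar
community of ~2,000 peptides (10 proteins/species, ~8 peptides/protein),
the 4-species mixtures at ~300–500 peptides, 50 randomized small bundles
for the conservation suite and 100 random instances for the monotonicity
suite. These sizes give sub-second EM runs while leaving Monte-Carlo error
well below the recovery tolerances (biomass MAE ≈ 0.002 observed against a
0.02 bound).
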