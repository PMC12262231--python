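"""Two-stage EM allocation of shared-peptide evidence with a biomass constraint.

The shared confidently identified peptide problem: a peptide may match
proteins of several species, and within a species several GO terms, so its
quantitative weight (XIC area or spectral count) cannot be attributed
directly.  Stage 1 fits a mixture over species: each peptide i with weight
w_i and candidate species set C_i contributes ``w_i * log(sum_{t in C_i} p_t)``
to the log-likelihood, and EM yields biomass fractions p_t summing to 1.
Stage 2 fits joint abundances theta_{t,k} over (species, GO term) components
with the *biomass constraint*: after each raw M-step the per-species rows are
rescaled so that ``sum_k theta_{t,k} = p_t``, keeping function abundances a
partition of each species' biomass.  Species-level results are projected to
every named taxonomic rank, so the same set of distinct GO terms is reported
at every level of the lineage.

Species whose accepted proteins carry no annotation of the requested aspect
keep their biomass through an ``UNANNOTATED`` sentinel component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .evidence import EvidenceBundle, ProteinRecord, peptide_weight
from .taxonomy import RANK_ORDER, Taxonomy

__all__ = [
    "UNANNOTATED",
    "TAXON_ONLY",
    "Component",
    "EvidenceGraph",
    "BiomassEstimate",
    "FunctionAbundanceTable",
    "build_evidence_graph",
    "estimate_biomass",
    "estimate_function_abundances",
    "loglik",
]

UNANNOTATED = "UNANNOTATED"
TAXON_ONLY = "TAXON_ONLY"


@dataclass(frozen=True, order=True)
class Component:
    """A (species, GO term) allocation target; stage 1 uses TAXON_ONLY
    components that carry the UNANNOTATED sentinel."""

    species_tax_id: int
    go_id: str
    aspect: str

    def __post_init__(self) -> None:
        if self.aspect == TAXON_ONLY and self.go_id != UNANNOTATED:
            raise ValueError("TAXON_ONLY components must carry UNANNOTATED")


@dataclass
class EvidenceGraph:
    """Peptide weights and per-peptide candidate component sets."""

    aspect: str
    peptide_weights: Dict[str, float]
    candidates: Dict[str, frozenset[Component]]

    def __post_init__(self) -> None:
        if not self.peptide_weights:
            raise ValueError("evidence graph has no peptides")
        if set(self.peptide_weights) != set(self.candidates):
            raise ValueError("peptide_weights and candidates key mismatch")
        for pep, cands in self.candidates.items():
            if not cands:
                raise ValueError(f"peptide {pep} has no candidates")
        for w in self.peptide_weights.values():
            if not np.isfinite(w) or w < 0:
                raise ValueError("peptide weights must be finite and >= 0")

    def components(self) -> List[Component]:
        return sorted(set().union(*self.candidates.values()))

    def species(self) -> List[int]:
        return sorted({c.species_tax_id for c in self.components()})


@dataclass
class BiomassEstimate:
    """Species biomass fractions p_t (sum to 1) with the EM trace."""

    p: Dict[int, float]
    loglik_trace: List[float]
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        total = sum(self.p.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biomass fractions sum to {total}, not 1")
        if any(v < 0 for v in self.p.values()):
            raise ValueError("negative biomass fraction")


@dataclass
class FunctionAbundanceTable:
    """Joint abundances theta_{t,k} per species, projectable to any rank."""

    aspect: str
    species_abundance: Dict[Tuple[int, str], float]  # (species, go_id) -> theta
    biomass: BiomassEstimate
    taxonomy: Taxonomy | None
    loglik_trace: List[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    def go_ids(self) -> List[str]:
        return sorted({k for _, k in self.species_abundance})

    def at_rank(self, rank: str) -> Dict[Tuple[object, str], float]:
        """Project (taxon, go_id) abundances to ``rank``; totals conserved."""
        if self.taxonomy is None:
            raise ValueError("attach a taxonomy before projecting to ranks")
        out: Dict[Tuple[object, str], float] = {}
        by_go: Dict[str, Dict[int, float]] = {}
        for (t, k), v in self.species_abundance.items():
            by_go.setdefault(k, {})[t] = v
        for k, values in sorted(by_go.items()):
            for taxon, v in self.taxonomy.project_to_rank(values, rank).items():
                out[(taxon, k)] = v
        return out

    def to_frame(self, include_unannotated: bool = False) -> pd.DataFrame:
        """Long table over every rank: rank, taxon, go_id, aspect, abundance."""
        rows = []
        for rank in RANK_ORDER:
            for (taxon, k), v in sorted(self.at_rank(rank).items(),
                                        key=lambda kv: (str(kv[0][0]), kv[0][1])):
                if k == UNANNOTATED and not include_unannotated:
                    continue
                rows.append((rank, taxon, k, self.aspect, v))
        return pd.DataFrame(
            rows, columns=["rank", "taxon", "go_id", "aspect", "abundance"]
        )


def build_evidence_graph(
    bundle: EvidenceBundle,
    representatives: Iterable[ProteinRecord],
    aspect: str,
    weight_mode: str = "area",
) -> EvidenceGraph:
    """Map each peptide to its candidate components via representative proteins.

    For ``TAXON_ONLY`` the candidates are the distinct species of the
    representatives containing the peptide.  For a GO aspect they are
    (species, go_id) pairs over each containing representative's terms of that
    aspect, with a (species, UNANNOTATED) candidate when a species' containing
    proteins carry no term of the aspect.
    """
    reps = list(representatives)
    if not reps:
        raise ValueError("no representative proteins")
    if aspect not in {"BP", "MF", "CC", TAXON_ONLY}:
        raise ValueError(f"unknown aspect {aspect!r}")

    weights: Dict[str, float] = {}
    candidates: Dict[str, frozenset[Component]] = {}
    n_dropped = 0
    containing: Dict[str, List[ProteinRecord]] = {}
    for prot in reps:
        for pep in prot.peptides:
            containing.setdefault(pep, []).append(prot)

    for pep, obs in bundle.peptides.items():
        prots = containing.get(pep)
        if not prots:
            n_dropped += 1
            continue
        comps: set[Component] = set()
        if aspect == TAXON_ONLY:
            for prot in prots:
                comps.add(Component(prot.species_tax_id, UNANNOTATED, TAXON_ONLY))
        else:
            terms_by_species: Dict[int, set[str]] = {}
            for prot in prots:
                terms_by_species.setdefault(prot.species_tax_id, set()).update(
                    prot.go_of_aspect(aspect)
                )
            for tid, terms in terms_by_species.items():
                if terms:
                    comps.update(Component(tid, g, aspect) for g in terms)
                else:
                    comps.add(Component(tid, UNANNOTATED, aspect))
        weights[pep] = peptide_weight(obs, weight_mode)
        candidates[pep] = frozenset(comps)

    if n_dropped:
        warnings.warn(
            f"{n_dropped} peptides contained by no representative protein "
            "were dropped",
            stacklevel=2,
        )
    if not weights:
        raise ValueError("every peptide was dropped; evidence graph is empty")
    return EvidenceGraph(aspect, weights, candidates)


# -- EM machinery -----------------------------------------------------------


def _index_graph(graph: EvidenceGraph):
    """Flatten the bipartite peptide/component structure into index arrays."""
    comps = graph.components()
    comp_idx = {c: j for j, c in enumerate(comps)}
    peps = sorted(graph.peptide_weights)
    w = np.array([graph.peptide_weights[p] for p in peps], dtype=float)
    cand_pep: List[int] = []
    cand_comp: List[int] = []
    for i, pep in enumerate(peps):
        for c in sorted(graph.candidates[pep]):
            cand_pep.append(i)
            cand_comp.append(comp_idx[c])
    return comps, w, np.asarray(cand_pep), np.asarray(cand_comp)


def _em_loop(w, cand_pep, cand_comp, n_comp, theta0, tol, max_iter,
             project=None):
    """Generic weighted-mixture EM.  ``project`` (optional) maps the raw
    M-step estimate onto a constraint set after every iteration."""
    n_pep = w.size
    w_total = w.sum()
    if w_total <= 0:
        raise ValueError("total peptide weight is zero")
    theta = theta0.copy()
    trace: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = np.zeros(n_pep)
        np.add.at(denom, cand_pep, theta[cand_comp])
        with np.errstate(divide="ignore"):
            ll = float(np.sum(w * np.log(denom)))
        trace.append(ll)
        z = np.where(denom[cand_pep] > 0,
                     theta[cand_comp] / np.where(denom[cand_pep] > 0,
                                                 denom[cand_pep], 1.0),
                     0.0)
        new = np.bincount(cand_comp, weights=w[cand_pep] * z,
                          minlength=n_comp) / w_total
        if project is not None:
            new = project(new)
        delta = float(np.max(np.abs(new - theta)))
        theta = new
        if delta < tol:
            converged = True
            break
    denom = np.zeros(n_pep)
    np.add.at(denom, cand_pep, theta[cand_comp])
    with np.errstate(divide="ignore"):
        trace.append(float(np.sum(w * np.log(denom))))
    return theta, trace, it, converged


def estimate_biomass(
    graph: EvidenceGraph, tol: float = 1e-9, max_iter: int = 2000
) -> BiomassEstimate:
    """Stage-1 EM: species biomass fractions from a TAXON_ONLY evidence graph.

    Maximizes ``sum_i w_i log(sum_{t in C_i} p_t)`` subject to ``sum_t p_t = 1``
    from a uniform start.  With no shared peptides this converges in a single
    step to each species' weight share (closed form).
    """
    if graph.aspect != TAXON_ONLY:
        raise ValueError("estimate_biomass expects a TAXON_ONLY graph")
    comps, w, cand_pep, cand_comp = _index_graph(graph)
    k = len(comps)
    theta0 = np.full(k, 1.0 / k)
    theta, trace, n_iter, converged = _em_loop(
        w, cand_pep, cand_comp, k, theta0, tol, max_iter
    )
    # Masses that converged below 1e-12 are reported as exact zeros (they
    # are never pruned mid-run, which could break monotonicity).
    theta[theta < 1e-12] = 0.0
    theta = theta / theta.sum()
    p = {c.species_tax_id: float(v) for c, v in zip(comps, theta)}
    return BiomassEstimate(p, trace, n_iter, converged)


def estimate_function_abundances(
    graph: EvidenceGraph,
    biomass: BiomassEstimate,
    taxonomy: Taxonomy | None = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> FunctionAbundanceTable:
    """Stage-2 EM: joint (species, GO term) abundances under the biomass
    constraint ``sum_k theta_{t,k} = p_t``.

    The E-step splits each peptide's weight across its candidate components in
    proportion to the current theta; the raw M-step re-estimates theta; the
    projection step rescales each species' row to its fixed biomass p_t.
    Species carrying biomass but absent from the graph keep their whole mass
    on the UNANNOTATED sentinel (warned).
    """
    if graph.aspect == TAXON_ONLY:
        raise ValueError("function abundances need a GO-aspect graph")
    comps, w, cand_pep, cand_comp = _index_graph(graph)
    for c in comps:
        if c.species_tax_id not in biomass.p:
            raise ValueError(
                f"candidate species {c.species_tax_id} has no biomass estimate"
            )
    n_comp = len(comps)
    species = np.array([c.species_tax_id for c in comps])
    sp_ids = sorted(biomass.p)
    sp_index = {t: j for j, t in enumerate(sp_ids)}
    sp_of_comp = np.array([sp_index[t] for t in species])
    p_vec = np.array([biomass.p[t] for t in sp_ids])

    missing = [t for t in sp_ids if t not in set(species.tolist())
               and biomass.p[t] > 0]
    if missing:
        warnings.warn(
            f"species {missing} have biomass but no peptide evidence in the "
            f"{graph.aspect} graph; their mass stays UNANNOTATED",
            stacklevel=2,
        )

    def project(theta_raw: np.ndarray) -> np.ndarray:
        row_sum = np.bincount(sp_of_comp, weights=theta_raw,
                              minlength=len(sp_ids))
        scale = np.where(row_sum > 0, p_vec / np.where(row_sum > 0, row_sum, 1.0),
                         0.0)
        return theta_raw * scale[sp_of_comp]

    # Uniform-within-species start already on the constraint set.
    counts = np.bincount(sp_of_comp, minlength=len(sp_ids))
    theta0 = p_vec[sp_of_comp] / counts[sp_of_comp]
    theta, trace, n_iter, converged = _em_loop(
        w, cand_pep, cand_comp, n_comp, theta0, tol, max_iter, project=project
    )

    theta[theta < 1e-12] = 0.0  # report converged-out components as zero
    abundance: Dict[Tuple[int, str], float] = {
        (c.species_tax_id, c.go_id): float(v) for c, v in zip(comps, theta)
    }
    for t in missing:
        abundance[(t, UNANNOTATED)] = biomass.p[t]
    # Renormalize each species row exactly onto p_t (floating drift guard).
    for t in sp_ids:
        row = {k: v for (tt, k), v in abundance.items() if tt == t}
        s = sum(row.values())
        if s > 0:
            for k in row:
                abundance[(t, k)] = row[k] * biomass.p[t] / s
        elif biomass.p[t] > 0:
            abundance[(t, UNANNOTATED)] = biomass.p[t]
    return FunctionAbundanceTable(
        graph.aspect, abundance, biomass, taxonomy, trace, n_iter, converged
    )


def loglik(graph: EvidenceGraph, params: Mapping[Component, float]) -> float:
    """Weighted mixture log-likelihood ``sum_i w_i log(sum_{c in C_i} params_c)``.

    Returns -inf if any peptide has zero total candidate mass.
    """
    total = 0.0
    for pep, cands in graph.candidates.items():
        mass = sum(params.get(c, 0.0) for c in cands)
        if mass <= 0:
            return float("-inf")
        total += graph.peptide_weights[pep] * float(np.log(mass))
    return total
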