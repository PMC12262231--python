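"""Count-based comparison baselines: peptide LCA, NTA, BA, 0.5% species filter.

These reproduce the abundance arithmetic used by LCA-centred workflows:

* ``NTA_t = TA_t / sum_b TA_b`` where TA_t is the spectral count (redundancy
  included) of peptides unique to taxon t at the requested rank;
* ``BA_g = sum_i I(peptide_i maps to g)`` counted with redundancy, a peptide
  mapping to m terms contributing its full count to each;
* the heuristic species filter that drops species holding less than a set
  fraction (default 0.5%) of the taxon-specific peptide count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

from .evidence import EvidenceBundle, ProteinRecord
from .taxonomy import RANK_ORDER, Taxonomy

__all__ = [
    "NtaTable",
    "BaTable",
    "assign_peptide_lca",
    "compute_nta",
    "compute_ba",
    "unipept_species_filter",
]


@dataclass
class NtaTable:
    """Per-taxon peptide counts (ta) and normalized abundances (nta)."""

    rank: str
    rows: Dict[int, Dict[str, float]]  # tax_id -> {"ta": int, "nta": float}

    def nta(self, tax_id: int) -> float:
        return self.rows.get(tax_id, {"nta": 0.0})["nta"]

    def as_dict(self) -> Dict[int, float]:
        return {t: r["nta"] for t, r in self.rows.items()}


@dataclass
class BaTable:
    rows: Dict[tuple[str, str], int]  # (go_id, aspect) -> count

    def ba(self, go_id: str, aspect: str) -> int:
        return self.rows.get((go_id, aspect), 0)


def _peptide_species(
    bundle: EvidenceBundle, proteins: Optional[Iterable[ProteinRecord]] = None
) -> Dict[str, set[int]]:
    prots = list(proteins) if proteins is not None else list(
        bundle.proteins.values())
    out: Dict[str, set[int]] = {}
    for prot in prots:
        for pep in prot.peptides:
            if pep in bundle.peptides:
                out.setdefault(pep, set()).add(prot.species_tax_id)
    return out


def assign_peptide_lca(
    bundle: EvidenceBundle,
    taxonomy: Taxonomy,
    proteins: Optional[Iterable[ProteinRecord]] = None,
) -> Dict[str, int]:
    """Assign each peptide the LCA of the species whose proteins contain it.

    Peptides contained by no protein are dropped with a warning.
    """
    by_pep = _peptide_species(bundle, proteins)
    orphans = set(bundle.peptides) - set(by_pep)
    if orphans:
        warnings.warn(f"{len(orphans)} orphan peptides dropped from LCA "
                      "assignment", stacklevel=2)
    return {pep: taxonomy.lca(sp) for pep, sp in by_pep.items()}


def compute_nta(
    bundle: EvidenceBundle,
    taxonomy: Taxonomy,
    rank: str = "species",
    proteins: Optional[Iterable[ProteinRecord]] = None,
) -> NtaTable:
    """Normalized taxa abundance at ``rank`` from taxon-unique peptide counts.

    A peptide is unique to taxon t at rank r when all its matching species
    collapse to the single taxon t at that rank; its spectral count then
    accrues to TA_t.  NTA is TA normalized to sum to 1.
    """
    if rank not in RANK_ORDER:
        raise ValueError(f"unknown rank {rank!r}")
    by_pep = _peptide_species(bundle, proteins)
    ta: Dict[int, int] = {}
    for pep, species in by_pep.items():
        ancestors = {taxonomy.ancestor_at_rank(t, rank) for t in species}
        if len(ancestors) == 1 and None not in ancestors:
            (taxon,) = ancestors
            ta[taxon] = ta.get(taxon, 0) + bundle.peptides[pep].spectral_count
    total = sum(ta.values())
    if total == 0:
        warnings.warn(f"no taxon-unique peptides at rank {rank!r}", stacklevel=2)
        return NtaTable(rank, {t: {"ta": 0, "nta": 0.0} for t in ta})
    return NtaTable(
        rank, {t: {"ta": c, "nta": c / total} for t, c in sorted(ta.items())}
    )


def compute_ba(
    bundle: EvidenceBundle,
    proteins: Optional[Iterable[ProteinRecord]] = None,
) -> BaTable:
    """Biological-function abundance: redundant peptide counts per GO term.

    Each peptide's GO set is the union over its matching proteins' terms; the
    peptide contributes its full spectral count to every term in the set.
    """
    prots = list(proteins) if proteins is not None else list(
        bundle.proteins.values())
    terms_by_pep: Dict[str, set[tuple[str, str]]] = {}
    for prot in prots:
        for pep in prot.peptides:
            if pep in bundle.peptides:
                terms_by_pep.setdefault(pep, set()).update(prot.go_terms)
    rows: Dict[tuple[str, str], int] = {}
    for pep, terms in terms_by_pep.items():
        count = bundle.peptides[pep].spectral_count
        for key in terms:
            rows[key] = rows.get(key, 0) + count
    return BaTable(rows)


def unipept_species_filter(
    species_peptide_counts: Mapping[int, float], fraction: float = 0.005
) -> set[int]:
    """Retain species holding at least ``fraction`` of the taxon-specific
    peptide count (boundary inclusive); the heuristic false-positive filter
    used with LCA-style species lists."""
    if any(c < 0 for c in species_peptide_counts.values()):
        raise ValueError("negative peptide count")
    total = sum(species_peptide_counts.values())
    if total == 0:
        warnings.warn("no taxon-specific peptides; empty retention set",
                      stacklevel=2)
        return set()
    threshold = fraction * total
    return {t for t, c in species_peptide_counts.items() if c >= threshold}
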