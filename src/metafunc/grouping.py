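"""Protein clustering / unclustering and decoy-free protein-level FDR control.

Proteins sharing most of their identified peptides (overlap coefficient
``|Pa ∩ Pb| / min(|Pa|, |Pb|) >= threshold``) are grouped into clusters
(connected components).  Within each cluster, one representative protein per
species — the best E-value — is "unclustered" and carries that species' GO
annotation forward.  Protein acceptance is controlled without decoys by
reading an E-value as an expected false-positive count: accept the longest
E-value-sorted prefix whose last member satisfies E/rank <= alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

import networkx as nx

from .evidence import ProteinRecord

__all__ = ["ProteinCluster", "control_protein_pfd", "cluster_proteins", "uncluster"]


@dataclass
class ProteinCluster:
    cluster_id: int
    members: frozenset[str]
    representatives: Dict[int, str]  # species_tax_id -> accession


def control_protein_pfd(
    proteins: Iterable[ProteinRecord],
    alpha: float = 0.01,
    evalue_cap: float = 1.0,
) -> List[ProteinRecord]:
    """Accept proteins at an estimated proportion of false discoveries <= alpha.

    With E-values interpreted as expected false-positive counts, the PFD of
    the top-r E-value-ranked proteins is estimated as E_r / r.  The longest
    prefix with E_r / r <= alpha is accepted, then intersected with
    E-value <= evalue_cap.  Ties break lexicographically on accession.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    ranked = sorted(proteins, key=lambda p: (p.evalue, p.accession))
    n_accept = 0
    for r, prot in enumerate(ranked, start=1):
        if prot.evalue / r <= alpha:
            n_accept = r
    accepted = [p for p in ranked[:n_accept] if p.evalue <= evalue_cap]
    if not accepted:
        warnings.warn("no proteins accepted at the requested PFD", stacklevel=2)
    return accepted


def overlap_coefficient(a: frozenset, b: frozenset) -> float:
    return len(a & b) / min(len(a), len(b))


def cluster_proteins(
    proteins: Iterable[ProteinRecord], overlap_threshold: float = 0.8
) -> List[ProteinCluster]:
    """Group proteins whose peptide sets overlap substantially.

    Edge rule: overlap coefficient >= threshold; clusters are connected
    components.  Cluster ids are assigned in order of the lexicographically
    smallest member accession, so the output is deterministic.
    """
    if not (0 < overlap_threshold <= 1):
        raise ValueError("overlap_threshold must be in (0, 1]")
    prots = {p.accession: p for p in proteins}
    for p in prots.values():
        if not p.peptides:
            raise ValueError(f"protein {p.accession} has no peptides")
    g = nx.Graph()
    g.add_nodes_from(prots)
    accs = sorted(prots)
    # Candidate pairs via shared-peptide index; avoids the all-pairs scan.
    by_pep: Dict[str, list[str]] = {}
    for acc in accs:
        for pep in prots[acc].peptides:
            by_pep.setdefault(pep, []).append(acc)
    seen_pairs: set[tuple[str, str]] = set()
    for members in by_pep.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair = (a, b) if a < b else (b, a)
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                if overlap_coefficient(prots[a].peptides, prots[b].peptides) \
                        >= overlap_threshold:
                    g.add_edge(*pair)
    comps = sorted(nx.connected_components(g), key=min)
    clusters = []
    for cid, comp in enumerate(comps):
        clusters.append(ProteinCluster(cid, frozenset(comp), {}))
    return clusters


def uncluster(
    clusters: Iterable[ProteinCluster], proteins: Mapping[str, ProteinRecord]
) -> List[ProteinRecord]:
    """Retain, per cluster and per species, the best-E-value member protein.

    Ties break on lexicographic accession.  Fills each cluster's
    ``representatives`` map in place and returns the union of representatives.
    """
    reps: List[ProteinRecord] = []
    for cluster in clusters:
        best: Dict[int, ProteinRecord] = {}
        for acc in sorted(cluster.members):
            prot = proteins[acc]
            cur = best.get(prot.species_tax_id)
            if cur is None or (prot.evalue, prot.accession) < (cur.evalue,
                                                               cur.accession):
                best[prot.species_tax_id] = prot
        cluster.representatives = {t: p.accession for t, p in best.items()}
        reps.extend(best[t] for t in sorted(best))
    return reps
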