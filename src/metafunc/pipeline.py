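"""End-to-end orchestration: filters -> grouping -> EM -> rank projection.

`run_quantify` executes the whole quantification workflow on the five
evidence tables and returns tables plus a machine-readable report with the
config echo, iteration counts and the results of every conservation check.
`run_evaluate` drives the evaluation metrics over quantification outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import __version__ as _version
from .em import (TAXON_ONLY, UNANNOTATED, BiomassEstimate,
                 FunctionAbundanceTable, build_evidence_graph,
                 estimate_biomass, estimate_function_abundances)
from .evidence import (ASPECTS, EvidenceBundle, filter_confident_peptides,
                       filter_confident_species, load_evidence)
from .grouping import cluster_proteins, control_protein_pfd, uncluster
from .metrics import (FoldChangeComparison, TermSet, log2fc_error_metrics,
                      overlap_matrix, sensitivity_pfd)
from .taxonomy import RANK_ORDER, Taxonomy, load_taxonomy

__all__ = ["RunConfig", "QuantifyResult", "run_quantify", "run_evaluate",
           "quantify_bundle", "compute_log2fc"]


@dataclass
class RunConfig:
    peptides: str
    proteins: str
    peptide_map: str
    go: str
    taxonomy: str
    peptide_evalue: float = 1.0
    species_evalue: float = 0.01
    protein_pfd: float = 0.01
    protein_evalue_cap: float = 1.0
    cluster_overlap: float = 0.8
    weight_mode: str = "area"
    aspects: Sequence[str] = ASPECTS
    tol: float = 1e-9
    max_iter: int = 2000
    report_unannotated: bool = False
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("peptide_evalue", "species_evalue", "protein_pfd",
                     "protein_evalue_cap", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QuantifyResult:
    biomass: BiomassEstimate
    tables: Dict[str, FunctionAbundanceTable]
    taxonomy: Taxonomy
    representatives: List
    report: Dict = field(default_factory=dict)

    def biomass_at_rank(self, rank: str) -> Dict:
        return self.taxonomy.project_to_rank(self.biomass.p, rank)

    def write_outputs(self, outdir, include_unannotated: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "biomass.tsv", "w") as fh:
            fh.write("#rank\ttax_id\tname\tprobability\n")
            for rank in RANK_ORDER:
                for taxon, p in sorted(self.biomass_at_rank(rank).items(),
                                       key=lambda kv: str(kv[0])):
                    name = (self.taxonomy.nodes[taxon].name
                            if isinstance(taxon, int) else taxon)
                    fh.write(f"{rank}\t{taxon}\t{name}\t{p!r}\n")
        with open(outdir / "functions.tsv", "w") as fh:
            fh.write("#rank\ttax_id\tname\tgo_id\taspect\tabundance\n")
            for aspect in sorted(self.tables):
                frame = self.tables[aspect].to_frame(include_unannotated)
                for row in frame.itertuples(index=False):
                    name = (self.taxonomy.nodes[row.taxon].name
                            if isinstance(row.taxon, int) else row.taxon)
                    fh.write(f"{row.rank}\t{row.taxon}\t{name}\t{row.go_id}\t"
                             f"{row.aspect}\t{row.abundance!r}\n")
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=1, sort_keys=True)


def _check_invariants(result: QuantifyResult, tol: float = 1e-9) -> Dict:
    """Conservation checks the run report must carry; all should pass."""
    checks: Dict[str, bool] = {}
    p = result.biomass.p
    checks["biomass_sums_to_one"] = abs(sum(p.values()) - 1.0) <= tol
    trace = result.biomass.loglik_trace
    checks["stage1_loglik_monotone"] = all(
        b - a >= -1e-9 * max(1.0, abs(a))
        for a, b in zip(trace, trace[1:])
    )
    for aspect, table in result.tables.items():
        by_species: Dict[int, float] = {}
        for (t, _k), v in table.species_abundance.items():
            by_species[t] = by_species.get(t, 0.0) + v
        checks[f"{aspect}_rows_sum_to_biomass"] = all(
            abs(by_species.get(t, 0.0) - p[t]) <= tol for t in p
        )
        go_sets = {
            rank: {k for (_t, k) in table.at_rank(rank)}
            for rank in RANK_ORDER
        }
        first = go_sets["species"]
        checks[f"{aspect}_go_set_constant_across_ranks"] = all(
            s == first for s in go_sets.values()
        )
        checks[f"{aspect}_rank_totals_conserved"] = all(
            abs(sum(table.at_rank(rank).values()) - 1.0) <= 1e-6
            for rank in RANK_ORDER
        )
    return checks


def quantify_bundle(
    bundle: EvidenceBundle,
    config: Optional[RunConfig] = None,
    species_evalues: Optional[Mapping[int, float]] = None,
    weight_mode: str = "area",
    aspects: Sequence[str] = ASPECTS,
    peptide_evalue: float = 1.0,
    species_evalue: float = 0.01,
    protein_pfd: float = 0.01,
    cluster_overlap: float = 0.8,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> QuantifyResult:
    """Run filters, grouping and both EM stages on an in-memory bundle."""
    if config is not None:
        weight_mode = config.weight_mode
        aspects = config.aspects
        peptide_evalue = config.peptide_evalue
        species_evalue = config.species_evalue
        protein_pfd = config.protein_pfd
        cluster_overlap = config.cluster_overlap
        tol, max_iter = config.tol, config.max_iter

    stage = "peptide filter"
    try:
        filtered = filter_confident_peptides(bundle, peptide_evalue)
        stage = "species filter"
        filtered = filter_confident_species(filtered, species_evalues,
                                            species_evalue)
        stage = "protein PFD control"
        accepted = control_protein_pfd(
            filtered.proteins.values(), alpha=protein_pfd,
            evalue_cap=1.0 if config is None else config.protein_evalue_cap,
        )
        stage = "protein clustering"
        clusters = cluster_proteins(accepted, cluster_overlap)
        representatives = uncluster(clusters, {p.accession: p
                                               for p in accepted})
        stage = "biomass EM"
        tax_graph = build_evidence_graph(filtered, representatives,
                                         TAXON_ONLY, weight_mode)
        biomass = estimate_biomass(tax_graph, tol=tol, max_iter=max_iter)
        tables: Dict[str, FunctionAbundanceTable] = {}
        for aspect in aspects:
            stage = f"{aspect} function EM"
            graph = build_evidence_graph(filtered, representatives, aspect,
                                         weight_mode)
            tables[aspect] = estimate_function_abundances(
                graph, biomass, taxonomy=bundle.taxonomy, tol=tol,
                max_iter=max_iter,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = QuantifyResult(biomass, tables, bundle.taxonomy,
                            representatives)
    report = {
        "version": _version,
        "config": asdict(config) if config is not None else {
            "weight_mode": weight_mode, "aspects": list(aspects),
            "peptide_evalue": peptide_evalue,
            "species_evalue": species_evalue,
            "protein_pfd": protein_pfd, "cluster_overlap": cluster_overlap,
            "tol": tol, "max_iter": max_iter,
        },
        "n_peptides": len(filtered.peptides),
        "n_proteins_accepted": len(accepted),
        "n_clusters": len(clusters),
        "n_representatives": len(representatives),
        "biomass": {
            "n_iter": biomass.n_iter,
            "converged": biomass.converged,
            "final_loglik": biomass.loglik_trace[-1],
        },
        "aspects": {
            aspect: {"n_iter": t.n_iter, "converged": t.converged,
                     "n_go_terms": len(t.go_ids())}
            for aspect, t in tables.items()
        },
    }
    report["invariants"] = _check_invariants(result)
    result.report = report
    return result


def run_quantify(config: RunConfig) -> QuantifyResult:
    """Load the five evidence tables and quantify; write outputs if asked."""
    taxonomy = load_taxonomy(config.taxonomy)
    bundle = load_evidence(config.peptides, config.proteins,
                           config.peptide_map, config.go, taxonomy)
    result = quantify_bundle(bundle, config=config)
    if config.outdir:
        result.write_outputs(config.outdir, config.report_unannotated)
    return result


def compute_log2fc(
    table_a: FunctionAbundanceTable,
    table_b: FunctionAbundanceTable,
    rank: str = "species",
) -> Dict[Tuple[object, str], float]:
    """log2(a/b) per (taxon, go_id) at ``rank``, over keys with positive
    abundance in both runs (zero-abundance pairs are excluded)."""
    a, b = table_a.at_rank(rank), table_b.at_rank(rank)
    out = {}
    for key in sorted(set(a) & set(b), key=lambda kv: (str(kv[0]), kv[1])):
        if key[1] == UNANNOTATED:
            continue
        va, vb = a[key], b[key]
        if va > 0 and vb > 0:
            out[key] = math.log2(va / vb)
    return out


def run_evaluate(
    method_sets: Mapping[str, frozenset] | Mapping[str, set],
    gold_sets: Mapping[str, frozenset] | Mapping[str, set],
    fold_change_pairs: Optional[List[Tuple[FunctionAbundanceTable,
                                           FunctionAbundanceTable]]] = None,
    true_log2fc: float = 0.0,
    rank: str = "species",
    ev_bound: float = 2.0,
    rounding_digits: Optional[int] = 1,
) -> Dict:
    """Evaluation summary: sensitivity/PFD per aspect, overlap matrices, and
    fold-change error metrics over replicate-pair comparisons."""
    out: Dict = {"identification": {}, "overlap": {}}
    for aspect in sorted(gold_sets):
        if aspect not in method_sets:
            raise ValueError(f"method reports no {aspect} terms")
        gold = TermSet(f"gold-{aspect}", frozenset(gold_sets[aspect]))
        meth = TermSet(f"method-{aspect}", frozenset(method_sets[aspect]))
        sens, pfd = sensitivity_pfd(meth, gold, rounding_digits)
        out["identification"][aspect] = {"sensitivity_pct": sens,
                                         "pfd_pct": pfd}
        mat = overlap_matrix([gold, meth])
        out["overlap"][aspect] = {"labels": [gold.label, meth.label],
                                  "matrix": mat.tolist()}
    if fold_change_pairs:
        comparisons = []
        for ta, tb in fold_change_pairs:
            fc = compute_log2fc(ta, tb, rank)
            if fc:
                vals = list(fc.values())
                comparisons.append(
                    FoldChangeComparison(vals, [true_log2fc] * len(vals))
                )
        if comparisons:
            summary = log2fc_error_metrics(comparisons, ev_bound)
            out["fold_change"] = {
                "e_error": summary.e_error,
                "e_malfce": summary.e_malfce,
                "pct_ev": summary.pct_ev,
                "n_comparisons": summary.n_comparisons,
                "rank": rank,
                "ev_bound": ev_bound,
            }
    return out
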