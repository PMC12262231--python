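"""Evidence tables: peptide observations, protein records, confidence filters.

Inputs are four plain tab-separated tables (plus a taxonomy):

* ``peptides.tsv``   — ``peptide  spectral_count  xic_area  evalue``
* ``proteins.tsv``   — ``accession  species_tax_id  evalue  [species_evalue]``
* ``peptide_protein.tsv`` — ``peptide  accession``
* ``go.tsv``         — ``accession  go_id  aspect`` (aspects BP/MF/CC), or a
  GAF 2.2 file (columns 2, 5, 9) detected by the ``!gaf-version`` header.

Duplicate peptide rows (e.g. charge states) are merged per sequence: spectral
counts and XIC areas sum, the E-value is the best (minimum).  Confidence
filtering follows the standard metaproteomic workflow: peptides at E-value <=
1, species at E-value <= 0.01.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Mapping, Optional, Tuple

import pandas as pd

from .taxonomy import Taxonomy

__all__ = [
    "ASPECTS",
    "PeptideObservation",
    "ProteinRecord",
    "EvidenceBundle",
    "EvidenceError",
    "load_evidence",
    "filter_confident_peptides",
    "filter_confident_species",
]

ASPECTS = ("BP", "MF", "CC")
_GO_RE = re.compile(r"^GO:\d{7}$")
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


class EvidenceError(ValueError):
    """Raised for malformed or inconsistent evidence tables."""


@dataclass(frozen=True)
class PeptideObservation:
    """One confidently identified peptide sequence with its summed evidence."""

    peptide: str
    spectral_count: int
    xic_area: float
    evalue: float

    def __post_init__(self) -> None:
        if not self.peptide:
            raise EvidenceError("empty peptide sequence")
        if self.spectral_count < 1:
            raise EvidenceError(f"spectral_count < 1 for {self.peptide}")
        if self.xic_area < 0:
            raise EvidenceError(f"negative xic_area for {self.peptide}")
        if self.evalue <= 0:
            raise EvidenceError(f"non-positive evalue for {self.peptide}")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    species_tax_id: int
    evalue: float
    peptides: FrozenSet[str] = frozenset()
    go_terms: FrozenSet[Tuple[str, str]] = frozenset()  # (go_id, aspect)

    def go_of_aspect(self, aspect: str) -> FrozenSet[str]:
        return frozenset(g for g, a in self.go_terms if a == aspect)


@dataclass
class EvidenceBundle:
    """Peptide observations + protein records + the taxonomy they live in."""

    peptides: Dict[str, PeptideObservation]
    proteins: Dict[str, ProteinRecord]
    taxonomy: Taxonomy
    species_evalues: Dict[int, float] = field(default_factory=dict)

    def species(self) -> set[int]:
        return {p.species_tax_id for p in self.proteins.values()}

    def validate(self) -> "EvidenceBundle":
        """Check cross-table invariants; prune protein->peptide links that
        reference observations absent from the peptide table (warned)."""
        for acc, prot in self.proteins.items():
            node = self.taxonomy.node(prot.species_tax_id)
            if node.rank != "species":
                raise EvidenceError(
                    f"protein {acc}: tax_id {prot.species_tax_id} has rank "
                    f"{node.rank!r}, expected species"
                )
        dropped = 0
        pruned: Dict[str, ProteinRecord] = {}
        for acc, prot in self.proteins.items():
            keep = frozenset(p for p in prot.peptides if p in self.peptides)
            dropped += len(prot.peptides) - len(keep)
            pruned[acc] = replace(prot, peptides=keep)
        if dropped:
            warnings.warn(
                f"dropped {dropped} protein->peptide links with no matching "
                "peptide observation",
                stacklevel=2,
            )
        self.proteins = pruned
        return self


def _read_tsv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=columns, dtype=str
    )
    if df.isna().any().any():
        raise EvidenceError(f"{path}: missing fields")
    return df


def _read_go_table(path) -> pd.DataFrame:
    """Read accession/go_id/aspect rows from a 3-column TSV or a GAF 2.x file."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("!gaf-version"):
        df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        if df.shape[1] < 9:
            raise EvidenceError(f"{path}: GAF file with fewer than 9 columns")
        out = df.iloc[:, [1, 4, 8]].copy()
        out.columns = ["accession", "go_id", "aspect"]
        out["aspect"] = out["aspect"].map(_GAF_ASPECT)
        if out["aspect"].isna().any():
            raise EvidenceError(f"{path}: unknown GAF aspect code")
        return out
    return _read_tsv(path, ["accession", "go_id", "aspect"])


def load_evidence(
    peptides_path,
    proteins_path,
    peptide_map_path,
    go_path,
    taxonomy: Taxonomy,
) -> EvidenceBundle:
    """Load and validate the four evidence tables into an :class:`EvidenceBundle`.

    Duplicate peptide rows merge by summing spectral_count and xic_area and
    taking the minimum evalue.  The optional 4th column of ``proteins.tsv``
    carries the species-level identification E-value; the per-species map is
    the minimum over a species' proteins.
    """
    pep_df = _read_tsv(
        peptides_path, ["peptide", "spectral_count", "xic_area", "evalue"]
    )
    pep_df["spectral_count"] = pep_df["spectral_count"].astype(int)
    pep_df["xic_area"] = pep_df["xic_area"].astype(float)
    pep_df["evalue"] = pep_df["evalue"].astype(float)
    merged = pep_df.groupby("peptide", sort=True).agg(
        spectral_count=("spectral_count", "sum"),
        xic_area=("xic_area", "sum"),
        evalue=("evalue", "min"),
    )
    peptides = {
        pep: PeptideObservation(pep, int(r.spectral_count), float(r.xic_area),
                                float(r.evalue))
        for pep, r in merged.iterrows()
    }

    prot_raw = pd.read_csv(proteins_path, sep="\t", comment="#", header=None,
                           dtype=str)
    if prot_raw.shape[1] not in (3, 4):
        raise EvidenceError(f"{proteins_path}: expected 3 or 4 columns")
    prot_raw.columns = ["accession", "species_tax_id", "evalue",
                        "species_evalue"][: prot_raw.shape[1]]

    map_df = _read_tsv(peptide_map_path, ["peptide", "accession"])
    pep_by_acc: Dict[str, set] = {}
    for row in map_df.itertuples(index=False):
        pep_by_acc.setdefault(row.accession, set()).add(row.peptide)

    go_df = _read_go_table(go_path)
    go_by_acc: Dict[str, set] = {}
    for row in go_df.itertuples(index=False):
        if row.aspect not in ASPECTS:
            raise EvidenceError(f"unknown GO aspect code {row.aspect!r}")
        if not _GO_RE.match(row.go_id):
            raise EvidenceError(f"malformed GO id {row.go_id!r}")
        go_by_acc.setdefault(row.accession, set()).add((row.go_id, row.aspect))

    proteins: Dict[str, ProteinRecord] = {}
    species_evalues: Dict[int, float] = {}
    for row in prot_raw.itertuples(index=False):
        acc = row.accession
        if acc in proteins:
            raise EvidenceError(f"duplicate protein accession {acc!r}")
        tid = int(row.species_tax_id)
        if tid not in taxonomy:
            raise EvidenceError(
                f"protein {acc!r} references unknown species tax_id {tid}"
            )
        proteins[acc] = ProteinRecord(
            accession=acc,
            species_tax_id=tid,
            evalue=float(row.evalue),
            peptides=frozenset(pep_by_acc.get(acc, ())),
            go_terms=frozenset(go_by_acc.get(acc, ())),
        )
        if prot_raw.shape[1] == 4:
            sev = float(row.species_evalue)
            species_evalues[tid] = min(species_evalues.get(tid, sev), sev)

    return EvidenceBundle(peptides, proteins, taxonomy, species_evalues).validate()


def filter_confident_peptides(
    bundle: EvidenceBundle, evalue_cutoff: float = 1.0
) -> EvidenceBundle:
    """Keep peptide observations with E-value <= cutoff; prune protein links;
    drop proteins left with no peptides."""
    if evalue_cutoff <= 0:
        raise EvidenceError("evalue_cutoff must be positive")
    kept = {p: o for p, o in bundle.peptides.items() if o.evalue <= evalue_cutoff}
    if not kept:
        warnings.warn("no peptides survive the E-value filter", stacklevel=2)
    proteins = {}
    for acc, prot in bundle.proteins.items():
        peps = frozenset(p for p in prot.peptides if p in kept)
        if peps:
            proteins[acc] = replace(prot, peptides=peps)
    return EvidenceBundle(kept, proteins, bundle.taxonomy,
                          dict(bundle.species_evalues))


def filter_confident_species(
    bundle: EvidenceBundle,
    species_evalues: Optional[Mapping[int, float]] = None,
    cutoff: float = 0.01,
) -> EvidenceBundle:
    """Remove proteins of species whose identification E-value exceeds cutoff.

    ``species_evalues`` defaults to the map carried by the bundle.  Peptide
    observations are retained (they may still support surviving species).
    """
    scores = dict(species_evalues) if species_evalues is not None \
        else dict(bundle.species_evalues)
    for tid in bundle.species():
        if tid not in scores:
            raise EvidenceError(f"missing species E-value for tax_id {tid}")
    surviving = {t for t, e in scores.items() if e <= cutoff}
    proteins = {
        acc: prot
        for acc, prot in bundle.proteins.items()
        if prot.species_tax_id in surviving
    }
    if not proteins:
        warnings.warn("no species survive the E-value filter", stacklevel=2)
    return EvidenceBundle(dict(bundle.peptides), proteins, bundle.taxonomy,
                          {t: scores[t] for t in surviving if t in scores})


def peptide_weight(obs: PeptideObservation, mode: str = "area") -> float:
    """Quantitative weight of a peptide: its XIC area, falling back to the
    spectral count when the area is missing/zero; or the count directly."""
    if mode == "count":
        return float(obs.spectral_count)
    if mode == "area":
        return obs.xic_area if obs.xic_area > 0 else float(obs.spectral_count)
    raise EvidenceError(f"unknown weight mode {mode!r}")
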