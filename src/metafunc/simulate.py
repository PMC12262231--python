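"""Synthetic metaproteomic communities with known ground truth.

Emulates evidence-level data for benchmark-style mixtures — four species at
ratios 1:1:1:1, 4:2:2:1 or 1:2:2:4, and a 24-species equimolar community —
with cross-taxon peptide sharing, lognormal XIC intensity noise, and decoy
(absent-species) identifications, so every pipeline stage can be exercised
against a known answer without any external download.

Generative model, per true species t with biomass fraction b_t:

* a proteome of ``proteins_per_species`` proteins, each carrying
  ``1 + Poisson(peptides_per_protein - 1)`` tryptic-like peptides and
  ``Poisson(go_terms_per_protein)`` GO terms per aspect drawn from a
  species-preferred vocabulary (zero terms leaves the protein unannotated in
  that aspect);
* peptide XIC areas ``(b_t / n_t) * exp(sigma * Z - sigma^2 / 2)`` with n_t
  the species' peptide count, so the expected total area of species t equals
  b_t exactly and the sigma = 0, no-sharing community reproduces the biomass
  ratios in closed form;
* spectral counts ``1 + Poisson(spectral_rate * n_species * b_t)`` — counts
  grow with biomass but saturate at 1, the usual spectral-counting bias;
* sharing: each peptide is copied into a sibling species' proteome (same
  genus) with probability ``share_within_genus`` and into a random
  other-genus species with probability ``share_cross_genus``;
* decoys: ``round(decoy_rate * n_species)`` absent species attached to random
  genera, with species- and peptide-level E-values drawn uniform(0.1, 10) so
  the confidence filters have real work to do.

Function ground truth attributes each peptide's expected area equally among
its origin protein's GO terms of an aspect (UNANNOTATED when it has none),
normalized per species — the allocation a perfectly informed equal-split
would produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .em import UNANNOTATED
from .evidence import (ASPECTS, EvidenceBundle, PeptideObservation,
                       ProteinRecord)
from .taxonomy import Taxonomy, TaxonomyNode, write_taxonomy

__all__ = ["SimConfig", "SyntheticTruth", "simulate", "simulate_missingness",
           "simulate_replicate", "write_bundle"]

PRESET_RATIOS = {
    "equimolar": None,  # uniform over n_species
    "4:2:2:1": (4, 2, 2, 1),
    "1:2:2:4": (1, 2, 2, 4),
    "1:1:1:1": (1, 1, 1, 1),
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimConfig:
    n_species: int = 24
    biomass_truth: str | Sequence[float] = "equimolar"
    #: children per internal node, root-down: (classes/phylum, orders/class,
    #: families/order, genera/family, species/genus)
    taxonomy_shape: Tuple[int, ...] = (2, 2, 2, 2, 2)
    proteins_per_species: int = 10
    peptides_per_protein: float = 8.0
    go_terms_per_protein: float = 1.5
    go_pool_size: int = 40
    share_within_genus: float = 0.05
    share_cross_genus: float = 0.02
    area_lognormal_sigma: float = 0.5
    spectral_rate: float = 2.0
    decoy_rate: float = 0.0
    seed: int = 0

    def biomass_vector(self) -> np.ndarray:
        if isinstance(self.biomass_truth, str):
            ratios = PRESET_RATIOS.get(self.biomass_truth)
            if self.biomass_truth not in PRESET_RATIOS:
                raise ValueError(f"unknown preset {self.biomass_truth!r}")
            if ratios is None:
                vec = np.full(self.n_species, 1.0 / self.n_species)
            else:
                if len(ratios) != self.n_species:
                    raise ValueError(
                        f"preset {self.biomass_truth!r} needs n_species="
                        f"{len(ratios)}"
                    )
                vec = np.array(ratios, float)
        else:
            vec = np.array(list(self.biomass_truth), float)
            if len(vec) != self.n_species:
                raise ValueError("biomass_truth length != n_species")
        if (vec <= 0).any():
            raise ValueError("biomass fractions must be positive")
        return vec / vec.sum()

    def validate(self) -> "SimConfig":
        if self.n_species < 1 or self.proteins_per_species < 1:
            raise ValueError("need at least one species and one protein")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        for p in (self.share_within_genus, self.share_cross_genus):
            if not 0 <= p <= 1:
                raise ValueError("sharing probabilities must be in [0, 1]")
        if self.area_lognormal_sigma < 0 or self.decoy_rate < 0:
            raise ValueError("sigma and decoy_rate must be >= 0")
        self.biomass_vector()
        return self


@dataclass
class SyntheticTruth:
    config: SimConfig
    biomass_truth: Dict[int, float]
    #: (species_tax_id, aspect) -> {go_id or UNANNOTATED: p(k|t)}
    function_truth: Dict[Tuple[int, str], Dict[str, float]]
    bundle: EvidenceBundle
    species_evalues: Dict[int, float]
    decoy_manifest: Dict[str, list] = field(default_factory=dict)


def _build_taxonomy(n_species: int, shape: Tuple[int, ...]) -> tuple[Taxonomy,
                                                                     List[int]]:
    """Seven-rank tree with species distributed round-robin over genera."""
    if len(shape) != 5:
        raise ValueError("taxonomy_shape needs 5 branching factors")
    per_genus = max(1, shape[4])
    n_genus = -(-n_species // per_genus)
    n_family = -(-n_genus // max(1, shape[3]))
    n_order = -(-n_family // max(1, shape[2]))
    n_class = -(-n_order // max(1, shape[1]))
    n_phylum = -(-n_class // max(1, shape[0]))

    nodes: Dict[int, TaxonomyNode] = {1: TaxonomyNode(1, 1, "root", "root")}
    next_id = 2

    def make_level(count, rank, parents):
        nonlocal next_id
        ids = []
        for i in range(count):
            tid = next_id
            next_id += 1
            parent = parents[i % len(parents)]
            nodes[tid] = TaxonomyNode(tid, parent, rank, f"{rank}_{i}")
            ids.append(tid)
        return ids

    phyla = make_level(n_phylum, "phylum", [1])
    classes = make_level(n_class, "class", phyla)
    orders = make_level(n_order, "order", classes)
    families = make_level(n_family, "family", orders)
    genera = make_level(n_genus, "genus", families)
    species = []
    for i in range(n_species):
        tid = 10000 + i
        genus = genera[i % n_genus]
        nodes[tid] = TaxonomyNode(tid, genus, "species", f"species_{i}")
        species.append(tid)
    return Taxonomy(nodes), species


def _random_peptides(rng: np.random.Generator, n: int, taken: set,
                     length: int = 12) -> List[str]:
    out = []
    while len(out) < n:
        seq = "".join(rng.choice(_AA, size=length))
        if seq not in taken:
            taken.add(seq)
            out.append(seq)
    return out


def simulate(config: SimConfig) -> SyntheticTruth:
    """Generate a deterministic synthetic community for ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    biomass = config.biomass_vector()
    taxonomy, species_ids = _build_taxonomy(
        config.n_species, config.taxonomy_shape
    )
    biomass_truth = {t: float(b) for t, b in zip(species_ids, biomass)}

    # Decoy species are grafted onto existing genera after the true species.
    n_decoy = int(round(config.decoy_rate * config.n_species))
    decoy_ids: List[int] = []
    if n_decoy:
        genera = sorted(t for t, n in taxonomy.nodes.items()
                        if n.rank == "genus")
        nodes = dict(taxonomy.nodes)
        for j in range(n_decoy):
            tid = 20000 + j
            genus = genera[int(rng.integers(len(genera)))]
            nodes[tid] = TaxonomyNode(tid, genus, "species", f"decoy_{j}")
            decoy_ids.append(tid)
        taxonomy = Taxonomy(nodes)

    go_pool = {
        aspect: [f"GO:{7000000 + a * 100000 + i:07d}"
                 for i in range(config.go_pool_size)]
        for a, aspect in enumerate(ASPECTS)
    }
    # Species-preferred vocabularies: half the pool each, overlapping.
    vocab: Dict[Tuple[int, str], List[str]] = {}
    for tid in species_ids + decoy_ids:
        for aspect in ASPECTS:
            k = max(2, config.go_pool_size // 2)
            vocab[(tid, aspect)] = sorted(
                rng.choice(go_pool[aspect], size=k, replace=False)
            )

    taken: set[str] = set()
    proteins: Dict[str, ProteinRecord] = {}
    pep_origin: Dict[str, Tuple[int, str]] = {}  # peptide -> (species, accession)
    prot_peps: Dict[str, set] = {}
    species_evalues: Dict[int, float] = {}
    decoy_peptides: List[str] = []
    decoy_accessions: List[str] = []

    pseudo_biomass = float(biomass.min()) / 2.0
    for tid in species_ids + decoy_ids:
        is_decoy = tid in decoy_ids
        sp_idx = (species_ids + decoy_ids).index(tid)
        if is_decoy:
            species_evalues[tid] = float(rng.uniform(0.1, 10.0))
        else:
            species_evalues[tid] = float(10.0 ** rng.uniform(-8, -3))
        for j in range(config.proteins_per_species):
            acc = f"P{sp_idx:03d}_{j:03d}"
            n_pep = 1 + int(rng.poisson(max(0.0,
                                            config.peptides_per_protein - 1)))
            peps = _random_peptides(rng, n_pep, taken)
            go_terms = set()
            for aspect in ASPECTS:
                n_go = int(rng.poisson(config.go_terms_per_protein))
                n_go = min(n_go, len(vocab[(tid, aspect)]))
                if n_go:
                    for g in rng.choice(vocab[(tid, aspect)], size=n_go,
                                        replace=False):
                        go_terms.add((str(g), aspect))
            if is_decoy:
                evalue = float(rng.uniform(0.1, 10.0))
                decoy_accessions.append(acc)
                decoy_peptides.extend(peps)
            else:
                evalue = float(10.0 ** rng.uniform(-6, -2))
            proteins[acc] = ProteinRecord(acc, tid, evalue, frozenset(),
                                          frozenset(go_terms))
            prot_peps[acc] = set(peps)
            for pep in peps:
                pep_origin[pep] = (tid, acc)

    # Peptide sharing: copy sequences into other species' proteomes.
    accs_by_species: Dict[int, List[str]] = {}
    for acc, prot in proteins.items():
        accs_by_species.setdefault(prot.species_tax_id, []).append(acc)
    genus_of = {t: taxonomy.ancestor_at_rank(t, "genus")
                for t in species_ids + decoy_ids}
    all_species = species_ids + decoy_ids
    for pep in sorted(pep_origin):
        tid, _ = pep_origin[pep]
        siblings = [s for s in all_species
                    if s != tid and genus_of[s] == genus_of[tid]]
        strangers = [s for s in all_species
                     if s != tid and genus_of[s] != genus_of[tid]]
        if siblings and rng.random() < config.share_within_genus:
            target = siblings[int(rng.integers(len(siblings)))]
            acc = accs_by_species[target][
                int(rng.integers(len(accs_by_species[target])))]
            prot_peps[acc].add(pep)
        if strangers and rng.random() < config.share_cross_genus:
            target = strangers[int(rng.integers(len(strangers)))]
            acc = accs_by_species[target][
                int(rng.integers(len(accs_by_species[target])))]
            prot_peps[acc].add(pep)

    # Observations: areas normalized so E[total area of t] = biomass_t.
    n_per_species: Dict[int, int] = {}
    for pep, (tid, _) in pep_origin.items():
        n_per_species[tid] = n_per_species.get(tid, 0) + 1
    sigma = config.area_lognormal_sigma
    peptide_obs: Dict[str, PeptideObservation] = {}
    for pep in sorted(pep_origin):
        tid, _ = pep_origin[pep]
        b_t = biomass_truth.get(tid, pseudo_biomass)
        mean_area = b_t / n_per_species[tid]
        noise = float(np.exp(sigma * rng.standard_normal()
                             - 0.5 * sigma * sigma)) if sigma > 0 else 1.0
        area = mean_area * noise
        lam = config.spectral_rate * config.n_species * b_t
        count = 1 + int(rng.poisson(lam))
        if tid in decoy_ids:
            evalue = float(rng.uniform(0.1, 10.0))
        else:
            evalue = float(10.0 ** rng.uniform(-8, -2))
        peptide_obs[pep] = PeptideObservation(pep, count, area, evalue)

    proteins = {
        acc: replace(prot, peptides=frozenset(prot_peps[acc]))
        for acc, prot in proteins.items()
    }
    bundle = EvidenceBundle(peptide_obs, proteins, taxonomy,
                            dict(species_evalues)).validate()

    # Equal-split attribution of expected areas -> per-species p(k|t) truth.
    function_truth: Dict[Tuple[int, str], Dict[str, float]] = {}
    for tid in species_ids:
        for aspect in ASPECTS:
            profile: Dict[str, float] = {}
            for acc in accs_by_species[tid]:
                terms = sorted(proteins[acc].go_of_aspect(aspect)) or \
                    [UNANNOTATED]
                own = [p for p in prot_peps[acc]
                       if pep_origin.get(p, (None,))[0] == tid
                       and pep_origin[p][1] == acc]
                share = len(own) / n_per_species[tid] / len(terms)
                for g in terms:
                    profile[g] = profile.get(g, 0.0) + share
            total = sum(profile.values())
            function_truth[(tid, aspect)] = {
                g: v / total for g, v in sorted(profile.items())
            }

    manifest = {
        "decoy_species": decoy_ids,
        "decoy_accessions": sorted(decoy_accessions),
        "decoy_peptides": sorted(decoy_peptides),
    }
    return SyntheticTruth(config, biomass_truth, function_truth, bundle,
                          species_evalues, manifest)


def simulate_missingness(
    truth: SyntheticTruth, dropout_rate: float, seed: int | None = None
) -> SyntheticTruth:
    """Remove each peptide observation independently with ``dropout_rate``.

    The ground truth is untouched; only the observed bundle thins.  Seeded
    from the config seed unless overridden.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(
        truth.config.seed + 1 if seed is None else seed
    )
    kept = {
        pep: obs
        for pep, obs in sorted(truth.bundle.peptides.items())
        if rng.random() >= dropout_rate
    }
    bundle = EvidenceBundle(
        kept, dict(truth.bundle.proteins), truth.bundle.taxonomy,
        dict(truth.bundle.species_evalues)
    ).validate()
    return SyntheticTruth(truth.config, dict(truth.biomass_truth),
                          dict(truth.function_truth), bundle,
                          dict(truth.species_evalues),
                          dict(truth.decoy_manifest))


def simulate_replicate(truth: SyntheticTruth, seed: int) -> SyntheticTruth:
    """A technical replicate: identical community (taxonomy, proteomes,
    peptide sharing, ground truth), fresh intensity and spectral-count noise.

    Each peptide keeps its expected area (biomass_t / n_t) but redraws the
    lognormal factor and the spectral count, mimicking re-injection of the
    same sample.
    """
    rng = np.random.default_rng(seed)
    cfg = truth.config
    sigma = cfg.area_lognormal_sigma
    # Recover per-species origin peptide counts from the expected areas.
    origin: Dict[str, int] = {}
    for acc in sorted(truth.bundle.proteins):
        prot = truth.bundle.proteins[acc]
        for pep in prot.peptides:
            origin.setdefault(pep, prot.species_tax_id)
    # A shared peptide's origin is ambiguous here; use the species whose
    # protein listed it first in sorted-accession order — the noise model is
    # identical either way for equimolar designs and near-identical otherwise.
    n_per_species: Dict[int, int] = {}
    for pep in truth.bundle.peptides:
        tid = origin[pep]
        n_per_species[tid] = n_per_species.get(tid, 0) + 1
    pseudo = min(truth.biomass_truth.values()) / 2.0
    peptides = {}
    for pep in sorted(truth.bundle.peptides):
        obs = truth.bundle.peptides[pep]
        tid = origin[pep]
        b_t = truth.biomass_truth.get(tid, pseudo)
        mean_area = b_t / n_per_species[tid]
        noise = float(np.exp(sigma * rng.standard_normal()
                             - 0.5 * sigma * sigma)) if sigma > 0 else 1.0
        lam = cfg.spectral_rate * cfg.n_species * b_t
        peptides[pep] = PeptideObservation(
            pep, 1 + int(rng.poisson(lam)), mean_area * noise, obs.evalue
        )
    bundle = EvidenceBundle(peptides, dict(truth.bundle.proteins),
                            truth.bundle.taxonomy,
                            dict(truth.bundle.species_evalues)).validate()
    return SyntheticTruth(cfg, dict(truth.biomass_truth),
                          dict(truth.function_truth), bundle,
                          dict(truth.species_evalues),
                          dict(truth.decoy_manifest))


def write_bundle(truth: SyntheticTruth, outdir) -> Dict[str, Path]:
    """Write the five evidence TSVs plus truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv" for name in
             ("peptides", "proteins", "peptide_protein", "go", "taxonomy")}
    bundle = truth.bundle
    with open(paths["peptides"], "w") as fh:
        fh.write("#peptide\tspectral_count\txic_area\tevalue\n")
        for pep in sorted(bundle.peptides):
            o = bundle.peptides[pep]
            fh.write(f"{pep}\t{o.spectral_count}\t{o.xic_area!r}\t"
                     f"{o.evalue!r}\n")
    with open(paths["proteins"], "w") as fh:
        fh.write("#accession\tspecies_tax_id\tevalue\tspecies_evalue\n")
        for acc in sorted(bundle.proteins):
            p = bundle.proteins[acc]
            fh.write(f"{acc}\t{p.species_tax_id}\t{p.evalue!r}\t"
                     f"{truth.species_evalues[p.species_tax_id]!r}\n")
    with open(paths["peptide_protein"], "w") as fh:
        fh.write("#peptide\taccession\n")
        for acc in sorted(bundle.proteins):
            for pep in sorted(bundle.proteins[acc].peptides):
                fh.write(f"{pep}\t{acc}\n")
    with open(paths["go"], "w") as fh:
        fh.write("#accession\tgo_id\taspect\n")
        for acc in sorted(bundle.proteins):
            for go_id, aspect in sorted(bundle.proteins[acc].go_terms):
                fh.write(f"{acc}\t{go_id}\t{aspect}\n")
    write_taxonomy(bundle.taxonomy, paths["taxonomy"])

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "biomass_truth": {str(t): v
                                  for t, v in truth.biomass_truth.items()},
                "function_truth": {
                    f"{t}|{aspect}": prof
                    for (t, aspect), prof in truth.function_truth.items()
                },
                "species_evalues": {str(t): v
                                    for t, v in truth.species_evalues.items()},
                "decoy_manifest": truth.decoy_manifest,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(truth.config).items()
                           if not isinstance(v, np.ndarray)},
            },
            fh, indent=1, sort_keys=True,
        )
    paths["truth"] = truth_path
    return paths
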