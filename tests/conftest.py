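"""Shared fixtures: tiny hand-built taxonomies/bundles and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from metafunc.evidence import EvidenceBundle, PeptideObservation, ProteinRecord
from metafunc.taxonomy import RANK_ORDER, Taxonomy, TaxonomyNode


def make_taxonomy(edges):
    """Build a Taxonomy from (tax_id, parent_id, rank, name) tuples."""
    return Taxonomy({e[0]: TaxonomyNode(*e) for e in edges})


@pytest.fixture
def chain_taxonomy():
    """Minimal root -> genus -> species chain."""
    return make_taxonomy([
        (1, 1, "root", "root"),
        (10, 1, "genus", "G"),
        (100, 10, "species", "S"),
    ])


@pytest.fixture
def two_genus_taxonomy():
    """Root with two genera, three species (two sharing a genus)."""
    return make_taxonomy([
        (1, 1, "root", "root"),
        (2, 1, "phylum", "P"),
        (3, 2, "class", "C"),
        (4, 3, "order", "O"),
        (5, 4, "family", "F"),
        (10, 5, "genus", "G1"),
        (11, 5, "genus", "G2"),
        (100, 10, "species", "S1"),
        (101, 10, "species", "S2"),
        (102, 11, "species", "S3"),
    ])


def random_taxonomy(rng: np.random.Generator, n_species: int = 10):
    """Random 7-rank tree: each named level partitions the one below."""
    edges = [(1, 1, "root", "root")]
    parents = [1]
    next_id = 2
    for rank in RANK_ORDER[1:-1]:
        count = max(1, int(rng.integers(1, max(2, n_species // 2))))
        level = []
        for i in range(count):
            edges.append((next_id, parents[i % len(parents)], rank,
                          f"{rank}{i}"))
            level.append(next_id)
            next_id += 1
        parents = level
    species = []
    for i in range(n_species):
        tid = 1000 + i
        edges.append((tid, parents[int(rng.integers(len(parents)))],
                      "species", f"sp{i}"))
        species.append(tid)
    return make_taxonomy(edges), species


def make_bundle(taxonomy, proteins_spec, peptides_spec):
    """Bundle from  {acc: (species, evalue, [peptides], {(go, aspect)})}
    and {peptide: (count, area, evalue)}."""
    peptides = {
        pep: PeptideObservation(pep, c, a, e)
        for pep, (c, a, e) in peptides_spec.items()
    }
    proteins = {
        acc: ProteinRecord(acc, tid, ev, frozenset(peps), frozenset(gos))
        for acc, (tid, ev, peps, gos) in proteins_spec.items()
    }
    return EvidenceBundle(peptides, proteins, taxonomy).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
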