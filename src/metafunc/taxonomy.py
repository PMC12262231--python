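"""Rank-annotated taxonomy: lineages, lowest common ancestors, rank projection.

The taxonomy is a rooted tree over integer NCBI-style tax_ids with a fixed
seven-level rank ladder (root > phylum > class > order > family > genus >
species).  Intermediate ranks that real taxonomies carry (suborder, species
group, ...) are accepted as ``no_rank`` pass-throughs: they sit on the path to
root but never appear as keys of a lineage.  Names are display-only; every
operation keys on tax_id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

__all__ = [
    "RANK_ORDER",
    "TaxonomyNode",
    "Taxonomy",
    "TaxonomyError",
    "load_taxonomy",
]

#: Most-general to most-specific named ranks.
RANK_ORDER = ("root", "phylum", "class", "order", "family", "genus", "species")

_VALID_RANKS = frozenset(RANK_ORDER) | {"no_rank"}


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomies or unknown tax_ids."""


@dataclass(frozen=True)
class TaxonomyNode:
    tax_id: int
    parent_id: int
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.tax_id <= 0 or self.parent_id <= 0:
            raise TaxonomyError(f"tax_id/parent_id must be positive: {self}")
        if self.rank not in _VALID_RANKS:
            raise TaxonomyError(f"unknown rank {self.rank!r} for tax_id {self.tax_id}")
        if not self.name:
            raise TaxonomyError(f"empty name for tax_id {self.tax_id}")


@dataclass
class Taxonomy:
    """Validated rooted tree of :class:`TaxonomyNode` keyed by tax_id."""

    nodes: Dict[int, TaxonomyNode]
    root_id: int = field(init=False)
    _lineage_cache: Dict[int, Dict[str, int]] = field(
        init=False, default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        roots = [n.tax_id for n in self.nodes.values() if n.parent_id == n.tax_id]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0]
        if self.nodes[self.root_id].rank != "root":
            raise TaxonomyError("root node must carry rank 'root'")
        for node in self.nodes.values():
            if node.tax_id != self.root_id and node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"dangling parent: tax_id {node.tax_id} points to "
                    f"missing parent {node.parent_id}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Walk every node to root; any revisit inside one walk is a cycle.
        resolved: set[int] = {self.root_id}
        for start in self.nodes:
            path: list[int] = []
            seen: set[int] = set()
            tid = start
            while tid not in resolved:
                if tid in seen:
                    cycle = path[path.index(tid):]
                    raise TaxonomyError(f"taxonomy cycle: {cycle}")
                seen.add(tid)
                path.append(tid)
                tid = self.nodes[tid].parent_id
            resolved.update(path)

    # -- queries ------------------------------------------------------------

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def node(self, tax_id: int) -> TaxonomyNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise TaxonomyError(f"unknown tax_id {tax_id}") from None

    def ancestors(self, tax_id: int) -> list[int]:
        """Path from ``tax_id`` (inclusive) to the root (inclusive)."""
        node = self.node(tax_id)
        path = [node.tax_id]
        while node.tax_id != self.root_id:
            node = self.nodes[node.parent_id]
            path.append(node.tax_id)
        return path

    def lineage(self, tax_id: int) -> Dict[str, int]:
        """Map each named rank on the path to root to its ancestor tax_id."""
        cached = self._lineage_cache.get(tax_id)
        if cached is not None:
            return dict(cached)
        out: Dict[str, int] = {}
        for tid in self.ancestors(tax_id):
            rank = self.nodes[tid].rank
            if rank != "no_rank" and rank not in out:
                out[rank] = tid
        self._lineage_cache[tax_id] = out
        return dict(out)

    def lca(self, ids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of tax_ids."""
        ids = list(ids)
        if not ids:
            raise TaxonomyError("lca of an empty set is undefined")
        common = None
        for tid in ids:
            anc = set(self.ancestors(tid))
            common = anc if common is None else common & anc
        assert common  # root is always shared
        # Deepest member of the shared ancestor set: the one whose own
        # ancestor path contains every other member.
        return max(common, key=lambda t: len(self.ancestors(t)))

    def ancestor_at_rank(self, tax_id: int, rank: str) -> int | None:
        return self.lineage(tax_id).get(rank)

    def species_ids(self) -> list[int]:
        return sorted(t for t, n in self.nodes.items() if n.rank == "species")

    def project_to_rank(
        self, values: Mapping[int, float], rank: str
    ) -> Dict[int | str, float]:
        """Aggregate species-keyed values up to ``rank``; totals are conserved.

        A species lacking a named ancestor at ``rank`` lands in a synthetic
        ``"unranked@<rank>"`` bucket (with a warning) rather than being
        dropped.
        """
        if rank not in RANK_ORDER:
            raise TaxonomyError(f"unknown rank {rank!r}")
        out: Dict[int | str, float] = {}
        bucket = f"unranked@{rank}"
        missing = []
        for tid, val in values.items():
            node = self.node(tid)
            if node.rank != "species":
                raise TaxonomyError(f"tax_id {tid} is {node.rank}, not species")
            anc = self.ancestor_at_rank(tid, rank)
            if anc is None:
                missing.append(tid)
                out[bucket] = out.get(bucket, 0.0) + val
            else:
                out[anc] = out.get(anc, 0.0) + val
        if missing:
            warnings.warn(
                f"{len(missing)} species lack an ancestor at rank {rank!r}; "
                f"assigned to {bucket!r}",
                stacklevel=2,
            )
        return out


def load_taxonomy(path) -> Taxonomy:
    """Load a 4-column tab-separated nodes table: tax_id, parent_id, rank, name.

    Lines starting with ``#`` are treated as comments/headers.
    """
    nodes: Dict[int, TaxonomyNode] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise TaxonomyError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            tax_id, parent_id = int(parts[0]), int(parts[1])
            if tax_id in nodes:
                raise TaxonomyError(f"{path}:{lineno}: duplicate tax_id {tax_id}")
            nodes[tax_id] = TaxonomyNode(tax_id, parent_id, parts[2], parts[3])
    if not nodes:
        raise TaxonomyError(f"{path}: no taxonomy nodes")
    return Taxonomy(nodes)


def write_taxonomy(tax: Taxonomy, path) -> None:
    """Serialize back to the 4-column nodes format (round-trips with load)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#tax_id\tparent_id\trank\tname\n")
        for tid in sorted(tax.nodes):
            n = tax.nodes[tid]
            fh.write(f"{n.tax_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")
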