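"""Rooted, rank-labelled taxonomy with lineage and LCA queries.

The taxonomy is the backbone of every classifier and evaluator in the
package. It uses a fixed seven-rank ladder — root, phylum, class, order,
family, genus, species — and requires every species to carry a complete
lineage through all six sub-root ranks. Taxids are opaque positive
integers; names are display-only and never used for identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import (
    CycleError,
    EmptyInputError,
    IncompleteLineageError,
    OrphanParentError,
    RankOrderError,
    UnknownTaxonError,
)

#: Canonical ranks, shallowest first. Index in this tuple is the rank depth.
RANKS: tuple[str, ...] = (
    "root",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_DEPTH: Mapping[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Ranks a classifier can emit, deepest last (no root).
SUB_ROOT_RANKS: tuple[str, ...] = RANKS[1:]


@dataclass(frozen=True)
class Node:
    name: str
    rank: str
    parent: int


NodeRecord = tuple[int, int, str, str]  # (taxid, parent, rank, name)


class Taxonomy:
    """Validated rooted taxonomy over the canonical rank ladder.

    Construct with :meth:`from_records` (or the module-level
    :func:`build_taxonomy`); the constructor itself assumes pre-validated
    input and is not part of the public surface.
    """

    def __init__(self, nodes: dict[int, Node], root: int):
        self.nodes = nodes
        self.root = root
        self._children: dict[int, list[int]] = {t: [] for t in nodes}
        for taxid, node in nodes.items():
            if taxid != root:
                self._children[node.parent].append(taxid)
        for kids in self._children.values():
            kids.sort()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(cls, node_records: Iterable[NodeRecord]) -> "Taxonomy":
        records = sorted(node_records)
        if not records:
            raise EmptyInputError("no taxonomy records")
        nodes: dict[int, Node] = {}
        root = None
        for taxid, parent, rank, name in records:
            if rank not in RANK_DEPTH:
                raise RankOrderError(f"taxid {taxid}: unknown rank {rank!r}")
            if taxid in nodes:
                raise CycleError(f"taxid {taxid} defined twice")
            if taxid <= 0:
                raise RankOrderError(f"taxid {taxid}: taxids must be positive")
            nodes[taxid] = Node(name=name, rank=rank, parent=parent)
            if rank == "root":
                if root is not None:
                    raise RankOrderError(
                        f"taxid {taxid}: second root (root already {root})"
                    )
                if parent != taxid:
                    raise RankOrderError(f"root {taxid} must be its own parent")
                root = taxid
        if root is None:
            raise OrphanParentError("no root node in record set")
        for taxid, node in nodes.items():
            if taxid == root:
                continue
            if node.parent == taxid:
                raise CycleError(f"taxid {taxid} is its own parent")
            if node.parent not in nodes:
                raise OrphanParentError(
                    f"taxid {taxid}: parent {node.parent} not in record set"
                )
            parent = nodes[node.parent]
            if RANK_DEPTH[parent.rank] >= RANK_DEPTH[node.rank]:
                raise RankOrderError(
                    f"taxid {taxid} ({node.rank}) under parent "
                    f"{node.parent} ({parent.rank})"
                )
        t = cls(nodes, root)
        # Strict rank ordering plus parent existence already rules out
        # cycles; what remains to enforce is lineage completeness.
        for taxid, node in nodes.items():
            if node.rank == "species" and len(t.lineage(taxid)) != 6:
                raise IncompleteLineageError(
                    f"species {taxid}: lineage skips a canonical rank"
                )
        return t

    # -- basic queries ---------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Taxonomy)
            and self.root == other.root
            and self.nodes == other.nodes
        )

    def rank_of(self, taxid: int) -> str:
        self._check(taxid)
        return self.nodes[taxid].rank

    def name_of(self, taxid: int) -> str:
        self._check(taxid)
        return self.nodes[taxid].name

    def parent_of(self, taxid: int) -> int:
        self._check(taxid)
        return self.nodes[taxid].parent

    def taxa_at_rank(self, rank: str) -> list[int]:
        _check_rank(rank)
        return sorted(t for t, n in self.nodes.items() if n.rank == rank)

    def _check(self, taxid: int) -> None:
        if taxid not in self.nodes:
            raise UnknownTaxonError(f"taxid {taxid} not in taxonomy")

    # -- lineage / projection -------------------------------------------

    def root_path(self, taxid: int) -> list[int]:
        """Path from the root down to ``taxid``, inclusive."""
        self._check(taxid)
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent)
        path.reverse()
        return path

    def lineage(self, taxid: int) -> dict[str, int]:
        """Per-rank ancestors of ``taxid`` (strictly above its own rank,
        root included); a species therefore has 6 entries."""
        self._check(taxid)
        out: dict[str, int] = {}
        cur = taxid
        while cur != self.root:
            cur = self.nodes[cur].parent
            out[self.nodes[cur].rank] = cur
        return out

    def project(self, taxid: int, rank: str) -> int | None:
        """Ancestor-or-self of ``taxid`` at ``rank``; None when ``rank`` is
        deeper than the taxon's own rank (no downward projection)."""
        self._check(taxid)
        _check_rank(rank)
        cur = taxid
        target = RANK_DEPTH[rank]
        while True:
            depth = RANK_DEPTH[self.nodes[cur].rank]
            if depth == target:
                return cur
            if depth < target:
                return None
            cur = self.nodes[cur].parent

    def lca(self, taxa: Iterable[int]) -> int:
        taxa = list(taxa)
        if not taxa:
            raise EmptyInputError("lca of an empty taxon set")
        paths = [self.root_path(t) for t in taxa]
        shortest = min(len(p) for p in paths)
        anc = self.root
        for i in range(shortest):
            level = {p[i] for p in paths}
            if len(level) != 1:
                break
            anc = level.pop()
        return anc

    def children_at(self, taxid: int, rank: str) -> set[int]:
        """All descendants of ``taxid`` whose rank equals ``rank``."""
        self._check(taxid)
        _check_rank(rank)
        own = RANK_DEPTH[self.nodes[taxid].rank]
        if RANK_DEPTH[rank] <= own:
            raise RankOrderError(
                f"rank {rank} is not strictly below {self.nodes[taxid].rank}"
            )
        out: set[int] = set()
        stack = [taxid]
        while stack:
            cur = stack.pop()
            for child in self._children[cur]:
                if self.nodes[child].rank == rank:
                    out.add(child)
                elif RANK_DEPTH[self.nodes[child].rank] < RANK_DEPTH[rank]:
                    stack.append(child)
        return out

    def children_of(self, taxid: int) -> list[int]:
        """Immediate children, sorted by taxid."""
        self._check(taxid)
        return list(self._children[taxid])

    def to_records(self) -> list[NodeRecord]:
        return sorted(
            (t, n.parent, n.rank, n.name) for t, n in self.nodes.items()
        )


def _check_rank(rank: str) -> None:
    if rank not in RANK_DEPTH:
        raise RankOrderError(f"unknown rank {rank!r}")


# -- spec-surface module functions -------------------------------------------

def build_taxonomy(node_records: Iterable[NodeRecord]) -> Taxonomy:
    """Build and validate a :class:`Taxonomy` from (taxid, parent, rank, name)
    records. Record order is irrelevant; cycles, orphan parents, rank
    inversions and incomplete species lineages are rejected."""
    return Taxonomy.from_records(node_records)


def project_to_rank(t: Taxonomy, taxon: int, rank: str) -> int | None:
    return t.project(taxon, rank)


def lca(t: Taxonomy, taxa: Iterable[int]) -> int:
    return t.lca(taxa)


def children(t: Taxonomy, taxon: int, rank: str) -> set[int]:
    return t.children_at(taxon, rank)


def fill_missing_ranks(
    node_records: Iterable[NodeRecord], start_taxid: int | None = None
) -> list[NodeRecord]:
    """Opt-in preprocessing: synthesize ``unranked-fill`` placeholder nodes so
    that every parent link steps exactly one canonical rank.

    Real taxonomy dumps frequently skip intermediate ranks; the strategies in
    this package assume a full ladder, so skipped ranks must either be
    rejected (the loader default) or padded with placeholders via this
    helper. New taxids are allocated above the current maximum (or
    ``start_taxid``) deterministically.
    """
    records = sorted(node_records)
    by_id = {r[0]: r for r in records}
    next_id = (start_taxid if start_taxid is not None
               else max(by_id) + 1 if by_id else 1)
    out: list[NodeRecord] = []
    for taxid, parent, rank, name in records:
        if rank not in RANK_DEPTH:
            raise RankOrderError(f"taxid {taxid}: unknown rank {rank!r}")
        if rank == "root" or parent not in by_id:
            out.append((taxid, parent, rank, name))
            continue
        pdepth = RANK_DEPTH[by_id[parent][2]]
        depth = RANK_DEPTH[rank]
        cur_parent = parent
        for d in range(pdepth + 1, depth):
            filler = next_id
            next_id += 1
            out.append((filler, cur_parent, RANKS[d], f"unranked-fill-{filler}"))
            cur_parent = filler
        out.append((taxid, cur_parent, rank, name))
    return sorted(out)


# -- TSV dialect --------------------------------------------------------------

def read_taxonomy_tsv(path) -> Taxonomy:
    """Read a 4-column node table: taxid, parent_taxid, rank, name.

    Tab-separated, UTF-8, ``#``-prefixed comment lines ignored.
    """
    records: list[NodeRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise RankOrderError(
                    f"{path}:{lineno}: expected 4 tab-separated columns"
                )
            records.append((int(parts[0]), int(parts[1]), parts[2], parts[3]))
    return build_taxonomy(records)


def write_taxonomy_tsv(t: Taxonomy, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# taxid\tparent_taxid\trank\tname\n")
        for taxid, parent, rank, name in t.to_records():
            fh.write(f"{taxid}\t{parent}\t{rank}\t{name}\n")
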