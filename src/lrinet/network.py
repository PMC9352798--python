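"""Gene co-expression networks.

A co-expression network (N, g^E) is an undirected simple graph on a set of
gene identifiers N with link set g^E. Genes carrying at least one link are
the *active players* N(g^E); the *star* of a gene is the set of its
incident links. These are the primitives the microarray network game is
built from, so they are kept as an explicit, validated value type rather
than a bare ``networkx`` graph (networkx is still used for component
analysis in :func:`network_summary` in :mod:`lrinet.build`).
"""

from __future__ import annotations

from typing import Iterable, Iterator

from .errors import UnknownGeneError, ValidationError

Edge = tuple[str, str]


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair (a, b) in lexicographic order."""
    if a == b:
        raise ValidationError(f"self-loop on gene {a!r} is not allowed")
    return (a, b) if a < b else (b, a)


class CoexpressionNetwork:
    """Undirected gene network (N, g^E).

    Parameters
    ----------
    nodes
        Gene identifiers, order preserved (duplicates rejected). Genes may
        be isolated: membership in ``nodes`` does not imply any link.
    edges
        Unordered pairs of distinct known genes; duplicates (in either
        orientation) are rejected.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        self._nodes: list[str] = []
        seen: set[str] = set()
        for n in nodes:
            if n in seen:
                raise ValidationError(f"duplicate gene id {n!r}")
            seen.add(n)
            self._nodes.append(n)

        self._edges: list[Edge] = []
        self._adj: dict[str, set[str]] = {n: set() for n in self._nodes}
        eseen: set[Edge] = set()
        for a, b in edges:
            for g in (a, b):
                if g not in seen:
                    raise UnknownGeneError(f"edge endpoint {g!r} is not a known gene")
            e = canonical_edge(a, b)
            if e in eseen:
                raise ValidationError(f"duplicate edge {e[0]}-{e[1]}")
            eseen.add(e)
            self._edges.append(e)
            self._adj[e[0]].add(e[1])
            self._adj[e[1]].add(e[0])
        self._edges.sort()

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def edges(self) -> tuple[Edge, ...]:
        """All links, each a lexicographically ordered pair, sorted."""
        return tuple(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def _require(self, gene: str) -> None:
        if gene not in self._adj:
            raise UnknownGeneError(f"unknown gene id {gene!r}")

    # -- game-theoretic primitives ----------------------------------------

    def neighbors(self, gene: str) -> frozenset[str]:
        self._require(gene)
        return frozenset(self._adj[gene])

    def star(self, gene: str) -> frozenset[Edge]:
        """Links incident to *gene* (g_i^E); empty for isolated genes."""
        self._require(gene)
        return frozenset(canonical_edge(gene, j) for j in self._adj[gene])

    def degree(self, gene: str) -> int:
        self._require(gene)
        return len(self._adj[gene])

    @property
    def active_players(self) -> tuple[str, ...]:
        """Genes with at least one link, N(g^E), in node order."""
        return tuple(n for n in self._nodes if self._adj[n])

    @property
    def n_active(self) -> int:
        """n(g^E), the number of genes involved in at least one link."""
        return sum(1 for n in self._nodes if self._adj[n])

    def relabel(self, mapping: dict[str, str]) -> "CoexpressionNetwork":
        """Apply a gene relabeling (must be injective on the node set)."""
        new_nodes = [mapping.get(n, n) for n in self._nodes]
        new_edges = [(mapping.get(a, a), mapping.get(b, b)) for a, b in self._edges]
        return CoexpressionNetwork(new_nodes, new_edges)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"CoexpressionNetwork(n_nodes={len(self._nodes)}, "
            f"n_edges={len(self._edges)}, n_active={self.n_active})"
        )
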