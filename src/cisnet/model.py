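"""Domain model for integration-site proximity graphs.

Viral vectors and retroviruses insert into host genomes at integration
sites (IS).  Clusters of IS closer together than expected by chance --
common integration sites (CIS) -- flag genomic regions preferentially
targeted by the vector or selected for in the host (e.g. near
proto-oncogenes in insertional-mutagenesis screens).

The model is a weighted undirected graph: one node per IS, and an edge
between two IS on the same chromosome whenever their genomic distance is
strictly below a threshold ``T_H`` (50 kb by default, the upper bound of
the window in which an insertion measurably perturbs gene expression).
Edge weights carry the distance in bp.  A CIS is then simply a connected
component with at least two IS nodes: its *order* is the number of IS it
contains and its *dimension* the genomic span in bp.

A second node category, transcriptional elements (TE: protein-coding
genes, miRNAs, lincRNAs, snoRNAs anchored at their TSS), can be layered
onto the graph.  Every TE within the annotation threshold of at least one
IS is linked to *all* qualifying IS, giving a many-to-many IS-gene
mapping; the TEs attached to a CIS form its *gene atmosphere* (GA).
TE-TE edges are never created, but a gene sitting between two nearby CIS
can bridge them into one component -- such components are flagged and can
be re-split on demand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx

#: Default proximity threshold T_H in bp.
DEFAULT_THRESHOLD = 50_000

#: Source label used in compositions for IS without a source annotation.
UNLABELLED = "NA"

NodeCategory = Literal["IS", "TE"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class IntegrationSite:
    """One genomic integration event.

    Parameters
    ----------
    id:
        Opaque token, unique within a dataset.
    chrom:
        Chromosome name, kept verbatim ("chr1" and "1" are distinct).
    position:
        1-based position in bp.
    source:
        Optional categorical label (tumour type, dataset of origin, ...).
    """

    id: str
    chrom: str
    position: int
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("IntegrationSite.chrom must be non-empty")
        if self.position < 1:
            raise ValueError(
                f"IntegrationSite position must be >= 1 (1-based), got "
                f"{self.position!r} for id {self.id!r}"
            )


@dataclass(frozen=True, slots=True)
class TranscriptionalElement:
    """A gene-like feature anchored at its transcription start site."""

    id: str
    chrom: str
    tss: int
    name: str
    element_type: str = "other"
    strand: str | None = None  # read from inputs but never used downstream

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("TranscriptionalElement.chrom must be non-empty")
        if self.tss < 1:
            raise ValueError(
                f"TranscriptionalElement tss must be >= 1, got {self.tss!r}"
            )


@dataclass
class CISGraph:
    """Weighted proximity graph over IS (and optionally TE) nodes.

    Wraps a :class:`networkx.Graph` whose node keys are the IS/TE ids.
    Node attributes: ``category`` ("IS"|"TE"), ``chrom``, ``position``,
    ``label``, ``source`` and ``obj`` (the domain object).  Edge
    attribute: ``weight`` = genomic distance in bp, always strictly
    smaller than :attr:`threshold`.
    """

    graph: nx.Graph
    threshold: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of(self, category: NodeCategory) -> list[str]:
        return [
            n for n, c in self.graph.nodes(data="category") if c == category
        ]

    def site(self, node_id: str):
        return self.graph.nodes[node_id]["obj"]


@dataclass(frozen=True)
class CIS:
    """One common integration site: a connected component with >= 2 IS.

    ``order`` counts IS members only; TE nodes belong to the gene
    atmosphere and never contribute to order or dimension.  ``bridged``
    marks components whose IS fall apart into several clusters once TE
    nodes are removed (two CIS joined through a shared nearby gene).
    """

    members: tuple[IntegrationSite, ...]
    atmosphere: tuple[TranscriptionalElement, ...] = ()
    bridged: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a CIS requires at least 2 integration sites")
        if len({m.chrom for m in self.members}) != 1:
            raise ValueError("CIS members must share one chromosome")

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def order(self) -> int:
        return len(self.members)

    @property
    def start(self) -> int:
        return min(m.position for m in self.members)

    @property
    def end(self) -> int:
        return max(m.position for m in self.members)

    @property
    def dimension(self) -> int:
        return self.end - self.start

    @property
    def composition(self) -> Counter:
        """Counts of members per source label (``NA`` when unlabelled)."""
        return Counter(
            m.source if m.source is not None else UNLABELLED
            for m in self.members
        )


# ---------------------------------------------------------------------------
# Graph construction (CIS layer)
# ---------------------------------------------------------------------------

def _add_is_node(g: nx.Graph, site: IntegrationSite) -> None:
    g.add_node(
        site.id,
        category="IS",
        chrom=site.chrom,
        position=site.position,
        label=site.id,
        source=site.source if site.source is not None else "",
        obj=site,
    )


def build_cis_graph(
    sites: Sequence[IntegrationSite],
    threshold: int = DEFAULT_THRESHOLD,
) -> CISGraph:
    """Build the IS proximity graph at threshold ``T_H``.

    Two IS on the same chromosome are connected iff their distance is
    *strictly* smaller than ``threshold``; the edge weight is the
    distance in bp.  Cross-chromosome pairs are never connected.

    The construction sorts sites per chromosome and scans a sliding
    window, so the cost is O(n log n + E) rather than the O(n^2) of an
    all-pairs comparison; datasets of 1e5 sites are routine.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    ids = [s.id for s in sites]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate integration-site ids: {dup}")

    g = nx.Graph(threshold=threshold)
    for s in sites:
        _add_is_node(g, s)

    by_chrom: dict[str, list[IntegrationSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom_sites in by_chrom.values():
        chrom_sites.sort(key=lambda s: s.position)
        lo = 0
        for i, si in enumerate(chrom_sites):
            while si.position - chrom_sites[lo].position >= threshold:
                lo += 1
            for j in range(lo, i):
                sj = chrom_sites[j]
                g.add_edge(si.id, sj.id, weight=si.position - sj.position)
    return CISGraph(graph=g, threshold=threshold)


# ---------------------------------------------------------------------------
# Gene-atmosphere layer
# ---------------------------------------------------------------------------

def attach_gene_atmosphere(
    cis_graph: CISGraph,
    elements: Iterable[TranscriptionalElement],
    threshold: int | None = None,
) -> CISGraph:
    """Layer TE nodes onto a copy of the graph.

    A TE is added iff its TSS lies strictly within ``threshold`` bp of at
    least one IS on the same chromosome; it is then linked to *every*
    qualifying IS (many-to-many).  Elements with no qualifying IS are
    omitted.  TE-TE edges are never created.  The annotation threshold
    defaults to the graph's own ``T_H`` but may differ (sparse loci are
    typically re-annotated at 200 kb).

    Returns a new :class:`CISGraph`; the input graph is left untouched.
    """
    from bisect import bisect_left, bisect_right

    if threshold is None:
        threshold = cis_graph.threshold
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")

    g = cis_graph.graph.copy()
    # per-chromosome position-sorted IS index
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for n, data in g.nodes(data=True):
        if data["category"] == "IS":
            by_chrom.setdefault(data["chrom"], []).append(
                (data["position"], n)
            )
    for v in by_chrom.values():
        v.sort()

    for te in sorted(elements, key=lambda t: (t.chrom, t.tss, t.id)):
        index = by_chrom.get(te.chrom)
        if not index:
            continue
        positions = [p for p, _ in index]
        lo = bisect_right(positions, te.tss - threshold)
        hi = bisect_left(positions, te.tss + threshold)
        hits = [
            (p, n) for p, n in index[lo:hi] if abs(te.tss - p) < threshold
        ]
        if not hits:
            continue
        if te.id in g:
            raise ValueError(
                f"transcriptional-element id {te.id!r} collides with an "
                "existing node"
            )
        g.add_node(
            te.id,
            category="TE",
            chrom=te.chrom,
            position=te.tss,
            label=te.name,
            source=te.element_type,
            obj=te,
        )
        for p, n in hits:
            g.add_edge(te.id, n, weight=abs(te.tss - p))
    return CISGraph(graph=g, threshold=cis_graph.threshold)


# ---------------------------------------------------------------------------
# CIS extraction
# ---------------------------------------------------------------------------

def extract_cis(cis_graph: CISGraph, split_bridged: bool = False) -> list[CIS]:
    """Extract CIS as connected components with >= 2 IS nodes.

    Singleton IS are not CIS.  When TE nodes are present, components held
    together solely through a shared TE are reported as one CIS with
    ``bridged=True``; with ``split_bridged=True`` they are instead
    re-split along the IS-only subgraph (each part keeping the TEs
    adjacent to its own members).

    Results are ordered by (chrom, start) for reproducible output.
    """
    g = cis_graph.graph
    out: list[CIS] = []
    for comp in nx.connected_components(g):
        is_nodes = [n for n in comp if g.nodes[n]["category"] == "IS"]
        if len(is_nodes) < 2:
            continue
        te_nodes = [n for n in comp if g.nodes[n]["category"] == "TE"]
        is_clusters = list(
            nx.connected_components(g.subgraph(is_nodes))
        )
        if split_bridged:
            for cluster in is_clusters:
                if len(cluster) < 2:
                    continue
                atmosphere = {
                    nb
                    for n in cluster
                    for nb in g.neighbors(n)
                    if g.nodes[nb]["category"] == "TE"
                }
                out.append(_make_cis(g, cluster, atmosphere, bridged=False))
        else:
            out.append(
                _make_cis(g, is_nodes, te_nodes, bridged=len(is_clusters) > 1)
            )
    out.sort(key=lambda c: (c.chrom, c.start, c.order))
    return out


def _make_cis(
    g: nx.Graph, is_nodes: Iterable[str], te_nodes: Iterable[str], bridged: bool
) -> CIS:
    members = tuple(
        sorted(
            (g.nodes[n]["obj"] for n in is_nodes),
            key=lambda s: (s.position, s.id),
        )
    )
    atmosphere = tuple(
        sorted((g.nodes[n]["obj"] for n in te_nodes), key=lambda t: (t.tss, t.id))
    )
    return CIS(members=members, atmosphere=atmosphere, bridged=bridged)


def cis_dimension(cis: CIS) -> int:
    """Genomic span of a CIS in bp: max member position - min member position."""
    return cis.dimension
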