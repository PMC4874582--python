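"""Proximity-graph construction, CIS extraction and the gene-atmosphere layer."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisnet import (
    CIS,
    IntegrationSite,
    TranscriptionalElement,
    attach_gene_atmosphere,
    build_cis_graph,
    cis_dimension,
    extract_cis,
)
from conftest import make_sites


# ---------------------------------------------------------------------------
# build_cis_graph
# ---------------------------------------------------------------------------

class TestBuildGraph:
    def test_empty_input_gives_empty_graph(self):
        g = build_cis_graph([])
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_distance_at_or_above_threshold_gives_no_edge(self):
        g = build_cis_graph(make_sites([10_000, 70_000]), threshold=50_000)
        assert g.n_nodes == 2 and g.n_edges == 0
        # ties at exactly T_H produce no edge (strict predicate)
        g = build_cis_graph(make_sites([10_000, 60_000]), threshold=50_000)
        assert g.n_edges == 0

    def test_four_site_example(self, four_site_graph):
        g = four_site_graph
        assert g.n_nodes == 4
        edges = {
            tuple(sorted((a, b))): d["weight"]
            for a, b, d in g.graph.edges(data=True)
        }
        assert edges == {("s0", "s1"): 40_000, ("s1", "s2"): 40_000}

    def test_duplicate_ids_rejected(self):
        sites = [
            IntegrationSite("a", "chr1", 100),
            IntegrationSite("a", "chr1", 200),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_cis_graph(sites)

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            IntegrationSite("a", "chr1", 0)
        with pytest.raises(ValueError, match="positive"):
            build_cis_graph(make_sites([100]), threshold=0)


@st.composite
def site_sets(draw):
    positions = draw(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(min_value=1, max_value=300_000),
            ),
            max_size=60,
        )
    )
    threshold = draw(st.integers(min_value=1, max_value=120_000))
    sites = [
        IntegrationSite(id=f"h{i}", chrom=c, position=p)
        for i, (c, p) in enumerate(positions)
    ]
    return sites, threshold


def brute_force_edges(sites, threshold):
    return {
        tuple(sorted((a.id, b.id)))
        for a, b in itertools.combinations(sites, 2)
        if a.chrom == b.chrom and abs(a.position - b.position) < threshold
    }


@settings(derandomize=True, max_examples=80, deadline=None)
@given(site_sets())
def test_scan_window_matches_all_pairs_oracle(data):
    """The sorted scan-window build equals a brute-force all-pairs check."""
    sites, threshold = data
    g = build_cis_graph(sites, threshold=threshold)
    got = {tuple(sorted((a, b))) for a, b in g.graph.edges}
    assert got == brute_force_edges(sites, threshold)
    for a, b, d in g.graph.edges(data=True):
        assert 0 <= d["weight"] < threshold
        assert d["weight"] == abs(
            g.graph.nodes[a]["position"] - g.graph.nodes[b]["position"]
        )


@settings(derandomize=True, max_examples=40, deadline=None)
@given(site_sets(), st.integers(min_value=1, max_value=100_000))
def test_threshold_monotonicity(data, delta):
    """A larger threshold never removes edges nor splits components."""
    sites, threshold = data
    g1 = build_cis_graph(sites, threshold=threshold)
    g2 = build_cis_graph(sites, threshold=threshold + delta)
    e1 = {tuple(sorted(e)) for e in g1.graph.edges}
    e2 = {tuple(sorted(e)) for e in g2.graph.edges}
    assert e1 <= e2
    if sites:
        assert nx.number_connected_components(
            g2.graph
        ) <= nx.number_connected_components(g1.graph)


# ---------------------------------------------------------------------------
# extract_cis / cis_dimension
# ---------------------------------------------------------------------------

class TestExtractCIS:
    def test_four_site_example_gives_one_order3_cis(self, four_site_graph):
        cis = extract_cis(four_site_graph)
        assert len(cis) == 1
        assert cis[0].order == 3
        assert cis[0].dimension == 80_000
        assert cis[0].chrom == "chr1"

    def test_graph_without_edges_gives_no_cis(self):
        g = build_cis_graph(make_sites([1, 200_000, 400_000]))
        assert extract_cis(g) == []

    def test_every_site_in_at_most_one_cis(self):
        sites = make_sites([1000, 2000, 3000, 200_000, 210_000, 500_000])
        cis = extract_cis(build_cis_graph(sites))
        members = [m.id for c in cis for m in c.members]
        assert len(members) == len(set(members))
        assert sum(c.order for c in cis) <= len(sites)

    def test_composition_counts_sources(self):
        sites = make_sites([1000, 2000], source="Bcell") + make_sites(
            [3000], source="Tcell", prefix="t"
        )
        (cis,) = extract_cis(build_cis_graph(sites))
        assert cis.composition == {"Bcell": 2, "Tcell": 1}
        assert sum(cis.composition.values()) == cis.order

    def test_order_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CIS(members=tuple(make_sites([100])))


@pytest.mark.parametrize(
    "positions, expected",
    [
        ([100_000, 140_000, 180_000], 80_000),
        ([10_000, 12_280], 2_280),  # order-2 span mirroring a 2,280 bp CIS
        ([5_000, 5_000, 5_000], 0),  # degenerate: identical positions
    ],
)
def test_cis_dimension_is_position_span(positions, expected):
    cis = CIS(members=tuple(make_sites(positions)))
    assert cis_dimension(cis) == expected


# ---------------------------------------------------------------------------
# gene atmosphere
# ---------------------------------------------------------------------------

def te(tss, chrom="chr1", name="gene", te_id="g0"):
    return TranscriptionalElement(
        id=te_id, chrom=chrom, tss=tss, name=name,
        element_type="protein_coding",
    )


class TestGeneAtmosphere:
    def test_no_element_within_threshold_leaves_graph_unchanged(self):
        g = build_cis_graph(make_sites([100_000]))
        g2 = attach_gene_atmosphere(g, [te(400_000)])
        assert g2.n_nodes == 1 and g2.n_edges == 0

    def test_element_on_other_chromosome_not_attached(self):
        g = build_cis_graph(make_sites([100_000]))
        g2 = attach_gene_atmosphere(g, [te(100_000, chrom="chr2")])
        assert g2.n_nodes == 1

    def test_single_gene_near_single_is(self):
        g = build_cis_graph(make_sites([100_000]))
        g2 = attach_gene_atmosphere(g, [te(130_000)])
        assert g2.n_nodes == 2 and g2.n_edges == 1
        assert g2.graph.edges["g0", "s0"]["weight"] == 30_000

    def test_te_links_every_is_within_threshold(self):
        g = build_cis_graph(make_sites([100_000, 110_000, 120_000]))
        g2 = attach_gene_atmosphere(g, [te(115_000)])
        assert g2.graph.degree["g0"] == 3  # many-to-many, not nearest-only

    def test_input_graph_is_not_mutated(self):
        g = build_cis_graph(make_sites([100_000]))
        attach_gene_atmosphere(g, [te(130_000)])
        assert g.n_nodes == 1

    def twin_cis_graph(self):
        # two order-2 CIS whose nearest members are 60 kb apart, with a
        # gene halfway between them (30 kb from one IS of each CIS)
        sites = make_sites([1_000, 2_000, 62_000, 63_000])
        g = build_cis_graph(sites, threshold=50_000)
        assert len(extract_cis(g)) == 2
        return attach_gene_atmosphere(g, [te(32_000)])

    def test_shared_gene_bridges_twin_cis(self):
        g2 = self.twin_cis_graph()
        comps = list(nx.connected_components(g2.graph))
        assert len(comps) == 1 and len(comps[0]) == 5
        (cis,) = extract_cis(g2)
        assert cis.bridged
        assert cis.order == 4  # TE never contributes to order
        assert [t.name for t in cis.atmosphere] == ["gene"]

    def test_split_bridged_recovers_is_only_cis(self):
        g2 = self.twin_cis_graph()
        split = extract_cis(g2, split_bridged=True)
        assert [c.order for c in split] == [2, 2]
        assert not any(c.bridged for c in split)
        # each part keeps the bridging gene in its own atmosphere
        assert all(len(c.atmosphere) == 1 for c in split)

    def test_ga_never_changes_is_only_order_or_dimension(self):
        sites = make_sites(
            [1_000, 2_000, 62_000, 63_000, 200_000, 230_000]
        )
        g = build_cis_graph(sites, threshold=50_000)
        base = {
            (c.chrom, c.start): (c.order, c.dimension)
            for c in extract_cis(g)
        }
        genes = [te(p, te_id=f"g{i}") for i, p in
                 enumerate([32_000, 190_000, 500_000])]
        g2 = attach_gene_atmosphere(g, genes)
        after = {
            (c.chrom, c.start): (c.order, c.dimension)
            for c in extract_cis(g2, split_bridged=True)
        }
        assert base == after
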