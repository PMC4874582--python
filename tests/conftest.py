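import pytest

from cisnet import IntegrationSite, build_cis_graph


def make_sites(positions, chrom="chr1", source=None, prefix="s"):
    """Integration sites at the given positions, ids unique per call."""
    return [
        IntegrationSite(id=f"{prefix}{i}", chrom=chrom, position=p,
                        source=source)
        for i, p in enumerate(positions)
    ]


@pytest.fixture
def four_site_graph():
    """Three chr1 sites 40 kb apart plus one chr2 site, T_H = 50 kb.

    Expected edges: 100k-140k and 140k-180k (both w = 40,000); the
    100k-180k pair is 80 kb apart and chr2 is unreachable.
    """
    sites = make_sites([100_000, 140_000, 180_000]) + [
        IntegrationSite(id="x0", chrom="chr2", position=100_000)
    ]
    return build_cis_graph(sites, threshold=50_000)
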