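"""Simulators: random integration datasets and synthetic transfections.

Two generators make every statistic in the package testable without any
external dataset:

* **Random datasets** place IS uniformly within the mappable regions of
  a genome, with per-chromosome counts drawn from configurable weights.
  Batches of such datasets calibrate the random-CIS statistics: rarity
  samples grouped by (dataset size, CIS order), the maximal per-dataset
  CIS frequency per order, and the largest random CIS order ever seen.
  The packaged default genome is a synthetic 2.65 Gbp proxy -- twenty
  132.5 Mbp chromosomes with uniform weights -- standing in for a
  mappability-masked mammalian genome; real mappability BED tracks and
  chromosome frequencies can be supplied instead.

* **Synthetic transfections** place IS on a 100 Mbp artificial
  chromosome carrying 159 hotspots with lengths log-uniform between
  200 bp and 5 Mbp.  One quarter of the IS land in hotspots (one hotspot
  IS per three background IS -- a deliberately low signal-to-noise
  design) and the rest anywhere on the chromosome.  Each hotspot IS
  picks a hotspot uniformly at random and a position uniformly inside
  it, so short hotspots receive high local density, which is what makes
  the resulting proximity graph scale-free; placement uniform over the
  union of hotspot intervals is available as an option but spreads the
  signal too thinly to model preferential targeting.  The hotspot truth
  intervals are returned for evaluation.

All generators are deterministic given (design, seed); batch runs derive
one independent substream per dataset index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    DEFAULT_THRESHOLD,
    CIS,
    IntegrationSite,
    build_cis_graph,
    extract_cis,
)
from .rarity import rarity

DEFAULT_GENOME_SIZE = 2_650_000_000
DEFAULT_N_CHROMS = 20


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MappableGenome:
    """Mappable intervals (1-based, inclusive) plus per-chromosome weights."""

    regions: tuple[tuple[str, int, int], ...]
    chrom_weights: dict[str, float]

    def __post_init__(self) -> None:
        for chrom, start, end in self.regions:
            if start < 1 or end < start:
                raise ValueError(
                    f"invalid mappable region {chrom}:{start}-{end}"
                )
        total = sum(self.chrom_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"chromosome weights must sum to 1, got {total}")
        with_regions = {c for c, _, _ in self.regions}
        for chrom, w in self.chrom_weights.items():
            if w > 0 and chrom not in with_regions:
                raise ValueError(
                    f"chromosome {chrom!r} has weight {w} but no mappable "
                    "region"
                )

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_weights)


def default_genome(
    total_size: int = DEFAULT_GENOME_SIZE, n_chroms: int = DEFAULT_N_CHROMS
) -> MappableGenome:
    """Packaged synthetic genome proxy: equal chromosomes, uniform weights."""
    size = total_size // n_chroms
    regions = tuple(
        (f"chr{i + 1}", 1, size) for i in range(n_chroms)
    )
    weights = {f"chr{i + 1}": 1.0 / n_chroms for i in range(n_chroms)}
    return MappableGenome(regions=regions, chrom_weights=weights)


@dataclass(frozen=True)
class RandomExperimentDesign:
    """Batch design for random-CIS calibration experiments."""

    m: int = 100
    sizes: tuple[int, ...] = (500, 2000, 5000, 10_000)
    threshold: int = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("dataset sizes must be positive")


@dataclass(frozen=True)
class SyntheticDesign:
    """Hotspot-bearing artificial chromosome and its transfection."""

    chrom_length: int = 100_000_000
    n_hotspots: int = 159
    hotspot_min: int = 200
    hotspot_max: int = 5_000_000
    n_is: int = 1000
    hotspot_fraction: float = 0.25  # 1 hotspot IS : 3 background IS
    seed: int = 0
    chrom: str = "chrS"
    placement: str = "per_hotspot"  # or "union"

    def __post_init__(self) -> None:
        if not (0 < self.hotspot_min <= self.hotspot_max <= self.chrom_length):
            raise ValueError("need 0 < hotspot_min <= hotspot_max <= length")
        if not (0.0 <= self.hotspot_fraction <= 1.0):
            raise ValueError("hotspot_fraction must lie in [0, 1]")
        if self.placement not in ("per_hotspot", "union"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class RandomExperimentResult:
    """Per-(size, order) rarity groups and CIS-frequency summaries."""

    design: RandomExperimentDesign
    rarity_groups: dict[tuple[int, int], list[float]]
    max_count: dict[tuple[int, int], int]  # max per-dataset CIS count
    max_order: int  # largest CIS order over every dataset


# ---------------------------------------------------------------------------
# Random datasets
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_random_dataset(
    genome: MappableGenome,
    n: int,
    seed=0,
    id_prefix: str = "r",
) -> list[IntegrationSite]:
    """Place ``n`` IS uniformly within the genome's mappable regions.

    Per-chromosome counts are multinomial in ``chrom_weights``; within a
    chromosome, a region is picked with probability proportional to its
    length and the position uniformly inside it.  Deterministic given
    the seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    chroms = genome.chroms
    weights = np.array([genome.chrom_weights[c] for c in chroms])
    counts = rng.multinomial(n, weights)
    regions_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in genome.regions:
        regions_by_chrom.setdefault(chrom, []).append((start, end))

    sites: list[IntegrationSite] = []
    k = 0
    for chrom, count in zip(chroms, counts):
        if count == 0:
            continue
        regions = regions_by_chrom[chrom]
        lengths = np.array([e - s + 1 for s, e in regions], dtype=float)
        idx = rng.choice(len(regions), size=count, p=lengths / lengths.sum())
        for i in idx:
            start, end = regions[i]
            pos = int(rng.integers(start, end + 1))
            sites.append(
                IntegrationSite(id=f"{id_prefix}{k:06d}", chrom=chrom,
                                position=pos)
            )
            k += 1
    return sites


def run_random_experiment(
    design: RandomExperimentDesign,
    genome: MappableGenome | None = None,
) -> RandomExperimentResult:
    """Run m random datasets per size; group random-CIS rarity by order.

    For each (size l, order i) the result pools the rarity samples of
    every CIS of order i seen across the m datasets of size l, and
    records the maximal per-dataset count of such CIS (the expected
    random CIS frequency used for priors).  Also reports the largest
    CIS order observed anywhere.
    """
    if genome is None:
        genome = default_genome()
    streams = np.random.SeedSequence(design.seed).spawn(
        design.m * len(design.sizes)
    )
    rarity_groups: dict[tuple[int, int], list[float]] = {}
    max_count: dict[tuple[int, int], int] = {}
    max_order = 0
    stream = iter(streams)
    for size in design.sizes:
        for _ in range(design.m):
            rng = np.random.default_rng(next(stream))
            sites = generate_random_dataset(genome, size, seed=rng)
            cis_list = extract_cis(
                build_cis_graph(sites, threshold=design.threshold)
            )
            per_order: dict[int, int] = {}
            for cis in cis_list:
                order = cis.order
                max_order = max(max_order, order)
                per_order[order] = per_order.get(order, 0) + 1
                rarity_groups.setdefault((size, order), []).append(
                    rarity(cis).x
                )
            for order, cnt in per_order.items():
                key = (size, order)
                max_count[key] = max(max_count.get(key, 0), cnt)
    return RandomExperimentResult(
        design=design,
        rarity_groups=rarity_groups,
        max_count=max_count,
        max_order=max_order,
    )


# ---------------------------------------------------------------------------
# Synthetic transfection
# ---------------------------------------------------------------------------

def _merge_intervals(
    intervals: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def synthetic_transfection(
    design: SyntheticDesign,
) -> tuple[list[IntegrationSite], list[tuple[int, int]]]:
    """Simulate a transfection on a hotspot-bearing artificial chromosome.

    Marks ``n_hotspots`` intervals (uniform starts, log-uniform lengths,
    overlaps allowed) on a linear chromosome, then places
    ``round(n_is * hotspot_fraction)`` IS inside hotspots and the rest
    uniformly on the whole chromosome.  Returns the sites together with
    the ground-truth hotspot intervals (1-based, inclusive, unmerged).
    """
    rng = np.random.default_rng(design.seed)
    lengths = np.exp(
        rng.uniform(
            np.log(design.hotspot_min),
            np.log(design.hotspot_max),
            design.n_hotspots,
        )
    ).astype(np.int64)
    lengths = np.maximum(lengths, 1)
    starts = np.array(
        [
            int(rng.integers(1, design.chrom_length - int(ln) + 2))
            for ln in lengths
        ],
        dtype=np.int64,
    )
    hotspots = [(int(s), int(s + ln - 1)) for s, ln in zip(starts, lengths)]

    n_hot = round(design.n_is * design.hotspot_fraction)
    n_bg = design.n_is - n_hot
    positions: list[int] = []
    if n_hot:
        if design.placement == "per_hotspot":
            picks = rng.integers(0, design.n_hotspots, n_hot)
            for i in picks:
                s, e = hotspots[int(i)]
                positions.append(int(rng.integers(s, e + 1)))
        else:  # uniform over the union of hotspot intervals
            merged = _merge_intervals(hotspots)
            lens = np.array([e - s + 1 for s, e in merged], dtype=float)
            picks = rng.choice(len(merged), size=n_hot, p=lens / lens.sum())
            for i in picks:
                s, e = merged[int(i)]
                positions.append(int(rng.integers(s, e + 1)))
    positions.extend(
        int(p) for p in rng.integers(1, design.chrom_length + 1, n_bg)
    )
    sites = [
        IntegrationSite(id=f"syn{k:05d}", chrom=design.chrom, position=p)
        for k, p in enumerate(positions)
    ]
    return sites, hotspots


def in_intervals(position: int, intervals: Sequence[tuple[int, int]]) -> bool:
    """True iff a position falls inside any (start, end) inclusive interval."""
    return any(s <= position <= e for s, e in intervals)


def cis_overlaps_hotspot(
    cis: CIS, hotspots: Sequence[tuple[int, int]]
) -> bool:
    """True iff the CIS span [start, end] intersects any hotspot interval."""
    return any(cis.start <= e and s <= cis.end for s, e in hotspots)
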