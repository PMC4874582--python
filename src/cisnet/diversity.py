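"""Entropy-based heterogeneity of CIS composition.

When the IS of a dataset carry a categorical source (tumour type, vector,
study arm, ...), each CIS has a composition: how many of its members come
from each source.  Shannon entropy of that composition, normalised by the
maximal entropy attainable with the dataset-wide number of source classes
K, scores the CIS on a 0..1 scale: NE = 0 means a single source (a
candidate disease-specific hotspot), NE = 1 means all K sources
contribute equally.  The extreme tails of the NE distribution over all
sufficiently large CIS (order > 4 by default) select the candidate homo-
and heterogeneous hotspots; a multinomial tail probability then asks how
easily a composition as dominated as the observed one arises by chance
from the dataset-wide source frequencies.

K is dataset-level configuration, never inferred per CIS: entropy is in
nats and NE = H / ln(K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, TypeVar

import numpy as np

from .model import CIS, IntegrationSite, UNLABELLED

T = TypeVar("T")

PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """Source-label composition of one CIS.

    ``k_classes`` is the number of source classes defined for the whole
    dataset (not only those present in this CIS); it is required for
    normalised entropy.
    """

    counts: Mapping[str, int]
    k_classes: int | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("composition counts must be positive")
        if self.k_classes is not None and len(self.counts) > self.k_classes:
            raise ValueError(
                f"{len(self.counts)} labels present but k_classes="
                f"{self.k_classes}"
            )

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_cis(cls, cis: CIS, k_classes: int | None = None) -> "Composition":
        return cls(counts=dict(cis.composition), k_classes=k_classes)


@dataclass(frozen=True)
class EntropyTails:
    """CIS falling in the extreme tails of the NE distribution."""

    homogeneous: tuple
    heterogeneous: tuple
    lower_cutoff: float
    upper_cutoff: float
    quantile: float


def shannon_entropy(comp: Composition) -> float:
    """Shannon entropy H = -sum p_c ln p_c in nats, over classes present."""
    n = comp.n
    if n < 1:
        raise ValueError("empty composition has no entropy")
    h = -sum((c / n) * math.log(c / n) for c in comp.counts.values())
    return float(h + 0.0)  # avoid -0.0 for single-class compositions


def normalized_entropy(comp: Composition) -> float:
    """NE = H / ln(K) in [0, 1]; requires k_classes >= 2."""
    if comp.k_classes is None or comp.k_classes < 2:
        raise ValueError(
            "normalised entropy needs a dataset-level class count "
            f"k_classes >= 2, got {comp.k_classes!r}"
        )
    return shannon_entropy(comp) / math.log(comp.k_classes)


def entropy_tails(
    scored: Sequence[tuple[T, float]],
    min_order: int = 4,
    quantile: float = 0.10,
) -> EntropyTails:
    """Extract the extreme-NE CIS.

    ``scored`` pairs each CIS (or any object with an ``order``
    attribute) with its NE.  Only CIS of order strictly greater than
    ``min_order`` enter the distribution.  Cutoffs are the empirical
    ``quantile`` and ``1 - quantile`` quantiles (linear interpolation
    between order statistics); membership uses strict inequalities, so
    a degenerate distribution yields empty tails.
    """
    kept = [(c, ne) for c, ne in scored if c.order > min_order]
    if not kept:
        raise ValueError(
            f"no CIS of order > {min_order}; cannot form an NE distribution"
        )
    ne = np.array([x for _, x in kept], dtype=float)
    lower = float(np.quantile(ne, quantile))
    upper = float(np.quantile(ne, 1.0 - quantile))
    return EntropyTails(
        homogeneous=tuple(c for c, x in kept if x < lower),
        heterogeneous=tuple(c for c, x in kept if x > upper),
        lower_cutoff=lower,
        upper_cutoff=upper,
        quantile=quantile,
    )


def source_probabilities(
    sites: Sequence[IntegrationSite],
) -> dict[str, float]:
    """Per-IS source frequencies of a whole dataset (the multinomial model)."""
    if not sites:
        raise ValueError("cannot estimate source frequencies from no sites")
    labels = [s.source if s.source is not None else UNLABELLED for s in sites]
    n = len(labels)
    return {lab: labels.count(lab) / n for lab in sorted(set(labels))}


def _prob_max_count_lt(n: int, probs: np.ndarray, m: int) -> float:
    """Exact P(max_c N_c <= m) for N ~ Multinomial(n, probs).

    Truncated generating-function convolution: the probability equals
    n! * [z^n] prod_c sum_{j=0..m} (p_c z)^j / j!, an exact enumeration
    over all admissible compositions at polynomial cost.
    """
    if m < 0:
        return 0.0
    poly = np.zeros(n + 1)
    poly[0] = 1.0
    for p in probs:
        term = np.array(
            [p**j / math.factorial(j) for j in range(min(m, n) + 1)]
        )
        poly = np.convolve(poly, term)[: n + 1]
    return float(poly[n] * math.factorial(n))


def homogeneous_cis_pvalue(
    comp: Composition,
    class_probs: Mapping[str, float],
    seed: int | None = None,
    n_draws: int = 100_000,
    method: str = "auto",
) -> float:
    """P(max class count >= observed max) under Multinomial(n, class_probs).

    The chance that a CIS as dominated by one source as the observed one
    arises from random sampling of the dataset-wide source frequencies.
    Exact for n <= 12 (or ``method="exact"``); seeded Monte Carlo with
    ``n_draws`` multinomial draws otherwise.
    """
    probs = np.array(list(class_probs.values()), dtype=float)
    if abs(probs.sum() - 1.0) > PROB_SUM_TOL:
        raise ValueError(
            f"class probabilities must sum to 1 (got {probs.sum()!r})"
        )
    if any(p < 0 for p in probs):
        raise ValueError("class probabilities must be non-negative")
    n = comp.n
    if n < 1:
        raise ValueError("empty composition")
    observed_max = max(comp.counts.values())
    if method == "auto":
        method = "exact" if n <= 12 else "mc"
    if method == "exact":
        return 1.0 - _prob_max_count_lt(n, probs, observed_max - 1)
    if method == "mc":
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, probs, size=n_draws)
        return float(np.mean(draws.max(axis=1) >= observed_max))
    raise ValueError(f"unknown method {method!r}")
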