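"""Rarity statistic and the two-class Bayesian decision rule.

The rarity of a CIS, R = dimension / (order - 1), is its mean inter-IS
gap in bp: small rarity means compact accumulation.  Two hypotheses are
compared per CIS -- theta_rnd (the CIS arose from uniform random
integration) and theta_ex (it reflects an experimental/hotspot process).
Both rarity likelihoods are Gaussian, except that for order-2 random CIS
the single gap, conditioned on being below the connection threshold, is
uniform on (0, T_H) and is modelled as such.

Random-class parameters come from simulated random experiments: the
smallest per-(dataset-size, order) group mean and the largest group
standard deviation, a deliberately conservative envelope.  The packaged
defaults are mu_rnd = 26,000 bp and sigma_rnd = 12,000 bp.

Two scores are returned per CIS:

* ``p(theta_rnd | x) = p(theta_rnd) * Phi((x - mu_rnd) / sigma_rnd)`` --
  the prior-weighted lower-tail probability of the random class,
  reported verbatim as the probability of error when rejecting
  theta_rnd.  Note this is an *unnormalised* posterior with a CDF in the
  likelihood slot; it is kept in that literal form (an ``upper_tail``
  switch exposes the complementary reading) rather than silently
  replaced by a normalised density posterior.
* ``Lambda(x) = log2[ p(x|theta_ex) p(theta_ex) / p(x|theta_rnd)
  p(theta_rnd) ]`` with Gaussian *densities*; theta_rnd is rejected iff
  Lambda(x) > 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import CIS, DEFAULT_THRESHOLD

logger = logging.getLogger(__name__)

DEFAULT_MU_RND = 26_000.0
DEFAULT_SIGMA_RND = 12_000.0
# Experimental (hotspot-driven) CIS are markedly more compact than random
# ones; these packaged defaults apply when no experimental data is supplied.
DEFAULT_MU_EX = 5_000.0
DEFAULT_SIGMA_EX = 5_000.0


@dataclass(frozen=True)
class RarityObservation:
    """Rarity x = dimension / (order - 1) of one CIS, in bp."""

    x: float
    order: int

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("rarity is defined only for order >= 2")
        if self.x < 0:
            raise ValueError("rarity cannot be negative")


@dataclass(frozen=True)
class RarityModel:
    """Gaussian rarity parameters and class priors for both hypotheses."""

    mu_rnd: float = DEFAULT_MU_RND
    sigma_rnd: float = DEFAULT_SIGMA_RND
    mu_ex: float = DEFAULT_MU_EX
    sigma_ex: float = DEFAULT_SIGMA_EX
    prior_ex: float = 0.5
    prior_rnd: float = 0.5
    n_ex: int | None = None
    n_rnd: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_rnd <= 0 or self.sigma_ex <= 0:
            raise ValueError("rarity standard deviations must be positive")
        if not (0.0 <= self.prior_ex <= 1.0 and 0.0 <= self.prior_rnd <= 1.0):
            raise ValueError("priors must lie in [0, 1]")
        if abs(self.prior_ex + self.prior_rnd - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")


@dataclass(frozen=True)
class ScoredCIS:
    """A CIS with its rarity, error probability, LLR and verdict."""

    cis: CIS
    rarity: RarityObservation
    p_value: float
    llr: float
    verdict: bool  # True: theta_rnd rejected (Lambda > 0)

    @property
    def degenerate(self) -> bool:
        """True when a density underflow pushed the LLR to +/-infinity."""
        return math.isinf(self.llr)


def rarity(cis: CIS) -> RarityObservation:
    """R = dimension / (order - 1): the mean inter-IS gap of the CIS.

    For order 2 this is the single gap itself, which for random CIS is
    uniform over the connection threshold.
    """
    if cis.order < 2:
        raise ValueError("rarity requires a CIS of order >= 2")
    return RarityObservation(
        x=cis.dimension / (cis.order - 1), order=cis.order
    )


def priors_from_counts(n_ex: int, n_rnd: int) -> tuple[float, float]:
    """p(theta_ex) = N_ex / (N_ex + N_rnd); p(theta_rnd) = 1 - p(theta_ex).

    ``n_rnd`` is the expected random CIS count for the order at hand: the
    maximal per-dataset CIS frequency seen in the random experiments.
    """
    if n_ex < 0 or n_rnd < 0:
        raise ValueError("counts must be non-negative")
    total = n_ex + n_rnd
    if total == 0:
        raise ValueError("at least one of n_ex, n_rnd must be positive")
    p_ex = n_ex / total
    return p_ex, 1.0 - p_ex


def random_error_probability(
    obs: RarityObservation,
    model: RarityModel,
    threshold: int = DEFAULT_THRESHOLD,
    order2_uniform: bool = True,
    upper_tail: bool = False,
) -> float:
    """Probability of error when rejecting theta_rnd given rarity x.

    Literal form: prior_rnd times the lower-tail CDF of the random-class
    rarity law -- Gaussian in general, uniform(0, T_H) for order-2 CIS
    when ``order2_uniform`` (the default).  ``upper_tail=True`` reports
    the complementary tail instead.  Monotonically non-decreasing in x
    (non-increasing for the upper tail).
    """
    if obs.order == 2 and order2_uniform:
        cdf = min(max(obs.x / threshold, 0.0), 1.0)
    else:
        cdf = float(stats.norm.cdf((obs.x - model.mu_rnd) / model.sigma_rnd))
    if upper_tail:
        cdf = 1.0 - cdf
    return model.prior_rnd * cdf


def log_likelihood_ratio(
    obs: RarityObservation,
    model: RarityModel,
    threshold: int = DEFAULT_THRESHOLD,
    order2_uniform: bool = True,
) -> float:
    """Lambda(x) in log2 units; theta_rnd is rejected iff Lambda(x) > 0.

    Gaussian densities for both classes, except uniform(0, T_H) for the
    order-2 random class when ``order2_uniform``.  Density underflow in
    either class yields +/-inf (flagged as ``degenerate`` on the scored
    CIS) rather than an exception.
    """
    num = float(stats.norm.pdf(obs.x, model.mu_ex, model.sigma_ex))
    num *= model.prior_ex
    if obs.order == 2 and order2_uniform:
        den = (1.0 / threshold) if 0 <= obs.x < threshold else 0.0
    else:
        den = float(stats.norm.pdf(obs.x, model.mu_rnd, model.sigma_rnd))
    den *= model.prior_rnd
    if num == 0.0 and den == 0.0:
        return math.nan
    if den == 0.0:
        return math.inf
    if num == 0.0:
        return -math.inf
    return math.log2(num / den)


def score_cis(
    cis_list: Sequence[CIS],
    model: RarityModel | None = None,
    threshold: int = DEFAULT_THRESHOLD,
    order2_uniform: bool = True,
) -> list[ScoredCIS]:
    """Score every CIS: rarity, error probability, LLR and verdict."""
    if model is None:
        model = RarityModel()
    out = []
    for cis in cis_list:
        obs = rarity(cis)
        llr = log_likelihood_ratio(
            obs, model, threshold=threshold, order2_uniform=order2_uniform
        )
        out.append(
            ScoredCIS(
                cis=cis,
                rarity=obs,
                p_value=random_error_probability(
                    obs,
                    model,
                    threshold=threshold,
                    order2_uniform=order2_uniform,
                ),
                llr=llr,
                verdict=llr > 0,
            )
        )
    return out


def fit_rarity_model(
    random_groups: Mapping[tuple[int, int], Sequence[float]],
    experimental: Sequence[float] | None = None,
    min_group_size: int = 30,
    priors: tuple[float, float] | None = None,
) -> RarityModel:
    """Fit random-class rarity parameters from simulated random CIS.

    ``random_groups`` maps (dataset size l, CIS order i) to the rarity
    samples of that group.  Order-2 groups are excluded (their law is
    uniform, not Gaussian), as are groups below ``min_group_size`` whose
    single-draw "means" would be pure noise.  Then mu_rnd is the
    smallest group mean and sigma_rnd the largest group standard
    deviation -- a conservative envelope over the sampled conditions.

    Experimental parameters are the pooled mean/sd of ``experimental``
    when given, else the packaged defaults.  With no usable random group
    the packaged random defaults are kept and a warning is logged.
    """
    means, sds = [], []
    for (_, order), values in random_groups.items():
        if order == 2 or len(values) < min_group_size:
            continue
        arr = np.asarray(values, dtype=float)
        means.append(float(arr.mean()))
        sds.append(float(arr.std(ddof=1)))
    if means:
        mu_rnd, sigma_rnd = min(means), max(sds)
    else:
        logger.warning(
            "no usable random rarity group (order > 2, >= %d samples); "
            "keeping packaged defaults mu_rnd=%.0f sigma_rnd=%.0f",
            min_group_size,
            DEFAULT_MU_RND,
            DEFAULT_SIGMA_RND,
        )
        mu_rnd, sigma_rnd = DEFAULT_MU_RND, DEFAULT_SIGMA_RND
    if experimental is not None and len(experimental) >= 2:
        arr = np.asarray(experimental, dtype=float)
        mu_ex, sigma_ex = float(arr.mean()), float(arr.std(ddof=1))
    else:
        mu_ex, sigma_ex = DEFAULT_MU_EX, DEFAULT_SIGMA_EX
    model = RarityModel(
        mu_rnd=mu_rnd, sigma_rnd=sigma_rnd, mu_ex=mu_ex, sigma_ex=sigma_ex
    )
    if priors is not None:
        model = replace(model, prior_ex=priors[0], prior_rnd=priors[1])
    return model
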