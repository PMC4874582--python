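# Methods

## The model

A dataset of *n* integration sites (IS) is represented as an undirected
weighted graph *G* = (*V*, *e*): one vertex per IS, and an edge
*e*<sub>ij</sub> with weight *w*<sub>ij</sub> = |p<sub>i</sub> −
p<sub>j</sub>| whenever two IS lie on the same chromosome at a distance
*strictly* smaller than a threshold *T*<sub>H</sub>.  The default
*T*<sub>H</sub> = 50,000 bp is the upper bound of the window within
which an insertion event is known to perturb local gene expression; it
is a parameter, not a constant, and sparse loci are often re-annotated
at 200 kb.  Distances at exactly *T*<sub>H</sub> do not create an edge,
and no inter-chromosomal distance is defined, so components never span
chromosomes.  Construction sorts sites per chromosome and scans a
sliding window, giving O(n log n + E) cost; a brute-force all-pairs
oracle is kept in the test suite and must agree exactly on every random
input.

A **common integration site (CIS)** is a connected component with at
least two IS vertices (the smallest cluster that can witness
accumulation).  Its *order* is the number of IS, its *dimension* the
span max − min of member positions in bp.  Coordinates are 1-based
points throughout; BED input (0-based half-open) is converted at the
boundary, using the interval midpoint for multi-base records.

**Gene atmosphere (GA).**  Transcriptional elements (TE: protein-coding
genes, miRNAs, lincRNAs, snoRNAs) are anchored at their TSS — for
stranded interval records the start on "+" and the end on "−"; gene-body
overlap is deliberately not considered.  A TE within the annotation
threshold of at least one IS is added as a second-category node and
linked to *every* qualifying IS, which makes the IS–gene mapping
many-to-many (one IS may have several genes, one gene several IS).
TE–TE edges are never created: they would chain CIS together across
gene deserts, whereas the only biologically meaningful merge is two IS
clusters sharing a *near* gene.  That merge does happen — two twin CIS
can be joined through a common gene — so components whose IS fall apart
when TE nodes are removed carry a `bridged` flag, and
`extract_cis(..., split_bridged=True)` exposes the re-split view for
downstream statistics.  GA attachment never changes the IS-only order
or dimension of any CIS.  Strand is read from inputs but ignored by all
computations.

## Degree-distribution diagnostics

Hotspot-driven integration produces heavy-tailed vertex degrees.  The
degree histogram d(k) is fitted with d(k) = a·k<sup>−γ</sup> by
unweighted ordinary least squares of log₁₀ d(k) on log₁₀ k over the
non-empty bins with k ≥ 1 of the *raw* histogram (degree-0 nodes stay in
the histogram but cannot enter a log–log fit).  This mirrors the common
network-analysis tool convention; no logarithmic binning and no
maximum-likelihood (Clauset-style) estimator is used in the reference
path, and no goodness-of-fit test of power-law plausibility is
performed — classification uses only the exponent: *scale-free* iff
γ < 3, *random* otherwise, *undetermined* when fewer than two usable
bins exist.  The fit is invariant to rescaling all counts by a positive
constant, so whether d(k) is counts or frequencies only affects a,
never γ.

## Entropy and composition heterogeneity

When IS carry a source label (tumour type, vector, study), each CIS has
a composition {n<sub>c</sub>}.  Shannon entropy H = −Σ (n<sub>c</sub>/n)
ln(n<sub>c</sub>/n) is computed in nats and normalised by the maximal
entropy for the *dataset-wide* class count K: NE = H / ln K, so NE = 0
iff a single source is present and NE = 1 iff all K classes contribute
equally.  K is explicit configuration (15 for the mouse-tumour-database
style setup), never inferred per CIS — a CIS containing two of fifteen
possible sources is not maximally heterogeneous.  The homo/heterogeneous
candidate sets are the strict tails of the empirical NE distribution
over CIS of order > 4 (default), at the 10% quantile per side; quantiles
use linear interpolation between order statistics and the cutoffs are
reported so the convention is auditable.

The chance that a composition as dominated as the observed one arises
from random sampling is P(max<sub>c</sub> N<sub>c</sub> ≥ observed max)
under Multinomial(n, q) with q the per-IS source frequencies of the
whole dataset.  For n ≤ 12 this is computed exactly (truncated
generating-function convolution, an exact enumeration over admissible
compositions at polynomial cost); for larger n a seeded Monte Carlo with
10⁵ draws is used, and the two routes agree within three standard errors
on every overlap case in the test suite.

## Rarity and the two-class decision rule

Rarity R = dimension / (order − 1) is the mean inter-IS gap of a CIS in
bp; for order 2 it is the single gap, which for random CIS is uniform on
(0, T<sub>H</sub>) by construction.  Two fully specified hypotheses are
compared per CIS: θ<sub>rnd</sub> (uniform random integration) and
θ<sub>ex</sub> (experimental/hotspot process), with Gaussian rarity
likelihoods except for the order-2 random class, which uses the uniform
law (switchable off).

Random-class parameters are calibrated from simulated random
experiments: m = 100 datasets at each size l ∈ {500, 2000, 5000,
10000}, CIS extracted at 50 kb and grouped by (l, order).  μ<sub>rnd</sub>
is the *smallest* group mean and σ<sub>rnd</sub> the *largest* group
standard deviation — a conservative envelope.  Groups of order 2 are
excluded (uniform law), and groups with fewer than 30 samples are
excluded from the envelope: a "mean" over a handful of skewed gap
samples is an extreme-value draw, not a distribution parameter, and
letting it enter a min-selection makes the estimate collapse with the
number of groups.  With that guard the recovered μ<sub>rnd</sub> is
stable at ≈ 23–24 kb (the analytic mean of below-threshold gaps for
uniform placement is slightly under T<sub>H</sub>/2 = 25 kb).  The
packaged defaults μ<sub>rnd</sub> = 26,000 bp and σ<sub>rnd</sub> =
12,000 bp are the published reference calibration and are used whenever
no simulation is supplied.  Experimental-class parameters come from user
data when given; the packaged defaults μ<sub>ex</sub> = σ<sub>ex</sub> =
5,000 bp encode the observation that hotspot-driven CIS are markedly
more compact than random ones.  Priors follow the counts rule
p(θ<sub>ex</sub>) = N<sub>ex</sub>/(N<sub>ex</sub> + N<sub>rnd</sub>),
with N<sub>rnd</sub> the maximal per-dataset random CIS frequency of the
same order.

Two scores are reported per CIS:

* the probability of error when rejecting θ<sub>rnd</sub>,
  p(θ<sub>rnd</sub>) · Φ((x − μ<sub>rnd</sub>)/σ<sub>rnd</sub>).  This
  is kept in its literal form — an unnormalised posterior with a
  lower-tail CDF in the likelihood slot — rather than being silently
  "corrected" to a normalised density posterior; the direction (whether
  low rarity should make the random hypothesis more or less probable)
  is ambiguous in that form, so the complementary upper tail is exposed
  as an option (`upper_tail=True`) and off by default.  CIS with
  p < 0.05 are labelled significant; no multiple-testing correction is
  applied.
* the log-likelihood ratio Λ(x) = log₂[p(x|θ<sub>ex</sub>)p(θ<sub>ex</sub>)
  / p(x|θ<sub>rnd</sub>)p(θ<sub>rnd</sub>)] with *densities* (a ratio of
  CDFs would not satisfy the Bayes-rule derivation); θ<sub>rnd</sub> is
  rejected iff Λ(x) > 0.  Density underflow deep in a tail yields ±∞
  with a `degenerate` flag instead of an exception.

## Simulators

**Random datasets** place IS uniformly within mappable regions:
per-chromosome counts are multinomial in configurable weights, positions
uniform within length-weighted intervals.  The packaged default genome
is a synthetic 2.65 Gbp proxy — twenty 132.5 Mbp chromosomes with equal
weights — standing in for a mappability-masked mammalian genome; a real
100 bp-read mappability track (BED) and empirical chromosome frequencies
(TSV) can be supplied instead.  What the proxy does *not* emulate:
mappability gaps, centromeres, chromosome-size variation and
chromatin-driven integration bias; passing tests on it shows the
statistics behave correctly under their own null, not that real genomes
are uniform.

**Synthetic transfections** mark 159 hotspots on a 100 Mbp linear
chromosome, with lengths log-uniform on [200 bp, 5 Mbp] (spanning four
orders of magnitude without letting the 5 Mbp tail dominate) and uniform
starts, overlaps allowed.  One quarter of the n IS (1 hotspot IS per 3
background IS — a deliberately low signal-to-noise design; n ∈ {100,
500, 1000}) are placed in hotspots, the rest uniformly on the whole
chromosome.  Each hotspot IS picks a hotspot uniformly at random and
then a position uniformly inside it: short hotspots therefore receive
very high local density, which is exactly the accumulation process the
scale-free diagnostic is meant to detect.  Placement uniform over the
*union* of hotspot intervals is available (`placement="union"`) but is
not the default: the union covers roughly half the chromosome, the
density inside it is nearly flat, and the resulting graphs are
frequently indistinguishable from random placement (fitted γ > 3 in
~2/10 seeds) — a simulator that fails to simulate its own signal.
Ground-truth hotspot intervals are returned for evaluation; ≥ 50% of
CIS of order ≥ 5 overlap a true hotspot under the default design.

All generators are deterministic given (design, seed); batch experiments
derive one independent substream per dataset index, so identical seeds
give byte-identical outputs.

## Problem sizes and determinism of the test suite

The test suite and the acceptance script regenerate everything they
check.  Sizes used: the order-bound experiment runs the full m = 100 ×
l = 10,000 design (~10⁶ sites); rarity-model recovery uses m = 25 at
l ∈ {5000, 10000}; the scale-free/random dichotomy uses 10 seeds per
condition (synthetic: 1,000 IS on 100 Mbp; random: 15,000 IS on the
2.65 Gbp proxy, matching the size regimes of the reference datasets);
order-2 uniformity pools ~1,000–2,000 order-2 CIS.  Stochastic tests use
fixed seeds; property tests are derandomised.

## What is not reproduced here

The reference analyses behind the defaults were performed on external
IS collections — the RTCGD mouse insertional-mutagenesis database and
published LV, HIV, gammaretroviral (GV1/GV2) and AAV datasets.  Those
datasets are not bundled, so the statistics derived from them are *not*
recomputed by this package and are quoted only as context: the RTCGD
CIS order range ("order 2 to 82"), its 5110 CIS-member IS of which
4035 fall in CIS with p < 0.05, the 203-CIS entropy distribution with
tail cutoffs 0.1515 / 0.5375 (23 homogeneous, 18 heterogeneous CIS),
and the per-dataset degree exponents (e.g. γ = 3.6 for a ~15,000-IS
random placement, γ = 4.8 for AAV).  The simulators reproduce these
behaviours qualitatively — the order bound, the uniform order-2 rarity
law, the γ < 3 / γ ≥ 3 dichotomy — and the entropy worked examples
reproduce the published per-CIS NE values exactly from their printed
compositions; nothing else about the external datasets is claimed.

## Known limitations

* The proximity rule is purely linear-genomic; spatial genome
  organisation (Hi-C contact domains) is outside the model.
* The power-law fit on raw histograms is noisy for small sparse
  datasets (singleton high-k bins); at 1,000 uniformly placed IS on
  100 Mbp the fitted γ fluctuates by ±0.5 across seeds, which is why
  classification robustness is only claimed at the reference dataset
  sizes.
* The homogeneity p-value conditions on the observed CIS order, not on
  the CIS-formation process itself.
* Bridged components mix two defensible readings (merged vs re-split);
  both are exposed and the flag is always set, but downstream statistics
  default to the merged view.
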