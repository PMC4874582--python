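# cisnet

Graph-based modelling of virus and viral-vector integration sites.

Insertional-mutagenesis screens and gene-therapy safety studies produce
tables of genomic **integration sites (IS)**.  Positions where many IS
accumulate — **common integration sites (CIS)** — mark genomic regions
preferentially targeted by the vector or selected for in the host (for
example near proto-oncogenes), and detecting them reliably is central to
both vector safety assessment and cancer-gene discovery.  Fixed-window
CIS definitions depend strongly on dataset size; `cisnet` instead
represents a dataset as a proximity graph and lets graph structure carry
the analysis.

## The model

* **Graph.**  One vertex per IS; an edge *e*<sub>ij</sub> with weight
  *w*<sub>ij</sub> = |p<sub>i</sub> − p<sub>j</sub>| whenever two IS on
  the same chromosome are strictly closer than a threshold
  *T*<sub>H</sub> (default 50 kb).  A **CIS** is a connected component
  with ≥ 2 IS; its *order* is its IS count and its *dimension* the bp
  span.
* **Gene atmosphere.**  Transcriptional elements (genes, miRNAs, ...)
  within *T*<sub>H</sub> of any IS are layered onto the graph as a
  second node category, linked to every qualifying IS (a many-to-many
  IS–gene annotation).  The genes attached to a CIS form its gene
  atmosphere (GA).
* **Scale-free diagnostic.**  The degree distribution is fitted with
  d(k) = a·k<sup>−γ</sup> (least squares on the log–log histogram).
  Hotspot-driven datasets give γ < 3 (scale-free); uniform random
  placement gives γ ≥ 3.
* **Composition entropy.**  Per CIS, the Shannon entropy of its source
  composition normalised by ln K (K = dataset-wide class count):
  NE = 0 means single-source, NE = 1 all sources equal.  Tails of the
  NE distribution select candidate homo-/heterogeneous hotspots, and a
  multinomial model gives the chance of a composition that dominated
  arising at random.
* **Rarity statistic.**  R = dimension/(order − 1), the mean inter-IS
  gap.  A two-class Bayesian rule compares Gaussian rarity models for
  random (μ = 26,000 bp, σ = 12,000 bp, calibrated by simulation) and
  experimental CIS, reporting an error probability
  p(θ<sub>rnd</sub>)·Φ((x − μ<sub>rnd</sub>)/σ<sub>rnd</sub>) and a
  log-likelihood ratio Λ(x); θ<sub>rnd</sub> is rejected iff Λ(x) > 0.
* **Simulators.**  Mappability-aware uniform random datasets (for
  calibration and null behaviour) and synthetic transfections on a
  100 Mbp chromosome bearing 159 hotspots (for ground-truth signal), so
  every statistic is testable without external data.

See `docs/methods.md` for assumptions, parameter rationale and known
limitations.

## Worked example

```python
from cisnet import (SyntheticDesign, synthetic_transfection, build_cis_graph,
                    extract_cis, degree_distribution, fit_power_law,
                    classify_scale_free, score_cis, RarityModel)

sites, hotspots = synthetic_transfection(SyntheticDesign(n_is=1000, seed=1))
graph = build_cis_graph(sites, threshold=50_000)
cis_list = extract_cis(graph)
print(f"{len(sites)} IS -> {graph.n_edges} edges, {len(cis_list)} CIS")

fit = fit_power_law(degree_distribution(graph))
print(f"degree exponent gamma = {fit.gamma:.2f} ({classify_scale_free(fit)})")

scored = score_cis(cis_list, RarityModel())
sig = [s for s in scored if s.p_value < 0.05]
print(f"{len(sig)}/{len(scored)} CIS significant at p < 0.05")
```

prints

```
1000 IS -> 708 edges, 238 CIS
degree exponent gamma = 2.22 (scale_free)
42/238 CIS significant at p < 0.05
```

1,000 IS (250 of them in hotspots) form 238 CIS; the fitted exponent
γ = 2.22 < 3 classifies the dataset as hotspot-driven, and 42 CIS are
compact enough that rejecting the random hypothesis carries an error
probability below 0.05.  The biggest CIS here has order 9 and spans
38,883 bp (rarity 4,860 bp, Λ = 3.5, so θ<sub>rnd</sub> is rejected);
uniform placement of the same size gives γ well above 3 and almost no
high-order CIS.

The same pipeline is scriptable from the shell:

```sh
cisnet simulate-transfection --n-is 1000 --seed 1 --out-prefix syn
cisnet build syn.is.tsv --out-prefix syn
cisnet fit-powerlaw syn.is.tsv --out-prefix syn
cisnet analyze syn.cis.tsv --out-prefix syn
```

Every command writes a JSON manifest (parameters, seeds, input
checksums) sufficient to reproduce its outputs bit-exactly.

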