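# kogrowth

Analysis toolkit for genome-wide single-gene knockout growth screens in
bacteria: it links the exponential growth rate of each knockout strain to
the wild-type expression level of the deleted gene and to the gene's
position on the circular chromosome.

It is written for the kind of dataset a Keio-style screen produces — OD600
plate-reader curves for thousands of deletion strains in two media, bulk
RNA-seq of the parental strain (log10 RPKM), and a gene annotation with
essentiality flags and flat functional-category codes — and for anyone who
wants to reproduce that style of analysis on their own screen or on
simulated data.

## What it computes

- **Growth rates** from OD600 curves: per-interval rates
  `mu_i = ln(C_{i+1}/C_i)/(t_{i+1}-t_i)`, summarized as the mean of the
  best window of five consecutive rates (largest mean, then smallest SD),
  with replicate aggregation, no-growth handling, and well-location bias
  diagnostics (`kogrowth.growth`).
- **Fitness classes**: each knockout rate placed against the 1.5·IQR
  box-plot fences of its medium — `very_negative`, `negative`, `neutral`,
  `positive`, `very_positive` gene contributions (semantics invert the
  rate) — plus one-sided binomial category enrichment with Bonferroni
  correction (`kogrowth.fitness`).
- **Differential genes/strains** between media by the rank product with a
  replicate-permutation null, pfp and Benjamini–Hochberg FDR, after global
  median normalization (`kogrowth.differential`).
- **Growth–expression association**: Spearman correlation per medium, a
  1,000-shuffle randomization null, and category-level correlations
  (`kogrowth.association`).
- **Chromosomal periodicity**: per-gene values averaged in 100-kb sliding
  windows at 1-kb anchors on the circular genome, Fourier periodogram with
  wavelengths L/k, Fisher's exact g test, and the closed-form least-squares
  sinusoid of the dominant harmonic (`kogrowth.periodicity`).
- **Synthetic data** with the statistical structure the analysis assumes —
  logistic plate curves with a well-location bias on carrying capacity,
  expression with a six-period positional cosine, knockout growth
  anti-correlated with expression at a calibrated Spearman rho
  (`kogrowth.synthetic`) — so the whole pipeline is testable with no
  external data.

A `kogrowth` CLI (`simulate`, `growth`, `classify`, `enrich`, `diffexpr`,
`associate`, `periodicity`, `run-all`) wraps the library; `run-all` drives
file-based inputs end to end and writes TSVs plus a JSON manifest.

## Worked example

```python
import pandas as pd
from kogrowth import synthetic as S, fitness as F, association as A, periodicity as P

cfg = S.SyntheticConfig(n_genes=4200, seed=42)     # 4,632-kb circular genome
ann = S.generate_annotation(cfg)
expr = S.generate_expression(ann, cfg, "LB")
truth = S.generate_growth_truth(ann, expr, cfg, "LB")

ne = truth[~truth.essential]                       # the knockout library
rate = pd.DataFrame({"strain": ne.gene, "medium": "LB",
                     "mu_mean": ne.true_mu, "max_od_mean": 1.0})

cls = F.classify_genes(rate, "LB")
print(cls.fitness_class.value_counts().to_dict())

join = A.join_growth_expression(rate, expr, ann)
rho, p = A.spearman_growth_expression(join, "LB")
rand = A.randomization_test(join, "LB", n_shuffles=1000, seed=0)
print(f"rho = {rho:.3f} (p = {p:.2e}), randomization p = {rand.empirical_p['mu_mean']:.5f}")

sig = P.positional_signal(ann, rate.set_index("strain")["mu_mean"],
                          mode="nonessential_only", genome_length_kb=4632)
dom = P.dominant_period(sig)
print(f"dominant k = {dom.dominant_k}, wavelength = {dom.dominant_wavelength_kb:.0f} kb, "
      f"g = {dom.g:.3f}")
```

Output:

```
{'neutral': 1955, 'negative': 969, 'positive': 968, 'very_positive': 10, 'very_negative': 9}
rho = -0.376 (p = 5.99e-132), randomization p = 0.00100
dominant k = 6, wavelength = 772 kb, g = 0.942
```

Reading this: of 3,911 knockout strains, most genes are neutral and a
handful sit beyond the 1.5·IQR fences (10 strongly growth-supporting, 9
strongly costly); knockout growth is negatively correlated with wild-type
expression at the generator's calibrated rho ≈ −0.37 and none of 1,000
column shuffles reaches it (empirical p = 1/1001); and the planted
six-period chromosomal harmonic dominates the periodogram at a wavelength
of 4632/6 = 772 kb.

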