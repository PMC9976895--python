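# jloe

Estimating how much a pooled CRISPR knockout fitness screen misses — and
getting it back.

Genome-wide CRISPR-Cas9 screens in cancer cell lines are routinely treated as
saturating: a single well-powered screen is assumed to find essentially all of
a cell line's essential genes. In practice the cumulative count of unique
essential genes keeps climbing as screens accumulate, because each screen both
misses true essentials (false negatives, enriched among moderately expressed
genes) and contributes spurious hits (false positives). This package, aimed at
groups analysing BAGEL-style Bayes-factor (BF) matrices from screen panels
such as DepMap, implements three linked analyses:

1. **Synthetic-genome modeling** — from a genome of *N* genes with *n*
   essentials, each simulated screen reports *h* hits split
   `round(h·FDR)` nonessential / `h − round(h·FDR)` essential, drawn without
   replacement within a screen. Fitting the simulated mean cumulative-hits
   curve to the observed bootstrap curve by RMSE over a grid of (*n*, FDR)
   estimates the essential-gene count and per-screen FDR; the per-screen
   false negative rate follows as `FNR = 1 − mean_observed_hits / n̂`.
2. **Saturation resampling** — within a tissue, k initial screens are
   assumed to saturate; new hits in k disjoint subsequent screens bound the
   false-positive process. Binning genes by hit frequency b ∈ 1..k gives a
   bin-wise FDR, `FDR_b = FP_b / TP_b`, high for one-off hits and negligible
   for frequent ones. Genes at mean frequency ≥ 3/8 form the tissue's
   high-confidence essential set; intersecting tissues separates common from
   context essentials.
3. **JLOE (Joint Log Odds of Essentiality)** — per gene, screens are ranked
   by descending BF and evaluated sequentially with

   `posterior log₂ odds = BF + log₂(prior ratio)`,

   starting from the uninformative prior log₂(0.1/0.9) ≈ −3 and, after each
   essential call (posterior > 7, ≈ 99% posterior probability), updating the
   prior to `log₂((1 − FDR_b)/FDR_b)` for the bin b of calls so far (capped
   at 9). Marginal BFs backed by strong prior evidence are thereby rescued,
   while genes without an anchor call are judged exactly as plain BF ≥ 10
   thresholding — so JLOE recovers false negatives without simply lowering
   the threshold.

A truth-tabled synthetic data generator (`jloe.synthdata`) emulates the
assumed data structure — core essentials with expression-coupled dropout,
background false positives, subtype-restricted context essentials — so every
stage is testable without external downloads.

## Worked example

```python
import jloe

# a synthetic 2000-gene, 40-screen population with known ground truth
cfg = jloe.SynthConfig(seed=0)
bf, expr, ann, truth = jloe.generate_population(cfg)

# fit the synthetic-genome model to a reference cumulative curve
ref = jloe.simulate_genome_screens(
    jloe.GenomeModelConfig(n=1600, fdr=0.095, iterations=100, seed=1))
fit = jloe.fit_genome_model(ref, iterations=100, seed=2)
print(f"best fit: n={fit.best_n}, fdr={fit.best_fdr:.3f}")
print(f"screen FNR at 1287 observed hits: {jloe.estimate_fnr(fit.best_n, 1287):.3f}")

# saturation resampling and JLOE on one tissue
sub = bf[ann.screens_for_tissue("colorectal")]
profile, freq = jloe.saturation_sample(sub, seed=3)
priors = jloe.binwise_fdr(profile)
res = jloe.jloe_tissue(sub, priors, seed=4)
fn = jloe.classify_false_negatives(freq, res.mean_frequency)
print("bin-wise FDR:", {b: round(priors.fdr[b], 3) for b in priors.bins})
print(f"high-confidence essentials: {len(jloe.high_confidence_set(freq))}")
print(f"JLOE-rescued false negatives: {len(fn)}")
```

Output:

```
best fit: n=1600, fdr=0.095
screen FNR at 1287 observed hits: 0.196
bin-wise FDR: {1: 0.838, 2: 0.28, 3: 0.022, 4: 0.007, 5: 0.005, 6: 0.002, 7: 0.0}
high-confidence essentials: 346
JLOE-rescued false negatives: 115
```

The grid fit recovers the generating parameters (n = 1600, FDR = 9.5%)
exactly, and 1287 observed hits against that best fit imply that a single
screen misses ~20% of its essential genes. On the synthetic tissue the
bin-wise FDR drops from ~84% for one-off hits to under 3% for genes hit in
three or more of eight screens; 115 genes below saturation at BF ≥ 10 are
lifted to 8/8 essential calls by JLOE — the rescued false negatives.

The same pipeline is scriptable through the `jloe` executable
(`qc`, `cumulative`, `simulate-genome`, `fit-genome`, `saturation`, `jloe`,
`classify-fn`, `synth`); every subcommand takes `--seed`, writes TSV/JSON,
and logs its parameters next to the output.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, what the synthetic generator does and does not emulate,
and known limitations.
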