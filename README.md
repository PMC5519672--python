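# twinclock

A transcriptomic age clock built from a monozygotic-twin design.

Monozygotic (MZ) twins share a genome, so expression differences *within* a
couple isolate environmental and stochastic variation. Genes whose expression
stays concordant between aging twins while still tracking chronological age
are candidates for *normative* aging — change driven by intrinsic programs
rather than environment or disease. `twinclock` implements the full analysis
for probe-by-sample expression matrices from paired twin cohorts:

1. **Divergence scoring.** For probe *i* with expression `g_i`, the
   twin-divergence score is

   ```
   Δ_i = ⟨ |g_i¹ − g_i²| ⟩ / σ_{g_i}
   ```

   the mean absolute within-couple difference over all couples, rescaled by
   the probe's standard deviation over all samples. Low Δ marks genetically
   controlled, environment-insensitive expression. A whole-array companion
   statistic — per-couple Pearson R of the two members' full profiles,
   regressed on age — quantifies how twin concordance erodes over the
   lifespan.
2. **Signature extraction.** For each leave-one-couple-out fold, probes at
   least 2.5 SD below the mean z-scored Δ are selected; couples are split
   into two halves (one twin each), ridge regression of age (k = 10⁻⁴,
   standardized predictors) is fitted on one half and validated on the
   other; the final signature is the intersection of all per-fold
   selections, minus unannotated probes.
3. **Random-signature null.** The signature's validation R is ranked against
   an empirical distribution from many uniformly drawn probe subsets of
   matched size, each evaluated by the identical protocol.
4. **Cross-platform transfer.** Signatures move to other platforms by gene
   symbol (keeping the highest-average-expression probe per symbol), are
   re-tuned by ridge on the target, and evaluated by repeated 10-fold
   cross-validation.
5. **Pathway enrichment.** One-sided hypergeometric over-representation of
   low-divergence probe sets against an annotated background, with
   Benjamini–Hochberg q-values.

A bundled synthetic-cohort generator emulates the assumed data structure —
age-regulated, volatile (divergence growing with age) and stable probe
classes with couple-shared genetic effects — with ground-truth labels, so
every stage is testable end to end. All formats are plain text: TSV
matrices/metadata, GMT pathways, YAML config, JSON outputs.

## Worked example

```python
import twinclock as tc

config = tc.SyntheticConfig(seed=1)          # 27 couples, 5,000 probes, ages 22-98
matrix, cohort, truth = tc.generate_twin_cohort(config)
pipeline = tc.PipelineConfig(seed=1)         # z <= -2.5, ridge k = 1e-4

trend = tc.couple_correlation_trend(matrix, cohort)
print(f"couple concordance slope: {trend.slope:.2e}/yr "
      f"(95% CI [{trend.ci_low:.2e}, {trend.ci_high:.2e}])")

signature = tc.extract_signature(matrix, cohort, pipeline)
r, _ = tc.evaluate_signature(signature, matrix, cohort)
print(f"signature: {len(signature)} probes, twin-split validation R = {r:.3f}")

null = tc.random_signature_null(
    matrix, cohort, size=len(signature), n_iter=1000,
    protocol="twin-split", config=pipeline, split=signature.provenance["split"])
pct, n_out = tc.percentile_rank(null, r)
print(f"random-signature null: mean R = {null.mean:.2f} (SD {null.sd:.2f}); "
      f"{n_out} of {null.n} draws outperform (percentile {pct:.1f})")
```

prints

```
couple concordance slope: -3.06e-05/yr (95% CI [-4.24e-05, -1.87e-05])
signature: 33 probes, twin-split validation R = 0.996
random-signature null: mean R = 0.81 (SD 0.17); 0 of 1000 draws outperform (percentile 100.0)
```

The entirely negative confidence interval says twin couples grow slightly
more discordant with age; the extracted 33-probe signature predicts held-out
twins' ages almost perfectly, and no random signature of the same size
matches it. The same stages are available from the shell via the
`twinclock` command (`simulate`, `preprocess`, `divergence`,
`extract-signature`, `null-model`, `transfer`, `enrich`, `run-all`).

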