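# Methods

## The model

`rmesim` models random monoallelic expression (RME) as a binary,
independent, cis-acting activation process. Each allele *a* of a gene is
stably ON in a randomly chosen cell with probability *p₍a₎*, set by the
allele's cis-regulatory complement (its enhancers) and by the trans
environment (genetic background). Assumptions, in decreasing order of
load-bearing:

1. **Binary action.** Enhancers set the *probability* that an allele is
   ON, not the per-cell expression level. Expression level enters only in
   the synthetic staining layer.
2. **Independence.** Alleles of a gene, and alleles across genes, are
   independent — there is no covariance parameter anywhere in the model.
   This yields the product-form quadrants
   ((1−p₁)(1−p₂), p₁(1−p₂), (1−p₁)p₂, p₁p₂), the square-root rule
   p = 1 − √(1 − F_hom) for homozygotes, and the product rule for
   multi-receptor co-expression. Departures are *measured*, not modelled:
   `allele_probs_from_quadrants` reports the independence gap
   (both − p₁p₂) of any observed table.
3. **cis scope.** A lesion in one allele's enhancer changes only that
   allele's *p*. The knockout transform moves the first-allele-positive
   quadrant mass wholesale into the corresponding negative quadrants; the
   hypomorph transform scales it by a measured factor *s* and moves the
   complement (1 − *s*). *s* is supplied per experiment rather than
   estimated jointly — a deliberate two-step design, since *s* comes from
   an independent overall-frequency measurement.
4. **Mitotic stability.** Allelic states are heritable through division.
   The expansion engine's switch rates default to 0; nonzero rates are
   available to explore departures, with P(still ON after g divisions) =
   (1 − r)^g per allele.
5. **Context separation.** The same allele can have different *p* in
   different genetic backgrounds (trans effects, e.g. ~31% in an inbred
   context vs ~19% in an F1 hybrid). Probabilities are tied to a context
   label and never transferred across contexts.

The optional composition p = 1 − Π(1 − eⱼ) over enhancer strengths
(`activation_from_enhancers`) is a model extension for exploration; no
quantitative enhancer-to-p map is claimed.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| `activation_probability` (p) | probability | — (per allele) | the regulated quantity; knockout alleles force p = 0 |
| hypomorph scaling `s` | ratio | — (measured) | mutant/WT overall positive-fraction ratio, e.g. 0.477 |
| `switch_on_to_off`, `switch_off_to_on` | per division | 0 | phenotypes are stable through expansion |
| sort `purity` | proportion | 1.0 | post-sort contamination; contaminants drawn uniformly from the complement |
| staining `negative_log_mean`, `positive_log_mean`, `log_sd` | log intensity (a.u.) | 4.0, 8.0, 0.5 | 8-sigma component separation: gating error is negligible by the Gaussian overlap integral, so frequency errors are sampling-only |
| `allele_count_scaling` | fold | 2.0 | biallelic cells brighter by ×2 (geometric mean), the modest-MFI-shift regime |
| cohort `jitter_sd` | logit SD | 0 | true between-mouse variance of p is unknown; 0 keeps the generator at the model's stated conditions |
| ranking `window` | bp | 2000 | mark signal averaged over a 2-kb window on the peak midpoint |
| `filter_frac` | quantile | 0.05 | drop peaks in the bottom 5% of either mark before ranking |
| ratio `pseudocount` | SPMR | 1.0 | the default of standard coverage-comparison utilities; configurable, and with pseudocount 0 the raw ratio is used (zero-me3 peaks rank first with infinite ratio) |

## Synthetic data: what it emulates and what it does not

The generators exist so every inference input can be produced without any
measured dataset.

* `simulate_population` realises the model exactly: independent Bernoulli
  states, bit-reproducible given (genotype, n, seed).
* `flow.render_events` emulates the two-antibody staining readout:
  log-normal negative/positive components per marker, allele-specific or
  pan targeting, a brighter biallelic component, and a hidden truth column
  for accuracy measurement (dropped by `--blind`). **Not modelled:**
  spectral spillover/compensation, doublets, viability gating, epitope-
  blocking kinetics of the sequential allele-specific/pan staining scheme,
  cell death or proliferation differences between phenotypes.
* `chromatin.generate_tracks` lays classed peaks on a synthetic
  chromosome with log-normal me1/me3 plateau levels per class (enhancer:
  me1 ≫ me3; promoter: the reverse), split into noisy sub-segments.
  **Not modelled:** read-level noise, fragment-size effects, peak-shape
  asymmetry, copy-number or mappability artifacts.

Consequently a green test suite shows the *pipeline* is correct under the
model's own assumptions — product-form quadrants, stable inheritance,
separable staining components, class-ordered ratios. It does not show that
real populations satisfy independence or stability; those are empirical
claims the package is built to test, not presuppose.

## Numerical choices

* **Proportion hygiene.** Inputs within ±0.01 of [0, 1] are clipped with a
  warning (measurement noise); beyond that, an error. Quadrant tables must
  sum to 1 within 1e−9 (model-derived) or 1e−6 (empirical, renormalised on
  read).
* **Goodness of fit.** Chi-square without continuity correction by
  default; the exact multinomial test (full composition enumeration,
  probability-ordered two-sided p) is auto-selected when any expected
  count is below 5 and the total is ≤ 500. Categories with zero
  expectation are excluded; observed cells in such a category are reported
  as an infinite statistic with an explanatory flag rather than an
  arbitrary large number.
* **Mutant-slot convention.** The mutated allele is always the first
  quadrant slot; tables carry explicit column names so a silent swap
  cannot occur. Per-mouse expectations are computed from each mouse's own
  WT-derived quadrants; cross-mouse pooling is the caller's choice.
  Both the raw per-mouse expectations and the cohort means are emitted;
  no uncertainty propagation from the WT measurement is baked in.
* **Ranking conventions.** Quantiles for the bottom-fraction filter use
  linear interpolation and *strict* exclusion, so fully tied inputs lose
  nothing. Percentile = 100·rank/N with rank 1 = highest ratio and average
  ranks for ties, so "top X%" reads percentile ≤ X (ceiling for display).
  Peak midpoints floor on odd lengths; windows clip at position 0 and the
  mean is taken over the clipped length with uncovered bases contributing 0.
* **RNG.** Every stochastic operation takes its own seed;
  `generate_cohort` spawns independent child streams per mouse from a
  master `SeedSequence`, so adding a mouse or a downstream step never
  perturbs earlier draws. Expansion with zero switch rates consumes no
  randomness at all, making exact state inheritance structural rather than
  statistical.
* **Problem sizes.** The bundled checks use 2×10⁵ cells for
  hemizygote-frequency twins (binomial SE ≈ 0.11 pp) and 10⁷ cells for the
  double-negative rate (SE ≈ 0.0008 pp, needed to resolve a 0.06%
  population); the parameter-recovery suite uses 100 replicates of 10⁵
  cells, sized so a 99% Wilson interval has near-nominal coverage.

## Known limitations

* No feedback or allelic-exclusion mechanism is available, by design; the
  model cannot represent genes where one allele's activation suppresses
  the other's.
* The expansion engine is synchronous (fold targets convert to
  ceil(log₂ fold) doublings) and has no death or selection, so it should
  not be used to model growth-rate differences between phenotypes.
* The exact multinomial test enumerates compositions and is limited to
  totals ≤ 500; larger sparse tables fall back to chi-square.
* Event tables are plain TSV, not FCS: the quantities of interest are
  frequencies, and a binary container would add no tested behaviour.
* The element classifier implements ≥1-bp half-open overlap semantics
  only; no fractional-overlap or distance-based definitions.
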