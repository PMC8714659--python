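# Methods

## Model and assumptions

`cernet` operationalizes the competing-endogenous-RNA hypothesis as a
filter chain over paired case/control expression profiles. The underlying
mechanistic assumptions are:

* miRNA repression is driven by seed pairing (miRNA nucleotides 2–7,
  optionally 8, Watson–Crick, antiparallel), so a shared miRNA response
  element can be detected by scanning transcripts for seed-complementary
  sites. Site classes follow the canonical hierarchy 8mer > 7mer-m8 >
  7mer-A1 > 6mer; each matching position is reported once with the most
  specific class its flanks support.
* A true ceRNA pair (noncoding transcript, mRNA) competes for the same
  miRNA, so it should be (i) linked to that miRNA by seed sites on both
  sides, (ii) tightly co-expressed (Pearson r above a strict threshold),
  and (iii) co-directional, with the miRNA moving the opposite way
  (RISC competition).
* In a small paired design the differential-expression screen is the
  classic microarray one: log2 fold change plus a pooled-variance
  Student's t-test on log2 intensities, with raw p gating the flag.

The pipeline makes no attempt to estimate binding affinity
(hybridization-energy alignment is not implemented; the site scorer is a
pluggable surface) and no claim of statistical significance for the ceRNA
triples themselves — the correlation filter is a selection rule, not a
test.

## Parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `fc_log2_threshold` | 1.0 | log2 units; \|log2FC\| > 1 ⇔ fold change > 2 |
| `p_threshold` | 0.05 | two-tailed Student's t, raw |
| `r_threshold` | 0.95 | Pearson r, strict inequality, all samples pooled |
| `ppi_min_score` | 0.4 | STRING combined confidence, inclusive |
| `hub_k` | 30 | top-k nodes by degree |
| `q_threshold` | 0.05 | BH-adjusted Fisher p, inclusive |
| `direction_consistency` | on | RISC direction rule in the triple filter |

The t-test uses the equal-variance (pooled) form by default; Welch is
available via `equal_var=False`. Correlation is Pearson over case and
control samples pooled — pooling maximizes the group-shift signal the
ceRNA model predicts; Spearman is available behind
`correlation_method="spearman"`. Curated miRNA names match
case-insensitively, with an optional `hsa-` prefix and mature-arm
(`-3p`/`-5p`) suffix on the candidate matching a bare curated stem, since
literature lists stems while arrays report arms. G:U wobble is not
accepted in the seed (canonical-site convention).

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults emulate a paired 3-vs-3 profiling study on a
log2-intensity scale: per-feature baselines N(8, 2), a planted |log2FC| of
2.0 for affected features, about 20% of features affected, and 5 planted
ceRNA triples among 100 features (50 mRNA, 20 lncRNA, 20 circRNA,
10 miRNA; transcripts 100 nt, miRNAs 22 nt). Three construction choices
matter:

* **Sign-balanced planting.** Every planted effect is paired with a
  partner feature at an offset baseline carrying the opposite shift, so
  all sample columns share one value multiset. Quantile normalization is
  then exactly the identity at zero noise and fold-change-preserving
  otherwise. This mirrors the regime in which quantile normalization is
  valid on real arrays (balanced, minority changes); without it, the
  normalizer visibly shrinks — and for rank-preserving shifts erases —
  the planted fold changes at desk scale, and no exact ground-truth
  recovery exists. Consequently `frac_de` acts as a floor: triple members
  and their balance partners are always affected, extras are added in
  balanced pairs to approach the requested fraction.
* **Noise-proportional latent co-expression.** Triple members share a
  per-sample latent term (negated for the miRNA) with SD
  `latent_sd_ratio × noise_sd`. At zero noise the members are exactly
  correlated through the group shift alone; at positive noise the latent
  term keeps r near 1 while independent noise keeps it below 1.
* **Seed-clean background.** Background sequence is uniform over A/C/G/U
  conditional on containing no seed match for any simulated miRNA
  (rejection sampling), and miRNAs are drawn with pairwise-compatible,
  non-self-overlapping seeds. The planted-site table is therefore the
  exact truth of the targeting stage: candidacy is gated by planted sites
  only, which is what makes recovery precision exactly 1 testable.

What the generator does **not** emulate: probe-level microarray effects
(background, scanner saturation), realistic transcript length and
composition, sequence conservation, miRNA expression dynamics, or chance
seed sites — all present in real data. Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under its own model, not
expected sensitivity or specificity on real arrays, where seed matches
arise by chance roughly once per 4 kb per miRNA and correlation thresholds
behave very differently with 6 samples.

## Numerical choices

* Quantile normalization breaks ties by stable column order (ordinal
  substitution), which preserves the defining property — every output
  column carries the identical multiset (the row means of the column-
  sorted input) — exactly; tie-averaging variants differ only on tied
  values.
* Zero-variance features in the t-test: equal means → t = 0, p = 1;
  unequal means → the p → 0 limit is recorded (t = ±∞) with a warning,
  avoiding NaN propagation.
* Circular transcripts are scanned on the doubled sequence with
  coordinates reported modulo the length; site windows longer than the
  circle are rejected. Coordinates are 0-based, half-open, on the given
  (sense) strand only. DNA input (T) is mapped to U on load.
* Fisher's exact p is the hypergeometric upper tail P(X ≥ k) via the
  survival function; "q-value" is Benjamini–Hochberg step-up (Storey's
  estimator is not implemented). The universe defaults to the union of
  the collection's gene sets, overridable.
* Hub ranking breaks degree ties lexicographically by gene id, making the
  ranking invariant to input row order. STRING integer scores (0–999) are
  rescaled by 1/1000 with a warning.
* All stage outputs are deterministically sorted; a run manifest records
  per-artifact SHA-256 checksums, and identical config + seed reproduce
  identical checksums.

## Design decisions on genuinely open points

* The fold-change criterion is stated both as "FC > 2" and "|log2FC| > 1"
  in this tool family's source conventions; these are arithmetically
  equivalent on log2 data and the strict inequality is used.
* Whether DE correlation should be computed within groups or pooled is
  open; pooled was chosen (see above), within-group behaviour can be
  approximated with Spearman or by subsetting the matrix.
* Hub ranking implements degree centrality only — the method actually
  used for top-30 selection in this tool family — not MCC or other
  CytoHubba variants.
* The enrichment background and annotation versions underlying published
  figure-level results are generally unstated; enrichment here consumes
  user-supplied GMT collections and makes no attempt to reproduce any
  specific annotation snapshot.
* Problem sizes in the test suite and acceptance script (100-feature
  studies, 20-study replicates, 1,000 oracle pairs, 50 null studies) are
  desk-scale choices that keep the full suite in seconds while leaving
  every statistical check adequately powered; the generator scales to
  larger studies unchanged.

## Known limitations

* No probe-to-gene collapsing, no limma-style moderated statistics, no
  multiplicity adjustment on the DE gate (by design, mirroring the
  classic screen; q-values are reported for transparency).
* Seed matching ignores thermodynamics, 3′-supplementary pairing,
  conservation and CLIP evidence; counts of predicted pairs on real
  transcriptomes will be much larger and noisier than seed classes alone
  suggest.
* The correlation filter with 6 samples has enormous sampling variance on
  real data (r > 0.95 with n = 6 is weak evidence); the pipeline reports
  r but attaches no p-value to it.
* No identifier mapping between protein and gene namespaces in the PPI
  stage; callers must harmonize ids.
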