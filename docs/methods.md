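# Methods

This note documents the statistical procedures implemented in
`consensnet`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical edge-case policies.

## Consensome construction

A consensome summarizes ChIP-Seq evidence for one signaling node across
that node's datasets.  Conventions:

- **Averaging.**  `mean_strength(g) = Σ recorded strengths / n_datasets`,
  i.e. a dataset with no record for a gene contributes 0.  Rationale: a
  dataset in which no peak was called near a gene is evidence of absence
  for that dataset, so it should pull the consensus down rather than be
  ignored.  The alternative (average over datasets where the gene
  appears) would let a gene scored once, strongly, outrank a gene scored
  consistently but moderately.
- **Ranked universe.**  Genes with zero mean strength are excluded from
  the ranked list entirely — they are "not targeted", not bottom-ranked.
  `M` below is the number of ranked (positive-mean) genes.
- **Percentiles.**  `pct(g) = 100·(M − rank(g))/M` with rank 1 the
  strongest gene.  The top gene of 200 sits at 99.5; with `M` divisible
  by 20 the "95th percentile" is exactly the top 5%.  The bottom-ranked
  gene sits at percentile 0, so percentiles live in `[0, 100)`.
- **Ties.**  Tied mean strengths share the averaged rank (for reporting)
  and the tie block's most favorable percentile (for thresholding), so a
  block straddling a cutoff is included or excluded as a whole — no
  arbitrary within-tie selection.

**HCT extraction.**  High-confidence transcriptional targets are the
genes with `pct ≥ cutoff` (default 95).  Because short consensomes can
have even their top gene below the cutoff (at `M = 19` the top gene sits
at 94.7), membership is floored at `ceil((100 − cutoff)/100 · M)` genes:
every non-empty consensome yields its top fraction, and with distinct
strengths `|HCT| = ceil(0.05·M)` exactly.

## Overlap statistics

Each query-set × HCT-set comparison is a 2×2 table in a declared gene
universe `N` (defaults: 30,000 for mouse gene-level tests, a conservative
transcribed-genome estimate; 24,703 for tests against the annotated-gene
universe; the tested-node count for node-level tests).  The p-value is
the exact hypergeometric upper tail `P(X ≥ k)` — one-sided, because the
hypothesis is overrepresentation only.  The unit tests verify the tail
against exhaustive enumeration of all draws for every universe up to
N = 12.

The reported odds ratio is the **sample cross-product ratio**
`a·d/(b·c)`, defined as 0 when `k = 0` and flagged infinite when an
off-diagonal cell is empty with `k > 0`.  Some Fisher-test
implementations report the conditional maximum-likelihood estimate
instead; it is available via `or_estimator="conditional"`, but the
closed-form sample OR is the default because it is reproducible without
iteration and is what the cross-product definition states.  Published
odds ratios from tools whose estimator is unstated are therefore treated
as consistency checks, not exact targets.

`q`-values are Benjamini–Hochberg, always computed across all nodes of
one analysis batch in a single call — never per node — so significance
flags (`q < 0.05`, `q < 0.01`) are comparable across rows.

**Double-log plot coordinates** `x = log10(OR)`, `y = log10(−log10 p)`
spread node sets whose p-values span hundreds of orders of magnitude.
Points with `p ≥ 0.999` or `OR = 0` have no finite coordinates and are
returned flagged as unplottable rather than dropped; `p = 0` is clipped
to a configurable floor (default 1e−300) and flagged.

## Cohort phenotyping and qPCR

- Weight gain is last-day minus day-0 body weight.  The prone cohort is
  the `k` largest gainers, resistant the `k` smallest, from one global
  ordering (descending gain, ascending animal id), which makes boundary
  ties deterministic and overlap impossible.
- Group summaries report mean, SEM, n, and the percent difference
  `100·(mean_A − mean_B)/mean_B`, unrounded and nearest-integer (the
  convention behind statements like "19% more food per day").
- ΔΔCt: `ΔCt = Ct_target − mean(Ct_housekeeping)` (arithmetic mean of Ct,
  equivalent to a geometric mean of expression levels — the aggregation
  is a package choice since conventions differ), `ΔΔCt = ΔCt − mean ΔCt
  of the reference group`, `RQ = 2^−ΔΔCt`.  Adding a constant to every
  Ct (a global rescaling of expression) leaves RQ ratios invariant, and
  the reference group's geometric-mean RQ is 1 by construction.
- The per-gene screen is Welch's unequal-variance t-test
  (Welch–Satterthwaite df, two-sided p) with rejection by the two-stage
  adaptive linear step-up FDR procedure at level 0.10 by default.  A
  Shapiro–Wilk normality check is exposed as an informational gate; the
  screen never branches on it by default.  Zero variance in both groups
  yields p = 1 when the means agree and is an error otherwise.

## Synthetic data: what is emulated, and what is not

The generator plants a complete, recoverable ground truth:

- **Corpus.**  Each node's true targets draw log-normal peak strengths
  (median `target_strength = 10`, sigma `noise_sd`) in every dataset of
  the node; a `background_rate` fraction of other genes draws exponential
  noise (scale `noise_sd`) per dataset.  Log-normal-over-exponential
  gives heavy-tailed, strictly positive scores with a clean
  target/background separation that collapses as `noise_sd` grows, and
  both distributions shrink together in the noiseless limit so top-k
  recovery becomes exact.
- **Differential expression.**  Per gene, `n_prone` and `n_resistant`
  log2-expression samples are drawn around ±half the planted effect
  (`de_effect_lfc`, default 1.0 log2 unit; 0 for null genes) with noise
  `noise_sd`, and summarized by a vectorized Welch t-test.  Fold changes
  and p-values therefore have the correct joint sampling behavior — in
  null mode p-values are uniform by construction, which is what makes the
  downstream FDR calibration test meaningful.  A `driver_enrichment`
  fraction of planted prone genes (default 0.8) is drawn from the driver
  nodes' true targets; this is the planted signal the intersection
  analysis must recover.
- **Auxiliary maps.**  The ortholog map is identity-up-to-case (mouse
  Title-case ↔ human UPPER-case) with configurable dropped and
  one-to-many entries — deliberately exercising the cross-species symbol
  normalization path.  The phenotype set overlaps driver-node symbols at
  a configurable rate; the human weight/BMI-like set (size 157) seeds a
  configurable fraction from planted prone genes.
- **Cohorts.**  Planted prone/resistant animals draw their 14-day gain
  from N(6.3, 0.3) and N(1.3, 0.3) g; the remaining animals draw from an
  intermediate N(3.5, 0.5) g.  The extreme-group means, cohort sizes
  (5 + 5 of 40), course length, and intake means (3.1 vs 2.6 g/day) are
  the published study conditions; the intermediate-animal spread is a
  package choice set so that the extremes are separated but not trivially
  so.  Weights interpolate linearly from a ~19 g baseline with small
  per-day jitter; endpoints carry no jitter beyond the gain draw itself.
- **Determinism.**  Every generator call uses its own stream seeded as
  `(seed, fixed offset)`; identical config + seed reproduce outputs
  byte-for-byte, and adding one generator never perturbs another.

Not emulated: read-level RNA-seq (DE summary statistics are generated
directly), peak calling or genome coordinates, realistic gene-gene
correlation (genes are independent given the planted structure), batch
effects, and library-size artifacts.  Passing recovery and calibration
tests on this generator therefore demonstrates the correctness of the
statistical machinery under its stated model — not robustness to the
correlation structure of real transcriptomes.

## Problem sizes used by the simulation-based checks

The stochastic end-to-end checks run at desk scale, chosen as the
package's own sizes: FDR calibration uses one fixed corpus of 4,000 genes
× 100 nodes (50 targets per node) with 200 replicate null DE tables;
planted-driver recovery uses 100 seeds of a 3,000-gene × 15-node corpus
with 100 planted prone genes at `driver_enrichment = 0.8`,
`de_effect_lfc = 1.0`.  At these sizes the driver's overlap is far above
the null expectation, so recovery measures correctness of the pipeline
wiring rather than borderline power.

## Design choices where the design was open

- **Down-regulation cutoff.**  The derived down-set default is
  `FC < 0.75` (the figure-caption convention) rather than the reciprocal
  `1/1.25 = 0.8` that "FC > ±1.25" would imply; both are parameters, and
  the discrepancy is the reason the default is documented rather than
  silent.  All threshold inequalities are strict, exactly as printed.
- **DE filter p-value.**  The filter uses the unadjusted p (the
  convention of the source tables), never q.
- **Conservation-matrix inclusion rule.**  A node column is retained when
  a query gene is an HCT in *at least one* species (`rule="any"`,
  default) — the natural reading of "at least one of both orthologs is an
  HCT" — with `rule="both"` available; the rule used is recorded in the
  output's metadata.
- **Cross-species universes.**  Gene-level cross-species tests default to
  N = 30,000 but the universe is an explicit argument everywhere and is
  recorded in every output, because overlap p-values are meaningless
  without it.
- **Intake summary window.**  Percent intake difference uses the full
  treatment-course average (mean over days 1..14), matching the
  "average g/day" convention.

## Known limitations

- The two-stage adaptive FDR procedure does **not** universally reject a
  superset of plain BH rejections at the same level: when stage 1 rejects
  fewer than `m·q/(1+q)` hypotheses, the adaptive level
  `q·m/((1+q)·m̂0)` falls below `q`, and knife-edge p-vectors lose
  rejections (measured on ~1.9% of random vectors).  What is guaranteed,
  and property-tested, is equivalence to the literal two-stage
  transcription and dominance over BH at the stage-1 level `q/(1+q)`.
- Sample odds ratios are infinite whenever an off-diagonal cell is empty;
  downstream consumers must handle the flag (the pipeline manifest
  serializes them as JSON null).
- Enzyme-class enrichment needs the class-member count in the full
  annotated universe for a calibrated p-value; when the annotation table
  covers only the intersection genes, the counts `k` and `n1` are exact
  but the p-value depends on the caller-supplied class prevalence.
- The bundled cross-species marker test uses synthetic stand-in gene
  lists (of the published sizes, seeded with the four published conserved
  markers); the full originating gene lists are not redistributed with
  the package.
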