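# Methods

This note documents the statistical model, the numerical choices and the
synthetic data behind the package, including the places where the design
was genuinely open and what the implemented choice implies.

## Gene risk scores

Each omics layer contributes one two-sided two-sample Student's t-test
per gene. Expression and methylation contrast tumor against normal
samples using the design table; the copy-number test contrasts the
expression of samples whose gene-level call is non-zero ("variated")
against the rest, over the samples shared by the expression and CNV
matrices. Each test uses the samples available in its own layer, so the
three matrices need not share an identical sample set.

Choices that matter:

* **Pooled vs Welch.** Classical pooled-variance t is the default
  (`equal_var=True`), Welch is a switch. The pooled test is the textbook
  Student's t; Welch is more robust to unequal group variances but was
  not made the default to keep the canonical behavior.
* **Minimum group size 3** (`min_group_size`). Below that the p-value is
  recorded as missing rather than raising — a gene with too few calls in
  one CNV group simply contributes no `p_cnv`.
* **Zero variance in both groups → missing**, not p = 1: the t statistic
  is undefined there, and treating it as "no evidence" would silently
  promote constant genes.
* **"Variated" means call ≠ 0** by default; `variated_threshold=1`
  restricts to high-level events (|call| = 2).

Per layer, p-values are Benjamini–Hochberg adjusted across genes
(`adjust="fdr_bh"`; `None` disables). Adjusted p-values — not raw —
enter the combination; a raw-p mode is available via the switch.
Fisher's statistic S = −2 Σ ln p is referred to χ² with 2k degrees of
freedom, where k counts the layers actually available for that gene, so
a gene lacking CNV calls is combined over k = 2 layers with 4 df rather
than being dropped. p-values are floored at 1e−300 before logs; the risk
score RS = Φ⁻¹(1 − p_S) is clamped to ±8.2, roughly where the
double-precision normal quantile saturates. Both floors are logged when
hit. The three layers are not independent in real tumors, so Fisher's
independence assumption is knowingly optimistic; a dependence-adjusted
combiner (e.g. Brown's method) is a possible extension, not implemented.

## Activity score and greedy search

The activity score of a gene set is the √n-normalized sum of member risk
scores, AS = Σ RS_i / √n, with n counting only genes that carry an RS.
This is the aggregate z-score standard in greedy subnetwork search and
is the package default (`score_normalization="sqrt"`); the plain mean
(`"mean"`) is available. The choice is consequential: under a plain mean
with a multiplicative improvement rule, adding a gene whose RS equals
the current mean changes nothing, so a module of uniformly strong genes
can never grow past its seed — with the √n normalization, uniform
scores grow until the marginal relative gain √((k+1)/k) − 1 drops below
r, which at r = 0.05 happens at k = 10: exactly the subpathway sizes
the method is meant to produce. The
mean mode is retained because it is the literal reading of "average
risk score", and every search test runs under both.

Expansion starts from seed genes with p_S strictly below 0.001, in
decreasing RS order. Each step evaluates all graph neighbors of the
current set that carry an RS and whose addition keeps the **induced
diameter** (longest shortest path inside the subgraph induced by the
members) at most 3, adopts the AS-maximizing candidate (ties:
lexicographically smallest symbol, for determinism), and accepts it iff
AS_new − AS_cur > r·|AS_cur| with r = 0.05. This sign-safe form reduces
to the multiplicative rule AS_new > (1+r)·AS_cur whenever AS_cur > 0 but
does not invert the bar when the current score is negative; the literal
multiplicative rule is available (`acceptance_rule="literal"`). Distance
can alternatively be measured in the full pathway graph
(`distance_scope="full"`).

After per-seed expansion, identical gene sets are deduplicated, and
candidates of one pathway merge iteratively (fixed point, pairs
processed in id order) whenever their Jaccard index strictly exceeds
0.6. Merged scores are recomputed from the union rather than inherited,
and the distance constraint is *not* re-applied after merging — only the
size filter 5 < n < 100 is. Genes without an RS are never added by the
search: they cannot change the aggregate and would only inflate size.

## Permutation significance

Relabeling genes and rescoring a fixed node set is distributionally
identical to drawing n risk scores without replacement from the label
pool and aggregating them; the nulls are sampled that way (vectorized
argpartition of uniform keys; a loop fallback bounds memory). Test 1
draws from all genes of the whole pathway collection that carry an RS;
test 2 draws from the candidate's parent pathway. Same-size candidates
of one pathway share one pooled local null sample — pooling across
different sizes would conflate different null variances (the null mean
is size-invariant; the variance shrinks as n approaches the pool). Each
null stream is keyed by (master seed, test, subpathway or
pathway-and-size), so p-values do not depend on evaluation order.

The empirical p-value is (M+1)/(N+1) with ties counted into M; it can
never be exactly zero, which keeps BH adjustment meaningful at finite N.
The literal M/N estimator is a switch. Consequence: at N permutations
the smallest attainable p is 1/(N+1), so a both-FDR < 0.001 decision
requires N ≥ 1000; the default is N = 10,000. BH runs across all
candidates jointly, separately per test; significance requires both FDRs
below the threshold (an either-mode flag exists).

## Synthetic data

The generator emulates the structure of level-3 tumor/normal exports:

* **Expression**: per-gene log-normal background (log-mean uniform in
  [1, 3], log-sd 0.5·noise_sd). The planted shift is added on the raw
  scale as effect_size × the analytic background SD, so effect_size is a
  standardized mean difference on the scale the t-test sees. Log-normal
  noise is heavy-tailed — individual small-sample t-tests on RPKM-like
  values are noticeably variable, which is realistic and visible in the
  tests.
* **Methylation**: logit-normal β-values (baseline uniform in
  [0.2, 0.8], latent sd 0.4·noise_sd); the planted shift is applied on
  the latent scale so β stays strictly inside (0, 1). β is simulated
  directly rather than via methylated/unmethylated counts because the
  pipeline consumes β only.
* **CNV**: integer calls in {−2, −1, 0, 1, 2}. Background calls occur
  at rate 0.25 per cell (GISTIC2 gene-level thresholded matrices are
  dense; anything much sparser would be removed wholesale by the
  80%-zero gene filter that the pipeline applies to all three layers).
  Planted genes receive tumor-only gains at `cnv_event_rate` = 0.3, and
  carriers of any call get a linked expression shift — the CNV signal is
  expressed as a call-group expression contrast because that is what
  p_cnv measures.

Defaults are the study conditions used throughout: 1 scale-free pathway
of 100 genes, a planted connected 10-gene module with induced diameter
≤ 3 (chosen deterministically by degree-guided growth), 50 tumor and 50
normal samples, effect size 1.5, seed 0. The complementary fixture
splits the module into an expression-only half and a methylation-only
half (alternating over the sorted gene list), the construction that
separates integrated from single-layer scoring.

What the generator does **not** model: batch effects, tumor purity,
probe-level artifacts, gene–gene correlation beyond the planted module,
and inter-layer dependence of the noise. Passing tests therefore show
the machinery is correct under exchangeable noise with a planted signal,
not that real tumor cohorts behave this way.

## Problem sizes in the tests

The test suite and acceptance script scale the studies to desk size as
their own study design: the planted-module run uses 1,000 permutations;
the integration comparison runs 20 replicates at 10,000 permutations;
type-I control uses 100 (suite) or 50 (script) no-signal replicates of a
30-gene pathway at 2,000 permutations — 2,000 keeps the smallest
attainable p below the 0.001 threshold, so the null check is not
vacuous. Full-module recovery on the complementary fixture is a
stochastic event (≈95% per replicate: a weakly realized signal at a cut
vertex can fragment the expansion below the six-gene floor), so the
suite asserts it for at least 16 of 20 replicates while the
half-containment claims are asserted exactly in every replicate.

## Known limitations

* Fisher's combination ignores inter-layer dependence (see above).
* The greedy search is a heuristic: it has no optimality guarantee and
  the tests verify *trace correctness* (each step was the best
  admissible one), not global maximality.
* Merging can produce gene sets exceeding the search's distance cap by
  design; consumers who need compact regions should inspect
  `merged_from`.
* Isolated pathway nodes cannot be represented in the edge-list format;
  a gene with no relations simply never enters a graph from that reader
  (the KGML reader does keep isolated gene entries).
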