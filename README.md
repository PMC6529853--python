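# icds

Integrative identification of cancer dysfunctional subpathways from gene
expression, copy-number variation and DNA methylation.

Cancer perturbs pathways through several molecular layers at once: a gene
may be silenced by promoter hypermethylation, amplified in copy number, or
simply differentially expressed. Methods that score pathways from
expression alone miss regions whose members are disrupted through
different layers. This package scores every gene across all three layers,
then searches each pathway graph for the *subpathway* — a small connected
subgraph — whose combined gene risk is locally maximal, and attaches
permutation-based significance to it. It is aimed at anyone with
gene-level tumor/normal matrices (RPKM-like expression, methylation
β-values, GISTIC2-style integer calls) and pathway topology as gene-gene
edge lists or KGML.

## Method

**Gene risk score.** For each gene, three two-sample Student's t-tests
give per-layer p-values: tumor vs normal expression (*p*<sub>gene</sub>),
tumor vs normal methylation (*p*<sub>methy</sub>), and expression of
copy-number-variated vs un-variated samples (*p*<sub>cnv</sub>). After
per-layer Benjamini–Hochberg adjustment across genes, the available
p-values are combined with Fisher's method,

  *S* = −2 Σ<sub>m</sub> ln *p*<sub>m</sub>,  *m* ∈ {gene, cnv, methy},

where *S* follows a χ² distribution with 2*k* degrees of freedom under the
null (*k* = number of available layers). The combined p-value
*p*<sub>S</sub> maps through the inverse normal CDF to the risk score
RS = Φ<sup>−1</sup>(1 − *p*<sub>S</sub>), clamped to ±8.2.

**Greedy subpathway search.** Within each pathway graph, genes with
*p*<sub>S</sub> < 0.001 seed a greedy expansion that repeatedly adds the
neighboring gene maximizing the activity score
AS = Σ<sub>i</sub> RS<sub>i</sub> / √*n*, subject to an induced-diameter
cap of 3 and a relative improvement rate *r* = 0.05 (a step must raise AS
by more than 5%). Overlapping candidates from one pathway merge when
their Jaccard index exceeds 0.6; only subpathways with more than five and
fewer than 100 genes are kept. A plain-mean score
(`score_normalization="mean"`) and the literal (1+*r*)·AS stop rule are
available as configuration switches.

**Significance.** Two permutation nulls rescore each candidate's fixed
node set after relabeling genes — over the whole gene universe (test 1)
and within the parent pathway (test 2) — with 10,000 permutations by
default and empirical p = (M+1)/(N+1), M counting permuted scores ≥ the
real AS. Benjamini–Hochberg adjustment runs across all candidates,
separately per test; a subpathway is reported significant when FDR1 and
FDR2 both fall below 0.001.

Single-layer variants (`--mode g`, `--mode cnv`, `--mode m`) run the same
pipeline from exactly one layer, which is useful to demonstrate what the
integration adds.

## Worked example

Everything runs on generated fixtures — no downloads. Create a dataset
(one scale-free pathway of 100 genes, a planted connected 10-gene module
with a standardized shift of 1.5 on all three layers, 50 tumor and 50
normal samples) and run the pipeline:

```sh
icds make-fixtures --out demo/fixtures --seed 7
icds run \
  --expression demo/fixtures/expression.tsv \
  --methylation demo/fixtures/methylation.tsv \
  --cnv demo/fixtures/cnv.tsv \
  --design demo/fixtures/design.tsv \
  --pathways demo/fixtures/pathways.tsv \
  --outdir demo/results --n-perm 1000 --seed 7
```

`demo/results/results.tsv` then contains one significant subpathway:

```
subpath_id   pathway_id  size  AS      p1        p2        FDR1      FDR2      significant
path:s01_1   path:s01    10    25.87   0.000999  0.000999  0.000999  0.000999  True
```

Its ten genes are exactly the planted module (`demo/fixtures/truth.tsv`).
AS = 25.87 is the √n-normalized sum of member risk scores (10 genes at
the RS clamp 8.2 give 10·8.2/√10 ≈ 25.9); p1 = p2 = 1/1001 means no
permutation among 1,000 reached the real score under either null.
`demo/results/risk_table.tsv` holds the per-gene layer p-values and risk
scores, e.g. a planted gene shows p ≈ 0 in all three layers (k = 3,
RS = 8.2) while a background gene shows uniform p-values and RS near 0.

The stage commands `icds riskscore`, `icds search` and `icds significance`
run the three stages separately on intermediate files, and every `icds
run` writes a `manifest.json` (config, seeds, input hashes) that fully
determines the outputs: same manifest, byte-identical results.

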