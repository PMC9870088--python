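# Methods

`hepascreen` implements an integrative screen for transcription-factor-regulated
hepatokines: genes that (i) carry a reproducible ChIP binding site near their
TSS, (ii) sit in loci enriched for GWAS associations with a relevant metabolic
trait, (iii) encode secreted proteins, and (iv) co-express with a composite
readout of the transcription factor's activity. The package ships a synthetic
data generator with a planted ground truth, so every stage of the screen is
testable end to end without the external cohorts the original analysis used.

## Pipeline

### Reproducible peaks

A peak of a replicate's full set is kept when it overlaps (≥ 1 bp by default)
at least one peak in **each** of the replicate's two pseudoreplicates.
Reproducible peaks are pooled across replicates and deduplicated by interval.
An optional reciprocal-overlap fraction is exposed but off by default.
Coordinates are BED-style 0-based half-open throughout; the TSS is a single
base (`start` on +, `end − 1` on −).

### Differential occupancy

Given a peak × sample count matrix with two conditions (≥ 2 samples each):

- **Normalization** — median-of-ratios size factors, normalized by their
  median. Note that no count-scale exact test can be *exactly* invariant to
  rescaling a single library: rescaling one of *m* columns by *c* shifts the
  whole normalized matrix by the unidentifiable global factor `c^(1/m)`. The
  median reference cancels that factor exactly in the generic case (the
  rescaled column carries the extreme factor) and to rounding otherwise.
- **Dispersion** — per-peak method-of-moments on within-condition variation,
  shrunk 50/50 toward the common (mean) dispersion and floored at the common
  value. The floor matters: with 2 residual degrees of freedom the moment
  estimate cannot credibly establish below-ensemble dispersion, and letting it
  fall below the common value manufactures far-tail false positives (measured:
  BH-0.20 false discoveries in 48/50 null datasets without the floor, 1/50
  with it, while the p < 0.05 fraction stays calibrated at ≈ 0.038).
- **Test** — exact conditional NB test on the (rounded, normalized) group sum
  totals. The sum of *n* iid NB(μ, φ) draws is NB(nμ, φ/n); conditioning on
  the two-group total gives the reference distribution, and the two-sided
  p-value doubles the smaller tail (capped at 1). As φ → 0 this reduces to the
  conditional binomial. All-zero peaks get p = 1 and log2FC = 0; q-values are
  Benjamini–Hochberg; `significant` means q < 0.20 by default, mirroring the
  liberal FDR at which the original ChIP analysis reported a null.

### Peak-to-gene assignment

Each peak is anchored at its summit (midpoint when absent) and assigned to the
gene with the nearest TSS if that distance is ≤ 200 kb, ties broken by
lexicographically smallest gene id. Signed distances are strand-oriented
(positive = downstream of the TSS in the gene's reading direction). The
**candidate gene set** takes genes whose assigned peak comes within 20 kb of
the TSS — measured from the peak *interval* (its nearest edge, 0 if the TSS is
inside the peak), so a wide peak qualifies even when its anchor does not.
Whether the original analysis anchored this window on peak edges or centers is
not stated; the edge convention is the permissive reading and is configurable.

### GWAS gene scoring and enrichment

SNPs map to a gene when they fall in `[start − 110 kb, end + 40 kb)` oriented
by strand (the conventional regulatory window of best-SNP gene-set methods; a
SNP may belong to several genes, with no arbitration). The raw gene score is
−log10 of the best SNP p-value. Because longer genes with more SNPs win more
extreme minima by chance, the score is regressed (OLS) on log10 gene size and
log10 SNP count, and the adjusted score is the residual plus the grand mean —
so the mean is preserved and constant covariates drop out gracefully.
LD and recombination covariates of the original method require external maps
and are not modelled.

The set-level test places the cutoff at the 95th percentile (linear
interpolation) of all adjusted scores, counts set genes strictly above it, and
reports (i) the exact upper-tail hypergeometric probability and (ii) a
permutation p-value over random same-size gene sets with the add-one
estimator. The **leading edge** — the genes "contributing to the enrichment" —
is the set genes above the cutoff, sorted by descending score.

Gene-level q-values annotate the leading edge: the empirical p of a set gene
is `(1 + #non-set scored genes with score ≥ s) / N_scored`, BH-corrected
within the set. The tail is computed against the *complement* of the set: if
set members counted in their own tail, the i-th best set gene's p would be
floored at i/N and q < K/N would be unattainable for a K-gene set — the
definition would be vacuous exactly when the set is enriched. Even so, at
human-like gene density every strongly associated locus shares its best SNP
with ~1 neighboring gene through the mapping windows, which keeps gene-level
recovery of a planted 100-gene set around 45% at q < 0.05; this is a property
of best-SNP scoring, not a bug, and is why the screen's leading edge uses the
above-cutoff definition.

### Secretome filter and coexpression corroboration

Leading-edge genes are intersected with the secretome flag table (genes absent
from the table count as not secreted and are logged). For corroboration, the
expression matrix is filtered to genes with mean raw expression strictly > 20,
log-transformed as ln(x + 1) (base and pseudocount are not stated in the
source protocol; natural log with pseudocount 1 is the common choice), and
z-scored per gene with the population standard deviation. The composite
activity vector is the per-sample mean of the marker panel's z-rows; every
gene's Pearson r against it is reported, and each secreted leading-edge
candidate is annotated with its rank in that screen.

The top 5% of correlated genes (ceil, ties broken by gene id) can be tested
against a gene-set library: Fisher-exact (hypergeometric upper tail) p per
set, BH across the library, and a rank-deviation z measuring how much better
the set's p-value rank is than under random same-size queries. The combined
score is `ln(p) × z`, positive when a set is both enriched and better-ranked
than expected. The original tool's precomputed rank-null lookup tables are
replaced by a seeded Monte-Carlo null (default 1,000 random queries); a
degenerate null (zero rank s.d.) yields z = 0, and p is floored at 1e-300
under the log.

## Synthetic world

One global seed fans out to fixed per-generator child streams
(`SeedSequence(seed, spawn_key)`), so adding a generator never perturbs
earlier streams and every generator is byte-reproducible. Defaults, chosen
once as a desk-scale caricature of the real inputs:

| parameter | default | why |
|---|---|---|
| genome | 2,000 genes, 5 × 60 Mb | ~150 kb/gene, human gene density — the 110/40 kb SNP windows assume it |
| gene length | 2–20 kb uniform | compact protein-coding span |
| target set | 100 genes, 1 planted hepatokine | scale of a TF's direct-target complement |
| peaks | width 400 bp, center ~ Normal(TSS, 100 bp) | promoter-proximal binding |
| background peaks | 2 per Mb | matches a few thousand genome-wide sites |
| pseudoreplicate dropout | 0.1 | weak peaks lost in half-depth splits |
| counts | NB, mean ~ lognormal(50), dispersion 0.1 | typical ChIP count overdispersion |
| GWAS | ~3 SNPs/gene ∝ flanked span, p ~ U(0,1] | null background; SNP count confounds the best-SNP score by construction |
| planted GWAS effect | best-SNP −log10 p + Exp(mean = 3) per target gene | `gwas_effect` is the mean shift |
| planted hepatokine boost | deterministic 2 × effect, ≥ 1 SNP guaranteed | ground truth must be recoverable by design, not by a lucky draw; vanishes at effect = 0 |
| expression | counts = round(exp(base + loading·activity + N(0, 0.5))) | markers load 1.0, hepatokine 0.8, 100 extra "activity-driven" genes 0.6; loaded genes share baseline e⁵ ≈ 148 counts, others log-uniform 2–400 so the > 20 filter bites |
| secretome | planted gene + Bernoulli(0.1) | ~10% of genes annotated secreted |

What the generator does **not** emulate: LD between SNPs (each SNP is
independent; enrichment signal is per-locus), fragment-level read structure
(counts are drawn at the peak level), expression covariates/batches, and
ortholog ambiguity (the synthetic world is one namespace; identity mapping).
A green test therefore establishes the pipeline's statistical behaviour under
the stated generative model, not robustness to those real-data complications.

## Numerical conventions and edge cases

- Hypergeometric tails via `scipy.stats.hypergeom.sf(k − 1, ...)`, exact;
  verified against full subset enumeration on populations ≤ 12 at 1e-12.
- Percentile cutoffs use linear interpolation with strict `>` above, so the
  background above-cutoff fraction is ≤ (100 − pct)/100.
- Permutation p-values use the add-one estimator (never zero).
- The exact NB test is computed in log space with a per-row max shift; totals
  of zero give p = 1.
- Gene placement apportions genes to chromosomes by largest remainder and
  rejects capacity overflows; placement is uniform-without-overlap (gaps from
  sorted uniform draws), not clustered.
- Screen reports serialize to canonical JSON (sorted keys, no timestamp) for
  byte-level determinism checks; `--with-timestamp` adds the timestamp.
- Empty pipeline stages do not crash the screen: the report carries an
  `empty_stage` marker and the CLI exits with code 3 (distinct from errors).

## Known limitations

- The null calibration of the set-level test is bounded, not pinned: the exact
  hypergeometric tail is discrete, and at the default sizes (~2,000 scored
  genes, ~100 above cutoff, 100-gene set) the analytic probability of
  p < 0.05 is ≈ 0.028, not 0.05. The test is never anticonservative.
- Gene-level BH recovery is capped by best-SNP sharing between neighboring
  loci (see above); the screen's headline quantity is the set-level
  enrichment plus its above-cutoff leading edge.
- The differential test is a documented NB exact test, qualitatively — not
  numerically — matching edgeR.
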