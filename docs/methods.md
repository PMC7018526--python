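# Methods

## The antisense signal and its null model

In a strand-specific RNA-seq library every read has an orientation relative
to the gene it falls in: *sense* (matches the coding strand) or *antisense*
(matches the template strand). Two technical processes generate antisense
reads where no antisense transcription exists: residual second-strand cDNA
during library preparation flips a read's apparent strand, and genomic DNA
contamination contributes reads that are strand-balanced by construction.

The core statistic treats the strand-flip channel as the null. Let q be the
probability that a read is labelled antisense when no antisense transcript
exists. For a gene with k antisense reads out of n total in one sample, the
one-tailed p-value is

    p = P(X >= k),  X ~ Binomial(n, q)

computed with the exact survival function. q defaults to 0.01, with 0.05
available as a more conservative setting. p-values are Benjamini–Hochberg
corrected and a gene is called significantly antisense-transcribed at
adjusted p < 0.05 (0.01 available). The BH family is all tested genes of a
sample; this is the only choice that keeps samples statistically
independent, and a `global` family is available as a switch. Note the
significance call and the *antisense-enriched* label are deliberately
different things: enrichment is a plain fraction rule, antisense/total >=
0.95 (non-strict), independent of depth.

## Filtering cascade

Sample-wide data set, applied in order: (1) samples with total mapped reads
<= 1,000,000 are dropped (the read total is computed from the count table,
i.e. post-mapping, since raw totals are not an input of the artifact);
(2) only protein-coding (CDS) features are kept; (3) genes with zero counts
in strictly more than 75% of retained samples are dropped (a gene zero in
exactly 3 of 4 samples survives); (4) observations with fewer than 10 total
reads are dropped. Genome-wide data set: additionally, genomes failing
medium-quality MAG criteria (completeness >= 50%, contamination < 10%,
both boundaries exactly as written, so completeness 50.0 passes and
contamination 10.0 fails) are removed globally, and genomes with fewer than
50 genes above the 10-read detection limit are removed per sample. All
filters are idempotent.

TPM treats the sense and antisense counts of a gene as two features in one
per-sample normalization (`combined` mode, default), so a gene's sense and
antisense TPM are directly comparable and sample totals close to 1e6; a
`per_strand` mode normalizes each strand separately.

## Enrichment

Antisense-enriched genes (>= 95% antisense in at least one sample) are
compared against all genes above the detection limit. Each COG letter is a
category; genes with several letters count once per letter; genes without
any letter form an explicit "unannotated" category. Tails of the exact
hypergeometric distribution give one-sided over/under p-values, BH-corrected
across categories separately per tail at alpha = 0.05 to set the direction;
the reported two-sided p is twice the smaller tail, capped at 1.

## Genome covariates and association

Per genome: AT content (ambiguous bases excluded from numerator and
denominator), Pribnow-box density (exact overlapping TATAAT matches on the
forward sequence plus matches of its reverse complement, per Mbp; a
`max_mismatch` option exists for sensitivity analysis, default 0 for
determinism), and per-Mbp sense/antisense counts. The association module
regresses the per-(genome, sample) percentage of significant-asRNA genes on
one candidate at a time — genome and sample as categorical factors (R² is
then the between-group sum-of-squares ratio), AT content, total RNA per
Mbp, Pribnow density and DNA coverage as numeric — and ranks regressors by
R². Confounding is probed by a one-tailed Z-test on the change of a
coefficient between two models, z = (b_adj − b_uni)/sqrt(se_adj² + se_uni²),
treating the two estimates as independent (conservative; no covariance is
available from separate fits). R² gains across communities are compared with
the exact paired Wilcoxon signed-rank test; note that with five communities
its smallest attainable one-tailed p is 1/32 ≈ 0.031, then 0.0625 and
0.09375 — an intermediate value such as 0.08 cannot arise from this exact
paired test, which is a known mismatch with looser "rank sum" usages; an
unpaired alternative is not offered because the design is paired (same
communities, two models).

## Synthetic communities

The generator is the package's test bed and defines the conditions all
calibration checks run under. Per genome: a single contig whose bases are
i.i.d. with P(A)=P(T)=at/2, genes tiled on alternating strands without
overlap (lengths uniform in 300–1500 bp, gaps 20–200 bp), AT targets spread
over 0.35–0.65 by default. Expression theta_i is log-normal(mu=0, sigma=1.5)
— heavy-tailed so a few genes dominate, matching observed cumulative
rank-abundance curves — scaled to a mean depth of 200 reads/gene, with
log-normal library-size variation (CV 0.2). Antisense propensity is a
genome property: pi_g ~ Beta(1, 19) (mean 5%), and every ordinary gene on
genome g has true antisense fraction f_i = pi_g. Three hyper-asRNA genes
per community get f = 0.98 and expression above the 99th percentile,
emulating the handful of genes that dominate antisense pools in real
communities; they are COG-unannotated by default (a config switch assigns
them to one category instead, e.g. X). Counts: n ~ Poisson, antisense ~
Binomial(n, f_i), then every read flips strand independently with
probability q_true = 0.01, then contamination adds Poisson reads with
intensity proportional to gene length × genome DNA coverage, split
Binomial(·, 1/2) between strands and scaled so `rho` equals the expected
contamination share of all reads. Under this model the pooled antisense
fraction of silent-antisense genes has expectation (1−rho)·q + rho/2, which
is what the recovery tests assert.

What the generator does **not** emulate: operon structure and overlapping
genes, positional read coverage (counts are drawn at the gene level),
sequencing-error-driven mismapping, compositional coupling between samples,
and any real COG-function structure. Passing tests therefore demonstrate
the correctness and calibration of the statistics under the stated
generative assumptions, not biological conclusions about real communities.

## Numerical choices

Binomial and hypergeometric tails use exact survival/cumulative functions
(never 1 − cdf subtractions in the far tail). Rank-abundance ties are broken
by gene_id under a stable descending sort. The antisense-fraction histogram
gives exact 0% and exact 100% observations dedicated end bins; interior bins
are left-open/right-closed. A constant response is reported as R² = 0 with a
warning rather than an error. Degenerate inputs (zero-total observations in
the test, genomes absent from metadata) raise immediately; an empty filter
result warns but returns an empty table.

## Problem sizes

Calibration suites run at 10^4 null genes (type-I control), 2×250 genes ×
3 seeds (q recovery), 8 genomes × 80 genes × 4 samples × 10 replicates
(regressor recovery), and 6 genomes × 250 genes × 2 samples per
contamination level — sizes chosen so Monte-Carlo error is small relative
to the asserted tolerances while the whole suite stays fast.

## Known limitations

The counting semantics (>= 1 bp overlap, every overlapped gene incremented,
secondary alignments counted by default with a primary-only switch, mates
counted independently with the mate-2 flip) are one reasonable convention;
tools differ here, and multi-mapped reads in particular are counted once per
alignment. The 1M-read sample filter uses mapped reads. The Pribnow scan is
a motif count, not a promoter prediction — it deliberately ignores the −35
box and spacing. DNA contamination is modelled as perfectly strand-balanced;
real contamination inherits coverage biases the model omits.
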