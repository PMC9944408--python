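# Methods

This note documents the statistical procedures implemented in `rilqtl`,
the defaults they ship with, and what the synthetic-data tests do and do
not demonstrate.

## Population model and genotyping

A RIL genome is modelled as a fully homozygous mosaic of the two parental
genomes (codes MM = 0, PI = 1; residual heterozygosity is not modelled).
Genotypes are called from transcript SNPs in sliding windows:

* **SNP filter.** A site is usable when all replicates of each parent agree,
  the parents differ, and every RIL has a call. Parental-allele assignment
  happens here; downstream everything is MM/PI-coded.
* **Window genotyping.** Windows of `bin_size` SNPs (default 100) slide with
  step 1. The per-line genotype probability is the fraction of informative
  member SNPs matching MM; the call is the majority allele, NA on a tie or
  when fewer than 10% of member SNPs are informative (both configurable).
  The step of 1 SNP maximizes breakpoint resolution; the resulting
  redundancy is removed by collapsing consecutive markers with identical
  genotype columns (NA patterns included). Collapsing is idempotent, and
  member accounting accumulates across repeated collapses.
* **Marker coordinates.** A marker's point position is the mean position of
  its member SNPs; its *span* is first-to-last member SNP. Spans matter for
  eQTL confidence intervals (below). Coordinates are 1-based bp; BED
  exports are 0-based half-open.
* **Recombination and cM.** A recombination is a code change between
  consecutive non-NA markers of a chromosome; NA markers are skipped and
  the breakpoint interval spans the gap. The cM map accumulates
  100 x (recombination fraction) between adjacent markers (Morgan's map;
  Haldane's correction is available via `map_function="haldane"`). The first
  marker of every chromosome sits at 0 cM.

Window genotyping is a low-pass filter: segments shorter than about half a
window are voted away, so the recoverable crossover count depends on SNP
density relative to `bin_size`. The recovery test therefore runs in a dense
regime (24,000 SNPs, 2-SNP windows), where the pipeline count matches the
simulated crossover total within 2%.

## Expression

TPM is computed from counts and annotated gene lengths
(`TPM_gj = (c_gj/l_g) / sum_g(c_gj/l_g) x 1e6`; quantification from
alignments is out of scope — lengths are inputs). Two transforms feed the
statistics: `TPM_log = log2(TPM+1)` for all linear models, and
`TPM_rat = log2(TPM / per-gene mean TPM)` for sample-level PCA. The
per-gene mean is taken over the full analysis sample set (both treatments
together), which is also the set the expression filter applies to: genes
are kept only when TPM > 0 in every sample, jointly across treatments.
After filtering, `TPM_rat` is recomputed on the retained set and is finite
everywhere. PCA is centered, not scaled (the ratio transform already
normalizes per gene).

## Differential abundance

* **Treatment model.** Per gene, a one-factor least-squares fit of
  `TPM_log` on treatment over all samples of both environments — RILs and
  parental replicates alike. Significance from the F test, Bonferroni
  threshold `-log10(alpha/m)`. A gene with zero total variance gets effect
  0 and p 1.
* **Parental G×E model.** On the parental replicates only (2 lines x 2
  treatments x replicates), `TPM_log = T + L + T×L + e` with sum-to-zero
  ±1/2 coding, so coefficients read as log2 differences (treatment:
  HP − LN; line: MM − PI). Per-term F tests are BH-adjusted per term; the
  realized -log10(p) threshold of each term at FDR 0.05 is reported and
  overall significance uses the most stringent (largest) of the three. The
  realized thresholds depend on the data's p-value distribution and are
  not constants of the method.

Sign conventions everywhere: positive treatment effect = higher in HP;
positive line/allele effect = higher with the MM background/allele.

## Heritability and transgression

Broad-sense heritability is `H² = (V_RIL − V_e)/V_RIL` with `V_RIL` the
sample variance over RILs and `V_e` the pooled parental variance (n−1
denominators throughout). This is an upper-bound style estimator; `H²` may
be negative and is reported as computed, NA when `V_RIL = 0`. Transgression
counts RILs strictly beyond `min parental mean − 3σ` and
`max parental mean + 3σ` with σ the pooled parental SD; σ = 0 collapses the
bounds onto the means and is flagged degenerate.

Significance uses per-transcript permutation nulls: the values of one
transcript (RILs plus parental replicates of one treatment) are reshuffled
over the line designations preserving group sizes, the statistic is
recomputed 1000 times, and the 50th highest permuted value is the
threshold; the observed statistic must exceed it strictly. The 50-of-1000
rank is the conventional FDR = 0.05 label for this scan, although it is
closer to a per-test α = 0.05 under the null; on genotype-free synthetic
data ~5% of genes are flagged, which is the calibration the acceptance
suite checks. Thresholds are per-transcript; pooling permutation
distributions across transcripts was considered and not adopted, since the
per-transcript variant makes each gene's threshold self-contained.

## eQTL mapping

Per treatment, each transcript's `TPM_log` over that treatment's RILs
(parental replicates excluded) is regressed on the genotype code at every
marker; the F test gives a -log10(p) profile, and the effect sign is the
MM-minus-PI mean difference. Lines with NA genotype are dropped per marker;
monomorphic markers score 0 with NA effect.

**Multiple testing.** The trait matrix is line-permuted as a whole (one
reshuffle of the line order per permutation, preserving co-expression) and
fully remapped 10 times. Over a descending 0.1-step grid of candidate
cutoffs, RDS = transcripts whose real profile maximum exceeds the cutoff
and FDS = the mean of the same count over permutations; the chosen cutoff
is the smallest with RDS > 0 satisfying

    FDS / RDS <= (m0 / m) * q * log(m),   m0 = m − RDS,  q = 0.05,

with natural log (base-10 available). When no cutoff qualifies the scan
reports "no significant eQTLs" rather than failing. For cross-treatment
comparisons the two cutoffs can be harmonized at the stricter one
(`harmonize`, on by default in the pipeline).

**Peaks and intervals.** One record per chromosome per transcript above
threshold: peak = leftmost argmax marker; the confidence interval is the
contiguous marker run scoring within 1.5 of the peak. Because each marker
genotypes a physical window of SNPs, the interval is reported from the
leftmost member SNP of its first marker to the rightmost member SNP of its
last — with very strong effects the 1.5-drop run can shrink to a single
marker, and the window span is then the honest statement of where the
signal localizes. Secondary peaks within a chromosome are not split into
separate records.

**cis/trans.** *trans* requires the peak at least 1 Mb from the gene
(distance to the nearest gene edge; infinite across chromosomes) *and* the
gene interval outside the peak's confidence interval; everything else is
*cis*. Unannotated genes get type NA with a warning.

## Trans-bands

Trans-eQTL peaks are binned on a fixed 2-Mb grid per chromosome. The null
rate is lambda = total trans count / number of bins in the universe; the
default universe is the marker-bearing bins (peaks can only fall where
markers exist), with `all_bins` switching to the whole physical genome. A
bin is enriched when the Poisson upper tail P(X >= k) < 1e−4; runs of
enriched bins merge across at most one non-enriched grid bin, band bounds
run from the first to the last enriched bin, and band totals include the
gap bins. Counts are reported split by allele direction (+: MM raises the
targets). No permutation null is offered for bands — the Poisson model is
the method.

## Enrichment and overlaps

Upper-tail hypergeometric tests against a declared background (the
expressed genes), BH-adjusted across terms; term annotation is a flat
gene-term table (no ontology-graph propagation). Set overlaps between
environments report the hypergeometric p and the overlap as a percentage
of the union, |A∩B|/|A∪B| x 100.

## Synthetic data

The generator reproduces the *structure* of a two-environment RIL RNA-seq
experiment; defaults follow the reference design: 12 chromosomes of 65 Mb,
49 HP + 52 LN RILs (disjoint sets), 3 parental replicates per line per
environment, crossovers ~ Poisson(2) per chromosome with 80% forced into
the distal thirds (`arm_bias`), biallelic replicate-consistent parental
SNPs, optional missingness and chromosome-specific segregation distortion
(rejection sampling at a mid-chromosome locus; off by default).

Expression follows a latent log2 linear model per gene and sample:
baseline (Normal(5, 1.5) log2 units) + cis effect x genotype at the gene's
own position + environment-restricted hotspot effects + treatment term
(± half the effect per environment) + G×E term + Normal(0, residual SD
0.3). Counts are negative-binomial (dispersion 0.01) around TPM-consistent
means at a library size of 2e6; parental replicates share genotype and
differ only through residual and counting noise. Default effect settings:
30% of genes carry a cis effect of |1| log2, two environment-exclusive
50-target hotspots with sign skew, 20% treatment-affected genes, 5% G×E
genes. Heritability-recovery experiments design `H² = 0.5` by variance
partition (cis effect 0.6 = 2 x residual SD, so genetic variance
`a²/4 = 0.09` equals the residual variance), with low dispersion so
counting noise stays a minor term.

What the generator does **not** emulate: read-level sequencing error,
alignment/quantification artifacts, residual heterozygosity, linked-gene
co-regulation beyond the explicit hotspots, and realistic gene-density or
recombination landscapes. Passing recovery tests therefore demonstrates
the correctness and calibration of the statistical machinery under the
stated generative model, not performance on any particular real dataset.

## Problem sizes and numerical choices

Test and acceptance runs are scaled to make the suites quick while keeping
each estimate well-conditioned: calibration uses ~1100 genes x 1000
permutations; eQTL recovery 100 genes x 50 RILs with 2-residual-SD
effects; FDR calibration five replicate populations of 300 genes; hotspot
recovery 10–20 replicate populations of 150 genes with one 50-target
hotspot; dense-map crossover recovery 24,000 SNPs with 2-SNP windows.
p-values are clipped at 1e−300 before -log10; profile scores cap at 300.
Ties at a window vote are NA; ties at a profile argmax resolve leftmost.
All randomness flows from a single seed through fixed per-stage sub-seeds,
so identical configurations are bit-reproducible and stages can be re-run
in isolation.

## Known limitations

* Single-marker mapping only: no composite-interval or multi-QTL models,
  no kinship correction; closely linked QTLs merge into one record per
  chromosome.
* The permutation-threshold "FDR" labels follow the field convention but
  are per-test error rates under exchangeability, not formal FDR control.
* Marker resolution near centromeres is poor by construction (few
  crossovers), so peaks and bands there can displace by megabases — the
  synthetic tests place their reference hotspots on chromosome arms for
  that reason.
* The unique-marker count and the distinguishable-locus count of a real
  experiment depend on details of the upstream SNP caller that the
  generator does not model; no paper-exact reconstruction of those totals
  is claimed.
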