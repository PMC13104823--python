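# Methods

## Problem and model

The pipeline integrates two gene × sample matrices per cancer cohort:
log2-scale expression (tumors and matched normals) and GISTIC2-thresholded
copy-number calls (integers −2…+2; tumors only after preprocessing). Its
object of interest is the *discordant gene*: a gene lying in a region of
recurrent copy-number loss whose expression is nevertheless higher in
tumor than normal. Under a simple dosage model, log2 expression shifts
roughly linearly with copy number, so genes in lost regions should be
down; genes that instead go up are candidates for transcriptional programs
the tumor needs despite the deletion.

## Preprocessing

Samples are classified by TCGA barcode sample-type code (01–09 tumor,
10–19 normal); an explicit class table overrides this for non-TCGA data.
Tumors must be present in both matrices; normals are kept only on the
expression side, as the comparison group. The expression floor keeps a
gene iff its mean log2 expression exceeds 2.0 in tumor **or** in normal
("not above 2" is read as ≤ 2 → removed, i.e. a strict > test). Means are
arithmetic means of the stored log2 values; missing cells are excluded
from means rather than imputed. Genes are ordered by (chromosome, start,
end, id); a symbol mapping to more than one chromosome in the probemap is
dropped entirely, because a single ordering position cannot be assigned
(multiple loci on one chromosome are merged to their widest span).

## Region calling

Per gene, copy number is summarized as the arithmetic mean thresholded
call across tumors, binned at < −0.4 (loss) / > +0.4 (gain), strict
inequalities. A primary loss region is a contiguous run of
position-ordered genes with run mean ≤ −0.4, at least `min_genes` = 100
expressed genes, and no member at or above the tolerance bound −0.35;
members in (−0.4, −0.35) ride along only while the run mean still
qualifies. Sub-minimum qualifying runs are promoted ("rescued") when their
genomic span is fully contained in another cancer's primary region —
containment, not partial overlap, being the order-free reading of "fully
overlapped".

The scan uses a prefix-sum reformulation (run mean ≤ t ⇔ Q[j+1] ≤ Q[i]
with Q[k] = Σ cna[:k] − t·k) inside maximal tolerance-passing segments,
with a 1e-9 slack so that runs whose mean sits exactly on the threshold
qualify despite float noise. Boundaries were genuinely open design ground:
we report containment-**maximal** qualifying runs (absorbing nested
windows). Two maximal runs can partially overlap only when their union
fails the mean rule (otherwise the union would contradict maximality), so
a union-merge would create a non-qualifying "region"; instead the run with
more genes is kept, ties broken by lower mean then leftmost start. The
greedy scan is never trusted on its own: tests compare it exhaustively
against a brute-force enumeration of all contiguous windows on random
small chromosomes.

## Differential expression and tiers

Welch's unequal-variance two-sample t-test per gene on log2 values (a
pooled-variance flag exists; cohort tumor and normal group variances
generally differ), two-sided, with Benjamini–Hochberg adjustment across
all floor-passing genes of one dataset. Genes with fewer than two
observations in a group are flagged untested and excluded from the
adjustment; zero-variance degenerate genes get p = 1 rather than NaN so
they stay in the bookkeeping. Tier cut-offs: strict = (|log2FC| > 1,
p-adj < 1e-4), relaxed = (> 0.4, < 0.01); a record stores the most
stringent tier met, and strict lists are subsets of relaxed lists by
construction. The genome-wide bin-proportion table instead uses the fold
change alone (±1 log2) — the two cut-off systems are deliberately
separate configuration.

## Overlap and enrichment statistics

Pairwise cancer–cancer overlap of upregulated genes within a shared loss
region uses the upper-tail hypergeometric probability; the universe is the
conservative choice — floor-passing genes analyzed in both cancers and
inside both regions — and pairs are only tested when both lists have ≥ 15
genes. No cross-pair correction is applied (pairs are reported singly).
The local over-representation test is the same hypergeometric with BH
across sets. The common-essential four-bin comparison splits a region's
genes by CE membership × sign of log2FC (zero goes to the T<N class) and
t-tests CE vs other within each sign; the rank-cumulative curve sorts by
descending log2FC (ties by gene id) and reports a Kolmogorov-style max
deviation from the uniform diagonal — the curve itself is the object, the
scalar exists to make tests and comparisons concrete.

## Tag-mix quantification

Relative tag quantity is 2^(Ct_ref − Ct_tumor): one fewer cycle to
threshold means twice the template, and the time-zero mix anchors the
scale. Quantities are renormalized per tumor, which makes the proportions
exactly invariant to per-sample loading shifts (a constant added to one
tumor's Ct values cancels). The 12-cycle common-primer pre-amplification
is treated as tag-neutral and not modeled. Deviation from an even mix uses
the Wilcoxon signed-rank test, two-sided by default, exact when n ≤ 25 and
the magnitudes are tie-free (normal approximation otherwise); differences
exactly at the null are dropped.

## Synthetic cohorts

The generator emulates what the pipeline assumes about real cohorts:
genes laid out on chromosomes, tumor/normal barcodes, planted arm-scale
loss and gain regions, a linear dosage effect, and a planted
copy-number-independent up-program whose members inside loss regions are
the ground-truth discordant genes. Default conditions: 2000 genes on 5
chromosomes; 100 tumors + 20 normals; two 150-gene loss regions and one
gain region at |mean CNA| 0.5; dosage slope 1.0 log2 per copy-number
unit; noise sd 0.5 log2; program effect 1.5 log2 with 5 discordant genes
per region, 60 up-program genes (5 of them inside the gain region so the
program spans all three bins) and 60 down genes; baselines uniform on
(5, 10) log2 with 5% of genes planted below the floor on (0, 1.5).

Copy-number events are arm-level: each planted region draws one call per
tumor shared by all its genes, as GISTIC thresholded calls behave for arm
losses, and by default exactly round(fraction · n_tumors) tumors carry the
event so the realized per-gene mean hits the target; a flag restores
per-tumor Bernoulli carriers. Planted differentially-expressed genes skip
the dosage term — that copy-number independence is the defining property
of the program being modeled, and is what produces the flat
across-bins mean log2FC signature while the all-genes baseline orders
loss < nc < gain.

What the generator does **not** emulate: empirical per-cancer CNA
landscapes, focal deletions nested in arms, library-size or normalization
artifacts, expression–expression correlation structure, and subclonal
(fractional) copy number. Passing recovery tests therefore show the
machinery is correct under the stated model, not that real cohorts are
this clean; on real data the region boundaries and discordant lists
inherit all the noise the generator omits.

## Problem sizes and numerical choices

Tests and the acceptance script run at the default cohort size (2000 ×
120), 10–20 seeds for averaged recovery statistics, 1000 random ≤60-gene
chromosomes for the region-caller/oracle equivalence, enumeration oracles
at universe ≤ 15 (hypergeometric) and n ≤ 12 (signed rank), chosen so the
full suite completes in well under a minute while every combinatorial
code path is exercised. Determinism: every stochastic step takes a numpy
`default_rng` seed; pipeline outputs are byte-identical across re-runs
with the same config.

## Known limitations

- Gain regions are generated and binned but never called as regions (only
  per-gene gain binning is needed downstream).
- The hypergeometric overlap universe on real data is a modeling choice;
  alternatives (genome-wide, union-of-regions) are easy to wire but change
  p-values substantially.
- The exact signed-rank path requires tie-free magnitudes; Ct data rounded
  to coarse precision will silently use the normal approximation.
- `expression_by_copy_number` reports per-group t-tests without multiplicity
  correction across groups; it is a per-gene descriptive view.
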