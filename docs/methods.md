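# Methods

This note documents the models and procedures implemented in `panpop`, the
choices made where the published descriptions leave the design open, and
what the synthetic-data generators do and do not emulate.

## Inbreeding and the SNP-set filters

Rice is predominantly self-pollinating, so heterozygote counts far below
Hardy–Weinberg expectation are the norm and an *excess* of heterozygous
calls at a site is a signature of paralogous mis-mapping. The panel-wide
inbreeding coefficient is estimated as a ratio of sums,
F̂ = 1 − Σ<sub>s</sub> H<sub>obs,s</sub> / Σ<sub>s</sub> n<sub>s</sub>·2p<sub>s</sub>q<sub>s</sub>,
over all polymorphic sites (allele frequencies from called alleles only),
clamped to [0, 1]. The **base-set** filter then removes a SNP with k
heterozygotes among n called samples iff the one-sided exact binomial tail
P(X ≥ k | n, 2pq(1−F̂)) falls below α = 0.05. "Exceeds expectation" needs a
sampling-noise-aware criterion; an exact binomial test is the minimal such
realization, and a per-subpopulation F̂ can be supplied instead of the
panel-wide value.

The **filtered set** keeps SNPs with missing fraction ≤ 0.20 and MAF ≥ 0.01
(MAF computed over called alleles, denominator 2·n<sub>called</sub>). The
**core set** applies two pruning passes at r² > 0.8 with step one SNP: a
10-kb physical window, then a 50-SNP count window over the survivors. The
scan is left-to-right per chromosome; within a violating pair the lower-MAF
SNP is removed, MAF ties removing the right-hand SNP. This tie-break is a
documented choice — pruning tools do not specify which member of a pair they
drop — selected because it is deterministic and preserves informative
(higher-MAF) sites. Nesting core ⊆ filtered ⊆ base ⊆ input is asserted on
every run.

## Distances, trees, ordination, assignment

Two allele-sharing kernels are used on dosage vectors over
pairwise-complete loci: IBS distance d = 1 − (n<sub>IBS2</sub> +
0.5·n<sub>IBS1</sub>)/n, and simple matching (fraction of co-called loci
with unequal dosage). Pairs with fewer than a configurable minimum of
co-called loci (default 50) are errors, not silent NaNs. Trees come from
unweighted neighbour joining (Saitou–Nei, via scikit-bio) with negative
branch lengths clamped to zero; ordination from classical Torgerson scaling
(double-centre −D²/2, eigendecompose, scale eigenvectors by √λ, drop
non-positive eigenvalues), matching R's `cmdscale`.

Replicate admixture Q-matrices are aligned by optimal column assignment
(Hungarian algorithm on column correlations against the first run), runs are
clustered by connecting pairs whose mean aligned column correlation is
≥ 0.9, and the largest cluster is averaged and row-renormalized. The 0.9
cutoff is our choice; the replicate-averaging tools this replaces do not
publish a single canonical setting. Subpopulation assignment applies the
≥ 0.65 rule: the maximal component's subpopulation if it reaches the
threshold, else XI-adm / GJ-adm when the summed XI (GJ) components do, else
admix.

## Diversity statistics

Per-site diversity is the unbiased heterozygosity
(n/(n−1))·2pq over n called alleles; a window's π divides the per-site sum
by the window width (all bases). The full-window denominator matches
genome-scan convention and keeps windows comparable when call rates vary;
a called-sites denominator is available (`denominator="sites"`) because the
original windowed computation does not state which it used. Windows are
0-based half-open internally.

LD decay uses SNPs with subset MAF ≥ 0.10, pairs at most 300 kb apart
(identical positions excluded), r² as squared Pearson correlation of
dosages over co-called samples, 1-kb distance bins, the per-chromosome bin
median, and the mean of medians across chromosomes. Empty bins are missing,
never zero.

A private allele is carried by at least one sample of exactly one
subpopulation; both alleles of every SNP are examined. A doubleton is an
allele with total copy count exactly two, attributed to the unordered pair
of carrier subpopulations; a single homozygous carrier counts as a
within-subpopulation doubleton. Defining doubletons on allele copies (not
carrier samples) is a documented choice — it is the only definition under
which "exactly two copies" is well-posed for a selfer where homozygous
carriers dominate.

## Structural variants

Candidates need ≥ 3 supporting reads and (> 4 split reads OR ≥ 3 discordant
pairs); deletions, duplications and inversions must span 100 bp – 1 Mb,
translocations (inter-chromosomal breakpoint pairs) are size-exempt.
Intervals are half-open, so span length is end − start. Merging links two
same-type candidates when both breakpoints differ by ≤ 1 kb and the overlap
exceeds 50% of the *union* span; "total size" is read as the union because
it is symmetric and stricter than either member's length. Translocations
match on breakpoint proximity alone, with the breakpoint pair canonicalized
by chromosome order. Clusters are single-linkage (the pooled-then-merged
construction implies transitive identity); the representative is the member
with the median start, and output ordering makes cluster identity
independent of input order. Merging is idempotent and order-invariant, both
asserted in tests.

## Pan-genome classification

Presence calling is strict: CDS coverage > 0.95 AND gene-body coverage
> 0.85; a family is present when any member gene is. Classification over
the four major groups: a family present in every accession is **core**;
otherwise each group g with n<sub>g</sub> accessions and k<sub>g</sub>
losses gets the one-sided exact binomial tail
p<sub>g</sub> = P(X ≥ k<sub>g</sub> | n<sub>g</sub>, 0.01); the family is
**distributed** when p<sub>g</sub> < 0.05 in at least one group and
**candidate core** otherwise. The one-sided upper tail encodes "loss rate
significantly larger than 1%"; "not distributed in all types" is read as
non-significant in every group. The partition is exhaustive and exclusive
by construction. Small groups (cB has 10 accessions) are tested like any
other; their per-group power is low and visible in the reported
p-values.

The Freeman–Halton exact 2×K test conditions on both margins and sums
multivariate-hypergeometric probabilities of tables at most as probable as
the observed one (relative tolerance 1e-7, the conventional two-sided
definition). Enumeration runs when the candidate-table count is ≤ 200,000;
beyond that the tail is estimated by seeded Monte-Carlo from the null
(20,000 draws, standard error reported). Benjamini–Hochberg adjustment is
applied across all families within one grouping scheme (major groups, XI
subpopulations, GJ subpopulations — each scheme separately); the reported
balance class uses the precedence major-group > XI-subpop > GJ-subpop >
random.

Accumulation curves permute the accession order (permutation i seeded with
seed+i); step r records families present in ≥ 1 (pan) and in all (core) of
the first r genomes, summarized by per-step mean and 5%/95% quantiles.
Pairwise PAV difference is the symmetric-difference count between two
accessions' presence vectors, averaged within or between groups.

Gene age is the oldest phylostratum (PS1 oldest … PS13 youngest) with a
qualifying protein hit; no hits → PS13, rescued to PS12 when wild-rice
gene-body and CDS coverage both exceed 0.95; a family's age is its oldest
member's. The assembly k-mer model is K = 2·int(0.38·depth + 10) + 1
(truncating int), with a ±2 hill climb on N50 mirroring the published
iteration rule.

## Introgression test

For sample x at a locus, D(x) = d(x, XI) − d(x, GJ), where d(x, S) is the
mean simple-matching distance from x to the members of S over the window
SNPs, excluding x from its own pool (a sample that is its pool's only
member is at distance 0 to it). The GJ threshold is the lower bound of the
99% confidence interval of the *positive* GJ D-values — the positivity
restriction excludes GJ samples that themselves carry XI haplotypes. Two
constructions are provided because the published rule does not specify the
interval: a normal approximation (mean − z<sub>0.995</sub>·sd, sample sd)
as the default, and an empirical percentile mode. An XI sample is called
non-introgressed iff D < 0 AND D < bound; everything else is putative GJ
introgression. Locus windows default to the gene body ± 100 kb (the
published haplotype window width is unstated) and require ≥ 20 SNPs.

## Synthetic data: what it emulates, and what it does not

`syndata` generates the minimal structure the methods assume.
Subpopulation allele frequencies follow Balding–Nichols
(Beta(p(1−θ)/θ, (1−p)(1−θ)/θ) around a shared ancestral p drawn
Uniform(0.05, 0.95)); θ defaults to 0.15 for cohorts and 0.3 for the XI/GJ
introgression pools. Genotypes are drawn with P(het) = 2pq(1−F),
F defaulting to 0.95 (a partially inbred selfer); missingness is uniform at
random (2%). The PAV generator uses the 453-accession high-depth panel
split 303 XI / 92 GJ / 33 cA / 10 cB and the published class mix (53.5%
core, 8.6% candidate core, 37.9% distributed) as defaults; per-accession
loss rates are 0 (core), 0.008 (candidate core — below the 1% null in
expectation yet high enough that a candidate family rarely shows zero
losses across 453 accessions, so the planted mix is recoverable) and 0.08
(distributed). Presence is planted at the family level and expanded to
genes; present genes get coverage 1 − |N(0, 0.01)|, absent genes low
residual coverage, so default thresholds recover the planted states. SV
candidates replay each true event 1+n_dup times with breakpoints jittered
uniformly within ±jitter bp; true spans are 5–50 kb, long enough that the
50%-union-overlap rule holds for any jitter the 1-kb tolerance admits.
Introgression pools are fully homozygous at the locus, with the planted
fraction of XI samples drawing their genotypes from the GJ pool.

None of the generators model recombination, linkage beyond what Balding–
Nichols induces (sites are exchangeable), coalescent genealogies, mapping
or sequencing error, or segmental coverage biases. Passing tests therefore
demonstrate the statistical procedures are implemented correctly and are
calibrated under their stated assumptions — not that those assumptions hold
in any particular real panel.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: cohorts of 75–453
samples, hundreds to thousands of SNPs and families, 10,000 families for
classifier calibration, 200 XI samples for introgression recovery, 1,000
random tables for the exact-test oracle. These sizes give the binomial
bounds quoted in the tests while keeping a full run within a few minutes on
one CPU; all of them scale linearly if larger checks are wanted. Other
numerical conventions: dosage missing code −1; r² undefined (zero variance
or < 2 co-called samples) raises a typed error rather than returning NaN;
distances validate symmetry, zero diagonal and the [0, 1] range on
construction; Q-matrix rows must sum to 1 within 1e-6 and are renormalized
before thresholding, making assignment invariant to row rescaling; BH
adjustment delegates to statsmodels; neighbour joining delegates to
scikit-bio with deterministic input ordering.

## Known limitations

* The Monte-Carlo fallback of the exact 2×K test gives stochastic p-values
  near the enumeration budget boundary; the seed and the reported standard
  error make this reproducible and quantifiable, but p-values within ~2 SE
  of an FDR threshold can flip between seeds.
* The heterozygosity-excess filter realizes "exceeds Hardy–Weinberg
  expectation" as an exact binomial test at α = 0.05; the original
  filtering criterion was described only at this level of detail, so other
  reasonable realizations (e.g. mid-p) would keep slightly different SNP
  sets.
* `align_and_average_q` assumes replicate runs share the same k and sample
  order, and its similarity cutoff (0.9) is a heuristic; badly multimodal
  replicate sets should be inspected rather than averaged.
* Windowed π with the full-window denominator underestimates diversity
  where call rates are low; use the called-sites denominator when
  missingness is structured.
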