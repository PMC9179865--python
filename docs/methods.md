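# Methods

This note documents the models, numerical choices and limitations of
`radpop`, stage by stage.

## In-silico type-IIB digestion

BsaXI recognises the bipartite site `AC-N5-CTCC` (11 bp recognised
span) and cleaves on both sides of it. The exact duplex cut offsets
vary in the literature, so the tag window is a configurable parameter
rather than a hard-coded constant: the default is 12 bp upstream +
11 bp site + 10 bp downstream = 33 bp, a realistic duplex span for a
two-side cutter and the read length the rest of the pipeline assumes
after trimming. Both strands are searched; overlapping matches are all
reported; an `N` in the reference never matches any motif letter
(conservative). Coordinates are 0-based half-open throughout, with
1-based positions only at the VCF boundary.

## Read QC

* Pair merging takes the longest suffix–prefix overlap ≥ `min_overlap`
  (default 10) with mismatch fraction ≤ 0.1, keeping the
  higher-quality base at each overlapped position. This is a plain
  overlap merger, not a probabilistic one: 2b-RAD fragments are short
  and uniform, so near-complete overlaps dominate.
* Trimming removes exact adaptor prefixes/suffixes and then the final
  3 bases (ligation-site artefacts). Reads shorter than 20 bp after
  trimming are dropped.
* The three read filters, applied in order: N fraction **strictly
  greater** than 8%; low-quality (< Q30) position fraction **at
  least** 15%; no recognition site on either strand. The quality
  boundary is stated ambiguously in common protocol descriptions; the
  inclusive reading (≥ 15% removed) is the default here and the strict
  one is a config switch (`lowqual_strict`). The filters are
  independent per-read predicates, so their order only affects which
  filter a multiply-failing read is charged to; the QC report counts
  reads entering the filters as `merged` so that
  `retained = merged − removed_n − removed_quality − removed_no_site`
  holds exactly.

## Genotyping

Reads are trimmed to exactly tag length, which reduces alignment to
Hamming comparison against the tag panel in both orientations with a
2-mismatch budget and no random placement: a read equally close to two
tags is discarded (the conservative reading of "best unique hit
only"). Site discovery flags any tag position where ≥ 2 individuals
carry a non-reference base at ≥ `min_depth` copies; the alt allele is
the most frequent non-reference base cohort-wide, and bases other than
ref/alt at a site are ignored in the allele-depth pairs.

The genotype call is the maximum-likelihood choice among three
binomial hypotheses for the alt-allele read count: hom-ref
`Bin(n_alt | n, e)`, het `Bin(n_alt | n, ½)`, hom-alt
`Bin(n_alt | n, 1−e)`, with sequencing error rate `e = 0.01` and
`min_depth = 5` as defaults (both logged and configurable; neither is
dictated by the statistics — they are conventional desk values for
~30× tag coverage). Depth below `min_depth` yields a missing call. The
call is monotone in `n_alt` at fixed depth by construction.

## SNP filtering

The four retention criteria: (1) call rate ≥ 0.80 — inclusive, so
60/75 individuals exactly qualifies; (2) pooled MAF ≥ 0.01, computed
over all non-missing calls cohort-wide (the retained SNP set is a
single cohort-wide panel, not per-population); (3) exactly two
observed alleles; (4) tags carrying > 2 SNPs are removed atomically.
The three per-site filters commute as set operations; the tag-load
filter is cross-site (removing a site upstream can rescue a 3-SNP
tag), so the pipeline fixes the canonical order (1)→(4) and logs
per-step counts.

Concatenated genotype strings use one character per site: the base for
homozygotes, the IUPAC ambiguity code for heterozygotes (so het vs hom
counts as one difference under p-distance), and `-` for missing.

## Diversity statistics

Per site, with allele frequencies xᵢ (= Pᵢ) within one population:

* He = 1 − Σ xᵢ²; Ne = 1/Σ Pᵢ² (hence He = 1 − 1/Ne per site);
* PIC = 1 − Σ Pᵢ² − Σᵢ<ⱼ 2 Pᵢ² Pⱼ² (= He − 2p²q² for biallelic sites);
* Ho = heterozygous individuals / genotyped individuals;
* π = 2j(n−j)/(n(n−1)) with n non-missing allele copies and j alt
  copies (the unbiased mean pairwise difference, per SNP site — the
  per-site convention matches the magnitude of He);
* HW-P is the exact conditional test: the heterozygote count given the
  allele counts follows
  P(n_het | n, n_A) ∝ n! 2^{n_het} / (n_AA! n_het! n_aa!), and the p
  value sums all configurations no more probable than the observed one
  (monomorphic sites give p = 1).

Population-level values are **unweighted means over sites** with at
least one called genotype in that population; sites with no calls are
excluded from that population's mean. Reporting a single mean exact-p
per population is unusual as an inferential quantity but is the only
aggregation consistent with a per-population "HW-P" around 0.89 on a
mostly low-MAF SNP panel; it is reported as a descriptive index. The
drift coefficient is F = 1/(2·Ne) with Ne the population's mean
effective allele number — reading "F = 1/2 Ne" as 1/(2Ne), the only
interpretation bounded like an inbreeding-style coefficient.

All indicators are reported at 3 decimals, rounded half-even; full
precision is retained internally and in the returned frames.

## Differentiation

F_ST is Weir–Cockerham (1984) θ with the standard per-locus variance
components a (among populations), b (among individuals within), c
(within individuals), combined across loci as Σa / Σ(a+b+c) — ratio of
averages, the form recommended for multi-locus panels. Loci with no
calls in either population or mean sample size ≤ 1 are excluded;
monomorphic loci contribute zero to both sums. The estimator may be
slightly negative under no differentiation; pairwise reporting clamps
negatives to zero before the distance transform.

The companion distance is DR = −ln(1 − F_ST). This transform is
adopted because it reproduces every published pairwise distance from
its differentiation index within ±0.001 (the residual being rounding
of the unrounded source values); it is pluggable if another distance
is preferred.

Neighbor joining is Saitou–Nei with the standard Q criterion; ties
break toward the earliest pair in current join order; negative branch
lengths are clamped to zero with the excess moved to the sister
branch; output is an unrooted (trifurcating) Newick tree. Bootstrap
support resamples string columns with replacement (default 1000
replicates), rebuilds the tree, and annotates each internal
bipartition of the reference tree with its replicate frequency. A
distance matrix that is identically zero (all genotype strings equal)
is rejected rather than silently producing an arbitrary topology.

## Structure

The admixture likelihood is g_ij ~ Binomial(2, p_ij) with
p_ij = Σ_k q_ik f_kj, fitted by plain EM block updates (simultaneous Q
and F updates from expectations at the current parameters), which is
monotone in log-likelihood. Ancestral frequencies are clamped to
[1e−6, 1 − 1e−6]; Q rows renormalise every step; K = 1 has the closed
form f_j = pooled frequency and converges in one effective update.
Plain EM replaces quasi-Newton acceleration deliberately: convergence
is slower but the likelihood surface and optimum are the same, and
desk-scale panels fit in seconds. `tol = 1e−6` on the per-iteration
log-likelihood gain and `max_iter = 2000` are exposed.

K selection masks a random 10% of non-missing genotype entries,
refits on the remainder, and scores the masked dosages against 2·p̂_ij
by mean scaled binomial deviance, repeated `n_replicates` (default 10)
times per K for box-plot data. The meaningful output is the argmin-K
pattern, not the absolute error magnitudes, which depend on the loss
convention. On unstructured data the scan prefers K = 1 with error
increasing in K; on two planted populations it prefers K = 2 — both
verified in the acceptance suite.

PCA standardises each site's dosage by centering at 2p̂ and scaling by
√(2p̂(1−p̂)) (the binomial SD), sets missing entries to zero after
centering (mean imputation), drops monomorphic sites, and takes the
SVD. Scores are U·S; explained-variance fractions are s²/Σs².

## Synthetic-data generator

The generator emulates the target study design and is the test bed for
every downstream claim:

* **Reference**: random uniform background with exactly `n_sites`
  non-overlapping recognition sites planted on random strands; the
  background is rejection-scrubbed (mutating fixed motif positions
  only) until digestion finds the planted set and nothing else.
* **Genotypes**: Balding–Nichols — ancestral alt frequency
  p ~ Beta(α, β); per population, frequency ~
  Beta(p(1−F)/F, (1−p)(1−F)/F) with one global F; dosages ~
  Binomial(2, pop frequency). Defaults mirror the study conditions:
  5 populations × 15 diploids, 45,000 sites, global F = 0.05 (inside
  the reported 0.007–0.094 pairwise band), and Beta(0.14, 1.0)
  ancestral frequencies, a skewed prior giving expected
  heterozygosity near 0.12 before ascertainment.
* **Reads**: one SNP per tag at a random flank position (never inside
  the recognition span, so variant reads keep their site); per
  individual × tag, Poisson(`depth_mean` = 30) reads of the carried
  allele, plus 3 random terminal bases mimicking the ligation
  artefacts the trimmer removes; substitution errors at 0.005/base
  (assigned Q10) and N-masking at 0.001/base (Q2), against a Q40
  baseline.

Everything is deterministic given the single seed; the three
generators draw from independent substreams so each can be rerun
alone.

What the generator does **not** emulate: linkage between sites, indels
and quality-decay error profiles, PCR duplicates, adapter
read-through, per-pair-specific differentiation (one global F only),
and per-population sample-size imbalance. Consequently, passing
recovery tests demonstrate correctness of the estimators under the
idealised generative model, not robustness to real-library artefacts.

## Problem sizes in the test and acceptance suites

Simulation-based checks run at desk scale, chosen as the smallest
sizes at which the targeted effect is unambiguous: F_ST recovery and
null calibration at 5,000 loci × two populations of 50 over 10 seeds;
CV K scans at 300 loci × 60 individuals; the end-to-end genotyping
concordance at 150 tags × 20 individuals at 30× depth; PCA separation
at 5,000 loci; bootstrap checks at 10–50 replicates. The full-study
defaults (45,000 sites, 75 individuals, 1000 bootstrap replicates)
remain the package defaults for real runs.

## Known limitations

* The Hamming-matching genotyper requires reads trimmed to exactly tag
  length; it is not a general-purpose aligner and does not model
  mapping quality or indels.
* The exact HW test is per-site; the per-population "HW-P" is a mean
  of p values, a descriptive convention (see above), not a combined
  test.
* The admixture CV error is a masked-entry deviance; its magnitudes
  are not comparable with fold-based implementations, only the
  argmin-K behaviour is.
* `AlleleFrequencyTable` stores biallelic frequencies; the k-allele
  formulas accept general frequency vectors but upstream discovery
  reduces sites to two alleles before they reach the statistics.
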