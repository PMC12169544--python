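# Methods

## Locus definition and selection

Frames are fixed-width intervals (default 40 bp) tiled start-to-start at the
between-frame distance (default 40 bp, i.e. contiguous and non-overlapping);
a trailing interval shorter than the frame width is dropped so every locus
has identical width, which the haplotyper requires. The contiguous reading
of "between-frame distance" was chosen over a 40-bp-gap layout: it yields a
full tiling consistent with a sliding-frame scan, and no downstream quantity
distinguishes the two on selected loci alone.

A read "spans" a frame when its aligned reference interval contains the
frame entirely, its mapping quality clears the threshold (default 30), and
no insertion/deletion operation of its CIGAR overlaps the frame. A frame is
selected when strictly more than `completeness` (default 0.9) of samples
have at least `min_depth` (default 8) spanning reads. The strict inequality
follows the ">90%" rule; with 38 samples that means at least 35.

Coordinates are 0-based half-open everywhere internally and in BED output;
VCF positions are converted from 1-based on ingest. A SNP at 1-based
position *p* belongs to frame [s, e) iff s ≤ p−1 < e.

## SNP handling

Only bi-allelic single-nucleotide records are ingested; indel and
multi-allelic records are dropped with a logged count. Hard filters follow
the GATK-style site-annotation rules: a record fails when any *present*
annotation violates QD < 2.0, FS > 60.0, SOR > 3.0, MQ < 40.0, or
MQRankSum < −8.0; absent annotations never fail a record (standard practice
for hard filters). Filtering is idempotent and fail reasons name exactly the
violated keys.

A singleton SNP is heterozygous in exactly one sample while every other
sample with data carries one identical homozygous genotype — either
homozygote qualifies as the "fixed" background.

The naive pileup caller exists for synthetic alignments, where positions are
exact by construction: a site is emitted when at least two alleles each
reach `min_alt_fraction` (default 0.2) of some sample's pileup at depth ≥ 8;
per-sample genotypes are het when both the ref and alt allele reach that
fraction of the sample's ref+alt reads, otherwise the majority homozygote.
It performs no realignment or likelihood modeling and is not intended for
real reads.

## Dosage calling

Haplotype frequencies are percentages of the **total** cell read count;
there is no renormalization after removing sub-noise-floor haplotypes
(simplest reading of the 10% floor as a noise gate). With the default
coincident bounds 15/15/85/85 every frequency maps to a dosage; if a user
separates the bounds, a frequency inside an undefined gap voids the whole
cell rather than guessing. Diploid correctness means dosages sum to 2; the
correctness requirement is enforced as a flag (and later a mask), never by
truncating alleles. Cells failing correctness inside retained loci are set
missing downstream. Loci with zero SNPs yield a single monomorphic
haplotype (`ref`, dosage 2) and pass through filtering, since locus tables
legitimately contain single-allele loci. Base qualities are not consulted;
only mapping quality gates reads.

Per-sample heterozygosity is the fraction of a sample's non-missing correct
cells carrying ≥ 2 distinct haplotypes; a sample with no usable cells
reports missing, not zero.

## Relatedness and trees

JID is computed globally over (locus, haplotype) presence items
(dosage ≥ 1), not as an average of per-locus Jaccard values; dosage
magnitude does not weight the computation. Loci missing in either sample of
a pair are excluded for that pair only (pairwise-complete), which maximizes
data use. Bootstrap replicates resample loci with replacement to the
original locus count — node support concerns marker sampling variance —
and are computed by re-weighting per-locus intersection/union tallies, so
replicate matrices are exact.

Neighbor-Joining is the Saitou–Nei agglomeration with the standard
Q-criterion and two-point branch-length formulas. Ties on Q are broken by
the lexicographically smallest current-index pair, making output
deterministic; negative branch-length estimates are clamped to zero with
the clamped total logged (how the published workflow handled negatives is
unstated, so the common convention is used). Bipartition support ignores
branch lengths. Trees are dendropy objects; Newick round-trips preserve
topology, lengths to 1e-9, and support labels exactly.

## Population-genetic estimators

H<sub>s</sub> is the Nei–Chesser sample-size-corrected gene diversity
ñ/(ñ−1)·(1 − Σp² − H<sub>o</sub>/2ñ); reported "expected heterozygosity" is
this H<sub>s</sub>, following the hierfstat convention. Pairwise
F<sub>ST</sub> is Nei (1987) (H<sub>t</sub> − H<sub>s</sub>)/H<sub>t</sub>
with the two-population Nei–Chesser corrections
(H<sub>t</sub> = 1 − Σp̄² + H<sub>s</sub>/2ñ − H<sub>o</sub>/4ñ, ñ the
harmonic mean of the two sample sizes), averaged over loci as a ratio of
averages — the standard multi-locus behavior. Note the small-sample
correction means two populations with identical frequencies give exactly 0
only where H<sub>o</sub> = 4p̄q̄ (e.g. all-heterozygote panels); otherwise
permuted-label F<sub>ST</sub> is near zero with O(1/n) bias, which the
permutation test bounds at |mean| < 0.01.

π windows anchor at position 0 per contig, without overlap; the mean over
windows is unweighted over windows containing at least one SNP. Monomorphic
windows are omitted rather than zero-filled, matching the per-window
averaging convention.

PCA mean-imputes missing genotypes per column, centers, and does not scale
columns to unit variance (the cited workflows' default; with low
missingness the imputation choice is immaterial). The decomposition is an
exact SVD.

## Synthetic cohort generator

The generator emulates the study design: two diverged species with nested
subpopulations, ~20–38 diploids, 150-bp reads at 10–100× depth. Defaults
are 2 species × 2 subpopulations × 5 samples = 20 diploids over 2 × 50 kb
contigs at 30× — a deliberate scale-down of the real 425.7-Mb genome that
keeps a full run under a minute while leaving thousands of loci, enough to
make the three-level JID hierarchy and the F<sub>ST</sub>/PCA contrasts
statistically unambiguous.

Polymorphic sites arise at `snp_density` (default 0.02). A
`species_divergence` fraction (default 0.3) of them is fixed-different
between species; the remainder segregates at a shared frequency drawn
Uniform(0.1, 0.9) (intermediate frequencies, as fully shared rare variants
add little signal). Subpopulation frequencies perturb the species frequency
with Normal(0, `subpop_drift`) noise (default 0.08, a modest drift giving a
within- vs between-subpopulation JID contrast of a few percent), clamped to
[0, 1]; genotypes are binomial draws phased onto two chromosome copies.
`admixture_fraction` lets species-B subpopulations draw that fraction of
sites from the species-A frequency (default 0, matching the weak-admixture
baseline). Per contig, read count is Poisson(depth·L/read length) with
uniform starts, so genome-wide mean depth is unbiased; each read copies one
phased chromosome at every covered site and then applies uniform miscalls
(`error_rate`, default 0.001). Truth-VCF annotations come from two labeled
mixtures — pass-like values comfortably inside the hard-filter thresholds,
fail-like values violating one — with `annotation_fail_rate` (default 0.05)
choosing the mixture, so the filter stage sees both outcomes.

All randomness flows from one root seed through crc32-keyed child
generators per stage and sample; identical configs give byte-identical
FASTA/SAM/VCF output.

What the generator does **not** emulate: alignment errors (reads are
emitted pre-aligned with exact positions and full-match CIGARs — mapping
correctness is out of scope), indels, paired-end inserts, non-uniform error
profiles, LD beyond the site-frequency hierarchy, and reference bias.
Passing tests therefore demonstrate the correctness of locus selection,
haplotype extraction, dosage logic, and the estimators — not robustness to
mapping artifacts in real data.

## Numerical and degenerate-input choices

* Strict inequalities for completeness/correctness thresholds (">90%").
* Empty alignment → spanning depth 0; zero samples or an empty dosage
  matrix are errors, not silent empties.
* JID with no shared-data loci is missing (NaN), as is F<sub>ST</sub> for a
  population of one; a sample with no haplotype data reports missing
  heterozygosity rather than 0.
* Exact-recovery checks run at 60× error-free coverage: with ≥ ~40 reads
  spanning a frame, the probability that a true 50% haplotype falls below
  the 15% dosage bound is negligible (< 1e-6 per cell), so noiseless
  recovery is deterministic in practice at that depth.
* Test problem sizes: oracle-equivalence suites use ≤ 5-locus/≤ 10-sample
  instances against brute-force formula evaluation; recovery runs use 12
  samples × 100 kb; structure recovery uses the 20-sample default design
  with 200 bootstrap replicates.

## Known limitations

The naive caller requires the alt allele to be observable in some
sufficiently covered sample; sites fixed non-reference across the whole
cohort are invisible to it (and to any pileup caller without a joint
reference panel). Frame-level haplotypes cannot phase across frame
boundaries by design. The TSV dosage format cannot distinguish a
missing cell from an all-zero cell at a locus where a sample has no listed
haplotype; readers return such cells as missing. F<sub>ST</sub> and
F<sub>IS</sub> inherit the small-sample behavior of the Nei–Chesser
corrections discussed above.
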