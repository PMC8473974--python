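# Methods

This note records the models behind `allopanel`, the defaults that
matter, and the choices made where the design was genuinely open. It
states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

Point variants are 1-based inclusive (VCF convention); intervals, bins
and windows are 0-based half-open (BED convention). The composition
BED → internal → VCF is the identity and is property-tested. The VCF
support is a deliberately minimal dialect — GT (diploid only) plus
INFO/MQ, unknown INFO text carried opaquely — because the pipeline needs
nothing else and exact round trips are part of the contract. Intensity,
call-matrix, cluster-file and probe-manifest formats are plain TSV/CSV
dialects documented in `allopanel.io`; floats are serialized at full
precision (`%.17g`) so that write→read is lossless and repeated runs are
byte-identical. Probe flanks are always stored on the reference forward
strand; no reverse-complement bookkeeping.

## Candidate screening

The re-sequencing screen applies, in order: biallelic; MAF ≥ 0.05 **and**
mapping quality ≥ 30; minor allele carried by ≥ 10 samples (a carrier is
any sample with ≥ 1 copy — the natural reading of "present in N
varieties"); no other SNP within 50 bp (boundary inclusive: a neighbor
at exactly 50 bp disqualifies); probe-context uniqueness (below). The
neighbor universe for the clean-flank rule is the *input* site list — a
SNP removed by an earlier rule still disturbs a flank. The probe-QC
screen applies call frequency > 0.8 (strict), cluster separation ≥ 0.15,
MAF > 0.05 (strict — the two screens genuinely differ in strictness and
both are followed to the letter), uniqueness, then the 200-bp spacing
rule (a gap must exceed 200 bp; the lower-MAF probe of a violating pair
is dropped). Audits record (rule, in, removed, out) at every step and
conservation is machine-checked.

## Probe-context uniqueness

A competing match is any genome offset, other than the probe's own
locus, where the full 101-bp context (50-bp flanks + SNP base) aligns
ungapped with identity ≥ 85% (≤ 15 mismatches). Full-length ungapped
identity replaces a raw local alignment criterion because the best local
alignment of a short probe almost always contains a tiny perfect match
at 100% identity, which would make an identity threshold meaningless;
requiring the match to span the whole context is the stable surrogate
for a BLAST-style screen. Candidate offsets come from exact seed hits:
on genomes up to 2 Mb the seed length satisfies the pigeonhole bound
(6-mers for 15 mismatches over 101 bp), making the search provably
exact; larger genomes use 16-mer seeds, a documented heuristic that
finds every near-duplicate sharing one exact 16-mer. The test suite
checks the seeded search against a dense every-offset scan on a 100-kb
genome with planted duplicates straddling the boundary.

## LD grouping and panel selection

r² is the squared Pearson correlation of allele-dosage vectors over
pairwise-complete samples — the standard phase-free estimator for called
genotypes; haplotype EM r² is intentionally not used. Grouping within a
100-kb bin is a greedy star partition: the unassigned site with the
highest MAF (ties → smaller position) becomes a representative and
captures every unassigned site with r² ≥ 0.65 to it. Groups never span
bins. Selection per bin targets min(5, number of eligible LD groups),
at least 1, where eligible means design score ≥ 0.6; bins overlapping a
QTL interval widened by 150 kb on each side have the target raised to 3
(the maximum of the two rules). Within a bin, picks go by MAF descending,
one per group until every eligible group is represented, then recycle.
A final global spacing pass re-applies the 200-bp rule. An independent
checker (`validate_panel`) re-verifies score, caps, spacing and group
usage on every emitted manifest.

The design score is a documented deterministic surrogate for a
proprietary assay-design score: start at 1.0, −0.2 for GC outside
[0.30, 0.70], −0.2 per disjoint 6-bp homopolymer stretch, −0.5 for any
ambiguity character, floored at 0. Only its thresholding role (≥ 0.6)
matters downstream.

## Calling engine

θ = (2/π)·arctan(Y/X) ∈ [0, 1], R = X + Y; X = Y = 0 is the no-signal
sentinel. Because θ is an arctan of the allele-signal ratio, the ideal
cluster positions of the 5-dosage scale are the arctan image of dose
fractions {0, ¼, ½, ¾, 1}, i.e. {0, 0.205, 0.5, 0.795, 1}; the call map
assigns clusters to the ordered grid subset minimizing total distance,
which guarantees dosage monotone in θ.

Per-marker fitting: 1-D Gaussian mixtures, k = 1..5, spherical
covariance, `reg_covar = 1e-6`, chosen by BIC (ties to smaller k). For
each k the EM is started both from evenly spaced θ quantiles and from
every ordered canonical-grid subset — quantile starts alone miss rare
extreme clusters (e.g. a handful of BBBB samples). Fitted components
closer than 0.1 in θ are merged and all cluster parameters are
recomputed from the hard assignments: channel clipping at zero puts a
point mass at θ = 0/1 that would otherwise split a boundary cluster.
Cluster σ is floored at 0.01 — clipping deflates the empirical σ of
boundary clusters, and without the floor genuine members beyond the
3-σ call radius become spurious no-calls; 0.01 is small against the
0.205 minimum canonical spacing. Everything is deterministic given the
data.

Marker taxonomy: *no-signal* if the marker's median R is below
background; *monomorphic* (k = 1); *polymorphic_3* (k ∈ {2,3});
*intergenomic_5* (k ∈ {4,5}, homoeolog blending); *unclassifiable* when
cluster separation < 0.15 or the quality score < 0.5 — the
"could not genotype correctly" bucket. The background floor is
max(10% of the panel-wide median R, 0.05): the relative term survives
arbitrary rescaling of a normal panel, the absolute term (on the
normalized scale where full signal ≈ 1) catches the degenerate all-dark
panel that a purely relative rule cannot. The quality score is a
GenTrain-like surrogate: the mean silhouette of the hard θ assignments
rescaled to [0, 1], threshold 0.5; it is calibrated only to preserve
ordering, not to reproduce any proprietary value. Cluster separation is
the minimum gap between ±2-σ envelopes of adjacent clusters (1.0 for
k < 2, floored at 0).

Calling new samples: nearest cluster by |θ − μ|/σ; no-call if the
minimum exceeds 3, R is below 10% of the marker's mean cluster R, or θ
is undefined. Cluster files retain everything except no-signal and
unclassifiable markers; the audit identity retained + no-signal + poor =
input is enforced by the data type itself.

## Synthetic data: what it emulates and what it does not

The generator is the test bed standing in for a large re-sequenced
population; its defaults are the study conditions of the test suite.

*Populations.* Chromosomes are random sequence; sites are uniform with
density `snp_rate` (default 1/1500 bp). MAF targets are drawn from
0.5·Beta(0.8, 2) (a rare-skewed spectrum). LD comes from founder
mosaics: 8 founders, deterministic 20-kb block tiling, each haplotype
copying one founder per block. Within a block, founder alleles share one
frequency ranking (complete-D′ structure), so sites with similar
frequencies are in near-perfect r² while frequency-mismatched sites are
not — giving realistic group sizes — and founder allele frequency still
tracks the target MAF. Two closed-form limits anchor the model and are
tested: two founders and one block give r² = 1 for every polymorphic
pair; one-site blocks give independent sites with mean haplotype r²
≈ 1/(2n). The generator makes no attempt at coalescent realism,
demography, or any particular species' diversity.

*Crosses.* F1/F2/BCnF1 by gamete formation with Poisson crossovers.
The default cross recombination rate, 2 × 10⁻⁶ per bp per meiosis, is a
desk-scale convention: the 10-Mb toy chromosome is physically compressed
relative to a real one, and this rate keeps the genetic map resolvable
at the fixed 1-Mb scan window, so a consensus-bulk scan localizes a
causal locus to about one window — the behavior the downstream test
measures. It is not a physical per-bp rate.

*Intensities.* E[X] ∝ A-allele dose, E[Y] ∝ B-allele dose, summed over
both subgenome loci for the `homoeolog_fraction` (default 0.30) of
markers whose shadow locus is polymorphic (frequency ~ U(0.2, 0.8));
`no_signal_fraction` (default 0.13) of markers emit only background
(0.05 of full signal). Channel noise is Gaussian, σ = 0.01 in units of
the full signal (1.0), truncated at 0. The noise default encodes the
qualitative sensitivity the platform demonstrates — a ~3% transgene
admixture separable from negative controls while ~1% is not — and puts
θ cluster widths near 0.01, typical of a well-behaved assay. The truth
object records, per marker, the noise-free θ levels and the call codes
an ideal caller would emit; "accuracy vs truth" therefore measures
noise robustness, not the (unidentifiable) latent dosage of a blended
marker. What passing tests show about real data is correspondingly
limited: real intensities have affine channel distortions, sample-
quality variation and outlier clusters that this model does not emulate;
the engine's normalization-free design assumes upstream channel
correction has been applied.

*Dilution series.* A d:1 negative:positive mix carries positive-DNA
fraction 1/(1+d); the transgene-channel mean interpolates between
background and full signal by that fraction. The *reported* percent
genetic modification uses the positive-relative-to-negative convention
100/d (30:1 → 3.3%), which is the convention under which the printed
3.3% figure is exact; the physical fraction 100/(1+d) would give 3.2%.
The detector calls a ratio positive when a one-sided Mann–Whitney test
against ≥ 8 negative controls rejects at α = 0.01 *and* the median test
signal exceeds the negatives' 99th percentile; the guard controls the
false-positive rate where the rank test alone is anti-conservative at
small shifts. The test choice is a package convention — no specific
test is canonical for this screen.

## Downstream analyses

Bulks are represented as majority-consensus calls per marker (ties and
all-NC → NC), matching how pooled DNA is genotyped as a single array
sample; pool allele-frequency modeling is out of scope. Differential
scans count markers with different non-NC calls per 1-Mb window (ties
for the peak go to the leftmost window); scan conservation (window sum =
total differences) and symmetry are property-tested. Variety comparison
reports its denominator (markers called in both samples) explicitly
rather than assuming any particular panel size.

## Problem sizes and determinism

The shipped suites run the design path on a two-chromosome 10-Mb genome
with ~96 samples (~3,500 candidates after filtering), genotype recovery
on 500 markers × 192 samples, bulked-segregant localization on 100
replicate crosses of 200 BC2F1 offspring, and the dilution series with
24 replicates per ratio — sizes chosen so the whole study re-runs on one
CPU in minutes. All randomness flows from a single seed through named
child streams; identical configuration and seed reproduce every output
file byte-for-byte, which the suite asserts end to end.

## Known limitations

No IDAT/GTC/BPM binary compatibility; no affine intensity normalization
(assumed upstream); no haplotype-phase LD; no E-value-based duplicate
screen (the identity criterion replaces it); bulk scans use consensus
calls, not allele-frequency indices; the intergenomic 5-dosage model
assumes exactly one interfering homoeologous locus with equal per-copy
gain, while real probes can see more loci with unequal affinities.
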