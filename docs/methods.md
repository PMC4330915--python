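# Methods

## The coverage model

The observed depth of coverage at a position is modeled as the product of a
genome-wide sequencing depth, a locus-specific expected-coverage effect
shared by all genomes run through the same technology, a per-genome bias
that depends on local base composition (%GC), the local copy number, and
Poisson counting noise. None of the locus effects need to be explained
mechanistically: the method treats them as an empirical field to be
measured from a cohort and divided out, which is why a *reference coverage
profile* (RCP) learned from many genomes outperforms any single-genome
normalization.

## Condensed coverage representation

Coverage is stored as one byte per non-overlapping 20-bp window (the
arithmetic mean of the window's per-base depths, a scale at which coverage
is strongly autocorrelated, so little information is lost). Three regimes:

* 0–200×: stored exactly (window means round half-up to an integer);
* 200–2700×: `int(sqrt(c − 200) + 200)`, bytes 201–249;
* ≥ 2700×: sentinel byte 255 plus a sidecar record holding the unrounded
  mean at full resolution. Bytes 250–254 are reserved.

Decoding a square-root-regime byte returns the midpoint of its integer
preimage interval, which minimizes the worst-case absolute error; the error
is bounded by `2·sqrt(max(v − 200, 0)) + 1` and is verified exhaustively in
the tests. The boundary value 2700 itself goes to the overflow sidecar,
keeping the in-byte range closed. The binary layout is a fixed header
(magic, version, window size, chromosome table) followed by concatenated
byte arrays; random access is by computed offset, so region queries touch
only the bytes they need. Terminal partial windows average over their
existing bases only, avoiding systematic deflation at chromosome ends.

## %GC stratification

The genome is cut into 1-kb bins and each bin's GC fraction is computed
ignoring Ns; bins that are more than half N are masked and excluded
throughout. Bins are stratified into 25 buckets **by rank** — cutoffs are
the k/25 type-1 empirical quantiles (the ceil(k·m/25)-th smallest value) —
so every bucket spans ≈ 1/25 of the genome and no correction is estimated
from a sparse extreme-GC tail. A value equal to a cutoff belongs to the
lower bucket. Cutoffs are always recomputed for the reference in use; a
preset of GRCh37 1-kb cutoffs (30.1 … 56.0 %) ships for users who want the
published stratification, with one adjacent printed pair reordered to keep
the sequence monotone.

## Cohort scaling

A genome's *characteristic coverage vector* is its total autosomal decoded
coverage per GC bucket, excluding overflow windows (autosomes only, to
avoid sex-chromosome and mitochondrial artifacts). The cohort *target
vector* is the entry-wise geometric mean (computed in log space; genomes
with a zero entry are dropped from that entry's mean with a warning, since
a single zero would annihilate a geometric mean). Scaling multiplies each
1-kb bin by `target[bucket] / own[bucket]`, which equalizes the genome's
per-bucket totals to the target exactly. Note this removes the per-genome
GC-bias curve *exactly* when the bias is constant within a bucket, and it
makes the scaled profile invariant to the genome's overall depth — the
property the scale-invariance checks exercise through the full byte-encoded
path (deviations there are pure decode quantization, < 2 % of diploid). A
`literal_divide` flag provides plain division by the target entry for
users who want an unadjusted ratio; it does not remove the genome's own
depth and is not used by the pipeline.

## Diploid-level estimation (the RCP)

Per 1-kb bin, across up to 500 genomes:

* **Median path.** If MAD/median ≤ 0.15 *and* fewer than 20 % of genomes
  deviate from the median by more than 20 % of it, the level is the median.
  The second trigger matters because the MAD is blind to any minority
  cluster smaller than half the cohort — e.g. hemizygotes at allele
  frequency 0.2, or the non-modal genotypes of a common duplication where
  the homozygote is the majority (MAD ≈ 0 there).
* **Peak model.** Otherwise, scaled values are assumed to cluster near
  integer multiples of a haploid level *h*. A geometric grid of 200
  candidates (from max/6.5 to max) is scored by

  `score(h) = Σ_i log N(x_i; k_i h, σ²) − λ·χ²_HWE − λ_mix·min(n₋, n₊) − λ_triv·n·[no genome ≤ diploid]`

  with `k_i = round(x_i/h)` capped at 6 copies. Three deliberate choices:

  1. **σ is anchored to the data, not to h** (σ = 0.12 × the median of
     clearly positive values). If σ were proportional to h, every integer
     submultiple of the true level would fit the clusters equally well with
     ever narrower, higher-likelihood Gaussians and the search would
     collapse to aliased solutions; with fixed σ, aliases tie on likelihood
     and the priors decide.
  2. **The HWE χ²** compares the implied genotype counts (copies {0,1,2}
     for a deletion allele, {2,3,≥4} for a duplication allele, each at its
     own implied allele frequency) against Hardy–Weinberg proportions,
     penalizing genotype configurations no segregating biallelic CNV could
     produce.
  3. **Two priors close the χ²'s blind spots.** Readings that imply both a
     deletion and a duplication allele at one locus (e.g. copies 0/3/6) can
     tie the truth on likelihood and beat it on χ² by sampling noise; they
     are charged per genome on the minority side of diploid. And the
     "everyone homozygous-duplicated" relabeling — which halves the level —
     has implied allele frequency 1 and is therefore HWE-silent; readings
     with no genome at or below diploid are charged λ_triv per genome.

  After the grid search, if the most abundant non-zero cluster is not copy
  2 the solution is re-anchored so that it is, unless the re-anchored score
  is worse (this keeps the correct answer in the regime where hemizygotes
  are modal and the nullizygous cluster is the largest peak). If the final
  reading still implies variants on both sides of diploid the bin falls
  back to the median with a warning.

Bins supported by fewer genomes than min(20, cohort size), or missing in
more than half the cohort, are masked. Per-bin MAD and the method flag
(median / peak-model / masked) are stored alongside the level.

Parameter defaults (dispersion trigger 0.15, cluster CV 0.12, λ = λ_mix =
λ_triv = 2.0, 200 grid points, copy cap 6) were validated by parameter
recovery on simulated cohorts — 200 genomes × 5000 bins with CNV loci at
allele frequencies 0.05–0.8 of both types — not taken from any external
source; the recovery suite requires the level within 5 % on ≥ 95 % of
clean bins and within 10 % on ≥ 90 % of CNV bins, including the aliasing
case where variant carriers are modal.

## Normalization and segmentation

The normalized coverage profile is `100 × scaled / level` per bin, masked
where the RCP is masked or the level falls below 10 % of its genome-wide
median (dropout regions, where the ratio would explode). A five-state HMM
(copy states 0–4) with Gaussian emissions at 0/50/100/150/200 % decodes
each chromosome independently by Viterbi. Emission SDs default to
(12, 12, 12, 18, 30) % — state 4 is wide because it stands for "four or
more copies" — self-transition probability is 1 − 10⁻⁴ with the remainder
split equally, and the initial distribution concentrates on diploid
(0.001, 0.01, 0.978, 0.01, 0.001). All are overridable; they were tuned on
the synthetic recall/precision suite. Masked bins emit uniformly, letting
the transition structure bridge gaps without evidence. Ties in the dynamic
program break toward the lower state index, with a 10⁻⁹ log-space
tolerance because symmetric routes across masked stretches produce
mathematically equal scores that float rounding would otherwise decide
arbitrarily. Posterior decoding is not implemented; maximal runs of equal
state become segments annotated with bin count and median NCP.

## Population annotation and trio evaluation

Genotype frequency of a segment is the median, over its bins, of the count
of panel individuals in the same state, divided by the panel size. Allele
frequency integrates copy observations: `max(2 − s, 0)` deletion alleles or
`max(min(s,4) − 2, 0)` duplication alleles per individual per bin, summed
and divided by 2n, median over bins; state 4 is counted as exactly four
copies, missing states as diploid. Junctions cluster by single linkage with
a 400-bp cutoff; a cluster's frequency counts each assembly once. Rare
deletions are state-0/1 segments ≥ 3 kb with genotype frequency < 0.01;
gene impact trims each deletion's first and last bin before exon overlap
(so a deletion of ≤ 2 bins can never hit a gene), marking genes *affected*
(hemizygous exon) or *knocked out* (nullizygous exon).

Trio concordance uses a parsimonious haplotype-transmission table — a
parent in state 0/1/2/3/4 can transmit 0 / {0,1} / 1 / {1,2} / {2,3}
copies; the child set is the pairwise sums capped at state 4. The table is
fully enumerated in the tests against a brute-force oracle; alternatives
can be loaded from configuration. The loose metric is the consistent
fraction of analyzed bins; the strict metric drops all-diploid bins from
the denominator. Sex chromosomes, mitochondria, reference-gap bins, bins
with missing states and bins in the recurrent-discordance mask (discordant
in ≥ 100 trios, merged to segments) are excluded. Shuffled trios re-pair
each child with a random non-parent father and mother, deterministically
under a seed.

## The synthetic cohort generator

The generator emulates exactly the structure the method assumes: per-bin
locus effects lognormal with median 1 and log-SD 0.25 (shared by the
cohort); per-bin %GC uniform on 0.30–0.60, with a FASTA synthesized to
match so the GC stratification runs on real sequence; per-genome depth
multipliers uniform on 0.75–1.25 around a 40× mean (high-quality genome
territory); per-genome GC-bucket bias lognormal with log-SD 0.10; per-base
depth Poisson (a dispersion knob is deliberately absent — real data are
overdispersed, and the clean Poisson floor is part of what makes the
synthetic suite a best-case bound); founder CNV haplotypes Bernoulli at the
stated allele frequency (hence HWE genotypes); children inherit one
haplotype per parent per locus. Because a bin's 1000 Poisson bases sum to a
Poisson count, the generator offers an exact bin-level fast path
(`simulate_genome_bins`) used for the large recovery cohorts; the per-base
path feeds the condense/decode/aggregate stages in the end-to-end tests.

What the generator does **not** model: mapability artifacts, interspersed
repeat mismapping (LINE1/Alu-type false positives), overdispersed noise,
batch drift of the GC bias within a cohort, partial-bin CNV boundaries
(planted intervals are bin-aligned), or sex chromosomes. Passing the
synthetic suite therefore demonstrates correctness of the algorithms under
their stated model, not field performance on real sequencing data.

## Problem sizes and determinism

The shipped test and acceptance workloads use cohorts of 10–200 genomes
over 0.5–5 Mb single-chromosome genomes: large enough that genotype counts
resolve the peak model's ambiguities and small enough to run everywhere.
CNV loci are kept a small fraction of the simulated genome; planting a
large fraction of a toy genome as CNV distorts the per-bucket scaling
totals in a way real, rare CNVs do not. All randomness flows through
`numpy` `SeedSequence` from a single seed; identical seeds give identical
outputs end to end.

## Known limitations

* A bin where the truly diploid cluster is entirely absent *and* the
  remaining clusters are consistent with a one-sided HWE reading is
  fundamentally ambiguous; the priors pick the most parsimonious reading.
* The RCP is diploid-equivalent everywhere; haploid sex-chromosome states
  appear downstream as state 1, and no PAR-specific handling exists.
* Breakpoints are reported at 1-kb bin resolution; sub-bin boundaries need
  read-level evidence by design.
* `gene_impact` matches exons by interval overlap only; transcript
  structure beyond exon intervals is not consulted.
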