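# Methods

## Signal and data reduction

Deletions between a few hundred bp and ~10 kb leave three footprints in
paired-end alignments: inflated pair distances, split reads, and a local
depth drop.  This package keys on the first: a pair whose fragment spans a
deletion of length *l* shows an insert size inflated by *l* relative to the
sample's null distribution.  Depth enters implicitly (homozygously deleted
sequence yields no pairs), and split-read information is approximated by
the start-position tracking described below.

Profiling reduces each sample to (forward-read start, insert size, read
group) triples for confidently aligned pairs — both mates mapped, same
contig, FR orientation, primary, non-duplicate, MAPQ ≥ 30 (all
configurable) — plus one null insert-size histogram per read group.  The
insert size is clip-extended: from the forward read's leftmost aligned
position minus its left clip to the reverse read's rightmost aligned
position plus its right clip, so reads soft-clipped at a breakpoint still
measure the full fragment.  The null distribution is estimated from pairs
starting in sampling regions (a user BED, or by default the middle 60% of
each contig); inserts further than 8 robust standard deviations
(1.4826·MAD) from the median are trimmed first, so deletions inside the
sampling regions cannot inflate the null.  Inserts entering the histogram
are additionally capped at mean + 50·sd; stored records may exceed that cap
by up to `max_del_length` (default 10,000 bp) so pairs spanning long
deletions are kept.

The `.jdp` profile format is little-endian binary: magic/version header,
sample metadata, per-read-group histograms, per-contig blocks of zig-zag
delta-encoded positions in 2^16 bp buckets, and a trailing block index that
supports seeking to any genomic position.  On 30× simulated data a profile
is under 2% of the size of the SAM rendering of the same pairs.

## Window model

The caller slides a `window_size` (default 30 bp) grid across each contig.
For one window, the per-sample data are the integer deviations
δ = i − round(μ_S) of all pairs whose fragment footprint
[start, start + insert) overlaps the window.  The null histogram is
transformed into window-overlap likelihoods H_S(δ): the mass at insert size
i is the null count times (i + w − 1), the number of window placements a
fragment of that size can overlap, renormalised and floored at
`hist_floor` (1e-10) outside the observed support so products never vanish.
Genotype likelihoods for 0/1/2 deletion alleles multiply H_S(δ − ε_S),
½[H_S(δ − ε_S) + H_S(δ − l)], and H_S(δ − l) over the window's pairs, in
natural-log space.  ε_S is a per-sample reference shift for local biases
(GC, mappability); the default is 0, with an optional re-centering
(`local_recenter`) that uses the median of near-null deviations capped at
±1 sd.  With several read groups, a sample's likelihood is the product over
its read groups, each deviation scored against its own histogram.

The joint test multiplies samples: the null model uses every sample's
reference likelihood with prior 1 − π, the alternative mixes the three
genotype likelihoods with weights a_g^S ∝ L(G_g | Δ^S) · L(f, G_g) and
prior π (default 1e-4).  The null is rejected when −2 ln Λ ≥ 6.6349, the
χ²(1 df) quantile for the one-tailed P = 0.01 threshold (a precomputed
constant; `chi2_alpha` switches to other quantiles).

## Iterative estimation

Each window runs once per initial length.  Initial lengths are the medians
of greedily clustered per-sample third quartiles of Δ^S (descending order,
cluster tolerance max(pooled sd, 40 bp)); clusters below the minimum
detectable length are dropped, which is what screens out null-only
windows.  The initial allele frequency is the fraction of
deletion-supporting pairs (δ > 3 sd), clamped to
[1/(2N), 1 − 1/(2N)].  An iteration then alternates: genotype likelihoods
at the current *l* → weights at the current *f* → frequency update
f ← mean(a₁ + 2a₂)/2 → per-pair membership probabilities
P = a₁·H(δ−l)/(H(δ−ε)+H(δ−l)) + a₂ → length update l ← Σ δP / Σ P.
Iteration stops when |Δl| ≤ 2 bp and |Δf| ≤ 1e-3, at 15 iterations, when
*l* falls below the minimum detectable length (no-call), or when the state
oscillates (the state with the strongest Λ statistic seen is kept).

Numerical choices worth noting:

- **Minimum detectable length.** Derived from the null distribution as the
  95th percentile of |δ| (≈ 2 sd).  At ~1 sd, third-quartile sampling noise
  of null windows crosses the initialisation threshold often enough to
  flood the sweep with spurious length initialisations.
- **Model outliers in the length update.** A pair whose deviation is at
  the histogram floor under both the reference and the current length
  (e.g. a second, differently sized deletion segregating at the same
  window) is uninformative for this initialisation; it is excluded from
  the length update, which keeps two-length windows from converging to a
  meaningless average.  Each length initialisation still converges to its
  own deletion.
- **Candidate pre-screen.** Only windows where at least one sample shows
  ≥ 3 supporting pairs (`min_candidate_support`) are examined.  At 30× a
  carrier contributes ~20 spanning pairs to every window inside the
  deletion, while the Poisson rate of null pairs beyond 3 sd makes 3
  hits from one sample vanishingly rare, so the pre-screen trims the sweep
  by about two orders of magnitude without touching recall.

## Start positions, merging, output

The deletion start is one past the rightmost forward-read end among
supporting pairs (those with H(δ−l) > H(δ−ε); ties at the double floor
count only when δ > l/2, which keeps far null tails out).  Since profiles
store no per-pair clip information, read ends are reconstructed as
start + read_len − 1; forward reads crossing the breakpoint can therefore
overshoot the true start by up to a read length.  Two consequences are
handled explicitly: a candidate window must itself intersect the deletion
span it predicts (flank windows overlapped only by spanning fragments'
footprints see partial support and misplace the start), and per-sample
genotype likelihoods of a merged call are averaged only over windows inside
the called span minus a read-length margin at its tail (flank windows mix
reference pairs into carrier samples and bias homozygotes toward
heterozygous calls).

Significant (window, length) pairs are sorted by predicted start, length
and likelihood ratio and grouped left to right: a window joins a group when
its start is within max(l/2, 3·window_size) of the seed and its length
within 25% relative difference.  The grouping pass runs on group medians
and repeats until no two groups can be combined, so emitted calls are
pairwise non-redundant.  A call reports the median start and length, mean
natural-log genotype likelihoods converted to PHRED (PL, normalised to
min 0), GT as the most likely genotype (ties → `./.`), GQ as the gap
between the two smallest PLs, and a cohort allele frequency recomputed from
the emitted genotypes.  Samples with fewer than 3 pairs at the locus or
more than 4× the cohort median pair count are not genotyped.  Averaging
happens on natural-log likelihoods before PHRED scaling.  VCF output uses
symbolic `<DEL>` alleles with POS at the first deleted base (1-based),
END = POS + length and negative SVLEN.

## Simulator

The generator reproduces a population-cohort design at three levels.
Deletion sets draw lengths uniformly (default 100–10,000 bp) and allele
frequencies uniformly on (0, 1); positions are uniform subject to a 1 kb
minimum gap, realised as a single ordered-spacings draw (deterministic per
seed, placement failure = the contig cannot hold the request).  Haplotypes
carry each deletion independently with probability equal to its allele
frequency; diploids pair consecutive haplotypes, so a 2000-deletion cohort
gives E[het] = E[hom] = n/3 ≈ 666.7 per individual.  Trios draw parental
haplotypes the same way and children inherit one uniformly chosen haplotype
per parent.

Read pairs are generated at the fragment level: fragments are placed
uniformly on each haplotype with insert ~ round(Normal(450, 15)) truncated
at 2·read_len (read length 150); defaults give 30× diploid coverage.  A
fragment whose interior contains an excision breakpoint acquires the
deletion length in its apparent insert; homozygously deleted sequence
produces no fragments.  An optional SAM writer renders pairs as ungapped
150M matches to exercise the alignment-ingestion path.  The simulator omits
sequencing errors, GC bias, mappability structure, repeat-mediated
mis-mapping and real breakpoint microhomology; passing tests therefore
demonstrate the statistical machinery under the stated model, not
robustness to alignment artefacts in real genomes.  Because simulated reads
never soft-clip, simulated start estimates carry the read-length overshoot
described above (absorbed by the 50% reciprocal-overlap matching
criterion); on real data with clipped alignments the rule is sharper.

## Evaluation suite

Call/truth matching is greedy one-to-one in descending reciprocal overlap
with a 50% threshold.  Size and region filters reproduce standard
benchmarking practice (500–10,000 bp, any overlap with an exclude region
removes a call, containment in high-confidence regions when given,
genotypes below a GQ threshold are masked).  Sites are tested for
Hardy–Weinberg equilibrium with the exact conditional test (two-sided, no
mid-P correction; monomorphic sites keep P = 1) — exact rather than χ²
because deletion-scale genotype counts are often small.  Trio statistics
ignore trios with missing genotypes or all three samples 0/0; Mendelian
consistency enumerates allele transmissions; the transmission rate counts,
at sites with one heterozygous and one reference parent (optionally
restricted to sites whose deletion allele occurs in a single trio), the
fraction of children that are heterozygous — 50% expected.  De novo
candidates require both parents 0/0, a carrier child and all three GQs at
or above 50.

## Problem sizes and defaults used by the test suite

The end-to-end check runs 20 samples on a 5 Mb contig at 30× with 100
deletions of 500–10,000 bp (~470k pairs per sample), chosen to exercise
every code path at full coverage density while keeping the suite fast;
parameter recovery uses 100 windows of 100 samples at 30×-equivalent pair
counts.  At these sizes the joint sweep visits ~20,000 candidate windows
out of ~167,000 and completes in well under a minute on one core.

## Known limitations

- Deletions only; no insertions, duplications, inversions or break-ends.
- No X/Y-aware genotyping; all samples are treated as diploid everywhere.
- Start precision is limited by the lack of per-pair clip information in
  the profile (see above); lengths are estimated to a few bp.
- Deletions shorter than ~2 insert-size standard deviations are below the
  detection floor by construction.
- CRAM input and bgzip/tabix of the output VCF are left to external tools.
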