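# Methods

## Scope and model

The package analyzes low-depth, WGA-amplified single-nucleus and
single-kernel sequencing from maize haploid-induction studies. It starts
from aligned read placements (BED-like records with MapQ) and a biallelic
parental SNP panel; read trimming, alignment and SNP calling are upstream
and out of scope. Two measurement models are implemented:

1. **Relative read depth (CNR)** for integer copy-number states of
   haploid gamete nuclei (sperm, trophic, microspore; baseline 1), diploid
   embryos (baseline 2) and triploid endosperm (baseline 3).
2. **Allelic ratio (SNP ratio / RGR)** for the parental origin of DNA in
   hybrid embryo/endosperm, where relative depth is blind (see below).

## Uniform-depth variable bins

WGA produces locus-specific amplification hot spots that are largely
shared across samples of a batch. Instead of GC or mappability
correction, the genome is re-partitioned so that the *pooled* read count
(all samples of the batch, MapQ ≥ 10) is constant per bin: fixed
equal-width bins (default 4000 genome-wide, allocated to chromosomes by
largest remainder with leftmost tie-break) set a target pooled depth
(total pooled reads / number of fixed bins); a left-to-right walk then
closes a variable bin at the end coordinate of the read that brings the
running pooled count to the target. The trailing sub-target remainder of
each chromosome is merged into that chromosome's last bin, so bins always
partition the genome exactly; a chromosome with zero pooled reads becomes
a single whole-chromosome masked bin. The per-line target depth is an
explicit parameter everywhere rather than a constant.

Per sample, `CNR_b = count_b / median(counts)` over unmasked bins (median
of CNR is exactly 1 by construction) and `log2(CNR)` with zero counts
floored at a pseudocount of 0.5 reads. One correction is applied first:
each raw count is divided by its bin's pooled-depth share (pooled count /
target depth). For every regular bin the share is ~1 and the formula
reduces to plain count-over-median; for the merged trailing bin — which
by construction holds up to twice the target pooled depth — the division
is an exact correction. Without it, the last bin of nearly every
chromosome presents as a spurious copy-2 segment in every sample.

## Ploidy segmentation

Published single-nucleus ploidy calls of this kind are drawn by eye as
visible steps in the log2(CNR) dot plot. The reproducible
operationalization used here: assign each unmasked bin the copy state `c`
whose expected value `log2(c / baseline)` is nearest (copy 0 maps to the
pseudocount floor, ties break toward baseline); merge equal-state runs;
demote non-baseline runs whose mean log2(CNR) lies within a ±0.35 no-call
band around 0; absorb runs spanning less than the minimum segment length
into the common flanking state when both flanks agree, otherwise into the
baseline. The "both flanks agree" branch is the package's own choice
where the rule is otherwise ambiguous: it prevents one noisy bin from
splitting a genuine event into two, and is a no-op on noiseless input.
No HMM or changepoint machinery is used — run-merging keeps the noiseless
oracle exact (recovered segments equal planted truth at bin resolution).

The minimum segment span defaults to 10 Mb at full (~2 Gb) genome scale
and scales linearly with genome size (2 Mb on the 400 Mb test genome).
One rule is applied to gamete nuclei and kernels alike. The band width
(0.35), state sets and minimum span are all configurable.

## Sperm-pair typing and cohort statistics

Events of the two sperm of a pollen are paired by reciprocal overlap
≥ 0.5 (configurable); paired events are typed on their intersection,
unpaired events against the partner's copy state at the event midpoint:
joint states 0/2 → type I, 0/1 → type II, 0/0 → type III. When a
complementary 0/2 pair exists among three nuclei, those two nuclei are
identified as the sperm and the third as the trophic nucleus; otherwise
sample-sheet roles are retained (flagged unconfirmed when aneuploidy is
present). Cohort tables report AP1S/AP2S/TP (per pollen) and ASS/TS (per
sperm) as count ratios, with pooled regular-vs-inducer rows.

Group comparisons use the Pearson chi-square on the 2×2 counts *without*
continuity correction, implemented directly from Σ(O−E)²/E with a df=1
two-sided p-value. This variant reproduces all five published cohort
P values (0.0046, 0.057, 0.012, 9.5×10⁻⁴, 0.00005) from their printed
counts at printed precision; with Yates correction none of them matches
— the test suite checks both directions, with an independent
contingency-table implementation as numerical oracle.

## SNP ratio, RGR and kernel classes

Per-SNP genotypes are unreliable at ~1× depth, so 700 adjacent panel SNPs
form one bin (~500 kb at study SNP density) and the maternal-allele read
fraction is pooled per bin; bins with fewer than 50 informative reads are
masked. The ratio is defined as the *maternal* fraction — the only
orientation under which paternal genome loss drives log2(RGR) positive.
RGR divides each sample's bin ratio by the cross-sample mean of the same
tissue (masked entries excluded; zero ratios floored at half a read).
The mean includes aberrant samples, which attenuates the signal when
cohorts are small; the thresholds below tolerate this, but cohorts of
fewer than ~6 samples per tissue will lose sensitivity.

Loss thresholds on log2(RGR) sit at half the shift a full loss produces:
embryo ±0.3 (a paternal loss moves the ratio 0.5 → 1, i.e. +1 in log2);
endosperm +0.29 / −0.21 (2/3 → 1 is +0.585 for a paternal loss; 2/3 → 1/2
is −0.415 for the loss of one of two maternal copies).

Kernel classification combines both signals. A methodological point: a
*complete* genome-wide one-copy loss is invisible to median-normalized
relative depth — the profile renormalizes to flat — which is precisely
why the allelic ratio is needed. The class I "complete" rule therefore
requires the RGR loss fraction ≥ 0.95 of the unmasked genome *and* a CNV
profile consistent with a uniform drop (a single copy state covering
≥ 0.95 of the segmented genome). Partial elimination (loss fraction
≥ 0.5 with not-lost gaps ≥ the minimum segment span) is class I
incomplete, the gaps being the retained fragments (these also corroborate
as relative CNV gains). Otherwise a CNV loss segment ≥ the minimum span
whose mean log2(RGR) crosses a threshold is class II with the parent
given by the RGR sign; CNV segments without RGR support are reported
unconfirmed, never classified. The 0.95/0.5 fractions separate complete
from incomplete elimination quantitatively where the published
distinction is qualitative; both are configurable.

## The simulator

The generator emulates the statistical structure of the study data, not
its chemistry:

* **Genome** — scaled stand-in: 10 chromosomes totalling 400 Mb (vs ~2 Gb
  real scale) so the full pipeline runs in minutes; all bp thresholds
  scale by genome-size ratio. Centromere intervals (2% of chromosome
  length, seeded-random midpoint in the middle half) support the
  pericentromeric-event flag.
* **Bias field** — shared smooth multiplicative field: per-100 kb-tile
  Gaussian log-deviations (σ = 0.3), moving-average smoothed over 5
  tiles, exponentiated, renormalized to genome-wide mean 1. Per-sample
  overdispersion: i.i.d. gamma tile multipliers with mean 1 and variance
  0.05. The study does not state its WGA noise magnitude; these defaults
  were chosen once to make segmentation non-trivial (per-bin log2 noise
  ~0.2 sd at default depths) and are not calibrated to archived data.
* **Reads** — single-end fixed-length (100 bp) placements with start
  density ∝ bias × copy number; exactly n reads per nucleus (default
  2×10⁵, matching the scaled per-sample depth); MapQ is a two-point
  mixture (5% at MapQ 5, rest at 42) purely to exercise the ≥ 10 filter.
  No FASTQ, no alignment, no base errors.
* **Truths** — type I/II/III sperm events (lengths 8–20 Mb by default,
  half overlapping the centromere), kernel classes with explicit retained
  fragments, trophic nuclei always euploid. Planted events round-trip
  exactly through the truth manifest.
* **Allele counts** — per SNP, depth ~ Poisson(1); maternal count ~
  Binomial(depth, m/(m+f)) from the truth's local copies. Panel density
  matches the study (~1.45 SNPs/kb; 580 k SNPs on the scaled genome) so
  700-SNP bins span ~500 kb there too.
* The study-shaped default pollen cohort reproduces the published
  composition (22 CAU5 pollen triplets with 3+3 aneuploid, 25/26/33/35
  sperm-pair pollens for B73, B73-inducer, Chang7-2, CHOI3).

All randomness flows from one integer seed through named generators;
cohort writes are byte-reproducible.

What passing tests on these simulations do **not** show: robustness to
real WGA chemistry (chimeric reads, allelic dropout at single-molecule
scale), mappability structure, reference errors, or cell-cycle effects —
the bias field is smooth and shared by construction. Recovery rates on
real data should be expected to be lower than on the simulator.

## Numerical choices and degenerate inputs

* Reads are assigned to bins by start coordinate (half-open), making
  boundary-spanning reads unambiguous.
* Pseudocount 0.5 reads for zero-count bins keeps log2 finite; the same
  floor serves as the copy-0 expectation in segmentation.
* The CNR median is taken over unmasked bins only; an all-zero sample is
  an error ("no usable coverage"), as is a baseline outside the state
  set, mismatched bin schemes in joint typing, and a degenerate (zero
  margin) chi-square table.
* Segmentation is invariant to interior masked bins; increasing the
  minimum span never increases the number of called events.
* `summarize_cohort` is sample-order invariant; AP2S is reported over
  pollens (consistent with the published per-line columns).

## Problem sizes used in the tests

Recovery tests run the full pipeline on the study-shaped cohort (304
nuclei at 2×10⁵ reads each) and on 20-seed batteries of smaller cohorts
(kernel class recovery uses 9-kernel cohorts with a 150 k-SNP panel;
segmentation recall/precision uses single-event pollens). These sizes
were chosen so the whole validation battery completes in minutes on one
core while keeping per-bin depths at the scaled study level (~200–500
reads per bin pooled, ~700 informative reads per SNP bin).

## Known limitations

* No sub-bin breakpoint refinement: event boundaries snap to bin edges
  (~0.5–1 Mb at default scaled depths).
* Joint states outside {0,1,2}×{0,1,2} losses (e.g. pure gains) are
  reported untyped rather than forced into types I–III.
* The cross-sample RGR mean is not robust to cohorts dominated by
  aberrant samples.
* Tetrad microspores are typed independently at haploid baseline; no
  joint constraint across the four products of one meiosis is imposed
  beyond unit bookkeeping.
* No modeling of minichromosome propagation or of developmental timing;
  the type→mitosis mapping is reported as an annotation only.
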