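# Methods

This note records the models, conventions and numerical choices behind
`monodi`, and what the synthetic-data generator does and does not emulate.

## Coordinates and data model

All coordinates are 0-based half-open, in memory and in BED/bedGraph
outputs; GFF3 is converted from its 1-based inclusive convention at the
reader. A fragment's length is `end − start`. Fragments are unstranded
spans; 5′ tags and genes carry strand. "Completely overlapping" fragments
are those with exactly identical (chrom, start, end): deduplication
collapses them into positions carrying an origin count, keeps nested or
partially overlapping fragments distinct, and ignores strand. Length
filtering (mono ≤ 236 nt, di ≤ 436 nt, inclusive) precedes deduplication.

## Mapping numbers and the mono/di ratio

The *mapping number* of a nucleotide is read as span coverage: the number of
fragments whose interval covers the nucleotide, weighted by origin count
(`weighting="multiplicity"`, the default, so every mapped fragment counts)
or not (`"unique"`). A fragment-midpoint counting variant is provided as
`midpoint_profile` for comparison but is not the default, since only span
coverage makes the dinucleosome profile commensurable with the
mononucleosome profile at single positions. The MNase-sensitivity statistic
is log₂(mono/di) at nucleotides where **both** mapping numbers are ≥ 1;
other positions are excluded and counted. No library-size normalization is
applied anywhere: the ratio compares raw counts (summaries are medians and
quartiles, computed with linear interpolation, numpy's default), and r² is
scale-invariant. Ratios are pooled across genes within a category rather
than summarized per gene, consistent with category position counts in the
tens of thousands.

## Fragment-length peak calling

Histograms use exact 1-nt bins. The caller smooths with a centered moving
average (default window 5 nt, edge-truncated), takes local maxima of the
smoothed curve, discards candidates with prominence below 5% of the global
smoothed maximum, and greedily prunes candidates closer than 8 nt to a
taller one (ties toward the smaller length). The 8 nt separation is below
the 15 nt gap between the untreated 135/150 nt modes, so genuine bimodality
survives. Each surviving peak's reported location is the argmax of a
zero-padded 3-nt local mean of the **raw** histogram within ±window of the
smoothed maximum, ties again toward the smaller length. The 3-nt local mean
matters: at 200,000 fragments the raw inter-bin differences near a mode of a
discretized normal (SD 6–8 nt) are smaller than single-bin Poisson noise, so
a raw single-bin argmax misses the true mode by ±1 nt tens of percent of the
time, while the local mean is unbiased for symmetric peaks and reduces the
miss probability to a negligible level. Peak calling involves judgement
(what counts as two peaks rather than a shoulder); window, separation and
prominence are therefore exposed on the API and CLI.

## TSS calling and gene regions

TSSs are single-nucleotide: tags are grouped by exact (chrom, position,
strand) with no clustering of adjacent positions, and tag-count tiers
(> 100, > 1000) are strict inequalities. A gene's primary TSS is the
highest-count TSS on its strand between 1 kb upstream of the translational
start and the translational end; ties go to the most upstream candidate;
genes without a candidate are excluded from region analyses with a logged
warning. Promoter = 1 kb upstream of the TSS (strand-aware, clipped at
chromosome bounds with a warning), body = [translational start,
translational end). Activity classes rank non-rRNA genes by mean
treated-condition intensity (arithmetic mean of the two technical
replicates) and take the top/bottom *n* (default 50), ties broken by gene
id. Fold-change classes use FC = mean(treated)/mean(untreated) with
inclusive ≥ 2-fold boundaries; the "constant" class is the *n* genes with
the smallest |log₂ FC| among genes at or above an intensity floor (default:
the median per-gene mean intensity), a concrete rule for the otherwise
underdetermined notion of "constant expression".

## Conservation r² and the signed-rank test

Conservation over a region is the square of Pearson's correlation between
the two conditions' per-nucleotide mononucleosome mapping-number profiles,
on raw counts. Zero-variance profiles (typically all-zero coverage) give an
undefined r², carried as NaN, excluded from medians and test pairs, and
counted. Bodies and promoters are compared with a paired Wilcoxon
signed-rank test on per-gene (body r², promoter r²) pairs: zero differences
dropped, midranks for tied |d|, W = sum of positive ranks. For n ≤ 25 the
two-sided p-value is exact, computed by a dynamic program over the rank-sum
distribution on doubled (hence integer) midranks — mathematically identical
to enumerating all 2ⁿ sign assignments, which the tests verify against a
literal enumeration oracle. For n > 25 a normal approximation with
tie-corrected variance (−Σ(t³−t)/48) and a 0.5 continuity correction is
used; at n = 20 it agrees with the exact p to within 0.02. Two-sided
p-values double the smaller tail and are capped at 1. No multiple-testing
correction is applied (three classes, three raw p-values).

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
sequencing itself (no reads, base composition, MNase sequence preference or
GC bias).

**Genome and nucleosome ground truth.** Genes are placed on equal-length
chromosomes with ≥ 3 kb spacing (a slot of 7 kb per gene; infeasible
configurations raise). Each gene gets a CDS of 1.4–2.6 kb, a random strand,
and a true TSS 100–250 nt upstream of the translational start. Its
nucleosome dyads are: two fuzzy promoter nucleosomes (positional jitter
SD 12 nt) — an *NDR-edge* (−1) nucleosome 200–300 nt upstream of the TSS
with occupancy 0.4–0.9 and a deeper promoter nucleosome 500–700 nt upstream
with occupancy 1.0–1.8 — a well-positioned +1 nucleosome 80 nt downstream of
the TSS (jitter 3 nt, occupancy 1.5), and an irregular body ladder
(pitch drawn per step from 170–260 nt, occupancy drawn per dyad from
0.3–2.5, jitter 5 nt). The irregularity is essential: a
uniform ladder produces quasi-periodic profiles whose between-condition
correlation is dominated by the fragment-length difference between
conditions instead of by nucleosome positions. Promoter dyad density
(2 per kb) is strictly below body density (≥ 3.8 per kb) for every gene, and
pooled promoter coverage per nucleotide is below body coverage.

**Fragment sampling.** A mononucleosomal fragment picks a dyad with
probability proportional to occupancy; a dinucleosomal fragment picks an
adjacent dyad pair (gap ≤ 400 nt) and centers on its midpoint. Lengths are
drawn from discretized normal mixtures (rounded to 1 nt, minimum 50 nt)
whose modes are the design peak values — untreated mono (135, SD 4, 0.5 /
150, SD 4, 0.5), TSA mono 168 and 160 (SD 6), di 285/321/306 (SD 8). The
SDs are chosen narrow enough that each mixture's true modes sit exactly at
the design values (at ≥ 5 nt SD, a 0.5/0.5 mixture with modes 15 nt apart
pulls its modes ~1 nt inward) and that the mode is recoverable to the
nucleotide at 2×10⁵ fragments; peak location, not histogram shape, is what
the analyses consume. Fragments extending past a chromosome end are redrawn.

**The TSA condition.** Under treatment, body dyads of up-/down-regulated
genes move to new stable positions (a per-dyad Gaussian displacement,
SD 50 nt, fixed in the model so it is reproducible across fragment draws)
and their jitter doubles; in **every** gene the promoter nucleosomes' jitter
doubles and the NDR-edge nucleosome additionally drifts (SD 50 nt).
Displacement rather than pure blurring is deliberate: extra jitter alone
acts as a smoothing kernel that partially compensates the box-width mismatch
between the conditions' fragment lengths, and can paradoxically *raise* the
measured r² of regulated bodies. The parameter set was fixed by design
analysis so that (i) regulated gene bodies decohere strongly while their
promoters stay conserved, (ii) constantly expressed genes show no systematic
body-vs-promoter conservation difference (the paired differences change sign
from genome to genome), and (iii) the window just downstream of the TSS
(dominated by the conserved +1) scores higher r² than the window just
upstream (dominated by the drifting NDR edge).

**Tags and expression.** Each 5′ tag picks a gene proportional to its
expression level and lands on the true TSS with probability 0.7, otherwise
geometrically downstream — one major TSS with minor sites. Expression
tables carry two technical replicates per condition with multiplicative
log-normal noise (log₂-scale SD 0.05); class effects are exactly ±1.5 log₂
(up/down), 0 (constant), and a random |log₂ FC| in 0.25–0.9 for filler
genes — kept clear of both zero and the 2-fold boundary so the designed
classes remain identifiable. Constant-class genes draw baselines of
log₂-intensity 12.5 ± 0.6, clearly above the median-intensity floor, since
"constantly expressed" genes are by construction well expressed. rRNA genes
get very high baselines and are excluded from activity ranking.

**What passing tests do and do not show.** The generator shares the
analyses' own abstractions (coverage of intervals, single-nucleotide TSSs,
per-gene regions), so green tests demonstrate correctness of the
computations and internal consistency of the designed effects — not that
real chromatin behaves this way. Real data add mappability gaps, digestion
sequence preference, copy-number and library-size effects, overlapping and
antisense transcription, and dispersed TSS architecture, none of which are
modelled.

## Calibration experiments

`experiments.type1_error_simulation` checks the signed-rank test's size on
an exchangeable null: per gene, two iid condition-pair r² values are
computed on the *same* body region from four independent fragment draws, so
the paired differences are symmetric about zero by construction. (Body
minus promoter under "no condition effect" is *not* such a null — the
regions differ in length and depth — so calibrating there would conflate
test size with generator asymmetries.) With 20 genes the exact test's
achievable size is 0.0484; the empirical rate over 2,000 replicates is
required to lie within three binomial standard errors of the nominal 0.05.
`experiments.class_rejection_rates` redraws the genome each replicate so
gene-layout variability is part of the replication, and compares how often
the body-vs-promoter test rejects in the down-regulated vs the constant
class.

## Problem sizes

Default study sizes generate 200,000 fragments per digestion-ladder sample
for peak analysis (mode recovery to the nucleotide needs ~10⁵ fragments),
120,000 fragments and 150,000 tags for the 152-gene demo genome (4 × 300 kb
chromosomes; 28 up / 49 down / 50 constant / filler, 2 rRNA), and 40,000
fragments per condition for the replicated conservation experiments. These
sizes make every designed effect detectable with comfortable margins on a
single CPU in minutes.

## Known limitations

* Dinucleosome linker length is implicit in the preset modes; adjacent-pair
  sampling does not enforce `di ≈ 2×mono + linker` consistency.
* Digestion kinetics are not modelled: the 15- vs 30-minute contrast exists
  only through the length presets, and mono/di fragment counts are
  independent inputs, so regional MNase-sensitivity contrasts (beyond the
  ~−1 log₂ baseline from di spans being twice as long) are not designed
  into the synthetic data.
* The "completely overlapping" dedup criterion is exact coordinate identity;
  near-duplicates from alignment wobble are kept.
* `read_annotation` consumes gene/CDS/rRNA features only; UTRs and
  alternative isoforms are out of scope.
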