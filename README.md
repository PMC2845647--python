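# monodi

Analysis toolkit for **mono- and dinucleosome MNase-seq** experiments of the
kind used to map chromatin responses to histone-deacetylase inhibition
(e.g. trichostatin A, TSA, in *Aspergillus fumigatus*): paired-end
nucleosomal fragment intervals from a micrococcal-nuclease digestion ladder,
gel-separated into mononucleosomal and dinucleosomal bands, are turned into
genome-wide nucleosome position maps and compared between conditions.

`monodi` is a Python library (plus a thin `monodi` CLI) that implements the
full desk side of such a study:

* **Fragment processing** — BED/BEDPE reading, length filtering
  (mono ≤ 236 nt, di ≤ 436 nt, boundaries inclusive), and collapsing of
  completely overlapping (coordinate-identical) fragments into *positions*
  with origin counts.
* **Fragment-length peak calling** — exact 1-nt histograms and a
  smoothing/prominence-based mode caller that distinguishes unimodal from
  bimodal digestion ladders (e.g. the untreated bimodal 135/150 nt
  mononucleosome signature vs the single TSA peaks at 168/160 nt).
* **MNase-sensitivity ratio** — per-nucleotide *mapping numbers* (span
  coverage) for mono and di fragments and the statistic
  log₂(mono/di), evaluated only where both mapping numbers are ≥ 1, with
  pooled median/quartile summaries per gene category.
* **TSS calling** — 5′-end sequence tags grouped by exact
  (chromosome, position, strand); tag-count tiers (> 100, > 1000, strict);
  per-gene primary-TSS assignment; promoter = 1 kb upstream of the TSS,
  body = translational start to end, strand-aware.
* **Expression classes** — activity (top/bottom *n* by treated intensity,
  rRNA excluded) and fold-change classes (≥ 2-fold up/down, inclusive;
  "constant" = smallest |log₂ FC| among well-expressed genes).
* **Position conservation** — per-region squared Pearson correlation
  r² between the two conditions' mononucleosome mapping-number profiles, and
  a paired Wilcoxon signed-rank test (exact for n ≤ 25, enumerating all 2ⁿ
  sign assignments; tie-corrected normal approximation with continuity
  correction beyond) comparing gene bodies against promoters.
* **Synthetic data generator** — a first-class module that simulates
  genomes, nucleosome dyad ground truth, digestion-ladder fragment sets, 5′
  tags and replicate expression tables with the statistical structure the
  analyses assume, so every stage is testable without sequencing data.

## Worked example

Peak calling on simulated digestion ladders
(`python examples/01_fragment_length_peaks.py`):

```
untreated_mono  -> 2 peak(s): 135 nt (height 4993), 150 nt (height 5026)
tsa15_mono      -> 1 peak(s): 168 nt (height 6669)
tsa30_mono      -> 1 peak(s): 160 nt (height 6669)
untreated_di    -> 1 peak(s): 285 nt (height 4959)
tsa15_di        -> 1 peak(s): 321 nt (height 4959)
tsa30_di        -> 1 peak(s): 306 nt (height 4959)
```

Each location is the modal protected-fragment length in nt: the untreated
mononucleosomes are bimodal, TSA-treated ones longer and unimodal, and
30-minute MNase digestion trims fragments relative to 15 minutes.

Conservation of nucleosome positions between conditions
(`python examples/04_position_conservation.py`):

```
paired body-vs-promoter signed-rank per class:
  constant  n= 16  W=   72.0  p=0.86 (exact)
  down      n= 16  W=    0.0  p=3.05e-05 (exact)
  up        n=  8  W=    0.0  p=0.00781 (exact)

regulated genes: median body r^2 0.26 < promoter r^2 0.89
```

Bodies of regulated genes lose their nucleosome positions under TSA
(low r²), promoters stay conserved; constantly expressed genes show no
systematic body-vs-promoter difference.

The other examples cover the MNase-sensitivity ratio, TSS calling with gene
classification, and the one-command demo pipeline
(`monodi demo <dir> && monodi run <dir>/pipeline_config.json`).

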