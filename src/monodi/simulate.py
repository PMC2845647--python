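"""Synthetic MNase-digestion data generator.

Emulates the statistical structure of a paired-end mono-/di-nucleosome
sequencing experiment in a TSA (trichostatin A, a histone deacetylase
inhibitor) treated vs untreated design on a compact fungal-like genome:

* a genome of genes whose promoters (1 kb upstream of the true TSS) carry a
  strictly lower nucleosome (dyad) density than their bodies, with a
  well-positioned +1 nucleosome just downstream of the TSS and fuzzier,
  sparser promoter nucleosomes;
* fragment-length mixtures reproducing the digestion-ladder peak structure:
  untreated mononucleosomes bimodal at 135/150 nt, TSA-treated unimodal at
  168 nt (15-min MNase) and 160 nt (30-min); dinucleosomes at 285 nt
  (untreated) and 321/306 nt (TSA 15/30-min);
* TSA-induced repositioning: body nucleosomes of up-/down-regulated genes
  move to new stable positions (a per-dyad displacement) and blur mildly,
  while in every gene the promoter nucleosomes blur and the NDR-edge (-1)
  nucleosome drifts — so positions stay conserved in promoters and at the +1
  nucleosome but decohere in regulated gene bodies;
* 5'-end sequence tags concentrated on each gene's true TSS (70% exactly on
  it, the rest geometrically downstream), emulating one major TSS with minor
  sites;
* two-condition expression tables with two technical replicates, containing
  constant, >= 2-fold up- and >= 2-fold down-regulated gene classes plus
  moderately drifting filler genes.

All generators are pure functions of their inputs and an explicit seed; there
is no global random state. No sequence-level simulation is attempted (no
reads, no MNase sequence preference, no GC bias).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .genes import TagSet, ExpressionTable

# nucleosome layout constants (nt); ranges are drawn per gene so every gene's
# profile is idiosyncratic — conservation between conditions must come from
# shared dyad positions, not from a uniform ladder
NDR_EDGE_OFFSET_RANGE = (200, 300)   # -1 nucleosome, upstream of the TSS
NDR_EDGE_WEIGHT_RANGE = (0.4, 0.9)
PROMOTER_OFFSET_RANGE = (500, 700)   # deeper promoter nucleosome
PROMOTER_JITTER_SD = 12.0
PROMOTER_WEIGHT_RANGE = (1.0, 1.8)
PLUS1_OFFSET = 80                    # downstream of the TSS
PLUS1_JITTER_SD = 3.0
PLUS1_WEIGHT = 1.5
BODY_PITCH_RANGE = (170, 260)        # dyad-to-dyad spacing in gene bodies
BODY_MARGIN = 85
BODY_JITTER_SD = 5.0
BODY_WEIGHT_RANGE = (0.3, 2.5)
MAX_PAIR_GAP = 400                   # adjacent dyads further apart form no dinucleosome

MIN_FRAGMENT_LEN = 50
TSS_TAG_GEOM_P = 0.7  # share of a gene's tags landing exactly on the TSS

_GENE_SLOT = 7000     # nt of chromosome consumed per gene incl. >=3 kb spacing
_CHROM_MARGIN = 1400


@dataclass(frozen=True)
class LengthPreset:
    """A discretized normal mixture of fragment lengths."""

    name: str
    components: tuple  # of (modal length nt, SD nt, mixture weight)
    kind: str          # mono | di

    def __post_init__(self):
        if self.kind not in ("mono", "di"):
            raise ValueError(f"bad kind {self.kind!r}")
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mixture weights sum to {w}, not 1")
        limit = 236 if self.kind == "mono" else 436
        for mode, sd, _ in self.components:
            if not 0 < mode < limit:
                raise ValueError(f"{self.name}: modal length {mode} outside (0, {limit})")
            if sd <= 0:
                raise ValueError(f"{self.name}: SD must be positive")

    @property
    def modes(self) -> tuple[int, ...]:
        return tuple(int(c[0]) for c in self.components)


#: The six digestion-ladder presets. Peak locations are the design values the
#: peak caller must recover; component SDs are narrow enough that each
#: mixture's true modes sit exactly at the design values.
PRESETS: dict[str, LengthPreset] = {
    p.name: p
    for p in [
        LengthPreset("untreated_mono", ((135, 4.0, 0.5), (150, 4.0, 0.5)), "mono"),
        LengthPreset("tsa15_mono", ((168, 6.0, 1.0),), "mono"),
        LengthPreset("tsa30_mono", ((160, 6.0, 1.0),), "mono"),
        LengthPreset("untreated_di", ((285, 8.0, 1.0),), "di"),
        LengthPreset("tsa15_di", ((321, 8.0, 1.0),), "di"),
        LengthPreset("tsa30_di", ((306, 8.0, 1.0),), "di"),
    ]
}


@dataclass
class SimConfig:
    """Study-condition knobs for the generator."""

    presets: dict = field(default_factory=lambda: {
        "mono_untreated": "untreated_mono",
        "mono_tsa15": "tsa15_mono",
        "mono_tsa30": "tsa30_mono",
        "di_untreated": "untreated_di",
        "di_tsa15": "tsa15_di",
        "di_tsa30": "tsa30_di",
    })
    n_fragments: int = 200_000
    n_tags: int = 150_000
    seed: int = 0
    tsa_body_shift_sd: float = 50.0       # nt; dyad displacement, regulated bodies
    tsa_body_jitter_multiplier: float = 2.0
    tsa_ndr_shift_sd: float = 50.0        # nt; NDR-edge (-1) displacement, all genes
    tsa_ndr_jitter_multiplier: float = 2.0
    effects: dict = field(default_factory=lambda: {
        "up": 1.5, "down": -1.5, "constant": 0.0})  # log2 fold changes
    replicate_noise_sd: float = 0.05  # log2-scale multiplicative noise
    filler_effect_range: tuple = (0.25, 0.9)  # |log2 FC| of drifting fillers

    def __post_init__(self):
        if self.n_fragments < 0 or self.n_tags < 0:
            raise ValueError("counts must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["filler_effect_range"] = tuple(data.get("filler_effect_range", (0.25, 0.9)))
        return cls(**data)


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    cds_start: int
    cds_end: int
    strand: str
    tss: int
    expr_class: str   # constant | up | down | filler
    is_rrna: bool = False
    log2_baseline: float = 10.0


@dataclass
class GenomeModel:
    """Ground truth: chromosomes, genes, and nucleosome dyads.

    Dyads are stored as flat arrays for vectorized sampling; ``dyad_region``
    distinguishes promoter, +1 and body nucleosomes, and precomputed adjacent
    dyad pairs are the units dinucleosomal fragments are drawn over.
    """

    chromosomes: list          # of (name, length)
    genes: list                # of GeneTruth
    dyad_chrom: np.ndarray     # chromosome index per dyad
    dyad_pos: np.ndarray
    dyad_weight: np.ndarray
    dyad_jitter: np.ndarray
    dyad_gene: np.ndarray      # gene index per dyad
    dyad_region: np.ndarray    # 'ndr_edge' | 'promoter' | 'plus1' | 'body'
    dyad_tsa_shift: np.ndarray  # unit TSA displacement (body dyads; else 0)
    pair_chrom: np.ndarray
    pair_mid: np.ndarray       # midpoint of each adjacent dyad pair
    pair_weight: np.ndarray
    pair_jitter: np.ndarray
    pair_gene: np.ndarray
    pair_is_body: np.ndarray   # both dyads in the body
    pair_tsa_shift: np.ndarray

    @property
    def chrom_names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def regulated_body_dyads(self) -> np.ndarray:
        """Mask of body dyads belonging to up- or down-class genes."""
        classes = np.array([g.expr_class for g in self.genes], dtype=object)
        return (self.dyad_region == "body") & np.isin(
            classes[self.dyad_gene], ["up", "down"])

    def regulated_body_pairs(self) -> np.ndarray:
        classes = np.array([g.expr_class for g in self.genes], dtype=object)
        return self.pair_is_body & np.isin(classes[self.pair_gene], ["up", "down"])

    def dyad_densities(self) -> list[tuple[float, float]]:
        """Per-gene (promoter, body) dyad densities in dyads per kb."""
        out = []
        for gi, g in enumerate(self.genes):
            dy = self.dyad_pos[self.dyad_gene == gi]
            if g.strand == "+":
                prom_lo, prom_hi = g.tss - 1000, g.tss
            else:
                prom_lo, prom_hi = g.tss + 1, g.tss + 1001
            n_prom = int(((dy >= prom_lo) & (dy < prom_hi)).sum())
            n_body = int(((dy >= g.cds_start) & (dy < g.cds_end)).sum())
            out.append((n_prom / 1.0, n_body / ((g.cds_end - g.cds_start) / 1000.0)))
        return out

    def validate(self) -> None:
        clen = self.chrom_lengths
        for g in self.genes:
            if not (0 <= g.cds_start < g.cds_end <= clen[g.chrom]):
                raise ValueError(f"{g.gene_id}: CDS outside chromosome")
            if g.strand == "+" and g.tss > g.cds_start:
                raise ValueError(f"{g.gene_id}: TSS not upstream of CDS start")
            if g.strand == "-" and g.tss < g.cds_end - 1:
                raise ValueError(f"{g.gene_id}: TSS not upstream of CDS start")
        for (dp, db), g in zip(self.dyad_densities(), self.genes):
            if not dp < db:
                raise ValueError(
                    f"{g.gene_id}: promoter dyad density {dp} not below body {db}")


def _gene_dyads(gene: GeneTruth, rng):
    """(pos, weight, jitter, region) rows for one gene, sorted by position.

    Two fuzzy promoter nucleosomes (the TSS-proximal one labelled
    ``ndr_edge``), a well-positioned high-occupancy +1 just downstream of the
    TSS, and an irregular ladder of body nucleosomes with per-dyad occupancy.
    """
    rows = []
    sign = 1 if gene.strand == "+" else -1
    for rng_range, region in ((NDR_EDGE_OFFSET_RANGE, "ndr_edge"),
                              (PROMOTER_OFFSET_RANGE, "promoter")):
        off = int(rng.integers(*rng_range))
        ndr = region == "ndr_edge"
        wrange = NDR_EDGE_WEIGHT_RANGE if ndr else PROMOTER_WEIGHT_RANGE
        rows.append((gene.tss - sign * off, float(rng.uniform(*wrange)),
                     PROMOTER_JITTER_SD, region, float(rng.normal()) if ndr else 0.0))
    rows.append((gene.tss + sign * PLUS1_OFFSET, PLUS1_WEIGHT,
                 PLUS1_JITTER_SD, "plus1", 0.0))
    pos = gene.cds_start + BODY_MARGIN
    while pos <= gene.cds_end - BODY_MARGIN:
        # unit TSA displacement, scaled by the config's shift SD at draw time
        rows.append((pos, float(rng.uniform(*BODY_WEIGHT_RANGE)),
                     BODY_JITTER_SD, "body", float(rng.normal())))
        pos += int(rng.integers(*BODY_PITCH_RANGE))
    rows.sort(key=lambda r: r[0])
    return rows


def make_genome(n_chroms: int = 1, chrom_len: int = 100_000, n_genes: int = 10,
                seed: int = 0, class_counts: dict | None = None,
                n_rrna: int = 0) -> GenomeModel:
    """Place ``n_genes`` (plus ``n_rrna`` rRNA genes) on ``n_chroms``
    equal-length chromosomes with >= 3 kb spacing and build their nucleosome
    ground truth. Deterministic given ``seed``; raises when the genes cannot
    be placed without overlap.

    ``class_counts`` maps expression classes (up/down/constant) to gene
    counts; remaining genes become filler. Default: round-robin over
    constant/up/down/filler.
    """
    total = n_genes + n_rrna
    if total < 1:
        raise ValueError("need at least one gene")
    cap_per_chrom = max(0, (chrom_len - 2 * _CHROM_MARGIN)) // _GENE_SLOT
    if total > n_chroms * cap_per_chrom:
        raise ValueError(
            f"cannot place {total} genes with >=3 kb spacing on {n_chroms} "
            f"chromosome(s) of {chrom_len} nt (capacity {n_chroms * cap_per_chrom})")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", int(chrom_len)) for i in range(n_chroms)]

    # expression classes for the protein-coding genes
    if class_counts is None:
        cycle = ["constant", "up", "down", "filler"]
        classes = [cycle[i % 4] for i in range(n_genes)]
    else:
        classes = []
        for cls in ("constant", "up", "down"):
            classes += [cls] * int(class_counts.get(cls, 0))
        if len(classes) > n_genes:
            raise ValueError("class_counts exceed n_genes")
        classes += ["filler"] * (n_genes - len(classes))
    classes = [classes[i] for i in rng.permutation(n_genes)]
    classes += ["filler"] * n_rrna

    per_chrom = [total // n_chroms + (1 if i < total % n_chroms else 0)
                 for i in range(n_chroms)]
    genes: list[GeneTruth] = []
    gi = 0
    for ci, n_on in enumerate(per_chrom):
        if n_on == 0:
            continue
        slot = (chrom_len - 2 * _CHROM_MARGIN) / n_on
        for k in range(n_on):
            base = int(_CHROM_MARGIN + k * slot)
            cds_len = int(rng.integers(1400, 2601))
            strand = "+" if rng.random() < 0.5 else "-"
            off = int(rng.integers(100, 251))
            if strand == "+":
                cds_start = base + 1300
                cds_end = cds_start + cds_len
                tss = cds_start - off
            else:
                cds_start = base
                cds_end = base + cds_len
                tss = cds_end - 1 + off
            is_rrna = gi >= n_genes
            cls = classes[gi]
            if is_rrna:
                baseline = 15.0 + float(rng.normal(0, 0.2))
            elif cls == "constant":
                # kept clearly above the median-intensity floor so the
                # designed constant class stays recoverable downstream
                baseline = float(rng.normal(12.5, 0.6))
            elif cls in ("up", "down"):
                baseline = float(rng.normal(10, 1.5))
            else:
                baseline = float(rng.normal(10, 2.0))
            name = f"rrna{gi - n_genes:02d}" if is_rrna else f"gene{gi:04d}"
            genes.append(GeneTruth(name, chromosomes[ci][0], cds_start, cds_end,
                                   strand, tss, cls, is_rrna, baseline))
            gi += 1

    # flatten dyads and adjacent pairs
    d_chrom, d_pos, d_w, d_j, d_gene, d_reg, d_sh = [], [], [], [], [], [], []
    p_chrom, p_mid, p_w, p_j, p_gene, p_body, p_sh = [], [], [], [], [], [], []
    chrom_index = {name: i for i, (name, _) in enumerate(chromosomes)}
    for idx, g in enumerate(genes):
        rows = _gene_dyads(g, rng)
        ci = chrom_index[g.chrom]
        for pos, w, j, reg, sh in rows:
            d_chrom.append(ci); d_pos.append(pos); d_w.append(w)
            d_j.append(j); d_gene.append(idx); d_reg.append(reg); d_sh.append(sh)
        for (a, wa, ja, ra, sa), (b, wb, jb, rb, sb) in zip(rows, rows[1:]):
            if b - a <= MAX_PAIR_GAP:
                p_chrom.append(ci); p_mid.append((a + b) / 2.0)
                p_w.append((wa + wb) / 2.0); p_j.append((ja + jb) / 2.0)
                p_gene.append(idx); p_body.append(ra == "body" and rb == "body")
                p_sh.append((sa + sb) / 2.0)

    model = GenomeModel(
        chromosomes, genes,
        np.array(d_chrom, dtype=np.int64), np.array(d_pos, dtype=np.float64),
        np.array(d_w), np.array(d_j), np.array(d_gene, dtype=np.int64),
        np.array(d_reg, dtype=object), np.array(d_sh),
        np.array(p_chrom, dtype=np.int64), np.array(p_mid), np.array(p_w),
        np.array(p_j), np.array(p_gene, dtype=np.int64),
        np.array(p_body, dtype=bool), np.array(p_sh),
    )
    model.validate()
    return model


def _draw_lengths(rng, preset: LengthPreset, n: int) -> np.ndarray:
    weights = np.array([c[2] for c in preset.components])
    modes = np.array([c[0] for c in preset.components], dtype=float)
    sds = np.array([c[1] for c in preset.components], dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights)
    lengths = np.rint(rng.normal(modes[comp], sds[comp])).astype(np.int64)
    return np.maximum(lengths, MIN_FRAGMENT_LEN)


def simulate_fragments(model: GenomeModel, preset: LengthPreset | str, n: int,
                       condition: str = "untreated", seed: int = 0,
                       config: SimConfig | None = None) -> FragmentSet:
    """Draw ``n`` nucleosomal fragments from the model's dyads.

    Mononucleosomal fragments center on an occupancy-weighted dyad,
    dinucleosomal ones on the midpoint of an adjacent dyad pair; the length
    comes from the preset's discretized mixture (min 50 nt) and the center
    gets Gaussian positional jitter. Under the ``tsa`` condition body dyads
    of regulated (up/down) genes are displaced to new stable positions and
    their jitter mildly inflated (the repositioning effect), and promoter
    nucleosomes blur — the NDR-edge one also drifting — in every gene.
    Fragments that would extend past a chromosome end are discarded and
    redrawn. Deterministic given ``seed``.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        preset = PRESETS[preset]
    if condition not in ("untreated", "tsa"):
        raise ValueError(f"unknown condition {condition!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    config = config or SimConfig()
    provenance = f"{preset.name},{condition},seed={seed}"
    if n == 0:
        return FragmentSet.empty(kind=preset.kind, provenance=provenance)
    if preset.kind == "mono":
        pos, weight, jitter = model.dyad_pos, model.dyad_weight, model.dyad_jitter
        chrom_idx, regulated = model.dyad_chrom, model.regulated_body_dyads()
        promoter_like = np.isin(model.dyad_region, ["ndr_edge", "promoter"])
        ndr_edge = model.dyad_region == "ndr_edge"
        shift = model.dyad_tsa_shift
    else:
        pos, weight, jitter = model.pair_mid, model.pair_weight, model.pair_jitter
        chrom_idx, regulated = model.pair_chrom, model.regulated_body_pairs()
        promoter_like = np.zeros(len(pos), dtype=bool)
        ndr_edge = np.zeros(len(pos), dtype=bool)
        shift = model.pair_tsa_shift
    if pos.size == 0:
        raise ValueError("model has no dyads to sample from")
    jit = jitter.copy()
    pos = pos.astype(float)
    if condition == "tsa":
        # repositioning: regulated-gene body dyads move to new stable spots
        # and blur mildly; promoter nucleosomes blur in every gene (released
        # hyperacetylated histones) without moving
        pos = pos + np.where(regulated, shift * config.tsa_body_shift_sd, 0.0)
        pos = pos + np.where(ndr_edge, shift * config.tsa_ndr_shift_sd, 0.0)
        jit[regulated] *= config.tsa_body_jitter_multiplier
        jit[promoter_like] *= config.tsa_ndr_jitter_multiplier
    p = weight / weight.sum()
    clens = np.array([length for _, length in model.chromosomes], dtype=np.int64)
    names = np.array(model.chrom_names, dtype=object)

    rng = np.random.default_rng(seed)
    out_c, out_s, out_e = [], [], []
    need = n
    while need > 0:
        idx = rng.choice(len(pos), size=need, p=p)
        lengths = _draw_lengths(rng, preset, need)
        centers = pos[idx] + rng.normal(0.0, 1.0, size=need) * jit[idx]
        starts = np.rint(centers - lengths / 2.0).astype(np.int64)
        ends = starts + lengths
        ok = (starts >= 0) & (ends <= clens[chrom_idx[idx]])
        out_c.append(chrom_idx[idx][ok])
        out_s.append(starts[ok])
        out_e.append(ends[ok])
        need -= int(ok.sum())
    chroms = names[np.concatenate(out_c)]
    return FragmentSet(chroms, np.concatenate(out_s), np.concatenate(out_e),
                       kind=preset.kind, provenance=provenance)


def simulate_tss_tags(model: GenomeModel, n: int, seed: int = 0) -> TagSet:
    """Draw ``n`` 5'-end sequence tags.

    Each tag picks a gene with probability proportional to its (untreated)
    expression level and lands at the true TSS plus a geometric
    (p = 0.7) downstream offset on the gene's strand, so 70% of a gene's
    tags sit exactly on its TSS in expectation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    levels = np.array([2.0 ** g.log2_baseline for g in model.genes])
    gidx = rng.choice(len(model.genes), size=n, p=levels / levels.sum())
    offsets = rng.geometric(TSS_TAG_GEOM_P, size=n) - 1
    tss = np.array([g.tss for g in model.genes], dtype=np.int64)
    sign = np.array([1 if g.strand == "+" else -1 for g in model.genes])
    positions = tss[gidx] + sign[gidx] * offsets
    clens = model.chrom_lengths
    maxpos = np.array([clens[g.chrom] - 1 for g in model.genes], dtype=np.int64)
    positions = np.clip(positions, 0, maxpos[gidx])
    df = pd.DataFrame({
        "chrom": [model.genes[i].chrom for i in gidx],
        "position": positions,
        "strand": [model.genes[i].strand for i in gidx],
    })
    agg = (df.groupby(["chrom", "position", "strand"], sort=True)
             .size().reset_index(name="count"))
    return TagSet(agg)


def simulate_expression(model: GenomeModel, config: SimConfig | None = None,
                        seed: int = 0) -> ExpressionTable:
    """Two-condition expression table, two technical replicates per condition.

    Before noise, treated/untreated mean ratios equal the class effect
    sizes exactly: 2^1.5 for up, 2^-1.5 for down, 1.0 for constant; filler
    genes drift by a random |log2 FC| inside ``filler_effect_range`` (kept
    clear of both the 2-fold boundary and zero so designed classes stay
    recoverable). Replicate noise is multiplicative log-normal with the
    config's log2-scale SD.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.filler_effect_range
    rows = []
    for g in model.genes:
        if g.expr_class in config.effects:
            effect = config.effects[g.expr_class]
        else:
            effect = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
        mu_u = 2.0 ** g.log2_baseline
        mu_t = mu_u * 2.0 ** effect
        for cond, mu in (("untreated", mu_u), ("tsa", mu_t)):
            for rep in (1, 2):
                noise = 2.0 ** rng.normal(0.0, config.replicate_noise_sd)
                rows.append((g.gene_id, cond, rep, mu * noise))
    frame = pd.DataFrame(rows, columns=["gene_id", "condition", "replicate",
                                        "intensity"])
    return ExpressionTable(frame)


def write_annotation(model: GenomeModel, path) -> None:
    """Ground-truth gene models as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in model.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in model.genes:
            s, e = g.cds_start + 1, g.cds_end
            fh.write(f"{g.chrom}\tmonodi\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            child = "rRNA" if g.is_rrna else "CDS"
            phase = "." if g.is_rrna else "0"
            fh.write(f"{g.chrom}\tmonodi\t{child}\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                     f"ID={g.gene_id}.{child.lower()};Parent={g.gene_id}\n")


def write_truth(model: GenomeModel, path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in model.genes],
            "chrom": [g.chrom for g in model.genes],
            "cds_start": [g.cds_start for g in model.genes],
            "cds_end": [g.cds_end for g in model.genes],
            "strand": [g.strand for g in model.genes],
            "tss": [g.tss for g in model.genes],
            "expr_class": [g.expr_class for g in model.genes],
            "is_rrna": [g.is_rrna for g in model.genes],
            "log2_baseline": [round(g.log2_baseline, 4) for g in model.genes],
        }
    ).to_csv(path, sep="\t", index=False)
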