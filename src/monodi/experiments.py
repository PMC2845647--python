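"""Simulation studies built from the generator and the analysis stages.

These functions wire the synthetic generator through the same code paths a
real dataset would take, and are what the calibration tests and the
reproduction script run: digestion-ladder peak recovery, the signed-rank
test's type-I error under an exchangeable null, and the direction of the
body-vs-promoter conservation contrast between regulated and constant genes.
"""

from __future__ import annotations

import numpy as np

from .conservation import profile_r2, region_r2_table, wilcoxon_signed_rank
from .coverage import Region, coverage_profile
from .fragments import deduplicate, filter_by_length
from .genes import Gene
from .lengths import find_length_peaks, length_histogram
from .simulate import PRESETS, GenomeModel, SimConfig, make_genome, simulate_fragments


def _child_seed(seed: int, *key: int) -> int:
    """A stable derived seed below 2^31."""
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % (2**31))


def recover_length_peaks(preset_name: str, n: int = 200_000, seed: int = 42,
                         model: GenomeModel | None = None) -> list[int]:
    """Simulate -> length filter -> histogram -> peak caller; return the
    called peak locations (nt) for one preset."""
    preset = PRESETS[preset_name]
    if model is None:
        model = make_genome(1, 100_000, 10, seed=_child_seed(seed, 0))
    condition = "untreated" if preset_name.startswith("untreated") else "tsa"
    frags = simulate_fragments(model, preset, n, condition=condition,
                               seed=_child_seed(seed, 1))
    frags = filter_by_length(frags)
    hist = length_histogram(frags)
    return [p.length for p in find_length_peaks(hist)]


def _genes_from_truth(model: GenomeModel) -> list[Gene]:
    genes = []
    for g in model.genes:
        gene = Gene(g.gene_id, g.chrom, g.cds_start, g.cds_end, g.strand,
                    tss=g.tss, excluded_from_activity=g.is_rrna)
        gene.regulation = g.expr_class if g.expr_class in ("up", "down", "constant") else "other"
        genes.append(gene)
    return genes


def _body_regions(model: GenomeModel) -> list[Region]:
    return [Region(g.chrom, g.cds_start, g.cds_end, strand=g.strand, label="body")
            for g in model.genes]


def type1_error_simulation(n_replicates: int = 2000, n_genes: int = 20,
                           frags_per_draw: int = 5000, alpha: float = 0.05,
                           seed: int = 0) -> float:
    """Rejection rate of the signed-rank test under an exchangeable null.

    Per replicate, every gene receives two iid condition-pair r^2 values
    computed on the *same* body region from four independent fragment draws
    (no condition effect anywhere), so the paired differences are symmetric
    about zero by construction and the nominal level should be recovered.
    """
    model = make_genome(1, _size_for(n_genes), n_genes, seed=_child_seed(seed, 0))
    regions = _body_regions(model)
    preset = PRESETS["untreated_mono"]
    rejections = 0
    for rep in range(n_replicates):
        r2_pairs = np.empty((n_genes, 2))
        for j in range(2):
            draws = [
                deduplicate(simulate_fragments(
                    model, preset, frags_per_draw, seed=_child_seed(seed, 1, rep, j, k)))
                for k in range(2)
            ]
            for gi, region in enumerate(regions):
                pa = coverage_profile(draws[0], region)
                pb = coverage_profile(draws[1], region)
                r2_pairs[gi, j] = profile_r2(pa, pb)
        res = wilcoxon_signed_rank(r2_pairs[:, 0], r2_pairs[:, 1])
        if res.p < alpha:
            rejections += 1
    return rejections / n_replicates


def _size_for(n_genes: int) -> int:
    return 7000 * n_genes + 3000


def conservation_contrast(model: GenomeModel | None = None,
                          n_fragments: int = 150_000, seed: int = 0,
                          config: SimConfig | None = None):
    """One two-condition experiment; returns the per-class body/promoter r^2
    rows (a list of RegionR2) and the gene class mapping.

    Untreated mononucleosomes use the bimodal 135/150 preset, the treated
    ones the 168 nt 15-min preset, matching the conditions whose maps the
    conservation comparison is defined between.
    """
    config = config or SimConfig()
    if model is None:
        model = make_genome(2, 180_000, 48, seed=_child_seed(seed, 0),
                            class_counts={"constant": 16, "up": 8, "down": 16})
    ps_u = deduplicate(simulate_fragments(
        model, "untreated_mono", n_fragments, "untreated",
        seed=_child_seed(seed, 1), config=config))
    ps_t = deduplicate(simulate_fragments(
        model, "tsa15_mono", n_fragments, "tsa",
        seed=_child_seed(seed, 2), config=config))
    genes = _genes_from_truth(model)
    rows = region_r2_table(genes, ps_t, ps_u, chrom_lengths=model.chrom_lengths)
    classes = {g.gene_id: g.expr_class for g in model.genes}
    return rows, classes


def regulated_body_promoter_medians(n_fragments: int = 150_000,
                                    seed: int = 0) -> tuple[float, float]:
    """(median body r^2, median promoter r^2) over regulated (up/down) genes
    for one synthetic two-condition experiment."""
    rows, classes = conservation_contrast(n_fragments=n_fragments, seed=seed)
    reg = {g for g, c in classes.items() if c in ("up", "down")}
    body = [r.r2 for r in rows if r.gene_id in reg and r.label == "body" and r.defined]
    prom = [r.r2 for r in rows if r.gene_id in reg and r.label == "promoter" and r.defined]
    return float(np.median(body)), float(np.median(prom))


def class_rejection_rates(n_replicates: int = 30, n_per_class: int = 12,
                          frags_per_condition: int = 40_000, alpha: float = 0.05,
                          seed: int = 0) -> tuple[float, float]:
    """(down-class, constant-class) rejection rates of the body-vs-promoter
    signed-rank test over replicated synthetic experiments.

    Down-class gene bodies are repositioned under TSA, so their body profiles
    decohere between conditions while promoters stay put; constant genes have
    no repositioning effect. A fresh genome is drawn per replicate so that
    gene-layout variability is part of the replication.
    """
    rej = {"down": 0, "constant": 0}
    for rep in range(n_replicates):
        model = make_genome(1, _size_for(2 * n_per_class), 2 * n_per_class,
                            seed=_child_seed(seed, 0, rep),
                            class_counts={"constant": n_per_class,
                                          "down": n_per_class})
        genes = _genes_from_truth(model)
        classes = {g.gene_id: g.expr_class for g in model.genes}
        ps_u = deduplicate(simulate_fragments(
            model, "untreated_mono", frags_per_condition, "untreated",
            seed=_child_seed(seed, 1, rep)))
        ps_t = deduplicate(simulate_fragments(
            model, "tsa15_mono", frags_per_condition, "tsa",
            seed=_child_seed(seed, 2, rep)))
        rows = region_r2_table(genes, ps_t, ps_u,
                               chrom_lengths=model.chrom_lengths)
        for cls in ("down", "constant"):
            sub = [r for r in rows if classes.get(r.gene_id) == cls]
            body = {r.gene_id: r.r2 for r in sub if r.label == "body"}
            prom = {r.gene_id: r.r2 for r in sub if r.label == "promoter"}
            shared = sorted(set(body) & set(prom))
            res = wilcoxon_signed_rank(
                np.array([body[g] for g in shared]),
                np.array([prom[g] for g in shared]))
            if res.p < alpha:
                rej[cls] += 1
    return rej["down"] / n_replicates, rej["constant"] / n_replicates
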