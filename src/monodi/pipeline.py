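"""End-to-end orchestration: demo dataset generation and the full pipeline.

``make_demo`` writes a complete synthetic input set (six fragment BEDs for
mono/di x untreated/TSA-15/TSA-30, a GFF3 annotation, 5' tag and expression
tables, ground truth and a JSON config); ``run_pipeline`` executes
filter -> dedup -> length peaks -> TSS/classification -> MNase-sensitivity
ratio -> conservation on any conforming inputs and writes TSV outputs plus a
run manifest. Outputs are byte-deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conservation import (body_promoter_test, median_by_class, r2_rows_to_frame,
                           region_r2_table, tss_window_r2)
from .coverage import monodi_log2ratio, coverage_profile, pooled_ratio_summary, summaries_to_frame
from .fragments import deduplicate, filter_by_length, read_fragments, write_positions
from .genes import (apply_regulation_labels, assign_primary_tss, call_tss,
                    classes_to_frame, classify_activity, fold_change_classes,
                    partition_regions, read_annotation, read_expression, read_tags)
from .lengths import find_length_peaks, length_histogram, peaks_to_frame
from .simulate import (SimConfig, make_genome, simulate_expression,
                       simulate_fragments, simulate_tss_tags, write_annotation,
                       write_truth)
from .fragments import write_fragments

logger = logging.getLogger(__name__)

SAMPLES = ("mono_untreated", "mono_tsa15", "mono_tsa30",
           "di_untreated", "di_tsa15", "di_tsa30")


@dataclass
class PipelineConfig:
    fragments: dict                  # sample name -> BED path
    annotation: str
    tags: str
    expression: str
    outdir: str
    seed: int = 0
    max_mono_len: int = 236
    max_di_len: int = 436
    fc_threshold: float = 2.0
    promoter_len: int = 1000
    tss_tiers: tuple = (100, 1000)
    tss_half_window: int = 300
    n_active: int = 50
    n_constant: int = 50
    chrom_lengths: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["tss_tiers"] = tuple(data.get("tss_tiers", (100, 1000)))
        return cls(**data)

    def input_paths(self) -> dict[str, str]:
        paths = {name: p for name, p in self.fragments.items()}
        paths.update(annotation=self.annotation, tags=self.tags,
                     expression=self.expression)
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def make_demo(outdir, seed: int = 42, n_genes: int = 150, n_rrna: int = 2,
              n_fragments: int = 120_000, n_tags: int = 150_000) -> Path:
    """Write a full synthetic dataset plus a pipeline config; returns the
    config path. Gene classes follow the study design: 28 up-, 49
    down-regulated (>= 2-fold), 50 constant, the rest filler."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(10)]
    if n_genes >= 127:
        class_counts = {"constant": 50, "up": 28, "down": 49}
    else:  # scale the 50/28/49 study design down for small demos
        class_counts = {"constant": round(n_genes * 50 / 150),
                        "up": round(n_genes * 28 / 150),
                        "down": round(n_genes * 49 / 150)}
    model = make_genome(n_chroms=4, chrom_len=300_000, n_genes=n_genes,
                        seed=seeds[0], class_counts=class_counts, n_rrna=n_rrna)
    config = SimConfig(seed=seed, n_fragments=n_fragments, n_tags=n_tags)
    sample_specs = {
        "mono_untreated": ("untreated_mono", "untreated"),
        "mono_tsa15": ("tsa15_mono", "tsa"),
        "mono_tsa30": ("tsa30_mono", "tsa"),
        "di_untreated": ("untreated_di", "untreated"),
        "di_tsa15": ("tsa15_di", "tsa"),
        "di_tsa30": ("tsa30_di", "tsa"),
    }
    frag_paths = {}
    for i, (sample, (preset, condition)) in enumerate(sample_specs.items()):
        fs = simulate_fragments(model, preset, n_fragments, condition,
                                seed=seeds[1 + i], config=config)
        path = outdir / f"{sample}.bed"
        write_fragments(fs, path)
        frag_paths[sample] = str(path)
    tags = simulate_tss_tags(model, n_tags, seed=seeds[7])
    from .genes import write_tags, write_expression
    write_tags(tags, outdir / "tags.tsv")
    expr = simulate_expression(model, config, seed=seeds[8])
    write_expression(expr, outdir / "expression.tsv")
    write_annotation(model, outdir / "genes.gff3")
    write_truth(model, outdir / "truth.tsv")
    config.to_json(outdir / "sim_config.json")
    pc = PipelineConfig(
        fragments=frag_paths,
        annotation=str(outdir / "genes.gff3"),
        tags=str(outdir / "tags.tsv"),
        expression=str(outdir / "expression.tsv"),
        outdir=str(outdir / "results"),
        seed=seed,
        n_active=min(50, n_genes // 3),
        n_constant=class_counts["constant"],
        chrom_lengths=model.chrom_lengths,
    )
    cfg_path = outdir / "pipeline_config.json"
    pc.to_json(cfg_path)
    return cfg_path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the report directory.

    Any missing input aborts before the first stage, naming the path; a
    stage failure aborts with the stage name and cause.
    """
    for name, path in config.input_paths().items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input '{name}' not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- fragments: filter, dedup, length peaks -----------------------
        stage = "filter+dedup+lengthdist"
        positions, peak_frames = {}, []
        for sample in SAMPLES:
            if sample not in config.fragments:
                continue
            kind = "mono" if sample.startswith("mono") else "di"
            max_len = config.max_mono_len if kind == "mono" else config.max_di_len
            fs = read_fragments(config.fragments[sample], kind=kind,
                                provenance=sample)
            n_in = len(fs)
            fs = filter_by_length(fs, max_len)
            ps = deduplicate(fs)
            positions[sample] = ps
            write_positions(ps, outdir / f"{sample}.positions.bed")
            hist = length_histogram(fs)
            _write_tsv(hist.to_frame(), outdir / f"{sample}.lengths.tsv")
            pf = peaks_to_frame(find_length_peaks(hist))
            pf.insert(0, "sample", sample)
            pf["n_in"] = n_in
            pf["n_filtered"] = len(fs)
            pf["n_positions"] = len(ps)
            peak_frames.append(pf)
            logger.info("[%s] %d in, %d after filter, %d positions",
                        sample, n_in, len(fs), len(ps))
        _write_tsv(pd.concat(peak_frames, ignore_index=True),
                   outdir / "length_peaks.tsv")

        # --- TSS calling and gene models ----------------------------------
        stage = "tss"
        tags = read_tags(config.tags)
        tss = call_tss(tags)
        _write_tsv(tss.frame, outdir / "tss_table.tsv")
        tiers = tss.tier_counts(config.tss_tiers)
        _write_tsv(pd.DataFrame({"threshold": list(tiers), "n_tss": list(tiers.values())}),
                   outdir / "tss_tiers.tsv")
        genes = read_annotation(config.annotation)
        genes = assign_primary_tss(genes, tss, upstream_window=config.promoter_len)

        # --- expression classes -------------------------------------------
        stage = "classify"
        expr = read_expression(config.expression)
        activity = classify_activity(expr, genes, n=config.n_active)
        regulation = fold_change_classes(expr, config.fc_threshold,
                                         config.n_constant)
        apply_regulation_labels(genes, regulation)
        _write_tsv(classes_to_frame(activity, regulation),
                   outdir / "gene_classes.tsv")

        # --- MNase-sensitivity ratio --------------------------------------
        stage = "ratio"
        clens = {k: int(v) for k, v in config.chrom_lengths.items()} or None
        summaries = []
        for time in ("tsa15", "tsa30"):
            mono_ps, di_ps = positions.get(f"mono_{time}"), positions.get(f"di_{time}")
            if mono_ps is None or di_ps is None:
                continue
            series = {f"{a}-{r}": [] for a in ("active", "inactive")
                      for r in ("body", "promoter")}
            for gene in genes:
                if gene.tss is None or gene.activity not in ("active", "inactive"):
                    continue
                clen = clens.get(gene.chrom) if clens else None
                promoter, body = partition_regions(gene, config.promoter_len, clen)
                for region in (body, promoter):
                    mono_p = coverage_profile(mono_ps, region)
                    di_p = coverage_profile(di_ps, region)
                    series[f"{gene.activity}-{region.label}"].append(
                        monodi_log2ratio(mono_p, di_p))
            for cat in sorted(series):
                s = pooled_ratio_summary(series[cat], f"{time}:{cat}")
                summaries.append(s)
        _write_tsv(summaries_to_frame(summaries), outdir / "ratio_summary.tsv")

        # --- conservation of mononucleosome positions ---------------------
        stage = "conserve"
        ps_t, ps_u = positions.get("mono_tsa15"), positions.get("mono_untreated")
        if ps_t is not None and ps_u is not None:
            class_genes = [g for g in genes
                           if g.regulation in ("constant", "down", "up")]
            rows = region_r2_table(class_genes, ps_t, ps_u,
                                   config.promoter_len, clens)
            classes = {g.id: g.regulation for g in class_genes}
            _write_tsv(r2_rows_to_frame(rows, classes),
                       outdir / "conservation_r2.tsv")
            _write_tsv(median_by_class(rows, classes),
                       outdir / "conservation_medians.tsv")
            tests = []
            for cls in ("constant", "down", "up"):
                sub = [r for r in rows if classes.get(r.gene_id) == cls]
                res = body_promoter_test(sub)
                tests.append({"class": cls, "n": res.n_used, "W": res.w,
                              "p": res.p, "method": res.method})
            _write_tsv(pd.DataFrame(tests), outdir / "conservation_tests.tsv")
            # +-300 nt windows around high-confidence TSSs
            strong = tss.above(max(config.tss_tiers))
            strong_pos = set(zip(strong.frame["chrom"], strong.frame["position"]))
            strong_genes = [g for g in genes if g.tss is not None
                            and (g.chrom, g.tss) in strong_pos]
            wrows = tss_window_r2(strong_genes, ps_t, ps_u,
                                  config.tss_half_window, clens)
            wdf = r2_rows_to_frame(wrows)
            _write_tsv(wdf, outdir / "tss_window_r2.tsv")
            wsum = (wdf.dropna(subset=["r2"]).groupby("label")["r2"]
                    .median().reset_index(name="median_r2"))
            _write_tsv(wsum, outdir / "tss_window_summary.tsv")

        # --- manifest ------------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "max_mono_len": config.max_mono_len,
                "max_di_len": config.max_di_len,
                "fc_threshold": config.fc_threshold,
                "promoter_len": config.promoter_len,
                "tss_tiers": list(config.tss_tiers),
                "tss_half_window": config.tss_half_window,
                "n_active": config.n_active,
                "n_constant": config.n_constant,
            },
            "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                       for name, p in sorted(config.input_paths().items())},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return outdir
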