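"""Gene models: annotation parsing, TSS calling from 5'-end sequence tags,
promoter/body partitioning, and expression-based gene classification.

Coordinates are 0-based half-open throughout. A gene's *promoter* is the
1 kb upstream of its assigned TSS; its *body* runs from the translational
start to the translational end. TSSs are single-nucleotide: 5' tags are
grouped by exact (chrom, position, strand), with no clustering of adjacent
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import Region

logger = logging.getLogger(__name__)


@dataclass
class Gene:
    id: str
    chrom: str
    cds_start: int
    cds_end: int
    strand: str
    tss: int | None = None
    activity: str = "other"     # active | inactive | other
    regulation: str = "other"   # up | down | constant | other
    excluded_from_activity: bool = False  # rRNA genes

    def __post_init__(self):
        if self.cds_end <= self.cds_start:
            raise ValueError(f"{self.id}: cds_end <= cds_start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")


@dataclass
class TagSet:
    """Aggregated 5'-end sequence tags: unique (chrom, position, strand) with counts."""

    frame: pd.DataFrame  # columns: chrom, position, strand, count

    def __post_init__(self):
        need = ["chrom", "position", "strand", "count"]
        if list(self.frame.columns[:4]) != need:
            raise ValueError(f"TagSet frame needs columns {need}")

    @property
    def total(self) -> int:
        return int(self.frame["count"].sum())

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TssTable:
    """Tag-count-ranked transcription start sites (single-nucleotide)."""

    frame: pd.DataFrame  # columns: chrom, position, strand, count

    def __len__(self) -> int:
        return len(self.frame)

    def above(self, threshold: int) -> "TssTable":
        """TSSs with strictly more than ``threshold`` tags."""
        return TssTable(self.frame[self.frame["count"] > threshold].reset_index(drop=True))

    def tier_counts(self, thresholds=(100, 1000)) -> dict[int, int]:
        return {t: int((self.frame["count"] > t).sum()) for t in thresholds}


def read_tags(path) -> TagSet:
    df = pd.read_csv(path, sep="\t")
    return TagSet(df[["chrom", "position", "strand", "count"]])


def write_tags(tags: TagSet, path) -> None:
    tags.frame.to_csv(path, sep="\t", index=False)


def _prescan_gff3(path) -> None:
    """Cheap structural check so parse errors carry a line number."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {i}: expected 9 GFF3 columns, got {len(fields)}")
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(f"{path}: line {i}: non-integer coordinates") from None
            if e < s:
                raise ValueError(f"{path}: line {i}: end < start")


def read_annotation(path) -> list[Gene]:
    """Parse a GFF3 into Gene records.

    One Gene per ``gene`` feature; the CDS span is the min/max over its CDS
    parts (falling back to the gene span when no CDS exists, e.g. rRNA
    genes). Genes with an rRNA child feature (or typed rRNA themselves) are
    flagged ``excluded_from_activity``. GFF3 is 1-based inclusive on disk;
    Genes are 0-based half-open in memory.
    """
    import gffutils

    path = Path(path)
    if path.stat().st_size == 0:
        return []
    _prescan_gff3(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[Gene] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = list(db.children(feat, featuretype="CDS"))
        if cds:
            start = min(c.start for c in cds) - 1
            end = max(c.end for c in cds)
        else:
            start, end = feat.start - 1, feat.end
        rrna = feat.featuretype == "rRNA" or any(
            True for _ in db.children(feat, featuretype="rRNA"))
        genes.append(Gene(
            id=feat.id, chrom=feat.seqid, cds_start=start, cds_end=end,
            strand=feat.strand, excluded_from_activity=rrna,
        ))
    return genes


def call_tss(tags: TagSet, min_tags: int = 1) -> TssTable:
    """Group tags by exact (chrom, position, strand); keep groups with at
    least ``min_tags`` tags. Tier filters (>100, >1000) are separate and
    strict — use :meth:`TssTable.above`."""
    df = (
        tags.frame.groupby(["chrom", "position", "strand"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    df = df[df["count"] >= min_tags].reset_index(drop=True)
    return TssTable(df)


def assign_primary_tss(genes: list[Gene], tss: TssTable,
                       upstream_window: int = 1000) -> list[Gene]:
    """Assign each gene the highest-tag-count TSS on its strand within the
    span from ``upstream_window`` nt upstream of the translational start to
    the translational end; ties go to the most upstream candidate. Genes with
    no candidate keep ``tss=None`` and are skipped downstream (logged)."""
    df = tss.frame
    n_unset = 0
    for gene in genes:
        if gene.strand == "+":
            lo, hi = gene.cds_start - upstream_window, gene.cds_end
        else:
            lo, hi = gene.cds_start, gene.cds_end + upstream_window
        cand = df[(df["chrom"] == gene.chrom) & (df["strand"] == gene.strand)
                  & (df["position"] >= lo) & (df["position"] < hi)]
        if len(cand) == 0:
            gene.tss = None
            n_unset += 1
            continue
        top = cand[cand["count"] == cand["count"].max()]
        if gene.strand == "+":
            gene.tss = int(top["position"].min())  # most upstream = smallest
        else:
            gene.tss = int(top["position"].max())
    if n_unset:
        logger.warning("%d genes had no candidate TSS and remain unset", n_unset)
    return genes


def partition_regions(gene: Gene, promoter_len: int = 1000,
                      chrom_len: int | None = None) -> tuple[Region, Region]:
    """(promoter, body) regions for a gene with an assigned TSS.

    Plus strand: promoter [tss - promoter_len, tss), body [cds_start, cds_end).
    Minus strand: promoter [tss + 1, tss + 1 + promoter_len) on strand '-'.
    Promoters are clipped at chromosome bounds with a warning.
    """
    if gene.tss is None:
        raise ValueError(f"{gene.id}: tss unset")
    if gene.strand == "+":
        p_start, p_end = gene.tss - promoter_len, gene.tss
    else:
        p_start, p_end = gene.tss + 1, gene.tss + 1 + promoter_len
    clipped_start = max(0, p_start)
    clipped_end = p_end if chrom_len is None else min(p_end, chrom_len)
    if (clipped_start, clipped_end) != (p_start, p_end):
        logger.warning("%s: promoter clipped to [%d, %d)", gene.id,
                       clipped_start, clipped_end)
    promoter = Region(gene.chrom, clipped_start, clipped_end,
                      strand=gene.strand, label="promoter")
    body = Region(gene.chrom, gene.cds_start, gene.cds_end,
                  strand=gene.strand, label="body")
    return promoter, body


@dataclass
class ExpressionTable:
    """Two-condition expression intensities with technical replicates.

    Long form: one row per (gene_id, condition, replicate) with a positive
    intensity. Fold change FC = mean(tsa) / mean(untreated) over replicates.
    """

    frame: pd.DataFrame  # columns: gene_id, condition, replicate, intensity

    def __post_init__(self):
        need = ["gene_id", "condition", "replicate", "intensity"]
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise ValueError(f"expression table missing columns {missing}")
        if (self.frame["intensity"] <= 0).any():
            raise ValueError("intensities must be positive")

    def mean_intensity(self, condition: str) -> pd.Series:
        sub = self.frame[self.frame["condition"] == condition]
        return sub.groupby("gene_id")["intensity"].mean()

    def fold_changes(self) -> pd.Series:
        """FC = mean(tsa)/mean(untreated); every gene must have both conditions."""
        mu_u = self.mean_intensity("untreated")
        mu_t = self.mean_intensity("tsa")
        if not mu_u.index.equals(mu_t.index):
            missing = set(mu_u.index) ^ set(mu_t.index)
            raise ValueError(f"genes missing a condition: {sorted(missing)[:5]}")
        return mu_t / mu_u


def read_expression(path) -> ExpressionTable:
    return ExpressionTable(pd.read_csv(path, sep="\t"))


def write_expression(expr: ExpressionTable, path) -> None:
    expr.frame.to_csv(path, sep="\t", index=False)


def classify_activity(expr: ExpressionTable, genes: list[Gene],
                      n: int = 50) -> dict[str, str]:
    """Top/bottom ``n`` genes by mean TSA-condition intensity.

    rRNA-flagged genes are excluded from the ranking. Ties broken by gene id
    for determinism. Labels are also written onto the Gene records.
    """
    excluded = {g.id for g in genes if g.excluded_from_activity}
    mu = expr.mean_intensity("tsa")
    eligible = mu[~mu.index.isin(excluded)]
    if len(eligible) < 2 * n:
        raise ValueError(f"need >= {2 * n} eligible genes, have {len(eligible)}")
    ranked = eligible.reset_index().sort_values(
        ["intensity", "gene_id"], ascending=[False, True])["gene_id"].tolist()
    labels = {g: "other" for g in mu.index}
    for g in ranked[:n]:
        labels[g] = "active"
    for g in ranked[-n:]:
        labels[g] = "inactive"
    for gene in genes:
        gene.activity = labels.get(gene.id, "other")
    return labels


def fold_change_classes(expr: ExpressionTable, fc_threshold: float = 2.0,
                        n_constant: int = 50,
                        intensity_floor: float | None = None) -> dict[str, str]:
    """Up/down/constant regulation classes from two-condition fold changes.

    ``up`` if FC >= fc_threshold, ``down`` if FC <= 1/fc_threshold (both
    boundaries inclusive). ``constant`` = the ``n_constant`` genes with the
    smallest |log2 FC| among genes whose overall mean intensity is at or
    above ``intensity_floor`` (default: the median gene mean), excluding
    up/down genes. Everything else is ``other``.
    """
    fc = expr.fold_changes()
    labels = {g: "other" for g in fc.index}
    for g in fc.index[fc >= fc_threshold]:
        labels[g] = "up"
    for g in fc.index[fc <= 1.0 / fc_threshold]:
        labels[g] = "down"
    overall = expr.frame.groupby("gene_id")["intensity"].mean()
    if intensity_floor is None:
        intensity_floor = float(overall.median())
    candidates = [g for g in fc.index
                  if labels[g] == "other" and overall[g] >= intensity_floor]
    ranked = sorted(candidates, key=lambda g: (abs(np.log2(fc[g])), g))
    for g in ranked[:n_constant]:
        labels[g] = "constant"
    return labels


def apply_regulation_labels(genes: list[Gene], labels: dict[str, str]) -> None:
    for gene in genes:
        gene.regulation = labels.get(gene.id, "other")


def classes_to_frame(activity: dict[str, str],
                     regulation: dict[str, str]) -> pd.DataFrame:
    ids = sorted(set(activity) | set(regulation))
    return pd.DataFrame(
        {
            "gene_id": ids,
            "activity": [activity.get(g, "other") for g in ids],
            "regulation": [regulation.get(g, "other") for g in ids],
        }
    )
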