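"""Conservation of mononucleosome positions between conditions.

Conservation over a region is quantified as the square of Pearson's
correlation coefficient (r^2) between the two conditions' per-nucleotide
mononucleosome mapping-number profiles. r^2 is scale invariant, so raw
coverage counts are compared directly and library size cancels. Regions where
either profile has zero variance (typically all-zero coverage) yield an
undefined r^2, carried as NaN and excluded — with counting — from medians and
paired tests.

Bodies and promoters are compared with a paired Wilcoxon signed-rank test on
per-gene (body r^2, promoter r^2) pairs: zero differences are dropped, |d| is
ranked with midranks for ties, and W is the sum of positive ranks. For small
samples (n <= 25) the two-sided p-value is exact over all 2^n sign
assignments (computed by dynamic programming over the rank-sum distribution,
which enumerates the same space); for larger n a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used. Two-sided
p doubles the smaller tail and is capped at 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .coverage import Profile, Region, coverage_profile
from .fragments import PositionSet
from .genes import Gene, partition_regions

logger = logging.getLogger(__name__)

EXACT_LIMIT = 25  # largest n for the exact signed-rank distribution


def profile_r2(a: Profile | np.ndarray, b: Profile | np.ndarray) -> float:
    """Squared Pearson correlation of two equal-length profiles.

    Returns NaN (the undefined marker) when either vector has zero variance.
    """
    x = np.asarray(a.values if isinstance(a, Profile) else a, dtype=float)
    y = np.asarray(b.values if isinstance(b, Profile) else b, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"profile length mismatch: {len(x)} vs {len(y)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class RegionR2:
    gene_id: str
    label: str   # body | promoter | tss_down | tss_up
    r2: float    # NaN when undefined
    length: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r2)


def region_r2_table(genes: list[Gene], ps_a: PositionSet, ps_b: PositionSet,
                    promoter_len: int = 1000,
                    chrom_lengths: dict[str, int] | None = None) -> list[RegionR2]:
    """Per-gene body and promoter r^2 between two conditions' positions.

    Profiles use span coverage with multiplicity weighting. Genes without an
    assigned TSS are skipped (logged); undefined r^2 rows are kept with the
    NaN marker so downstream summaries can count them.
    """
    rows: list[RegionR2] = []
    skipped = 0
    for gene in genes:
        if gene.tss is None:
            skipped += 1
            continue
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        promoter, body = partition_regions(gene, promoter_len, chrom_len=clen)
        for region in (body, promoter):
            pa = coverage_profile(ps_a, region)
            pb = coverage_profile(ps_b, region)
            rows.append(RegionR2(gene.id, region.label,
                                 profile_r2(pa, pb), len(region)))
    if skipped:
        logger.warning("region_r2_table: skipped %d genes without TSS", skipped)
    n_undef = sum(not r.defined for r in rows)
    if n_undef:
        logger.info("region_r2_table: %d of %d r^2 values undefined", n_undef, len(rows))
    return rows


def tss_window_r2(genes: list[Gene], ps_a: PositionSet, ps_b: PositionSet,
                  half_window: int = 300,
                  chrom_lengths: dict[str, int] | None = None) -> list[RegionR2]:
    """r^2 in the windows just downstream and upstream of each gene's TSS.

    Strand-oriented: downstream is the ``half_window`` nucleotides following
    the TSS in the direction of transcription, upstream the ``half_window``
    preceding it. Windows are clipped at chromosome bounds (flagged through
    their shorter length).
    """
    rows: list[RegionR2] = []
    for gene in genes:
        if gene.tss is None:
            continue
        t = gene.tss
        if gene.strand == "+":
            windows = [("tss_down", t + 1, t + 1 + half_window),
                       ("tss_up", t - half_window, t)]
        else:
            windows = [("tss_down", t - half_window, t),
                       ("tss_up", t + 1, t + 1 + half_window)]
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        for label, lo, hi in windows:
            lo = max(0, lo)
            if clen is not None:
                hi = min(hi, clen)
            if hi <= lo:
                continue
            region = Region(gene.chrom, lo, hi, strand=gene.strand, label=label)
            pa = coverage_profile(ps_a, region)
            pb = coverage_profile(ps_b, region)
            rows.append(RegionR2(gene.id, label, profile_r2(pa, pb), len(region)))
    return rows


def r2_rows_to_frame(rows: list[RegionR2],
                     classes: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "label": [r.label for r in rows],
            "r2": [r.r2 for r in rows],
            "length": [r.length for r in rows],
        }
    )
    if classes is not None:
        df.insert(1, "class", [classes.get(g, "other") for g in df["gene_id"]])
    return df


def median_by_class(rows: list[RegionR2], classes: dict[str, str]) -> pd.DataFrame:
    """Median defined r^2 per (regulation class, region label) cell.

    Returns a tidy frame with one row per cell: class, label, n_defined,
    n_undefined, median (NaN marks an empty cell).
    """
    df = r2_rows_to_frame(rows, classes)
    out = []
    for (cls, label), grp in df.groupby(["class", "label"], sort=True):
        defined = grp["r2"].dropna()
        out.append(
            {
                "class": cls,
                "label": label,
                "n_defined": len(defined),
                "n_undefined": int(grp["r2"].isna().sum()),
                "median": float(defined.median()) if len(defined) else math.nan,
            }
        )
    return pd.DataFrame(out)


@dataclass
class SignedRankResult:
    n_used: int      # pairs after dropping zeros (and undefined)
    w: float         # sum of positive ranks (midranks)
    p: float         # two-sided
    n_zero: int      # zero differences dropped
    method: str      # exact | normal | degenerate


def _exact_two_sided_p(double_ranks: np.ndarray, w_double: float) -> float:
    """Exact two-sided p over all 2^n sign assignments via rank-sum DP.

    ``double_ranks`` are midranks times two, hence integers; the DP counts,
    for every achievable doubled rank sum, the number of sign assignments
    attaining it — identical to brute-force enumeration of 2^n assignments.
    """
    total = int(double_ranks.sum())
    poly = np.zeros(total + 1, dtype=float)
    poly[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(poly)
        shifted[r:] = poly[: total + 1 - r]
        poly = poly + shifted
    poly /= poly.sum()
    wd = int(round(w_double))
    p_le = float(poly[: wd + 1].sum())
    p_ge = float(poly[wd:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """Normal approximation with tie-corrected variance and 0.5 continuity."""
    n = len(ranks)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0
    cc = 0.5 if w > mu else (-0.5 if w < mu else 0.0)
    z = (w - mu - cc) / math.sqrt(var)
    return min(1.0, 2.0 * float(norm.sf(abs(z))))


def wilcoxon_signed_rank(x, y=None, exact_limit: int = EXACT_LIMIT) -> SignedRankResult:
    """Paired Wilcoxon signed-rank test on differences ``x - y`` (or on ``x``
    directly when ``y`` is None). NaN pairs and zero differences are dropped;
    if nothing remains the result is degenerate with p = 1.0."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[~np.isnan(d)]
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = len(d)
    if n == 0:
        logger.warning("signed-rank: all differences zero; degenerate result")
        return SignedRankResult(0, 0.0, 1.0, n_zero, "degenerate")
    ranks = rankdata(np.abs(d))  # midranks for ties
    w = float(ranks[d > 0].sum())
    if n <= exact_limit:
        p = _exact_two_sided_p(np.round(2 * ranks).astype(np.int64), 2 * w)
        method = "exact"
    else:
        p = _normal_two_sided_p(ranks, w)
        method = "normal"
    return SignedRankResult(n, w, p, n_zero, method)


def body_promoter_test(rows: list[RegionR2]) -> SignedRankResult:
    """Signed-rank test of per-gene body r^2 minus promoter r^2. Genes where
    either region's r^2 is undefined are dropped."""
    body = {r.gene_id: r.r2 for r in rows if r.label == "body"}
    prom = {r.gene_id: r.r2 for r in rows if r.label == "promoter"}
    shared = sorted(set(body) & set(prom))
    b = np.array([body[g] for g in shared])
    p = np.array([prom[g] for g in shared])
    return wilcoxon_signed_rank(b, p)
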