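"""Per-nucleotide mapping numbers and the log2 mono/di MNase-sensitivity ratio.

The *mapping number* of a nucleotide is the number of mapped nucleosomal
fragments whose span covers it (optionally weighted by how many identical
fragments collapsed into each position during dedup). The ratio of the
mononucleosome to the dinucleosome mapping number, on a log2 scale and
restricted to nucleotides where both numbers are >= 1, indexes how completely
the local chromatin was digested down to mononucleosomes — higher values mean
higher MNase sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet, PositionSet

REGION_LABELS = ("promoter", "body", "window", "tss_down", "tss_up")


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"
    label: str = "window"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"region end ({self.end}) <= start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Profile:
    """Mapping numbers over a region, oriented 5'->3' on the region's strand."""

    region: Region
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if len(self.values) != len(self.region):
            raise ValueError("profile length != region length")

    def genomic_values(self) -> np.ndarray:
        """Values in genomic (left-to-right) orientation."""
        return self.values[::-1] if self.region.strand == "-" else self.values

    def genomic_positions(self) -> np.ndarray:
        pos = np.arange(self.region.start, self.region.end)
        return pos[::-1] if self.region.strand == "-" else pos


def coverage_profile(ps: PositionSet | FragmentSet, region: Region,
                     weighting: str = "multiplicity") -> Profile:
    """Span-coverage mapping numbers for every nucleotide of ``region``.

    ``weighting='multiplicity'`` counts every originating fragment (a
    position's origin count); ``'unique'`` counts each distinct position once.
    A FragmentSet input counts each fragment once. Minus-strand regions are
    returned reversed (5'->3').
    """
    if weighting not in ("unique", "multiplicity"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n = len(region)
    starts = np.asarray(ps.starts)
    ends = np.asarray(ps.ends)
    if isinstance(ps, PositionSet) and weighting == "multiplicity":
        weights = np.asarray(ps.counts)
    else:
        weights = np.ones(len(starts), dtype=np.int64)
    mask = (np.asarray(ps.chroms, dtype=object) == region.chrom)
    mask &= (starts < region.end) & (ends > region.start)
    s = np.clip(starts[mask] - region.start, 0, n)
    e = np.clip(ends[mask] - region.start, 0, n)
    w = weights[mask]
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, s, w)
    np.subtract.at(diff, e, w)
    values = np.cumsum(diff[:-1])
    if region.strand == "-":
        values = values[::-1]
    return Profile(region, values)


def midpoint_profile(ps: PositionSet | FragmentSet, region: Region,
                     weighting: str = "multiplicity") -> Profile:
    """Fragment-midpoint counts per nucleotide — the alternative reading of
    "mapping number" kept behind its own function; span coverage is default."""
    n = len(region)
    starts = np.asarray(ps.starts)
    ends = np.asarray(ps.ends)
    if isinstance(ps, PositionSet) and weighting == "multiplicity":
        weights = np.asarray(ps.counts)
    else:
        weights = np.ones(len(starts), dtype=np.int64)
    mids = (starts + ends) // 2
    mask = (np.asarray(ps.chroms, dtype=object) == region.chrom)
    mask &= (mids >= region.start) & (mids < region.end)
    values = np.bincount(mids[mask] - region.start, weights[mask], minlength=n)
    values = values.astype(np.int64)
    if region.strand == "-":
        values = values[::-1]
    return Profile(region, values)


@dataclass
class RatioSeries:
    """log2(mono/di) at qualifying nucleotides (both mapping numbers >= 1)."""

    region: Region
    positions: np.ndarray  # genomic coordinates of qualifying nucleotides
    values: np.ndarray     # log2 ratios, all finite
    n_total: int
    n_qualifying: int = field(init=False)

    def __post_init__(self):
        self.n_qualifying = len(self.values)


def monodi_log2ratio(mono: Profile, di: Profile) -> RatioSeries:
    """log2 mono/di ratio at every position with both mapping numbers >= 1.

    Positions failing the joint >=1 rule are excluded (and counted via
    ``n_total`` minus ``n_qualifying``); every emitted value is finite.
    """
    if mono.region != di.region:
        raise ValueError("mono and di profiles cover different regions")
    m = np.asarray(mono.values, dtype=float)
    d = np.asarray(di.values, dtype=float)
    ok = (m >= 1) & (d >= 1)
    values = np.log2(m[ok] / d[ok])
    positions = mono.genomic_positions()[ok]
    return RatioSeries(mono.region, positions, values, n_total=len(m))


@dataclass
class RatioSummary:
    category: str
    n: int
    q1: float | None
    median: float | None
    q3: float | None

    @property
    def empty(self) -> bool:
        return self.n == 0


def pooled_ratio_summary(series: list[RatioSeries], category: str) -> RatioSummary:
    """Median and quartiles (linear interpolation) of pooled qualifying ratios.

    An empty pool yields an explicit empty-summary marker, never NaN.
    """
    values = (np.concatenate([s.values for s in series])
              if series else np.zeros(0))
    if len(values) == 0:
        return RatioSummary(category, 0, None, None, None)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return RatioSummary(category, len(values), float(q1), float(med), float(q3))


def summaries_to_frame(summaries: list[RatioSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [s.category for s in summaries],
            "n": [s.n for s in summaries],
            "q1": [s.q1 for s in summaries],
            "median": [s.median for s in summaries],
            "q3": [s.q3 for s in summaries],
        }
    )


def write_bedgraph(profile: Profile, path, name: str = "coverage") -> None:
    """Profile as bedGraph in genomic orientation (runs of equal value)."""
    vals = profile.genomic_values()
    pos0 = profile.region.start
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vals)]])
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for s, e in zip(starts, ends):
            fh.write(f"{profile.region.chrom}\t{pos0 + s}\t{pos0 + e}\t{vals[s]}\n")


def read_regions_bed6(path) -> list[Region]:
    """BED6 regions: name encodes the label as ``<anything>:<label>`` or is
    the label itself; score ignored."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    regions = []
    for _, row in df.iterrows():
        name = str(row[3]) if len(row) > 3 and pd.notna(row[3]) else "window"
        label = name.rsplit(":", 1)[-1]
        if label not in REGION_LABELS:
            label = "window"
        strand = str(row[5]) if len(row) > 5 and str(row[5]) in ("+", "-") else "+"
        regions.append(Region(str(row[0]), int(row[1]), int(row[2]),
                              strand=strand, label=label))
    return regions
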