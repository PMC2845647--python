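"""Nucleosomal fragment intervals: reading, validation, length filtering, dedup.

A *fragment* is one mapped mono- or dinucleosomal DNA interval, stored as a
0-based half-open span (``chrom``, ``start``, ``end``); its length is
``end - start``. Fragments are unstranded spans. Collapsing fragments with
exactly identical coordinates ("completely overlapping") yields nucleosome
*positions*, each carrying the number of fragments that produced it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default per-kind maximum fragment length (nt): fragments longer than this
#: are discarded as incomplete digestion products.
DEFAULT_MAX_LEN = {"mono": 236, "di": 436}

KINDS = ("mono", "di")


@dataclass
class FragmentSet:
    """A multiset of same-kind fragments (duplicates allowed)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    kind: str = "mono"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends must have equal length")
        if np.any(self.ends <= self.starts):
            bad = int(np.flatnonzero(self.ends <= self.starts)[0])
            raise ValueError(
                f"fragment {bad}: end ({self.ends[bad]}) <= start ({self.starts[bad]})"
            )

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @classmethod
    def empty(cls, kind: str = "mono", provenance: str = "") -> "FragmentSet":
        z = np.empty(0, dtype=np.int64)
        return cls(np.empty(0, dtype=object), z, z, kind=kind, provenance=provenance)

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            self.chroms[mask], self.starts[mask], self.ends[mask],
            kind=self.kind, provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )


@dataclass
class PositionSet:
    """Unique (chrom, start, end) spans with multiplicity-of-origin counts.

    Invariant: no two entries share coordinates, and ``counts.sum()`` equals
    the size of the FragmentSet the set was derived from.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    kind: str = "mono"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.counts is None:
            self.counts = np.ones(len(self.starts), dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_origin(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "count": self.counts,
            }
        )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_int_columns(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        if converted.isna().any():
            line = int(df.index[converted.isna()][0]) + 1
            raise ValueError(f"{path}: line {line}: non-integer coordinate in column {c + 1}")
        df[c] = converted.astype(np.int64)
    return df


def read_fragments(path, format: str = "bed", kind: str = "mono",
                   provenance: str = "") -> FragmentSet:
    """Read fragment intervals from BED (cols 1-3) or BEDPE (cols 1-6).

    BEDPE records collapse to the outer span (min start, max end of the two
    ends); the two ends must map to the same chromosome. Malformed lines
    raise ``ValueError`` naming the 1-based line number. Unknown chromosome
    names are allowed (no genome check at read time). Gzip transparent.
    """
    if format not in ("bed", "bedpe"):
        raise ValueError(f"unknown format {format!r}")
    ncols = 3 if format == "bed" else 6
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return FragmentSet.empty(kind=kind, provenance=provenance or str(path))
    if df.shape[1] < ncols:
        short = df.iloc[:, -1].isna() if df.shape[1] > 1 else pd.Series(True, index=df.index)
        line = int(df.index[short][0]) + 1 if short.any() else 1
        raise ValueError(f"{path}: line {line}: expected at least {ncols} columns")
    if format == "bed":
        df = _parse_int_columns(df, [1, 2], path)
        chroms, starts, ends = df[0].to_numpy(object), df[1].to_numpy(), df[2].to_numpy()
    else:
        df = _parse_int_columns(df, [1, 2, 4, 5], path)
        mismatch = df[0] != df[3]
        if mismatch.any():
            line = int(df.index[mismatch][0]) + 1
            raise ValueError(f"{path}: line {line}: BEDPE ends on different chromosomes")
        chroms = df[0].to_numpy(object)
        starts = np.minimum(df[1].to_numpy(), df[4].to_numpy())
        ends = np.maximum(df[2].to_numpy(), df[5].to_numpy())
    bad = ends <= starts
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"{path}: line {line}: end <= start")
    fs = FragmentSet(chroms, starts, ends, kind=kind,
                     provenance=provenance or str(path))
    logger.info("read %d %s fragments from %s", len(fs), kind, path)
    return fs


def write_fragments(fs: FragmentSet, path) -> None:
    """Write fragments as 6-column BED: chrom, start, end, name, kind, '.'."""
    df = fs.to_frame()
    df["name"] = [f"frag{i}" for i in range(len(fs))]
    df["kind"] = fs.kind
    df["strand"] = "."
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False)


def filter_by_length(fs: FragmentSet, max_len: int | None = None) -> FragmentSet:
    """Retain fragments with length <= ``max_len`` (default 236 mono / 436 di).

    The boundary is inclusive: a 236 nt mononucleosomal fragment survives the
    mono filter, a 237 nt one does not. Order and multiplicity preserved.
    """
    if max_len is None:
        max_len = DEFAULT_MAX_LEN[fs.kind]
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out = fs.subset(fs.lengths <= max_len)
    logger.info("length filter (<= %d nt): %d in, %d retained", max_len, len(fs), len(out))
    return out


def deduplicate(fs: FragmentSet) -> PositionSet:
    """Collapse completely overlapping (coordinate-identical) fragments.

    Fragments sharing (chrom, start, end) become one position carrying its
    origin count; partially overlapping or nested fragments remain distinct
    positions. Output sorted by (chrom, start, end).
    """
    if len(fs) == 0:
        return PositionSet(
            np.empty(0, dtype=object), np.empty(0, np.int64), np.empty(0, np.int64),
            np.empty(0, np.int64), kind=fs.kind, provenance=fs.provenance,
        )
    df = fs.to_frame()
    grouped = (
        df.groupby(["chrom", "start", "end"], sort=True)
        .size()
        .reset_index(name="count")
    )
    ps = PositionSet(
        grouped["chrom"].to_numpy(object),
        grouped["start"].to_numpy(),
        grouped["end"].to_numpy(),
        grouped["count"].to_numpy(),
        kind=fs.kind,
        provenance=fs.provenance,
    )
    logger.info("dedup: %d fragments -> %d positions", len(fs), len(ps))
    return ps


def write_positions(ps: PositionSet, path) -> None:
    """Write positions as BED5 with the origin count in the score column."""
    df = ps.to_frame()
    df.insert(3, "name", [f"pos{i}" for i in range(len(ps))])
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_positions(path, kind: str = "mono", provenance: str = "") -> PositionSet:
    """Read a BED5 position file written by :func:`write_positions`."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return PositionSet(np.empty(0, object), np.empty(0, np.int64),
                           np.empty(0, np.int64), np.empty(0, np.int64),
                           kind=kind, provenance=provenance or str(path))
    if df.shape[1] < 5:
        raise ValueError(f"{path}: expected 5 columns (chrom start end name count)")
    df = _parse_int_columns(df, [1, 2, 4], path)
    return PositionSet(
        df[0].to_numpy(object), df[1].to_numpy(), df[2].to_numpy(),
        df[4].to_numpy(), kind=kind, provenance=provenance or str(path),
    )
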