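"""Genomic interval algebra and window/bin geometry.

All coordinates are 0-based half-open (BED-native). Interval sets are held as a
pandas DataFrame sorted by (chrom, start, end); per-chromosome numpy views back
the vectorised operations. Book-ended intervals merge, matching the default of
the common command-line merge tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "WindowGrid",
    "CoordinateError",
    "merge_intervals",
    "overlap_stats",
    "build_window_grid",
    "filter_windows",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class CoordinateError(ValueError):
    """An interval lies outside its chromosome, or chromosome namespaces differ."""


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # floor midpoint; the convention every window is centred on
        return (self.start + self.end) // 2


class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate space."""

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        for name, length in chromosomes:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._lengths[name] = length

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._lengths.items())

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.names, "length": [self._lengths[c] for c in self.names]}
        )


class IntervalSet:
    """Per-chromosome sorted collection of half-open intervals.

    Parameters
    ----------
    intervals
        Iterable of :class:`Interval` or a DataFrame with at least
        ``chrom, start, end`` columns (``strand``/``name`` optional).
    layout
        Optional :class:`GenomeLayout`; when given, every interval is bound-checked.
    """

    def __init__(
        self,
        intervals: Iterable[Interval] | pd.DataFrame = (),
        layout: GenomeLayout | None = None,
    ):
        if isinstance(intervals, pd.DataFrame):
            df = intervals.copy()
        else:
            rows = list(intervals)
            df = pd.DataFrame(
                {
                    "chrom": [iv.chrom for iv in rows],
                    "start": [iv.start for iv in rows],
                    "end": [iv.end for iv in rows],
                    "strand": [iv.strand for iv in rows],
                    "name": [iv.name for iv in rows],
                }
            )
        if df.empty:
            df = pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                    "strand": pd.Series(dtype=str),
                    "name": pd.Series(dtype=object),
                }
            )
        if "strand" not in df:
            df["strand"] = "."
        if "name" not in df:
            df["name"] = None
        df = df[["chrom", "start", "end", "strand", "name"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            raise CoordinateError("intervals must satisfy 0 <= start < end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        self._df = df
        self.layout = layout
        if layout is not None:
            self._check_bounds(layout)

    def _check_bounds(self, layout: GenomeLayout) -> None:
        for chrom, sub in self._df.groupby("chrom", sort=False):
            L = layout.length(str(chrom))
            if int(sub["end"].max()) > L:
                raise CoordinateError(
                    f"interval on {chrom} exceeds chromosome length {L}"
                )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[Interval]:
        for row in self._df.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end), row.strand, row.name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._df[["chrom", "start", "end"]].equals(
            other._df[["chrom", "start", "end"]]
        )

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    @property
    def total_bp(self) -> int:
        return int((self._df["end"] - self._df["start"]).sum())

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) arrays for one chromosome."""
        sub = self._df[self._df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "IntervalSet":
        return IntervalSet(self._df[np.asarray(mask, bool)], layout=self.layout)

    def merge(self) -> "IntervalSet":
        return merge_intervals(self)


def merge_intervals(intervals: IntervalSet) -> IntervalSet:
    """Fuse overlapping or book-ended intervals into a minimal disjoint set.

    Idempotent; preserves the set of covered bases. Strand and name are dropped
    (a merged span has no single provenance).
    """
    pieces = []
    for chrom in intervals.chroms:
        starts, ends = intervals.arrays(chrom)
        run_end = np.maximum.accumulate(ends)
        # a new merged run begins where start > running max end of predecessors
        new_run = np.ones(len(starts), dtype=bool)
        new_run[1:] = starts[1:] > run_end[:-1]
        m_starts = starts[new_run]
        # run_end is a cumulative max, so each run's merged end sits at its last index
        last_of_run = np.append(np.flatnonzero(new_run)[1:] - 1, len(starts) - 1)
        m_ends = run_end[last_of_run]
        pieces.append(
            pd.DataFrame({"chrom": chrom, "start": m_starts, "end": m_ends})
        )
    if pieces:
        df = pd.concat(pieces, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return IntervalSet(df, layout=intervals.layout)


def _check_namespaces(a: IntervalSet, b: IntervalSet) -> None:
    if a.layout is not None and b.layout is not None and a.layout != b.layout:
        only_a = set(a.layout.names) - set(b.layout.names)
        only_b = set(b.layout.names) - set(a.layout.names)
        raise CoordinateError(
            "interval sets live on different genome layouts; "
            f"unmatched chromosomes: {sorted(only_a | only_b)}"
        )


def _count_overlapping(
    a_starts: np.ndarray, a_ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """Boolean mask: which [a_start, a_end) intervals touch the merged set."""
    if len(m_starts) == 0 or len(a_starts) == 0:
        return np.zeros(len(a_starts), dtype=bool)
    idx = np.searchsorted(m_starts, a_ends, side="left")
    hit = idx > 0
    hit[hit] = m_ends[idx[hit] - 1] > a_starts[hit]
    return hit


def _shared_bp(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> int:
    """Intersection bp between two merged (disjoint, sorted) interval lists."""
    total = 0
    i = j = 0
    while i < len(a_starts) and j < len(b_starts):
        lo = max(a_starts[i], b_starts[j])
        hi = min(a_ends[i], b_ends[j])
        if hi > lo:
            total += hi - lo
        if a_ends[i] <= b_ends[j]:
            i += 1
        else:
            j += 1
    return int(total)


def overlap_stats(a: IntervalSet, b: IntervalSet) -> tuple[int, int]:
    """Count of ``a`` intervals touching ``b`` (each once) and shared bp.

    Shared bp is computed between the merged covers, so it is symmetric:
    ``overlap_stats(a, b)[1] == overlap_stats(b, a)[1]``.
    """
    _check_namespaces(a, b)
    bm = merge_intervals(b)
    am = merge_intervals(a)
    count = 0
    shared = 0
    for chrom in a.chroms:
        a_starts, a_ends = a.arrays(chrom)
        m_starts, m_ends = bm.arrays(chrom)
        count += int(_count_overlapping(a_starts, a_ends, m_starts, m_ends).sum())
    for chrom in am.chroms:
        s1, e1 = am.arrays(chrom)
        s2, e2 = bm.arrays(chrom)
        shared += _shared_bp(s1, e1, s2, e2)
    return count, shared


@dataclass
class WindowGrid:
    """Fixed-width windows centred on feature midpoints, each tiled by bins.

    ``windows`` carries one interval per retained feature (strand inherited from
    the feature). Bins are implicit: within each window the ``n_bins`` bins of
    width ``bin_width`` partition it exactly, and ``bin_offsets`` gives the
    signed left edge of each bin relative to the window centre.
    """

    windows: IntervalSet
    window_width: int
    bin_width: int
    layout: GenomeLayout
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.window_width % self.bin_width != 0:
            raise ValueError("window width must be divisible by bin width")

    @property
    def n_bins(self) -> int:
        return self.window_width // self.bin_width

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def bin_offsets(self) -> np.ndarray:
        """Signed bp offset of each bin's left edge from the window centre."""
        half = self.window_width // 2
        return np.arange(self.n_bins) * self.bin_width - half

    @property
    def bin_centres(self) -> np.ndarray:
        return self.bin_offsets + self.bin_width / 2


def build_window_grid(
    features: IntervalSet, layout: GenomeLayout, window_width: int, bin_width: int
) -> WindowGrid:
    """One window of width ``window_width`` per feature midpoint, binned at ``bin_width``.

    Windows that would extend beyond a chromosome end are dropped (not clipped)
    so every bin offset averages over the same number of windows.
    """
    if window_width % bin_width != 0:
        raise ValueError("window width must be divisible by bin width")
    if len(features) == 0:
        raise ValueError("no features to build windows around")
    half = window_width // 2
    df = features.df
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    starts = mids - half
    ends = mids + half
    lengths = df["chrom"].map(lambda c: layout.length(c)).to_numpy()
    keep = (starts >= 0) & (ends <= lengths)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy()[keep],
            "start": starts[keep],
            "end": ends[keep],
            "strand": df["strand"].to_numpy()[keep],
            "name": df["name"].to_numpy()[keep],
        }
    )
    if len(out) == 0:
        warnings.warn("all windows fall outside chromosome bounds; grid is empty")
    return WindowGrid(
        windows=IntervalSet(out, layout=layout),
        window_width=window_width,
        bin_width=bin_width,
        layout=layout,
        n_dropped=int((~keep).sum()),
    )


def filter_windows(grid: WindowGrid, excluded: IntervalSet) -> WindowGrid:
    """Drop every window that overlaps the excluded set by >= 1 bp."""
    if len(excluded) == 0:
        return grid
    exm = merge_intervals(excluded)
    keep = np.ones(grid.n_windows, dtype=bool)
    df = grid.windows.df
    for chrom, sub in df.groupby("chrom", sort=False):
        m_starts, m_ends = exm.arrays(str(chrom))
        hit = _count_overlapping(
            sub["start"].to_numpy(), sub["end"].to_numpy(), m_starts, m_ends
        )
        keep[sub.index.to_numpy()] = ~hit
    return WindowGrid(
        windows=grid.windows.subset(keep),
        window_width=grid.window_width,
        bin_width=grid.bin_width,
        layout=grid.layout,
        n_dropped=grid.n_dropped + int((~keep).sum()),
    )
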