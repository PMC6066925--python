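"""Anchor-set construction and degenerate-consensus motif scanning.

Loop anchor points (LAPs) are built from per-cell-line CTCF-motif coordinate
sets: motifs are pooled, merged wherever they overlap so each motif is counted
once, and every merged span becomes a fixed 5-kb anchor centred on its
midpoint. The module also scans a genome for a degenerate IUPAC consensus
(the 13-bp PRDM9 core, CCTCCCTNNCCAC, in particular), builds control CTCF
sites away from anchors, and derives the stringent non-CTCF anchor subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GenomeLayout,
    Interval,
    IntervalSet,
    WindowGrid,
    merge_intervals,
    _count_overlapping,
)
from .io import SequenceStore

__all__ = [
    "MotifConsensus",
    "PRDM9_CORE",
    "CTCF_MOTIF_WIDTH",
    "AnchorSet",
    "build_union_laps",
    "scan_motif",
    "prdm9_stats",
    "build_nonctcf_laps",
    "build_control_ctcf",
]

#: width of the CTCF-binding motif, carried as metadata for focal-rate work
CTCF_MOTIF_WIDTH = 19

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifConsensus:
    """A degenerate consensus over {A, C, G, T, N}; N matches any base.

    An N in the *genome* never matches a non-N motif position, so the regex
    character class for N is restricted to ACGT.
    """

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - set("ACGTN"):
            raise ValueError("motif pattern must be a non-empty string over ACGTN")

    def __len__(self) -> int:
        return len(self.pattern)

    def _regex(self, pattern: str) -> re.Pattern:
        # lookahead so overlapping hits are all reported
        body = "".join("[ACGT]" if c == "N" else c for c in pattern)
        return re.compile(f"(?=({body}))")

    @property
    def forward_regex(self) -> re.Pattern:
        return self._regex(self.pattern)

    @property
    def reverse_regex(self) -> re.Pattern:
        return self._regex(reverse_complement(self.pattern))


PRDM9_CORE = MotifConsensus("CCTCCCTNNCCAC")


@dataclass
class AnchorSet:
    """5-kb anchors centred on merged CTCF-motif spans, with provenance.

    ``provenance[i]`` lists the indices of the cell lines whose motifs
    contributed to anchor ``i`` (empty when unknown).
    """

    laps: IntervalSet
    provenance: list[list[int]] = field(default_factory=list)
    anchor_width: int = 5000

    def __len__(self) -> int:
        return len(self.laps)

    @property
    def centres(self) -> pd.DataFrame:
        df = self.laps.df
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "centre": (df["start"] + df["end"]) // 2,
                "strand": df["strand"],
            }
        )


def build_union_laps(
    per_cell_line_motifs: list[IntervalSet],
    layout: GenomeLayout,
    anchor_width: int = 5000,
) -> AnchorSet:
    """Pool loop-assigned CTCF motifs across cell lines into the union anchor set.

    Motifs are merged wherever they overlap (each counted once) and each merged
    span is expanded to ``anchor_width`` bp around its midpoint. Anchors are
    clipped to chromosome bounds. Provenance records which cell lines
    contributed a motif to each merged span; the result is invariant under
    re-ordering of the input cell lines (up to provenance labels).
    """
    if not per_cell_line_motifs:
        raise ValueError("need at least one cell-line motif set")
    pooled = pd.concat([s.df for s in per_cell_line_motifs], ignore_index=True)
    merged = merge_intervals(IntervalSet(pooled, layout=layout))
    half = anchor_width // 2
    df = merged.df
    mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    lengths = df["chrom"].map(lambda c: layout.length(c)).to_numpy()
    starts = np.maximum(mids - half, 0)
    ends = np.minimum(mids + half, lengths)
    laps = IntervalSet(
        pd.DataFrame({"chrom": df["chrom"], "start": starts, "end": ends}),
        layout=layout,
    )
    provenance: list[list[int]] = [[] for _ in range(len(merged))]
    span_index = {
        (row.chrom, int(row.start)): i
        for i, row in enumerate(merged.df.itertuples(index=False))
    }
    for ci, cell_set in enumerate(per_cell_line_motifs):
        for chrom in cell_set.chroms:
            m_starts, m_ends = merged.arrays(chrom)
            c_starts, c_ends = cell_set.arrays(chrom)
            idx = np.searchsorted(m_starts, c_ends, side="left") - 1
            for j in np.unique(idx[idx >= 0]):
                if m_ends[j] > c_starts[idx == j].min():
                    provenance[span_index[(chrom, int(m_starts[j]))]].append(ci)
    provenance = [sorted(set(p)) for p in provenance]
    return AnchorSet(laps=laps, provenance=provenance, anchor_width=anchor_width)


def scan_motif(seqs: SequenceStore, motif: MotifConsensus) -> IntervalSet:
    """All exact degenerate-consensus matches on both strands.

    Overlapping hits are reported; a hit on the minus strand is recorded at
    the plus-strand coordinates of its reverse complement. The matched
    (plus-strand) sequence is carried in the ``name`` field.
    """
    rows = []
    width = len(motif)
    fwd, rev = motif.forward_regex, motif.reverse_regex
    for chrom in seqs.names:
        seq = seqs[chrom]
        for m in fwd.finditer(seq):
            rows.append((chrom, m.start(), m.start() + width, "+", m.group(1)))
        for m in rev.finditer(seq):
            rows.append((chrom, m.start(), m.start() + width, "-", m.group(1)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])
    return IntervalSet(df, layout=seqs.layout)


def prdm9_stats(
    anchors: AnchorSet, hits: IntervalSet, grid: WindowGrid
) -> tuple[float, float, bool]:
    """Fraction of anchors containing a motif hit, and central fold-enrichment.

    The enrichment compares the mean number of hits per *central* bin of the
    grid with the median number of hits per flanking bin (all non-central
    bins). Hits are assigned to bins by midpoint.

    Returns
    -------
    (fraction, enrichment, flank_median_zero)
        When the flank median is zero the enrichment is ``inf`` and the flag
        is set.
    """
    merged_hits = merge_intervals(hits)
    n_with = 0
    for chrom in anchors.laps.chroms:
        a_starts, a_ends = anchors.laps.arrays(chrom)
        h_starts, h_ends = merged_hits.arrays(chrom)
        n_with += int(_count_overlapping(a_starts, a_ends, h_starts, h_ends).sum())
    fraction = n_with / len(anchors) if len(anchors) else 0.0

    n_bins = grid.n_bins
    counts = np.zeros(n_bins, dtype=np.int64)
    hit_mids = {
        chrom: np.sort((hits.arrays(chrom)[0] + hits.arrays(chrom)[1]) // 2)
        for chrom in hits.chroms
    }
    for row in grid.windows.df.itertuples(index=False):
        mids = hit_mids.get(row.chrom)
        if mids is None:
            continue
        lo = np.searchsorted(mids, row.start, side="left")
        hi = np.searchsorted(mids, row.end, side="left")
        if hi > lo:
            bins = (mids[lo:hi] - row.start) // grid.bin_width
            np.add.at(counts, bins, 1)
    central = n_bins // 2 if n_bins % 2 else [n_bins // 2 - 1, n_bins // 2]
    central_idx = np.atleast_1d(np.asarray(central))
    flank_idx = np.setdiff1d(np.arange(n_bins), central_idx)
    n_windows = max(grid.n_windows, 1)
    central_mean = counts[central_idx].mean() / n_windows
    flank_median = np.median(counts[flank_idx]) / n_windows
    if flank_median == 0:
        return fraction, float("inf"), True
    return fraction, float(central_mean / flank_median), False


def build_nonctcf_laps(
    laps_without_motif: IntervalSet,
    motif_hits: IntervalSet,
    chip_bound: IntervalSet,
    mappable: IntervalSet | None = None,
) -> tuple[IntervalSet, dict[str, int]]:
    """Stringent non-CTCF anchors via a sequential filter chain.

    Starting from anchors with no annotated CTCF motif: drop any that contain
    a scanned CTCF motif hit, then any overlapping a ChIP-bound region, then
    (optionally) any not fully contained in mappable sequence. Per-stage
    survivor counts are returned alongside.
    """
    counts = {"input": len(laps_without_motif)}
    current = laps_without_motif

    def _drop_overlapping(s: IntervalSet, other: IntervalSet) -> IntervalSet:
        om = merge_intervals(other)
        keep = np.ones(len(s), dtype=bool)
        df = s.df
        for chrom, sub in df.groupby("chrom", sort=False):
            o_starts, o_ends = om.arrays(str(chrom))
            hit = _count_overlapping(
                sub["start"].to_numpy(), sub["end"].to_numpy(), o_starts, o_ends
            )
            keep[sub.index.to_numpy()] = ~hit
        return s.subset(keep)

    current = _drop_overlapping(current, motif_hits)
    counts["after_motif_removal"] = len(current)
    current = _drop_overlapping(current, chip_bound)
    counts["after_chip_removal"] = len(current)
    if mappable is not None:
        mm = merge_intervals(mappable)
        keep = np.ones(len(current), dtype=bool)
        for i, (chrom, sub) in enumerate(current.df.groupby("chrom", sort=False)):
            m_starts, m_ends = mm.arrays(str(chrom))
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if len(m_starts) == 0:
                contained = np.zeros(len(s), dtype=bool)
            else:
                idx = np.searchsorted(m_starts, s, side="right") - 1
                contained = (idx >= 0) & (m_ends[np.maximum(idx, 0)] >= e)
            keep[sub.index.to_numpy()] = contained
        current = current.subset(keep)
        counts["after_mappability"] = len(current)
    return current, counts


def build_control_ctcf(
    constitutive_motifs: IntervalSet,
    laps: AnchorSet | IntervalSet,
    flank: int = 10_000,
) -> IntervalSet:
    """Constitutively bound CTCF motifs at least ``flank`` bp clear of any anchor.

    Anchors are extended by ``flank`` on each side and any motif overlapping an
    extended anchor is excluded.
    """
    lap_set = laps.laps if isinstance(laps, AnchorSet) else laps
    df = lap_set.df.copy()
    df["start"] = np.maximum(df["start"] - flank, 0)
    df["end"] = df["end"] + flank
    extended = merge_intervals(IntervalSet(df))
    keep = np.ones(len(constitutive_motifs), dtype=bool)
    for chrom, sub in constitutive_motifs.df.groupby("chrom", sort=False):
        e_starts, e_ends = extended.arrays(str(chrom))
        hit = _count_overlapping(
            sub["start"].to_numpy(), sub["end"].to_numpy(), e_starts, e_ends
        )
        keep[sub.index.to_numpy()] = ~hit
    return constitutive_motifs.subset(keep)
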