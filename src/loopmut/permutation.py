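"""Circular-permutation overlap statistics and genome-wide composition tests.

The null model rigidly rotates one feature set around each chromosome (one
uniform offset per chromosome per permutation, wrapping at the end) so that
inter-feature spacing is preserved while the relationship to the other set is
randomised. Also here: shift curves, hypergeometric composition tests with
product-of-marginals expectations, GWAS-region construction, recurrently
disrupted loop detection, and the anchors-per-gene proportion comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .anchors import AnchorSet
from .intervals import (
    GenomeLayout,
    IntervalSet,
    _count_overlapping,
    merge_intervals,
)

__all__ = [
    "PermutationResult",
    "ShiftCurve",
    "CompositionResult",
    "circular_permutation_test",
    "shift_curve",
    "composition_test",
    "build_gwas_regions",
    "recurrently_disrupted_loops",
    "laps_per_gene_test",
]


@dataclass
class PermutationResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_perm: int
    seed: int | None = None
    null_counts: np.ndarray | None = field(default=None, repr=False)
    degenerate: bool = False

    def summary(self) -> str:
        return (
            f"circular permutation: observed={self.observed}, "
            f"null={self.null_mean:.1f}+/-{self.null_sd:.1f}, z={self.z:.2f}, "
            f"p={self.p:.2e} ({self.n_perm} permutations)"
        )


@dataclass
class ShiftCurve:
    offsets: np.ndarray
    z: np.ndarray
    observed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "z": self.z, "observed": self.observed}
        )


@dataclass
class CompositionResult:
    labels: tuple[str, ...]
    observed_count: int
    observed_fraction: float
    expected_fraction: float | None
    p: float | None

    def row(self) -> dict:
        return {
            "intersection": " & ".join(self.labels),
            "count": self.observed_count,
            "fraction": self.observed_fraction,
            "expected": self.expected_fraction,
            "p": self.p,
        }


def _rotate(
    starts: np.ndarray, ends: np.ndarray, length: int, offset: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigidly rotate merged intervals by ``offset`` bp, wrapping at the end.

    Returns sorted (starts, ends, feature_id): an interval crossing the end is
    split into two pieces sharing one feature id, so downstream counting can
    treat the split feature as a single feature.
    """
    n = len(starts)
    if n == 0:
        return starts, ends, np.array([], dtype=np.int64)
    s = (starts + offset) % length
    e = s + (ends - starts)
    ids = np.arange(n)
    wrap = e > length
    out_s = [s[~wrap], s[wrap], np.zeros(int(wrap.sum()), dtype=np.int64)]
    out_e = [e[~wrap], np.full(int(wrap.sum()), length), e[wrap] - length]
    out_i = [ids[~wrap], ids[wrap], ids[wrap]]
    rs = np.concatenate(out_s)
    re_ = np.concatenate(out_e)
    ri = np.concatenate(out_i)
    keep = re_ > rs  # drop empty pieces when the wrap lands exactly on the end
    rs, re_, ri = rs[keep], re_[keep], ri[keep]
    order = np.argsort(rs, kind="mergesort")
    return rs[order], re_[order], ri[order]


def _overlap_count_vs_pieces(
    a_starts: np.ndarray,
    a_ends: np.ndarray,
    b_starts: np.ndarray,
    b_ends: np.ndarray,
) -> np.ndarray:
    """Mask of a-intervals touching any of the (sorted, disjoint) b pieces."""
    return _count_overlapping(a_starts, a_ends, b_starts, b_ends)


def circular_permutation_test(
    a: IntervalSet,
    b: IntervalSet,
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    keep_null: bool = False,
) -> PermutationResult:
    """Significance of the count of ``a`` features overlapping ``b``.

    Each permutation draws one uniform offset per chromosome and rotates every
    ``b`` interval on that chromosome rigidly, wrapping past the chromosome
    end (wrapped intervals are split but still count as one feature).
    p = (1 + #{null >= observed}) / (1 + n_perm), so it is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else None

    bm = merge_intervals(b)
    chrom_data = []
    for chrom in layout.names:
        a_starts, a_ends = a.arrays(chrom)
        b_starts, b_ends = bm.arrays(chrom)
        chrom_data.append((a_starts, a_ends, b_starts, b_ends, layout.length(chrom)))

    observed = sum(
        int(_overlap_count_vs_pieces(as_, ae, bs, be).sum())
        for as_, ae, bs, be, _ in chrom_data
    )

    if len(a) == 0:
        return PermutationResult(
            observed=0, null_mean=float("nan"), null_sd=float("nan"),
            z=float("nan"), p=1.0, n_perm=n_perm, seed=seed_val, degenerate=True,
        )

    null = np.zeros(n_perm, dtype=np.int64)
    for k in range(n_perm):
        total = 0
        for as_, ae, bs, be, length in chrom_data:
            if len(bs) == 0 or len(as_) == 0:
                continue
            off = int(rng.integers(0, length))
            rs, re_, ri = _rotate(bs, be, length, off)
            total += int(_overlap_count_vs_pieces(as_, ae, rs, re_).sum())
        null[k] = total
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else float("nan")
    z = (observed - null_mean) / null_sd if null_sd and null_sd > 0 else float("nan")
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=p,
        n_perm=n_perm,
        seed=seed_val,
        null_counts=null if keep_null else None,
    )


def _shift_set(b: IntervalSet, layout: GenomeLayout, offset: int) -> IntervalSet:
    """Circularly shift every interval by ``offset`` bp (wrap-split)."""
    pieces = []
    bm = merge_intervals(b)
    for chrom in bm.chroms:
        starts, ends = bm.arrays(chrom)
        L = layout.length(chrom)
        rs, re_, _ = _rotate(starts, ends, L, offset % L)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": rs, "end": re_}))
    df = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    return IntervalSet(df, layout=layout)


def shift_curve(
    a: IntervalSet,
    b: IntervalSet,
    layout: GenomeLayout,
    offsets: list[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> ShiftCurve:
    """Permutation z-scores after circularly shifting ``b`` by each offset.

    Offset 0 reproduces the unshifted test (same seed throughout, so the null
    is directly comparable across offsets).
    """
    if 0 not in offsets:
        raise ValueError("offsets must include 0")
    zs, obs = [], []
    for off in offsets:
        shifted = _shift_set(b, layout, off) if off else b
        res = circular_permutation_test(a, shifted, layout, n_perm=n_perm, seed=seed)
        zs.append(res.z)
        obs.append(res.observed)
    return ShiftCurve(
        offsets=np.asarray(offsets), z=np.asarray(zs), observed=np.asarray(obs)
    )


def _member_mask(universe: IntervalSet, feature_set: IntervalSet) -> np.ndarray:
    fm = merge_intervals(feature_set)
    mask = np.zeros(len(universe), dtype=bool)
    for chrom, sub in universe.df.groupby("chrom", sort=False):
        f_starts, f_ends = fm.arrays(str(chrom))
        hit = _count_overlapping(
            sub["start"].to_numpy(), sub["end"].to_numpy(), f_starts, f_ends
        )
        mask[sub.index.to_numpy()] = hit
    return mask


def composition_test(
    universe: AnchorSet | IntervalSet,
    memberships: dict[str, IntervalSet],
    combos: list[tuple[str, ...]] | None = None,
) -> list[CompositionResult]:
    """Marginal and multi-way composition of a feature universe.

    For each label, the observed fraction of universe members overlapping that
    set. For each multi-way combination, the expected fraction under
    independence is the product of the marginal fractions and the p-value is a
    hypergeometric upper tail: with N = |universe|, K = members of the first
    k-1 labels jointly and n = members of the last label, p = P(X >= x) where
    x is the size of the full intersection.
    """
    uni = universe.laps if isinstance(universe, AnchorSet) else universe
    N = len(uni)
    if N == 0:
        raise ValueError("universe is empty")
    masks = {}
    for label, fset in memberships.items():
        masks[label] = _member_mask(uni, fset)
    results = [
        CompositionResult(
            labels=(label,),
            observed_count=int(m.sum()),
            observed_fraction=m.sum() / N,
            expected_fraction=None,
            p=None,
        )
        for label, m in masks.items()
    ]
    if combos is None:
        combos = list(combinations(masks, 2))
    for combo in combos:
        unknown = [l for l in combo if l not in masks]
        if unknown:
            raise KeyError(f"unknown membership label(s): {unknown}")
        joint = np.ones(N, dtype=bool)
        for label in combo:
            joint &= masks[label]
        x = int(joint.sum())
        expected = float(np.prod([masks[l].sum() / N for l in combo]))
        first = np.ones(N, dtype=bool)
        for label in combo[:-1]:
            first &= masks[label]
        K = int(first.sum())
        n = int(masks[combo[-1]].sum())
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        results.append(
            CompositionResult(
                labels=tuple(combo),
                observed_count=x,
                observed_fraction=x / N,
                expected_fraction=expected,
                p=p,
            )
        )
    return results


def build_gwas_regions(
    snps: IntervalSet, flank: int = 5000, layout: GenomeLayout | None = None
) -> IntervalSet:
    """Extend 1-bp SNP intervals by ``flank`` bp each side, clip and merge."""
    df = snps.df.copy()
    df["start"] = np.maximum(df["start"] - flank, 0)
    df["end"] = df["end"] + flank
    if layout is not None:
        df["end"] = np.minimum(df["end"], df["chrom"].map(lambda c: layout.length(c)))
    return merge_intervals(IntervalSet(df, layout=layout))


def recurrently_disrupted_loops(
    loops: pd.DataFrame,
    breakpoints: pd.DataFrame,
    min_hits: int = 5,
    distinct_samples: bool = False,
) -> pd.DataFrame:
    """Loops whose two anchors jointly carry >= ``min_hits`` SV breakpoints.

    ``loops`` columns: loop_id, chrom1, start1, end1, chrom2, start2, end2.
    ``breakpoints`` columns: sample_id, chrom, pos. With ``distinct_samples``
    the tally counts samples with >= 1 breakpoint rather than breakpoints.
    Returns the retained loops with a ``n_hits`` column.
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    by_chrom = {
        str(chrom): sub.sort_values("pos")
        for chrom, sub in breakpoints.groupby("chrom", sort=False)
    }

    def _hits(chrom: str, start: int, end: int) -> pd.DataFrame:
        sub = by_chrom.get(chrom)
        if sub is None:
            return pd.DataFrame(columns=["sample_id", "chrom", "pos"])
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return sub.iloc[lo:hi]

    tallies = []
    for row in loops.itertuples(index=False):
        hit_rows = pd.concat(
            [
                _hits(row.chrom1, row.start1, row.end1),
                _hits(row.chrom2, row.start2, row.end2),
            ]
        )
        tallies.append(
            hit_rows["sample_id"].nunique() if distinct_samples else len(hit_rows)
        )
    out = loops.copy()
    out["n_hits"] = tallies
    return out[out["n_hits"] >= min_hits].reset_index(drop=True)


def laps_per_gene_test(
    genes_a: IntervalSet,
    genes_b: IntervalSet,
    laps: AnchorSet | IntervalSet,
) -> tuple[float, float, float]:
    """Anchor-gene intersection rates for two gene sets and a chi-square p.

    rate = (number of anchor-gene overlapping pairs) / (number of genes). The
    p-value comes from a 2x2 chi-square on (intersections, genes) without
    continuity correction, treating each gene as one trial of being hit at
    least once; rates above 1 are collapsed to the per-gene hit counts' total
    for the contingency table.
    """
    lap_set = laps.laps if isinstance(laps, AnchorSet) else laps
    if len(genes_a) == 0 or len(genes_b) == 0:
        raise ValueError("gene sets must be non-empty")

    def _pairs(genes: IntervalSet) -> int:
        total = 0
        for chrom, sub in genes.df.groupby("chrom", sort=False):
            g_starts = sub["start"].to_numpy()
            g_ends = sub["end"].to_numpy()
            l_starts, l_ends = lap_set.arrays(str(chrom))
            if len(l_starts) == 0:
                continue
            # pairs overlapping = all - (ends before gene) - (starts after gene);
            # the two excluded sets are disjoint, so this is exact even for
            # overlapping anchors
            l_ends_sorted = np.sort(l_ends)
            before = np.searchsorted(l_ends_sorted, g_starts, side="right")
            after = len(l_starts) - np.searchsorted(l_starts, g_ends, side="left")
            total += int((len(l_starts) - before - after).sum())
        return total

    x_a, n_a = _pairs(genes_a), len(genes_a)
    x_b, n_b = _pairs(genes_b), len(genes_b)
    rate_a, rate_b = x_a / n_a, x_b / n_b
    # 2x2 chi-square on event vs non-event totals (prop.test without correction)
    table = np.array([[x_a, max(n_a - x_a, 0)], [x_b, max(n_b - x_b, 0)]], dtype=float)
    if table[:, 1].sum() == 0 or table[:, 0].sum() == 0:
        p = float("nan") if rate_a == rate_b else 0.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        p = float(p)
    return rate_a, rate_b, p
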