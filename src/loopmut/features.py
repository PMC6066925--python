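"""Per-window feature matrices, Spearman panels, and ensemble importance.

The response is the event count (SNVs or SV breakpoints) per 5-kb window
within 1 Mb of an anchor, counting each unique genomic region once. Predictor
importance uses a bagged ensemble of regression trees with out-of-bag
permutation importance (%IncMSE): the percentage increase in out-of-bag MSE
when a predictor's values are permuted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .intervals import IntervalSet, WindowGrid, merge_intervals
from .io import MutationCatalog
from .profiles import _event_positions

__all__ = [
    "FeatureMatrix",
    "ImportanceReport",
    "assemble_feature_matrix",
    "spearman_panel",
    "permutation_importance",
    "BaggedTreeRegressor",
]


@dataclass
class FeatureMatrix:
    """Deduplicated 5-kb windows with predictor columns and a count response."""

    table: pd.DataFrame  # chrom, start, end, <predictors...>, response
    predictors: list[str]
    response: str = "response"

    @property
    def X(self) -> np.ndarray:
        return self.table[self.predictors].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table[self.response].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class ImportanceReport:
    """%IncMSE per predictor plus ranks and the model's out-of-bag fit."""

    importance: pd.Series  # %IncMSE, indexed by predictor
    oob_mse: float
    oob_r: float  # correlation of OOB predictions with the response
    n_trees: int
    seed: int

    @property
    def ranks(self) -> pd.Series:
        return self.importance.rank(ascending=False, method="min").astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pct_inc_mse": self.importance, "rank": self.ranks}
        ).sort_values("rank")

    def summary(self) -> str:
        head = (
            f"bagged-tree importance ({self.n_trees} trees, seed {self.seed}); "
            f"OOB MSE {self.oob_mse:.4f}, OOB r {self.oob_r:.3f}"
        )
        return head + "\n" + self.to_frame().to_string()


def _tile_regions(regions: IntervalSet, width: int) -> pd.DataFrame:
    """Partition merged regions into ``width``-bp tiles, dropping remainders."""
    rows = []
    for row in regions.df.itertuples(index=False):
        n = (row.end - row.start) // width
        if n <= 0:
            continue
        starts = row.start + width * np.arange(n)
        rows.append(
            pd.DataFrame({"chrom": row.chrom, "start": starts, "end": starts + width})
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def assemble_feature_matrix(
    grid: WindowGrid,
    tracks: dict[str, IntervalSet | pd.DataFrame],
    catalog: MutationCatalog,
    events: str = "snv",
) -> FeatureMatrix:
    """Build the per-window predictor matrix and event-count response.

    The grid's (possibly overlapping) windows are merged so each genomic
    region is counted once, then tiled into ``grid.bin_width`` windows.
    Interval tracks contribute a bp-overlap column; signal tracks (DataFrames
    with chrom/start/end/value) contribute a bp-weighted window mean.
    """
    merged = merge_intervals(grid.windows)
    tiles = _tile_regions(merged, grid.bin_width)
    if tiles.empty:
        raise ValueError("no windows to assemble")
    layout = grid.layout
    for label, track in tracks.items():
        track_chroms = (
            track.chroms if isinstance(track, IntervalSet) else set(track["chrom"])
        )
        bad = [c for c in track_chroms if c not in layout]
        if bad:
            raise ValueError(f"track {label!r} has unknown chromosomes: {bad}")

    w = grid.bin_width
    cols: dict[str, np.ndarray] = {}
    for label, track in tracks.items():
        values = np.zeros(len(tiles))
        if isinstance(track, IntervalSet):
            tm = merge_intervals(track)
            for chrom, sub in tiles.groupby("chrom", sort=False):
                t_starts, t_ends = tm.arrays(str(chrom))
                idx = sub.index.to_numpy()
                if len(t_starts) == 0:
                    continue
                # covered-bp prefix function over the merged track:
                # C(x) = total track bp strictly before position x
                cum = np.concatenate([[0], np.cumsum(t_ends - t_starts)])

                def coverage_before(x: np.ndarray) -> np.ndarray:
                    i = np.searchsorted(t_starts, x, side="right")
                    partial = np.clip(x - t_starts[np.maximum(i - 1, 0)], 0, None)
                    partial = np.minimum(
                        partial, (t_ends - t_starts)[np.maximum(i - 1, 0)]
                    )
                    return np.where(i > 0, cum[np.maximum(i - 1, 0)] + partial, 0)

                values[idx] = coverage_before(
                    sub["end"].to_numpy()
                ) - coverage_before(sub["start"].to_numpy())
        else:
            for chrom, sub in tiles.groupby("chrom", sort=False):
                seg = track[track["chrom"] == chrom]
                s_starts = seg["start"].to_numpy()
                s_ends = seg["end"].to_numpy()
                s_vals = seg["value"].to_numpy(dtype=float)
                idx = sub.index.to_numpy()
                out = np.zeros(len(idx))
                for j, (ts, te) in enumerate(zip(sub["start"], sub["end"])):
                    lo = np.maximum(s_starts, ts)
                    hi = np.minimum(s_ends, te)
                    bp = np.maximum(hi - lo, 0)
                    total = bp.sum()
                    out[j] = (s_vals * bp).sum() / total if total else 0.0
                values[idx] = out
        cols[label] = values

    positions = _event_positions(catalog, events)
    response = np.zeros(len(tiles), dtype=np.int64)
    by_chrom = {
        str(chrom): np.sort(sub["pos"].to_numpy())
        for chrom, sub in positions.groupby("chrom", sort=False)
    }
    for chrom, sub in tiles.groupby("chrom", sort=False):
        pos = by_chrom.get(str(chrom))
        if pos is None:
            continue
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        response[sub.index.to_numpy()] = hi - lo

    table = tiles.copy()
    for label, values in cols.items():
        table[label] = values
    table["response"] = response
    return FeatureMatrix(table=table, predictors=list(tracks), response="response")


def spearman_panel(
    matrix: FeatureMatrix, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Spearman rho of each predictor against the response, bootstrap 95% CIs.

    Bootstrap resampling is over rows (percentile interval); heavy ties in
    count responses make the rank-based bootstrap preferable to the Fisher
    transform. Constant predictors are flagged with rho = NaN.
    """
    if len(matrix) < 10:
        raise ValueError("need at least 10 rows")
    rng = np.random.default_rng(seed)
    y = matrix.y
    n = len(y)
    rows = []
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    for name in matrix.predictors:
        x = matrix.table[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append((name, np.nan, np.nan, np.nan, True))
            continue
        rho = stats.spearmanr(x, y).statistic
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = boot_idx[b]
            boots[b] = stats.spearmanr(x[idx], y[idx]).statistic
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows.append((name, float(rho), float(lo), float(hi), False))
    return pd.DataFrame(
        rows, columns=["predictor", "rho", "ci_low", "ci_high", "constant"]
    )


class BaggedTreeRegressor:
    """Bagged regression trees with explicit out-of-bag bookkeeping.

    The base learner is pluggable (any sklearn-style regressor factory); the
    bagging loop is kept in-package so out-of-bag permutation importance can
    be computed exactly as %IncMSE is defined for tree ensembles.
    """

    def __init__(
        self,
        n_trees: int = 200,
        seed: int = 0,
        base_learner=None,
        max_features: float | str = 1.0 / 3,
    ):
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features
        self.base_learner = base_learner or (
            lambda rs: DecisionTreeRegressor(
                max_features=self.max_features, min_samples_leaf=5, random_state=rs
            )
        )
        self.trees_: list = []
        self.oob_masks_: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTreeRegressor":
        n = len(y)
        if n < 2:
            raise ValueError("need at least 2 rows to fit")
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.oob_masks_ = []
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = self.base_learner(int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        return self

    def oob_predict(self, X: np.ndarray) -> np.ndarray:
        """Mean prediction per row over the trees for which it was out-of-bag."""
        n = len(X)
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if oob.any():
                sums[oob] += tree.predict(X[oob])
                counts[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.mean([tree.predict(X) for tree in self.trees_], axis=0)


def permutation_importance(
    matrix: FeatureMatrix,
    n_trees: int = 200,
    seed: int = 0,
    model: BaggedTreeRegressor | None = None,
) -> ImportanceReport:
    """Out-of-bag permutation importance (%IncMSE) for every predictor.

    For each predictor, its column is permuted (one seeded permutation),
    out-of-bag predictions are recomputed and the importance is
    100 x (OOB MSE permuted - OOB MSE baseline) / OOB MSE baseline.
    A constant predictor scores exactly 0. Deterministic under fixed seed.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    if len(matrix.predictors) < 2:
        raise ValueError("need at least 2 predictors")
    X, y = matrix.X, matrix.y
    est = model or BaggedTreeRegressor(n_trees=n_trees, seed=seed)
    est.fit(X, y)
    pred = est.oob_predict(X)
    valid = ~np.isnan(pred)
    base_mse = float(np.mean((pred[valid] - y[valid]) ** 2))
    rng = np.random.default_rng(seed + 1)
    scores = {}
    for j, name in enumerate(matrix.predictors):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        pp = est.oob_predict(Xp)
        v = ~np.isnan(pp)
        mse = float(np.mean((pp[v] - y[v]) ** 2))
        scores[name] = 100.0 * (mse - base_mse) / base_mse if base_mse > 0 else 0.0
    r = (
        float(np.corrcoef(pred[valid], y[valid])[0, 1])
        if valid.sum() > 1 and np.std(y[valid]) > 0 and np.std(pred[valid]) > 0
        else float("nan")
    )
    return ImportanceReport(
        importance=pd.Series(scores),
        oob_mse=base_mse,
        oob_r=r,
        n_trees=est.n_trees,
        seed=seed,
    )
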