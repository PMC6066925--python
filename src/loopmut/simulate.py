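"""Synthetic genomes, anchor/hotspot sets, tracks and mutation catalogs.

The generator reproduces the statistical structure the analyses assume on a
desk-scale genome: a multi-chromosome layout; per-cell-line anchor motif sets
sharing a common core; a planted fraction of anchors co-located with
recombination hotspots; SNV catalogs whose rate dips smoothly near anchors
with a focal peak over the 19-bp CTCF motif; SV catalogs whose breakpoints
are enriched at anchors; PRDM9 consensus occurrences planted in a synthetic
FASTA; and auxiliary DSB-peak and replication-timing tracks.

Rate model (per sample, per bp, at distance d from the nearest anchor centre):

* SNVs:        r(d) = r0 * (1 - delta * exp(-d / lam)), times ``focal_mult``
  inside the 19-bp motif span at each anchor centre;
* breakpoints: b(d) = b0 * (1 + epsilon * exp(-d / lam)).

Exponential kernels are the simplest smooth shapes consistent with the
dip/enrichment profiles being emulated. Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anchors import CTCF_MOTIF_WIDTH, AnchorSet, build_union_laps
from .intervals import GenomeLayout, IntervalSet
from .io import (
    MutationCatalog,
    SequenceStore,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_mutation_table,
)

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "simulate_genome",
    "simulate_anchors_hotspots",
    "simulate_mutations",
    "simulate_tracks",
    "simulate_bundle",
]

_BASES = np.array(list("ACGT"))
_PRDM9_SEQ = "CCTCCCTNNCCAC"


@dataclass
class SimulationConfig:
    """All knobs of the generator, with desk-scale defaults.

    Rates are per sample per Mb; fractions in [0, 1]. The defaults encode the
    study conditions being emulated: an SNV rate of 4 /sample/Mb, SV
    breakpoints two orders of magnitude rarer, a ~0.12 chance anchor-hotspot
    overlap with 0.16 planted, a 13% PRDM9 planting fraction, a 3x focal
    motif multiplier and a 3.7-fold DSB enrichment at anchors.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_cell_lines: int = 7
    n_union_anchors: int = 200
    shared_core_fraction: float = 0.6
    anchor_width: int = 5000
    motif_width: int = CTCF_MOTIF_WIDTH
    prdm9_fraction: float = 0.13
    hotspot_count: int = 350
    hotspot_width: int = 2000
    overlap_fraction: float = 0.16  # planted anchor-hotspot co-location, rho
    n_samples: int = 50
    snv_rate: float = 4.0  # r0, SNVs per sample per Mb
    dip_depth: float = 0.5  # delta
    dip_scale: float = 100_000.0  # lam, bp
    focal_mult: float = 3.0  # m, over the 19-bp motif
    sv_rate: float = 0.1  # b0, breakpoints per sample per Mb
    sv_enrichment: float = 1.0  # epsilon
    dsb_count: int = 2000
    dsb_width: int = 250
    dsb_fold: float = 3.7
    rt_step: int = 5000
    rt_amplitude: float = 1.0
    nucleosome_ripple: float = 0.0  # optional sinusoidal modulation, off by default

    def __post_init__(self) -> None:
        for name in (
            "shared_core_fraction",
            "prdm9_fraction",
            "overlap_fraction",
            "dip_depth",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("snv_rate", "sv_rate", "sv_enrichment", "focal_mult", "dsb_fold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_lengths.items())


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    layout: GenomeLayout
    sequences: SequenceStore
    cell_line_motifs: list[IntervalSet]
    anchors: AnchorSet
    hotspots: IntervalSet
    dsb_peaks: IntervalSet
    replication_timing: pd.DataFrame  # chrom, start, end, value
    catalog: MutationCatalog
    ground_truth: dict

    def write(self, outdir: str | Path) -> None:
        """Serialise the bundle as plain-text files plus a ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.layout, outdir / "genome.chrom.sizes")
        write_fasta(self.sequences, outdir / "genome.fa")
        for i, motifs in enumerate(self.cell_line_motifs):
            write_bed(motifs, outdir / f"cell_line_{i}_motifs.bed")
        write_bed(self.anchors.laps, outdir / "anchors.bed")
        write_bed(self.hotspots, outdir / "hotspots.bed")
        write_bed(self.dsb_peaks, outdir / "dsb_peaks.bed")
        self.replication_timing.to_csv(
            outdir / "replication_timing.tsv", sep="\t", index=False
        )
        write_mutation_table(self.catalog, outdir / "snvs.tsv", kind="snv")
        write_mutation_table(self.catalog, outdir / "svs.tsv", kind="sv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)


def _anchor_centres(anchors: AnchorSet) -> dict[str, np.ndarray]:
    c = anchors.centres
    return {
        str(chrom): np.sort(sub["centre"].to_numpy())
        for chrom, sub in c.groupby("chrom", sort=False)
    }


def _nearest_distance(pos: np.ndarray, centres: np.ndarray) -> np.ndarray:
    if len(centres) == 0:
        return np.full(len(pos), np.inf)
    idx = np.searchsorted(centres, pos)
    left = centres[np.clip(idx - 1, 0, len(centres) - 1)]
    right = centres[np.clip(idx, 0, len(centres) - 1)]
    return np.minimum(np.abs(pos - left), np.abs(pos - right))


def simulate_genome(
    config: SimulationConfig,
    anchors: AnchorSet | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeLayout, SequenceStore]:
    """I.i.d. uniform ACGT sequences, with PRDM9 consensus planted at anchors.

    When ``anchors`` is given, the consensus (its two N positions drawn
    uniformly) is written at a uniform position inside a ``prdm9_fraction``
    of the anchors.
    """
    rng = rng or np.random.default_rng(config.seed)
    layout = config.layout()
    seqs = {}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom, length in layout:
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        seqs[chrom] = base_bytes[codes].tobytes().decode("ascii")
    if anchors is not None and config.prdm9_fraction > 0:
        df = anchors.laps.df
        n_plant = int(round(config.prdm9_fraction * len(df)))
        chosen = rng.choice(len(df), size=n_plant, replace=False)
        for i in sorted(chosen):
            row = df.iloc[i]
            lo, hi = int(row["start"]), int(row["end"]) - len(_PRDM9_SEQ)
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            motif = "".join(
                str(_BASES[rng.integers(0, 4)]) if c == "N" else c for c in _PRDM9_SEQ
            )
            s = seqs[row["chrom"]]
            seqs[row["chrom"]] = s[:pos] + motif + s[pos + len(motif):]
    return layout, SequenceStore(seqs, layout=layout)


def simulate_anchors_hotspots(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[IntervalSet], AnchorSet, IntervalSet]:
    """Per-cell-line motif sets, the union anchor set, and hotspots.

    A ``shared_core_fraction`` of the union anchors carries a motif in every
    cell line; each remaining anchor is private to one cell line. A fraction
    ``overlap_fraction`` of union anchors receives a hotspot overlapping its
    centre; the remaining hotspots are placed uniformly away from anchors.
    """
    rng = rng or np.random.default_rng(config.seed)
    layout = config.layout()
    margin = 600_000  # keep 1-Mb windows on-chromosome
    # anchor motif centres: uniform with a minimum separation of 4x anchor width
    centres: list[tuple[str, int]] = []
    names = layout.names
    weights = np.array([layout.length(c) for c in names], dtype=float)
    weights /= weights.sum()
    min_sep = 4 * config.anchor_width
    occupied: dict[str, list[int]] = {c: [] for c in names}
    attempts = 0
    while len(centres) < config.n_union_anchors:
        attempts += 1
        if attempts > 200 * config.n_union_anchors:
            raise RuntimeError("could not place anchors; genome too small")
        chrom = str(rng.choice(names, p=weights))
        L = layout.length(chrom)
        if L <= 2 * margin:
            raise ValueError(f"chromosome {chrom} too short for 1-Mb windows")
        pos = int(rng.integers(margin, L - margin))
        if all(abs(pos - q) >= min_sep for q in occupied[chrom]):
            occupied[chrom].append(pos)
            centres.append((chrom, pos))

    mw = config.motif_width
    motif_df = pd.DataFrame(
        {
            "chrom": [c for c, _ in centres],
            "start": [p - mw // 2 for _, p in centres],
            "end": [p - mw // 2 + mw for _, p in centres],
            "strand": [str(rng.choice(["+", "-"])) for _ in centres],
        }
    )
    n_core = int(round(config.shared_core_fraction * len(motif_df)))
    order = rng.permutation(len(motif_df))
    core_idx = set(order[:n_core].tolist())
    owner = {
        int(i): int(rng.integers(0, config.n_cell_lines))
        for i in order[n_core:]
    }
    cell_sets = []
    for cl in range(config.n_cell_lines):
        rows = [
            i for i in range(len(motif_df)) if i in core_idx or owner.get(i) == cl
        ]
        cell_sets.append(IntervalSet(motif_df.iloc[rows], layout=layout))
    anchors = build_union_laps(cell_sets, layout, anchor_width=config.anchor_width)

    # hotspots: planted overlaps first, the rest uniform and anchor-free
    n_planted = int(round(config.overlap_fraction * len(anchors)))
    if n_planted > config.hotspot_count:
        raise ValueError("overlap_fraction infeasible for hotspot_count")
    lap_df = anchors.laps.df
    chosen = rng.choice(len(lap_df), size=n_planted, replace=False)
    hs_rows = []
    hw = config.hotspot_width
    for i in chosen:
        row = lap_df.iloc[int(i)]
        centre = int((row["start"] + row["end"]) // 2)
        jitter = int(rng.integers(-config.anchor_width // 4, config.anchor_width // 4))
        s = max(centre + jitter - hw // 2, 0)
        hs_rows.append((row["chrom"], s, s + hw))
    anchor_centres = _anchor_centres(anchors)
    placed = 0
    guard = 0
    while placed < config.hotspot_count - n_planted:
        guard += 1
        if guard > 200 * config.hotspot_count:
            raise RuntimeError("could not place hotspots away from anchors")
        chrom = str(rng.choice(names, p=weights))
        L = layout.length(chrom)
        pos = int(rng.integers(hw, L - hw))
        d = _nearest_distance(np.array([pos]), anchor_centres.get(chrom, np.array([])))
        if d[0] > config.anchor_width:  # clear of every anchor
            hs_rows.append((chrom, pos - hw // 2, pos - hw // 2 + hw))
            placed += 1
    hotspots = IntervalSet(
        pd.DataFrame(hs_rows, columns=["chrom", "start", "end"]), layout=layout
    )
    return cell_sets, anchors, hotspots


def _draw_inhomogeneous(
    rng: np.random.Generator,
    layout: GenomeLayout,
    rate_fn,
    bound: float,
) -> pd.DataFrame:
    """Thinning sampler: candidate positions at the per-bp ``bound`` rate,
    accepted with probability rate(chrom, pos)/bound."""
    rows = []
    for chrom, length in layout:
        n_cand = rng.poisson(bound * length)
        if n_cand == 0:
            continue
        pos = rng.integers(0, length, size=n_cand)
        accept = rng.random(n_cand) < rate_fn(chrom, pos) / bound
        rows.append(pd.DataFrame({"chrom": chrom, "pos": np.sort(pos[accept])}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos"])
    return pd.concat(rows, ignore_index=True)


def simulate_mutations(
    config: SimulationConfig,
    anchors: AnchorSet,
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
    sequences: SequenceStore | None = None,
) -> MutationCatalog:
    """SNV and SV catalogs from the inhomogeneous point-process rate model.

    Samples are i.i.d.; the aggregate process over ``n_samples`` is drawn at
    once and sample labels are assigned uniformly. SV records pair breakpoints
    drawn from the enriched process within each chromosome (sample assigned
    per pair), so the realised breakpoints follow b(d) exactly; at most one
    drawn breakpoint per chromosome is lost to pairing.
    """
    rng = rng or np.random.default_rng(config.seed)
    centres = _anchor_centres(anchors)
    motif_half = config.motif_width // 2
    lam = config.dip_scale

    def snv_rate(chrom: str, pos: np.ndarray) -> np.ndarray:
        d = _nearest_distance(pos, centres.get(chrom, np.array([])))
        rate = 1.0 - config.dip_depth * np.exp(-d / lam)
        if config.nucleosome_ripple > 0:
            rate *= 1.0 + config.nucleosome_ripple * np.cos(2 * np.pi * d / 190.0)
        in_motif = d <= motif_half
        rate = np.where(in_motif, rate * config.focal_mult, rate)
        return config.snv_rate / 1e6 * config.n_samples * rate

    def bp_rate(chrom: str, pos: np.ndarray) -> np.ndarray:
        d = _nearest_distance(pos, centres.get(chrom, np.array([])))
        return (
            config.sv_rate
            / 1e6
            * config.n_samples
            * (1.0 + config.sv_enrichment * np.exp(-d / lam))
        )

    snv_bound = (
        config.snv_rate / 1e6 * config.n_samples * max(1.0, config.focal_mult)
        * (1.0 + config.nucleosome_ripple)
    )
    snv_pos = _draw_inhomogeneous(rng, layout, snv_rate, snv_bound)
    sample_ids = np.array([f"S{i:04d}" for i in range(config.n_samples)])
    snv_samples = sample_ids[rng.integers(0, config.n_samples, size=len(snv_pos))]
    refs, alts = [], []
    for row in snv_pos.itertuples(index=False):
        ref = (
            sequences[row.chrom][row.pos]
            if sequences is not None
            else str(_BASES[rng.integers(0, 4)])
        )
        if ref not in "ACGT":
            ref = str(_BASES[rng.integers(0, 4)])
        others = [b for b in "ACGT" if b != ref]
        refs.append(ref)
        alts.append(others[int(rng.integers(0, 3))])
    snvs = pd.DataFrame(
        {
            "sample_id": snv_samples,
            "chrom": snv_pos["chrom"],
            "pos": snv_pos["pos"],
            "ref": refs,
            "alt": alts,
        }
    )

    bp_bound = config.sv_rate / 1e6 * config.n_samples * (1.0 + config.sv_enrichment)
    bp_pos = _draw_inhomogeneous(rng, layout, bp_rate, bp_bound)
    sv_rows = []
    classes = np.array(["DEL", "DUP", "INV"])
    # pair breakpoints within each chromosome across the cohort and assign a
    # sample per pair: at most one drawn breakpoint per chromosome is lost
    for chrom, sub in bp_pos.groupby("chrom", sort=False):
        pos = rng.permutation(sub["pos"].to_numpy())
        for k in range(len(pos) // 2):
            p1, p2 = sorted((int(pos[2 * k]), int(pos[2 * k + 1])))
            if p1 == p2:
                p2 += 1
            sample = str(sample_ids[rng.integers(0, config.n_samples)])
            sv_rows.append(
                (sample, chrom, p1, p2, str(classes[rng.integers(0, 3)]))
            )
    svs = pd.DataFrame(
        sv_rows, columns=["sample_id", "chrom", "start", "end", "sv_class"]
    )
    return MutationCatalog(snvs=snvs, svs=svs)


def simulate_tracks(
    config: SimulationConfig,
    anchors: AnchorSet,
    layout: GenomeLayout,
    rng: np.random.Generator | None = None,
) -> tuple[IntervalSet, pd.DataFrame]:
    """DSB peaks with a planted fold-enrichment at anchors, plus a smooth
    replication-timing signal with an anchor-proximal elevation."""
    rng = rng or np.random.default_rng(config.seed)
    anchor_bp = anchors.laps.total_bp
    total_bp = layout.total_bp
    fold = config.dsb_fold
    # peak-centre placement: inside-anchor probability proportional to fold x bp
    p_anchor = fold * anchor_bp / (fold * anchor_bp + (total_bp - anchor_bp))
    n_in = int(rng.binomial(config.dsb_count, p_anchor))
    lap_df = anchors.laps.df
    w = config.dsb_width
    rows = []
    lap_pick = rng.integers(0, len(lap_df), size=n_in)
    for i in lap_pick:
        row = lap_df.iloc[int(i)]
        # peaks sit fully inside the anchor so bp-overlap ratios recover the fold
        c = int(rng.integers(row["start"] + w // 2, row["end"] - w // 2))
        rows.append((row["chrom"], c - w // 2, c - w // 2 + w))
    names = layout.names
    weights = np.array([layout.length(c) for c in names], dtype=float)
    weights /= weights.sum()
    centres = _anchor_centres(anchors)
    placed = 0
    guard = 0
    while placed < config.dsb_count - n_in:
        guard += 1
        if guard > 200 * config.dsb_count:
            raise RuntimeError("could not place DSB peaks outside anchors")
        chrom = str(rng.choice(names, p=weights))
        L = layout.length(chrom)
        c = int(rng.integers(w, L - w))
        d = _nearest_distance(np.array([c]), centres.get(chrom, np.array([])))
        if d[0] > config.anchor_width // 2 + w:
            rows.append((chrom, c - w // 2, c - w // 2 + w))
            placed += 1
    dsb = IntervalSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), layout=layout
    )

    rt_rows = []
    for chrom, length in layout:
        edges = np.arange(0, length - config.rt_step + 1, config.rt_step)
        mids = edges + config.rt_step // 2
        noise = rng.normal(0, 1, size=len(edges))
        kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(noise, kernel, mode="same")
        d = _nearest_distance(mids, centres.get(chrom, np.array([])))
        signal = smooth + config.rt_amplitude * np.exp(-d / config.dip_scale)
        rt_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": edges,
                    "end": edges + config.rt_step,
                    "value": signal,
                }
            )
        )
    rt = pd.concat(rt_rows, ignore_index=True)
    return dsb, rt


def simulate_bundle(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SyntheticBundle:
    """Generate a fully consistent bundle from one config and seed."""
    rng = np.random.default_rng(config.seed)
    cell_sets, anchors, hotspots = simulate_anchors_hotspots(config, rng)
    layout, sequences = simulate_genome(config, anchors=anchors, rng=rng)
    catalog = simulate_mutations(config, anchors, layout, rng, sequences=sequences)
    dsb, rt = simulate_tracks(config, anchors, layout, rng)
    truth = {k: (v if not isinstance(v, dict) else v) for k, v in asdict(config).items()}
    bundle = SyntheticBundle(
        config=config,
        layout=layout,
        sequences=sequences,
        cell_line_motifs=cell_sets,
        anchors=anchors,
        hotspots=hotspots,
        dsb_peaks=dsb,
        replication_timing=rt,
        catalog=catalog,
        ground_truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
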