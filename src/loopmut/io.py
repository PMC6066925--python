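"""Readers/writers for the text formats the pipeline touches.

Mutation tables follow the ICGC simple-somatic-mutation export layout
(1-based inclusive coordinates) with a configurable column mapping; BED is
0-based half-open; FASTA goes through Biopython. All readers are
gzip-transparent (by file extension).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import BED_COLUMNS, CoordinateError, GenomeLayout, IntervalSet

__all__ = [
    "SNVRecord",
    "SVRecord",
    "MutationCatalog",
    "SequenceStore",
    "SchemaError",
    "ICGC_COLUMNS",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_mutation_table",
    "write_mutation_table",
]

SNV_FIELDS = ["sample_id", "chrom", "pos", "ref", "alt"]
SV_FIELDS = ["sample_id", "chrom", "start", "end", "sv_class"]

#: default column mapping, mirroring ICGC simple-somatic-mutation exports
ICGC_COLUMNS: Mapping[str, str] = {
    "sample_id": "icgc_sample_id",
    "chrom": "chromosome",
    "start": "chromosome_start",
    "end": "chromosome_end",
    "ref": "reference_genome_allele",
    "alt": "mutated_to_allele",
    "sv_class": "variant_type",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class SNVRecord:
    sample_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-base alleles are supported")


@dataclass(frozen=True)
class SVRecord:
    sample_id: str
    chrom: str
    start: int
    end: int
    sv_class: str = "other"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("SV start exceeds end")


@dataclass
class MutationCatalog:
    """Per-sample SNV and SV calls as two flat tables.

    ``snvs`` columns: sample_id, chrom, pos (0-based), ref, alt.
    ``svs`` columns: sample_id, chrom, start, end (0-based half-open), sv_class.
    """

    snvs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SNV_FIELDS))
    svs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SV_FIELDS))

    def __post_init__(self) -> None:
        snvs = self.snvs[SNV_FIELDS].copy() if len(self.snvs) else pd.DataFrame(
            columns=SNV_FIELDS
        )
        snvs["pos"] = snvs["pos"].astype(np.int64)
        self.snvs = snvs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )
        svs = self.svs[SV_FIELDS].copy() if len(self.svs) else pd.DataFrame(
            columns=SV_FIELDS
        )
        svs["start"] = svs["start"].astype(np.int64)
        svs["end"] = svs["end"].astype(np.int64)
        self.svs = svs.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        ids = set(self.snvs["sample_id"]) | set(self.svs["sample_id"])
        return len(ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def n_svs(self) -> int:
        return len(self.svs)

    def merged_with(self, other: "MutationCatalog") -> "MutationCatalog":
        return MutationCatalog(
            snvs=pd.concat([self.snvs, other.snvs], ignore_index=True),
            svs=pd.concat([self.svs, other.svs], ignore_index=True),
        )


class SequenceStore:
    """Uppercase per-chromosome nucleotide strings over {A, C, G, T, N}."""

    def __init__(self, sequences: Mapping[str, str], layout: GenomeLayout | None = None):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        if layout is not None:
            for name, seq in self._seqs.items():
                if layout.length(name) != len(seq):
                    raise ValueError(
                        f"sequence length for {name} ({len(seq)}) does not match "
                        f"layout ({layout.length(name)})"
                    )
        self.layout = layout or GenomeLayout(
            (name, len(seq)) for name, seq in self._seqs.items()
        )

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs.items())

    @property
    def names(self) -> list[str]:
        return list(self._seqs)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# -- chrom.sizes ------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeLayout(zip(df["chrom"], df["length"]))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, sep="\t", header=False, index=False)


# -- BED --------------------------------------------------------------------

def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read BED3/BED6; comment, header and track lines are skipped."""
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise CoordinateError(f"{path}:{ln}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, strand, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])
    return IntervalSet(df, layout=layout)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED6 (name '.' when unset, score 0)."""
    df = intervals.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["name"].fillna("."),
            "score": 0,
            "strand": df["strand"],
        }
    )
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path, layout: GenomeLayout | None = None) -> SequenceStore:
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA record {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    return SequenceStore(seqs, layout=layout)


def write_fasta(store: SequenceStore, path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in store:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- mutation tables --------------------------------------------------------

def read_mutation_table(
    path: str | Path,
    kind: str,
    columns: Mapping[str, str] = ICGC_COLUMNS,
) -> tuple[MutationCatalog, int]:
    """Read an ICGC-like TSV of SNV or SV calls.

    Input coordinates are 1-based inclusive and are converted to the internal
    0-based half-open convention exactly once here. Malformed rows (non-numeric
    positions, identical ref/alt, multi-base alleles for SNVs) are dropped and
    counted.

    Returns
    -------
    (catalog, n_malformed)
    """
    if kind not in ("snv", "sv"):
        raise ValueError("kind must be 'snv' or 'sv'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["sample_id", "chrom", "start", "end"] + (
        ["ref", "alt"] if kind == "snv" else ["sv_class"]
    )
    for key in needed:
        col = columns.get(key, key)
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} (for {key})")
    ren = {columns.get(k, k): k for k in needed}
    df = df.rename(columns=ren)[needed]

    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    bad = start.isna() | end.isna()
    if kind == "snv":
        bad |= (
            (df["ref"] == df["alt"])
            | (df["ref"].str.len() != 1)
            | (df["alt"].str.len() != 1)
        )
    else:
        bad |= end < start
    n_bad = int(bad.sum())
    df, start, end = df[~bad], start[~bad], end[~bad]

    if kind == "snv":
        snvs = pd.DataFrame(
            {
                "sample_id": df["sample_id"],
                "chrom": df["chrom"],
                "pos": start.astype(np.int64) - 1,  # 1-based -> 0-based
                "ref": df["ref"],
                "alt": df["alt"],
            }
        )
        return MutationCatalog(snvs=snvs), n_bad
    svs = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "chrom": df["chrom"],
            "start": start.astype(np.int64) - 1,
            "end": end.astype(np.int64),  # inclusive end -> half-open
            "sv_class": df["sv_class"],
        }
    )
    return MutationCatalog(svs=svs), n_bad


def write_mutation_table(
    catalog: MutationCatalog,
    path: str | Path,
    kind: str,
    columns: Mapping[str, str] = ICGC_COLUMNS,
) -> None:
    """Write the catalog back out in the 1-based inclusive TSV layout."""
    if kind == "snv":
        df = catalog.snvs
        out = pd.DataFrame(
            {
                columns.get("sample_id", "sample_id"): df["sample_id"],
                columns.get("chrom", "chrom"): df["chrom"],
                columns.get("start", "start"): df["pos"] + 1,
                columns.get("end", "end"): df["pos"] + 1,
                columns.get("ref", "ref"): df["ref"],
                columns.get("alt", "alt"): df["alt"],
            }
        )
    elif kind == "sv":
        df = catalog.svs
        out = pd.DataFrame(
            {
                columns.get("sample_id", "sample_id"): df["sample_id"],
                columns.get("chrom", "chrom"): df["chrom"],
                columns.get("start", "start"): df["start"] + 1,
                columns.get("end", "end"): df["end"],
                columns.get("sv_class", "sv_class"): df["sv_class"],
            }
        )
    else:
        raise ValueError("kind must be 'snv' or 'sv'")
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def normalize_chrom_names(names: pd.Series, add_prefix: bool | None = None) -> pd.Series:
    """Optionally strip or add a 'chr' prefix (None leaves names untouched)."""
    if add_prefix is None:
        return names
    stripped = names.str.removeprefix("chr")
    return ("chr" + stripped) if add_prefix else stripped
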