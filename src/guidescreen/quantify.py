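"""Guide quantification from raw amplicon reads.

Single-end reads carry an 8-mer sample barcode at a fixed offset and the
protospacer at a second fixed offset. Both lookups are exact-match only: a
read whose barcode matches no sample is unassigned; a read whose extracted
L-mer matches no library protospacer is counted as unmatched for its sample.
No mismatch tolerance, no quality filtering.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from guidescreen.counts import CountMatrix
from guidescreen.library import GuideLibrary

BARCODE_LENGTH = 8
VALID_GROUP_PREFIXES = ("cells_500x", "lung_4h", "lung_19d")


class QuantificationError(ValueError):
    pass


@dataclass
class SampleSheet:
    """Sample annotations: id, 8-mer barcode, group, optional mouse/run."""

    records: pd.DataFrame  # columns: sample_id, barcode, group, mouse_id, run

    def __post_init__(self) -> None:
        df = self.records
        required = {"sample_id", "barcode", "group"}
        missing = required - set(df.columns)
        if missing:
            raise QuantificationError(f"sample sheet missing columns: {sorted(missing)}")
        for opt in ("mouse_id", "run"):
            if opt not in df.columns:
                df[opt] = ""
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise QuantificationError(f"duplicate sample_id(s): {dups}")
        bad_len = df.loc[df["barcode"].str.len() != BARCODE_LENGTH, "barcode"].tolist()
        if bad_len:
            raise QuantificationError(f"barcodes not {BARCODE_LENGTH}-mers: {bad_len}")
        for run, sub in df.groupby(df["run"].fillna("")):
            if sub["barcode"].duplicated().any():
                dups = sub.loc[sub["barcode"].duplicated(), "barcode"].tolist()
                raise QuantificationError(f"duplicate barcode(s) within run {run!r}: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    def groups(self) -> dict[str, str]:
        return dict(zip(self.records["sample_id"], self.records["group"]))

    def barcode_map(self) -> dict[str, str]:
        return dict(zip(self.records["barcode"], self.records["sample_id"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep, dtype=str).fillna(""))

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class CountColumn:
    """Per-sample quantification result; matched + unmatched = total reads."""

    sample_id: str
    counts: pd.Series  # index = guide_id, nonnegative ints
    n_unmatched: int = 0

    @property
    def n_matched(self) -> int:
        return int(self.counts.sum())

    @property
    def n_total_reads(self) -> int:
        return self.n_matched + self.n_unmatched


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ (optionally gzipped) file."""
    with _open_text(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


def demultiplex(
    reads: Iterable[str], sheet: SampleSheet, barcode_offset: int = 0
) -> tuple[dict[str, list[str]], int]:
    """Route reads to samples by exact 8-mer barcode match at the given offset.

    Returns (sample_id -> list of reads, number of unassigned reads).
    """
    barcode_map = sheet.barcode_map()  # validated unique per run at sheet build
    out: dict[str, list[str]] = {sid: [] for sid in sheet.sample_ids}
    unassigned = 0
    end = barcode_offset + BARCODE_LENGTH
    for seq in reads:
        sid = barcode_map.get(seq[barcode_offset:end])
        if sid is None:
            unassigned += 1
        else:
            out[sid].append(seq)
    return out, unassigned


def count_guides(
    reads: Iterable[str],
    lib: GuideLibrary,
    spacer_offset: int,
    sample_id: str = "",
) -> CountColumn:
    """Count exact protospacer matches at a fixed offset.

    Reads shorter than ``spacer_offset + L`` and reads whose extracted L-mer
    is not in the library are counted as unmatched, never truncated-matched.
    """
    index = lib.spacer_index()
    if len(index) != lib.n_total:
        raise QuantificationError("ambiguous index: duplicate protospacers")
    L = lib.protospacer_length
    end = spacer_offset + L
    counts = dict.fromkeys(lib.guide_ids, 0)
    unmatched = 0
    for seq in reads:
        if len(seq) < end:
            unmatched += 1
            continue
        gid = index.get(seq[spacer_offset:end].upper())
        if gid is None:
            unmatched += 1
        else:
            counts[gid] += 1
    return CountColumn(sample_id, pd.Series(counts, name=sample_id), unmatched)


def find_spacer_offset(reads: Iterable[str], anchor: str, max_reads: int = 1000) -> int:
    """Fallback for variable-offset data: locate the constant vector-homology
    anchor in a sample of reads and return the majority offset just past it."""
    from collections import Counter

    offsets: Counter[int] = Counter()
    for i, seq in enumerate(reads):
        if i >= max_reads:
            break
        pos = seq.find(anchor)
        if pos >= 0:
            offsets[pos + len(anchor)] += 1
    if not offsets:
        raise QuantificationError(f"anchor {anchor!r} not found in any read")
    return offsets.most_common(1)[0][0]


def merge_columns(
    columns: Iterable[CountColumn],
    sheet: SampleSheet,
    lib: GuideLibrary,
    duplicates: str = "sum",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Assemble count columns into a guides x samples matrix.

    Technical re-runs of the same sample_id are combined according to
    ``duplicates``: "sum" (default), "keep-first", or "keep-both" (suffixed
    ids). A concordance report (Pearson r of log1p counts between duplicate
    pairs) is returned alongside the matrix.
    """
    if duplicates not in ("sum", "keep-first", "keep-both"):
        raise QuantificationError(f"unknown duplicates mode {duplicates!r}")
    guide_index = pd.Index(lib.guide_ids)
    merged: dict[str, pd.Series] = {}
    concordance_rows = []
    for col in columns:
        if not col.counts.index.equals(guide_index):
            raise QuantificationError(
                f"column {col.sample_id!r} does not match the library guide axis"
            )
        sid = col.sample_id
        if sid in merged:
            a = np.log1p(merged[sid].to_numpy(dtype=float))
            b = np.log1p(col.counts.to_numpy(dtype=float))
            r = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else np.nan
            concordance_rows.append(dict(sample_id=sid, pearson_r_log=r))
            if duplicates == "sum":
                merged[sid] = merged[sid] + col.counts
            elif duplicates == "keep-both":
                k = 2
                while f"{sid}__rep{k}" in merged:
                    k += 1
                merged[f"{sid}__rep{k}"] = col.counts
            # keep-first: drop the rerun
        else:
            merged[sid] = col.counts
    values = pd.DataFrame(merged, index=guide_index)
    genes = pd.Series(lib.genes, name="gene").reindex(guide_index)
    groups = sheet.groups()
    groups = {s: groups.get(s.split("__rep")[0], "") for s in values.columns}
    cm = CountMatrix(values, genes, groups)
    report = pd.DataFrame(concordance_rows, columns=["sample_id", "pearson_r_log"])
    return cm, report


def quantify_fastq(
    fastq_paths: Iterable[str | Path],
    sheet: SampleSheet,
    lib: GuideLibrary,
    barcode_offset: int = 0,
    spacer_offset: int = 30,
    duplicates: str = "sum",
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Demultiplex and count one or more FASTQ files against a library.

    Returns (count matrix, demux summary table, duplicate-concordance table).
    """
    all_columns: list[CountColumn] = []
    summary_rows = []
    for path in fastq_paths:
        per_sample, unassigned = demultiplex(iter_reads(path), sheet, barcode_offset)
        for sid, reads in per_sample.items():
            col = count_guides(reads, lib, spacer_offset, sample_id=sid)
            all_columns.append(col)
            summary_rows.append(
                dict(sample_id=sid, fastq=str(path), n_reads=col.n_total_reads,
                     n_matched=col.n_matched, n_unmatched=col.n_unmatched)
            )
        summary_rows.append(
            dict(sample_id="<unassigned>", fastq=str(path), n_reads=unassigned,
                 n_matched=0, n_unmatched=unassigned)
        )
    cm, concordance = merge_columns(all_columns, sheet, lib, duplicates=duplicates)
    return cm, pd.DataFrame(summary_rows), concordance
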