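"""Readers and writers for the pipeline's plain-text formats.

Three formats are handled here:

* **readcounts TSV** — one file per pooled library. A header line followed by
  tab-separated columns ``chrom  pos  ref  depth  BASE:count [BASE:count ...]``
  with 1-based positions. ``depth`` must equal the sum of the listed allele
  counts. This is a documented simplification of the Varscan2 "readcounts"
  output the dialect is modelled on; base qualities are assumed to have been
  applied upstream by the readcount producer and are not re-filtered here.
* **BED3+** — gene and pre-miRNA hairpin intervals, 0-based half-open on disk.
  Internal coordinates are 1-based inclusive everywhere; the conversion
  happens only at this boundary.
* **depth TSV** — per-base coverage, columns ``chrom  pos  depth_<lib>...``.

All readers accept gzip-compressed input (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: Column order of the wide per-site count matrix used by the association scan.
SITE_KEY_COLUMNS = ["chrom", "pos", "ref_base", "alt_base", "multiallelic"]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class GenomicInterval:
    """A named 1-based inclusive interval (gene or pre-miRNA hairpin)."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str = "gene"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid interval {self.name}: [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.start, iv.end, iv.name, iv.kind) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "kind"])


def frame_to_intervals(frame: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.name, r.kind)
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# readcounts TSV
# ---------------------------------------------------------------------------

def parse_readcounts(path) -> pd.DataFrame:
    """Parse one library's readcounts file into per-base counts.

    Returns a frame with columns ``chrom, pos, ref, A, C, G, T``; alleles not
    listed on a row are 0. Raises :class:`ParseError` with the offending line
    number on malformed rows or unknown base symbols.
    """
    rows = []
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ParseError(f"{path}: missing header line (expected 'chrom...')")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
            chrom, pos_s, ref, depth_s = fields[:4]
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer pos/depth") from exc
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1")
            if ref not in BASES:
                raise ParseError(f"{path}:{lineno}: unknown reference base {ref!r}")
            counts = dict.fromkeys(BASES, 0)
            for pair in fields[4:]:
                base, _, count_s = pair.partition(":")
                if base not in BASES:
                    raise ParseError(f"{path}:{lineno}: unknown base symbol {base!r}")
                try:
                    count = int(count_s)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer count {count_s!r}") from exc
                if count < 0:
                    raise ParseError(f"{path}:{lineno}: negative count")
                counts[base] = count
            if depth != sum(counts.values()):
                raise ParseError(
                    f"{path}:{lineno}: depth {depth} != sum of allele counts "
                    f"{sum(counts.values())}"
                )
            rows.append((chrom, pos, ref, counts["A"], counts["C"], counts["G"], counts["T"]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T"])


def write_readcounts(counts: pd.DataFrame, path) -> None:
    """Write a per-base count frame (``parse_readcounts`` layout) to TSV."""
    with open(path, "wt") as fh:
        fh.write("chrom\tpos\tref\tdepth\tcounts\n")
        for r in counts.itertuples(index=False):
            base_counts = {b: getattr(r, b) for b in BASES}
            depth = sum(base_counts.values())
            pairs = [
                f"{b}:{c}" for b, c in base_counts.items() if c > 0 or b == r.ref
            ]
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{depth}\t" + "\t".join(pairs) + "\n")


def _reduce_biallelic(merged: pd.DataFrame, library_ids: Sequence[str]) -> pd.DataFrame:
    """Pick ref/alt per site from pooled counts across libraries.

    The alt allele is the non-reference allele with the largest count summed
    over all libraries; sites with any third observed allele are flagged
    multiallelic. Orientation is fixed by the stated ref base so the
    association statistic is invariant to allele labelling.
    """
    pooled = {b: sum(merged[f"{b}_{lib}"] for lib in library_ids) for b in BASES}
    pooled_mat = np.column_stack([pooled[b] for b in BASES])
    ref_idx = merged["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    nonref = pooled_mat.copy()
    nonref[np.arange(len(merged)), ref_idx] = -1
    alt_idx = nonref.argmax(axis=1)
    n_observed = (pooled_mat > 0).sum(axis=1)
    out = merged[["chrom", "pos"]].copy()
    out["ref_base"] = merged["ref"].to_numpy()
    out["alt_base"] = np.array(BASES)[alt_idx]
    out["multiallelic"] = n_observed > 2
    for lib in library_ids:
        lib_mat = np.column_stack([merged[f"{b}_{lib}"] for b in BASES])
        out[f"ref_{lib}"] = lib_mat[np.arange(len(merged)), ref_idx]
        out[f"alt_{lib}"] = lib_mat[np.arange(len(merged)), alt_idx]
    return out


def load_pool_counts(
    paths: Mapping[str, object], min_coverage: int = 22
) -> pd.DataFrame:
    """Read one readcounts file per library and build the wide site matrix.

    ``paths`` maps library ids (e.g. ``R1, R2, S1, S2`` — strain letter plus
    replicate index) to file paths. Sites with total depth below
    ``min_coverage`` in *any* library are excluded, matching the upstream
    minimum-coverage requirement of one read per pooled diploid genome.
    Multiallelic sites are reduced to the reference base plus the highest-count
    alternate allele (pooled across libraries) and flagged.
    """
    if not paths:
        raise SchemaError("no libraries given")
    tables = {}
    for lib, path in paths.items():
        table = parse_readcounts(path)
        table["depth"] = table[list(BASES)].sum(axis=1)
        tables[lib] = table
    library_ids = list(paths)
    merged = None
    for lib, table in tables.items():
        renamed = table.rename(
            columns={b: f"{b}_{lib}" for b in BASES} | {"depth": f"depth_{lib}"}
        )
        if merged is None:
            merged = renamed
        else:
            merged = merged.merge(renamed, on=["chrom", "pos", "ref"], how="inner")
    depth_cols = [f"depth_{lib}" for lib in library_ids]
    keep = (merged[depth_cols] >= min_coverage).all(axis=1)
    merged = merged.loc[keep].reset_index(drop=True)
    wide = _reduce_biallelic(merged, library_ids)
    wide["depth_total"] = sum(
        wide[f"ref_{lib}"] + wide[f"alt_{lib}"] for lib in library_ids
    )
    return wide


def read_readcounts(path, min_coverage: int = 22) -> pd.DataFrame:
    """Read a single library's sites, applying the coverage filter.

    Single-library convenience over :func:`load_pool_counts`; the returned
    frame has ``ref_count``/``alt_count``/``depth`` columns for that library.
    """
    wide = load_pool_counts({"lib": path}, min_coverage=min_coverage)
    out = wide[SITE_KEY_COLUMNS].copy()
    out["ref_count"] = wide["ref_lib"]
    out["alt_count"] = wide["alt_lib"]
    out["depth"] = out["ref_count"] + out["alt_count"]
    return out


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path, kind: str = "gene") -> list[GenomicInterval]:
    """Read BED3+ intervals, converting to 1-based inclusive coordinates.

    Ordering is preserved and overlapping intervals are permitted. Rows with
    ``end <= start`` (empty/inverted in BED) are rejected.
    """
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start0 >= end0:
                raise ParseError(f"{path}:{lineno}: start >= end in BED row")
            name = fields[3] if len(fields) > 3 else f"{kind}_{lineno}"
            intervals.append(GenomicInterval(chrom, start0 + 1, end0, name, kind))
    return intervals


def write_intervals_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# per-base depth tables
# ---------------------------------------------------------------------------

def read_depth_table(path) -> pd.DataFrame:
    """Read a per-base depth TSV (``chrom  pos  depth...`` with header)."""
    with _open_text(path) as fh:
        table = pd.read_csv(fh, sep="\t")
    required = {"chrom", "pos"}
    if not required.issubset(table.columns):
        raise SchemaError(f"{path}: depth table needs columns {sorted(required)}")
    depth_cols = [c for c in table.columns if c not in ("chrom", "pos")]
    if not depth_cols:
        raise SchemaError(f"{path}: depth table has no depth columns")
    if (table[depth_cols].to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative depth")
    return table


def write_depth_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def interval_mean_depth(
    depth: pd.DataFrame,
    interval: GenomicInterval,
    min_coverage: int = 22,
) -> tuple[float, float]:
    """Mean per-base depth over an interval, absent positions counted as 0.

    Returns ``(mean_depth, covered_fraction)`` where ``covered_fraction`` is
    the fraction of interval bases with total depth >= ``min_coverage``.
    Depth columns beyond the first are summed (one column per library). A
    chromosome missing from the table yields mean 0 with a logged warning.
    """
    depth_cols = [c for c in depth.columns if c not in ("chrom", "pos")]
    on_chrom = depth.loc[depth["chrom"] == interval.chrom]
    if on_chrom.empty:
        logger.warning(
            "chromosome %s absent from depth table; interval %s gets mean depth 0",
            interval.chrom,
            interval.name,
        )
        return 0.0, 0.0
    in_iv = on_chrom.loc[
        (on_chrom["pos"] >= interval.start) & (on_chrom["pos"] <= interval.end)
    ]
    per_base = in_iv[depth_cols].sum(axis=1).to_numpy()
    mean = float(per_base.sum()) / interval.length
    covered = float((per_base >= min_coverage).sum()) / interval.length
    return mean, covered
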