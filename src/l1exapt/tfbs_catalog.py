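"""ChIP-derived TF binding-site catalogues.

Ingests binding-site tables in two source dialects (GTRD meta-cluster
TSV and ChIP-Atlas BED), filters by cell line and by a whitelist of
sequence-specific DNA-binding TFs, merges nearby sites of the same TF
(bedtools-merge ``-d`` semantics: edge-to-edge gap <= d unions,
book-ended intervals merge at d = 0) and combines the two sources into
one catalogue per cell line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import MAIN_CHROMOSOMES, GenomicInterval

__all__ = [
    "TFBS",
    "TableDialect",
    "GTRD_DIALECT",
    "CHIPATLAS_DIALECT",
    "read_tfbs_table",
    "merge_per_tf",
    "filter_tf_whitelist",
    "combine_sources",
    "group_by_tf",
    "write_catalogue_bed",
]

GTRD = "GTRD"
CHIPATLAS = "CHIPATLAS"
COMBINED = "COMBINED"


@dataclass(frozen=True, order=True)
class TFBS:
    """One (merged) TF binding site.  ChIP peaks carry no meaningful
    strand, so the interval is unstranded."""

    interval: GenomicInterval
    tf: str
    cell_line: str
    source: str

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("TFBS requires a non-empty TF name")


@dataclass(frozen=True)
class TableDialect:
    """Column map for a tabular binding-site file.

    ``cell_line_col`` may be None for file-per-cell-line dialects (the
    caller's ``cell_line`` label is then attached to every record).
    ``tf_pattern`` optionally extracts the TF symbol from the name
    column (first capture group), for BED name fields that embed it.
    """

    chrom_col: int
    start_col: int
    end_col: int
    tf_col: int
    cell_line_col: int | None = None
    tf_pattern: str | None = None


#: GTRD meta-cluster dialect: chrom, start, end, TF symbol, cell line.
GTRD_DIALECT = TableDialect(0, 1, 2, 3, cell_line_col=4)

#: ChIP-Atlas BED dialect: chrom, start, end, name (the TF symbol), score.
CHIPATLAS_DIALECT = TableDialect(0, 1, 2, 3, cell_line_col=None)


def _norm_label(label: str) -> str:
    return label.strip().casefold()


def read_tfbs_table(
    path: str | Path,
    dialect: TableDialect,
    cell_line: str,
    source: str,
    main_chroms_only: bool = True,
) -> list[TFBS]:
    """Read one binding-site file, keeping records of ``cell_line``.

    Cell-line matching is exact after case-folding and whitespace
    stripping.  Records on alternate/unplaced chromosomes are dropped
    when ``main_chroms_only`` is set.  TF symbols are upper-cased.
    """
    tf_re = re.compile(dialect.tf_pattern) if dialect.tf_pattern else None
    want = _norm_label(cell_line)
    ncols = max(
        c
        for c in (
            dialect.chrom_col,
            dialect.start_col,
            dialect.end_col,
            dialect.tf_col,
            dialect.cell_line_col if dialect.cell_line_col is not None else 0,
        )
    )
    sites: list[TFBS] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= ncols:
                raise ValueError(f"{path}, line {lineno}: too few columns")
            raw_start = fields[dialect.start_col].strip()
            if lineno == 1 and not raw_start.lstrip("-").isdigit():
                continue  # header line
            try:
                start = int(fields[dialect.start_col])
                end = int(fields[dialect.end_col])
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: non-numeric coordinates"
                ) from None
            if dialect.cell_line_col is not None:
                if _norm_label(fields[dialect.cell_line_col]) != want:
                    continue
            chrom = fields[dialect.chrom_col]
            if main_chroms_only and chrom not in MAIN_CHROMOSOMES:
                continue
            name = fields[dialect.tf_col]
            if tf_re is not None:
                m = tf_re.search(name)
                if not m:
                    raise ValueError(
                        f"{path}, line {lineno}: cannot extract TF from {name!r}"
                    )
                name = m.group(1)
            sites.append(
                TFBS(
                    interval=GenomicInterval(chrom, start, end, "."),
                    tf=name.strip().upper(),
                    cell_line=cell_line,
                    source=source,
                )
            )
    return sites


def merge_per_tf(sites: Sequence[TFBS], gap_bp: int) -> list[TFBS]:
    """Union intervals of one TF whose edge-to-edge gap is <= ``gap_bp``.

    Overlapping and book-ended intervals always merge.  All input sites
    must share tf/cell_line/source (group first with :func:`group_by_tf`).
    Output is sorted by (chrom, start).
    """
    if not sites:
        return []
    keys = {(s.tf, s.cell_line, s.source) for s in sites}
    if len(keys) > 1:
        raise ValueError(f"merge_per_tf requires a single TF group, got {keys}")
    tf, cell_line, source = next(iter(keys))
    merged: list[TFBS] = []
    ordered = sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    cur = ordered[0].interval
    cur_start, cur_end, cur_chrom = cur.start, cur.end, cur.chrom
    for s in ordered[1:]:
        iv = s.interval
        if iv.chrom == cur_chrom and iv.start - cur_end <= gap_bp:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(
                TFBS(GenomicInterval(cur_chrom, cur_start, cur_end, "."), tf, cell_line, source)
            )
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(
        TFBS(GenomicInterval(cur_chrom, cur_start, cur_end, "."), tf, cell_line, source)
    )
    return merged


def filter_tf_whitelist(
    sites: Iterable[TFBS], whitelist: Iterable[str]
) -> list[TFBS]:
    """Keep sites whose TF is in ``whitelist`` (case-insensitive)."""
    allowed = {_norm_label(t) for t in whitelist}
    if not allowed:
        raise ValueError("empty TF whitelist")
    return [s for s in sites if _norm_label(s.tf) in allowed]


def group_by_tf(sites: Iterable[TFBS]) -> dict[str, list[TFBS]]:
    groups: dict[str, list[TFBS]] = {}
    for s in sites:
        groups.setdefault(s.tf, []).append(s)
    return groups


def combine_sources(a: Sequence[TFBS], b: Sequence[TFBS]) -> list[TFBS]:
    """Combine two source catalogues of one cell line.

    Per TF, the union of both lists is merged at gap 0 (overlapping and
    book-ended sites union); the result carries source ``COMBINED``.  A
    TF present in only one source passes through.
    """
    cells = {s.cell_line for s in a} | {s.cell_line for s in b}
    if len(cells) > 1:
        raise ValueError(f"cell-line mismatch between sources: {cells}")
    pooled = [replace(s, source=COMBINED) for s in list(a) + list(b)]
    out: list[TFBS] = []
    for tf in sorted(group_by_tf(pooled)):
        out.extend(merge_per_tf(group_by_tf(pooled)[tf], gap_bp=0))
    return out


def write_catalogue_bed(sites: Iterable[TFBS], path: str | Path) -> None:
    """Write a catalogue as BED with the TF symbol in the name column."""
    ordered = sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start, s.tf))
    with open(path, "w") as fh:
        for s in ordered:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.tf}\t0\t.\n")
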