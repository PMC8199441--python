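"""Repeat annotation handling for L1 transposon copies.

Reads RepeatMasker-dialect annotation tables (UCSC ``rmsk`` flavour),
models individual L1 insertions together with the coordinates of their
aligned span within the subfamily consensus sequence, derives full-length
elements and 5' UTR intervals, and extracts strand-specific genomic
sequence.

Coordinates are 0-based, half-open throughout, matching the UCSC table
dialect and BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pyfaidx import Fasta

__all__ = [
    "MAIN_CHROMOSOMES",
    "GenomicInterval",
    "TransposonCopy",
    "RmskFormatError",
    "read_rmsk_table",
    "full_length_filter",
    "derive_five_prime_utr",
    "extract_sequences",
    "write_bed",
]

#: Primary-assembly chromosome names (autosomes, sex chromosomes, chrM).
#: Alternate/random/unplaced contigs ("_alt", "_random", "chrUn...") are
#: excluded from every analysis when the main-chromosome filter is on.
MAIN_CHROMOSOMES = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
)

_STRANDS = {"+", "-", "."}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with optional strand ('.' = unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TransposonCopy:
    """One genomic L1 insertion.

    ``consensus_start``/``consensus_end`` give the half-open span of the
    copy's aligned bases within the subfamily consensus sequence, as
    recovered from the RepStart/RepEnd/RepLeft triple of the annotation.
    """

    interval: GenomicInterval
    subfamily: str
    consensus_start: int
    consensus_end: int
    element_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.consensus_start >= self.consensus_end:
            raise ValueError(
                f"consensus span must be non-empty, got "
                f"[{self.consensus_start}, {self.consensus_end})"
            )
        if not self.element_id:
            iv = self.interval
            object.__setattr__(
                self,
                "element_id",
                f"{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}:{self.subfamily}",
            )


class RmskFormatError(ValueError):
    """Raised when an annotation table cannot be parsed."""


#: Column map for a minimal 8-column repeat table.
MINIMAL_RMSK_COLUMNS: Mapping[str, int] = {
    "chrom": 0,
    "genoStart": 1,
    "genoEnd": 2,
    "strand": 3,
    "repName": 4,
    "repStart": 5,
    "repEnd": 6,
    "repLeft": 7,
}

#: Column map for the full 17-column UCSC rmsk table dump.
UCSC_RMSK_COLUMNS: Mapping[str, int] = {
    "chrom": 5,
    "genoStart": 6,
    "genoEnd": 7,
    "strand": 9,
    "repName": 10,
    "repStart": 13,
    "repEnd": 14,
    "repLeft": 15,
}

_REQUIRED_COLUMNS = (
    "chrom",
    "genoStart",
    "genoEnd",
    "strand",
    "repName",
    "repStart",
    "repEnd",
    "repLeft",
)

_INT_RE = re.compile(r"^-?\d+$")


def _is_negative_field(raw: str) -> bool:
    # "-0" is a meaningful value in the rmsk dialect (zero unaligned
    # remainder on the sign-marked side), so test the sign character
    # rather than the parsed integer.
    return raw.lstrip().startswith("-")


def _normalise_consensus(
    rep_start: str, rep_end: str, rep_left: str, strand: str
) -> tuple[int, int]:
    """Recover the consensus-match span from the rmsk coordinate triple.

    Of (repStart, repEnd, repLeft), the two non-negative values delimit
    the aligned span; the remaining, sign-marked value is the unaligned
    remainder.  This handles both strand conventions of the dialect
    without hard-coding either.  If the sign marking is ambiguous (no
    negative field), fall back on the strand convention: the remainder is
    repLeft on '+' and repStart on '-'.
    """
    raw = [rep_start, rep_end, rep_left]
    values = []
    for r in raw:
        if not _INT_RE.match(r.strip()):
            raise RmskFormatError(f"non-integer consensus coordinate {r!r}")
        values.append(int(r))
    negative = [i for i in range(3) if _is_negative_field(raw[i])]
    if len(negative) == 1:
        keep = [values[i] for i in range(3) if i != negative[0]]
    elif len(negative) == 0:
        drop = 2 if strand == "+" else 0
        keep = [values[i] for i in range(3) if i != drop]
    else:
        raise RmskFormatError(
            f"ambiguous consensus coordinates {raw}: more than one negative"
        )
    lo, hi = sorted(keep)
    if lo >= hi:
        raise RmskFormatError(f"degenerate consensus span {raw}")
    return lo, hi


def read_rmsk_table(
    path: str | Path,
    subfamilies: Sequence[str],
    main_chroms_only: bool = True,
    column_map: Mapping[str, int] | None = None,
) -> list[TransposonCopy]:
    """Read a RepeatMasker-dialect table and return copies of the named
    subfamilies.

    The file is tab-separated; a single header line and ``#`` comment
    lines are tolerated.  Rows on alternate/unplaced chromosomes are
    dropped when ``main_chroms_only`` is set.  Malformed rows abort the
    read with the offending line number.
    """
    columns = dict(column_map or MINIMAL_RMSK_COLUMNS)
    missing = [c for c in _REQUIRED_COLUMNS if c not in columns]
    if missing:
        raise RmskFormatError(f"column map lacks required columns: {missing}")
    wanted = set(subfamilies)
    copies: list[TransposonCopy] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                raw_start = fields[columns["genoStart"]]
            except IndexError:
                raise RmskFormatError(
                    f"{path}, line {lineno}: too few columns"
                ) from None
            if lineno == 1 and not _INT_RE.match(raw_start.strip()):
                continue  # header line
            try:
                chrom = fields[columns["chrom"]]
                start = int(fields[columns["genoStart"]])
                end = int(fields[columns["genoEnd"]])
                strand = fields[columns["strand"]].strip()
                name = fields[columns["repName"]]
            except (IndexError, ValueError) as exc:
                raise RmskFormatError(f"{path}, line {lineno}: {exc}") from None
            if name not in wanted:
                continue
            if main_chroms_only and chrom not in MAIN_CHROMOSOMES:
                continue
            if strand not in ("+", "-"):
                raise RmskFormatError(
                    f"{path}, line {lineno}: unknown strand symbol {strand!r}"
                )
            if start >= end or start < 0:
                raise RmskFormatError(
                    f"{path}, line {lineno}: invalid span {start}..{end}"
                )
            try:
                cons_start, cons_end = _normalise_consensus(
                    fields[columns["repStart"]],
                    fields[columns["repEnd"]],
                    fields[columns["repLeft"]],
                    strand,
                )
            except RmskFormatError as exc:
                raise RmskFormatError(f"{path}, line {lineno}: {exc}") from None
            copy = TransposonCopy(
                interval=GenomicInterval(chrom, start, end, strand),
                subfamily=name,
                consensus_start=cons_start,
                consensus_end=cons_end,
            )
            if copy.element_id in seen_ids:
                raise RmskFormatError(
                    f"{path}, line {lineno}: duplicate element {copy.element_id}"
                )
            seen_ids.add(copy.element_id)
            copies.append(copy)
    return copies


def full_length_filter(
    copies: Iterable[TransposonCopy], min_bp: int = 6000
) -> list[TransposonCopy]:
    """Keep copies whose genomic length strictly exceeds ``min_bp``.

    The full-length definition is "over ``min_bp``", so a copy of exactly
    ``min_bp`` bases is dropped.
    """
    if min_bp <= 0:
        raise ValueError("min_bp must be positive")
    return [c for c in copies if c.interval.length > min_bp]


def derive_five_prime_utr(
    copy: TransposonCopy, utr_len: int = 1000
) -> GenomicInterval:
    """Interval of the first ``utr_len`` bases at the copy's 5' end.

    Strand-aware: on '+' this is the leftmost ``utr_len`` bases, on '-'
    the rightmost.  Raises for copies shorter than ``utr_len`` (such
    copies are not full-length and carry no intact 5' UTR).
    """
    iv = copy.interval
    if iv.length < utr_len:
        raise ValueError(
            f"copy {copy.element_id} is shorter ({iv.length} bp) than the "
            f"requested 5' UTR length ({utr_len} bp); not a full-length element"
        )
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.start, iv.start + utr_len, "+")
    if iv.strand == "-":
        return GenomicInterval(iv.chrom, iv.end - utr_len, iv.end, "-")
    raise ValueError(f"copy {copy.element_id} has no strand; cannot orient 5' UTR")


def extract_sequences(
    fasta: str | Path | Fasta, intervals: Sequence[GenomicInterval]
) -> list[str]:
    """Extract uppercase, strand-specific sequences for ``intervals``.

    Minus-strand intervals are reverse-complemented.  Output order
    matches input order.
    """
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    out: list[str] = []
    for iv in intervals:
        if iv.chrom not in fa:
            raise KeyError(
                f"chromosome {iv.chrom!r} (interval "
                f"{iv.chrom}:{iv.start}-{iv.end}) not in FASTA"
            )
        if iv.end > len(fa[iv.chrom]):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {len(fa[iv.chrom])}"
            )
        seq = fa[iv.chrom][iv.start : iv.end].seq.upper()
        if iv.strand == "-":
            seq = reverse_complement(seq)
        out.append(seq)
    return out


def write_bed(
    records: Iterable[TransposonCopy | tuple[str, GenomicInterval]],
    path: str | Path,
) -> None:
    """Write copies or (name, interval) pairs as 6-column BED (score 0)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, TransposonCopy):
                name, iv = rec.element_id, rec.interval
            else:
                name, iv = rec
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )
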