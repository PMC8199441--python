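"""PWM motif scanning with exact p-values.

Motif models are position count matrices (JASPAR PFM or MEME-minimal
input).  Windows are scored with a log-odds matrix

    score[i][x] = log2( (counts[i][x] + pc * bg[x]) / (total_i + pc) / bg[x] )

where ``pc`` is the pseudocount (default 0.1, distributed by the
background) and ``bg`` the background letter probabilities (default
uniform).  Statistical significance of a window score is the exact tail
probability P(score >= s) for a random background sequence, computed by
discretising the per-position scores onto an integer lattice and running
a dynamic program over positions — the same construction the standard
scanners use.  Scanning is same-strand only: the reverse complement is
never scored, matching promoter-oriented repeat analyses where strand
has meaning.

Per-subfamily summaries report the occurrence frequency of a motif (the
fraction of elements with at least one significant hit) and a prevalence
filter that retains motifs exceeding a frequency cut in at least one
(or, optionally, every) subfamily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

__all__ = [
    "MotifModel",
    "MotifHit",
    "MotifFormatError",
    "read_motifs",
    "log_odds_matrix",
    "ScoreDistribution",
    "exact_pvalue_table",
    "scan_sequence",
    "occurrence_frequency",
    "prevalence_filter",
    "occurrence_matrix",
]

ALPHABET = "ACGT"
_LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: default site count assumed when a MEME-minimal record omits nsites
DEFAULT_NSITES = 20


class MotifFormatError(ValueError):
    """Raised when a motif file cannot be parsed."""


@dataclass(frozen=True)
class MotifModel:
    """Position count matrix with background model and pseudocount.

    ``counts`` has shape (length, 4) in A,C,G,T column order.
    """

    tf: str
    motif_id: str
    counts: np.ndarray
    pseudocount: float = 0.1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise MotifFormatError(
                f"motif {self.motif_id}: counts must be (length, 4)"
            )
        if np.any(counts < 0):
            raise MotifFormatError(f"motif {self.motif_id}: negative count")
        if np.any(counts.sum(axis=1) + self.pseudocount <= 0):
            raise MotifFormatError(
                f"motif {self.motif_id}: empty column after pseudocount"
            )
        if np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be positive and sum to 1")

    @property
    def length(self) -> int:
        return int(self.counts.shape[0])


@dataclass(frozen=True)
class MotifHit:
    """One significant window on the scanned strand of one sequence."""

    sequence_id: str
    offset: int
    score: float
    p_value: float


def _read_jaspar(path: str | Path) -> list[tuple[str, str, np.ndarray]]:
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise MotifFormatError(f"{path}: not valid JASPAR PFM: {exc}") from exc
        out = []
        for m in records:
            counts = np.array(
                [[m.counts[letter][i] for letter in ALPHABET] for i in range(m.length)]
            )
            out.append((m.name or m.matrix_id, m.matrix_id, counts))
    return out


def _read_meme_minimal(path: str | Path) -> list[tuple[str, str, np.ndarray]]:
    """Parse MEME minimal-format motifs.

    Probability rows are converted to pseudo-counts by multiplying by the
    header's ``nsites`` (default 20 if absent).
    """
    out = []
    name = None
    rows: list[list[float]] | None = None
    nsites = DEFAULT_NSITES
    width = None

    def flush():
        if name is None:
            return
        if rows is None or (width is not None and len(rows) != width):
            raise MotifFormatError(
                f"{path}: motif {name}: matrix has {0 if rows is None else len(rows)}"
                f" rows, expected {width}"
            )
        mat = np.array(rows, dtype=float) * nsites
        if np.any(mat < 0):
            raise MotifFormatError(f"{path}: motif {name}: negative entry")
        out.append((name, name, mat))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise MotifFormatError(f"{path}: MOTIF line without a name")
                name = parts[1]
                rows, width, nsites = None, None, DEFAULT_NSITES
            elif line.startswith("letter-probability matrix"):
                rows = []
                for tok, val in zip(line.split(), line.split()[1:]):
                    if tok == "w=":
                        width = int(val)
                    elif tok == "nsites=":
                        nsites = float(val)
            elif rows is not None and line and line[0] in "0123456789.":
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise MotifFormatError(
                        f"{path}: motif {name}: ragged probability row"
                    )
                rows.append(vals)
    flush()
    return out


def read_motifs(
    path: str | Path,
    format: str = "jaspar_pfm",
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
) -> list[MotifModel]:
    """Read motif models from a JASPAR PFM or MEME-minimal file.

    Count matrices are stored in A,C,G,T order regardless of on-disk
    order.  TF names are taken from the record names, upper-cased.
    """
    if format == "jaspar_pfm":
        parsed = _read_jaspar(path)
    elif format == "meme_minimal":
        parsed = _read_meme_minimal(path)
    else:
        raise ValueError(f"unknown motif format {format!r}")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return [
        MotifModel(
            tf=name.upper(),
            motif_id=motif_id,
            counts=counts,
            pseudocount=pseudocount,
            background=bg,
        )
        for name, motif_id, counts in parsed
    ]


def log_odds_matrix(m: MotifModel) -> np.ndarray:
    """Per-position log2 odds scores, shape (length, 4).

    Letters with zero smoothed probability (possible only at
    pseudocount 0) score -inf.
    """
    totals = m.counts.sum(axis=1, keepdims=True)
    probs = (m.counts + m.pseudocount * m.background) / (totals + m.pseudocount)
    with np.errstate(divide="ignore"):
        return np.log2(probs / m.background)


class ScoreDistribution:
    """Discretised null distribution of window scores for one motif.

    Per-position scores are mapped onto an integer lattice (``bins``
    levels across the attainable score range); the exact distribution of
    the lattice total under the background model is obtained by dynamic
    programming over positions.  Window p-values are tail sums on the
    lattice, which makes the scanner's decisions exactly reproducible by
    enumeration for short motifs.
    """

    def __init__(self, motif: MotifModel, granularity: int = 1000):
        if granularity < 100:
            raise ValueError("granularity must be >= 100")
        if motif.length > 30:
            raise ValueError("exact p-value table limited to motifs <= 30 bp")
        self.motif = motif
        scores = log_odds_matrix(motif)
        self.scores = scores
        finite = np.isfinite(scores)
        if not finite.any(axis=1).all():
            raise ValueError("motif has a position with no scorable letter")
        col_min = np.where(finite, scores, np.inf).min(axis=1)
        col_max = np.where(finite, scores, -np.inf).max(axis=1)
        span = float((col_max - col_min).sum())
        self.scale = (granularity - 1) / span if span > 0 else 1.0
        self.offset = float(col_min.sum())
        # integer per-position scores; -1 marks an unscorable (-inf) letter
        lattice = np.full(scores.shape, -1, dtype=np.int64)
        lattice[finite] = np.rint(
            (scores[finite] - col_min[np.nonzero(finite)[0]]) * self.scale
        ).astype(np.int64)
        self.lattice = lattice
        max_total = int(lattice.max(axis=1).sum())
        dist = np.zeros(max_total + 1)
        dist[0] = 1.0
        bg = motif.background
        for i in range(motif.length):
            nxt = np.zeros_like(dist)
            for x in range(4):
                if lattice[i, x] < 0:
                    continue  # -inf letter: mass leaves the finite lattice
                s = lattice[i, x]
                nxt[s:] += bg[x] * dist[: dist.size - s if s else None]
            dist = nxt
        self.pmf = dist
        # tail[s] = P(lattice total >= s) among finite-scoring windows
        self.tail = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])

    def window_lattice_score(self, letter_idx: np.ndarray) -> int:
        """Integer lattice score of one window (-1 if unscorable)."""
        vals = self.lattice[np.arange(self.motif.length), letter_idx]
        if (vals < 0).any():
            return -1
        return int(vals.sum())

    def pvalue_from_lattice(self, s: int) -> float:
        """Exact tail probability of a lattice score (1.0 for unscorable)."""
        if s < 0:
            return 1.0
        return float(min(1.0, self.tail[min(s, self.tail.size - 1)]))

    def pvalue(self, score: float) -> float:
        """Tail probability of a real-valued log-odds score."""
        if not np.isfinite(score):
            return 1.0 if score < 0 else self.pvalue_from_lattice(self.tail.size - 2)
        s = int(np.rint((score - self.offset) * self.scale))
        return self.pvalue_from_lattice(max(s, 0))


def exact_pvalue_table(m: MotifModel, granularity: int = 1000) -> ScoreDistribution:
    """Exact null score distribution (see :class:`ScoreDistribution`)."""
    return ScoreDistribution(m, granularity=granularity)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to A,C,G,T indices; any other letter becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for letter, idx in _LETTER_INDEX.items():
        out[arr == ord(letter)] = idx
    return out


def scan_sequence(
    m: MotifModel,
    seq: str,
    threshold: float = 1e-4,
    sequence_id: str = "",
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan the given strand of ``seq``; return hits with p < ``threshold``.

    Only the provided strand is scored (no reverse-complement scanning).
    Windows containing any non-ACGT letter are skipped.  A sequence
    shorter than the motif yields no hits.  Hits are sorted by offset.
    """
    L = m.length
    idx = encode_sequence(seq)
    n = idx.size - L + 1
    if n <= 0:
        return []
    if dist is None:
        dist = exact_pvalue_table(m)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    hits: list[MotifHit] = []
    if not valid.any():
        return hits
    lat = dist.lattice
    scores = dist.scores
    pos = np.arange(L)
    vwin = windows[valid]
    lat_scores = lat[pos, vwin]
    scorable = (lat_scores >= 0).all(axis=1)
    totals = lat_scores.sum(axis=1)
    offsets = np.nonzero(valid)[0]
    for off, scorable_i, tot, win in zip(offsets, scorable, totals, vwin):
        if not scorable_i:
            continue
        p = dist.pvalue_from_lattice(int(tot))
        if p < threshold:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    offset=int(off),
                    score=float(scores[pos, win].sum()),
                    p_value=p,
                )
            )
    return hits


def occurrence_frequency(
    hits_by_sequence: Mapping[str, Sequence[MotifHit]],
    group: Sequence[str],
) -> float:
    """Fraction of elements in ``group`` with at least one hit."""
    if not group:
        raise ValueError("empty element group")
    hit = sum(1 for eid in group if hits_by_sequence.get(eid))
    return hit / len(group)


def occurrence_matrix(
    motif_hits: Mapping[str, Mapping[str, Sequence[MotifHit]]],
    groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Motif x subfamily occurrence-frequency matrix.

    ``motif_hits`` maps motif id -> {sequence id -> hits}; ``groups``
    maps subfamily -> element ids.
    """
    data = {
        motif_id: {
            subfam: occurrence_frequency(hits, list(members))
            for subfam, members in groups.items()
        }
        for motif_id, hits in motif_hits.items()
    }
    return pd.DataFrame(data).T.reindex(columns=list(groups))


def prevalence_filter(
    freq: pd.DataFrame, threshold: float = 0.10, mode: str = "any"
) -> list[str]:
    """Motifs whose occurrence frequency strictly exceeds ``threshold``.

    ``mode`` = "any": in at least one subfamily (default); "all": in
    every subfamily.  Rows are motifs, columns subfamilies.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    exceeds = freq > threshold
    keep = exceeds.any(axis=1) if mode == "any" else exceeds.all(axis=1)
    return list(freq.index[keep])
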