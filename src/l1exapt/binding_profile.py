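"""Assignment of binding sites to transposon copies and per-subfamily
binding statistics.

A binding site is assigned to an element when at least a configurable
fraction of the *site* (default one half, inclusive at the boundary)
overlaps the element — the fractional-overlap convention of
``bedtools intersect -f`` with the site as the query.  Binding
frequencies are reported at two levels: the bound fraction (elements
with any site / all elements of the subfamily) and the per-TF binding
frequency (elements with a site of that TF / TF-bound elements of the
subfamily).

For positional analysis, assigned sites are projected into the
subfamily consensus sequence by linear interpolation between the copy's
consensus-match endpoints (RepStart/RepEnd), strand-aware, and pooled
into fixed-width histograms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, TransposonCopy
from .tfbs_catalog import TFBS

__all__ = [
    "Element",
    "BindingAssignment",
    "BindingProfile",
    "ConsensusHistogram",
    "assign_tfbs",
    "bound_fraction",
    "format_percent",
    "per_tf_binding_frequency",
    "project_to_consensus",
    "consensus_histogram",
]

logger = logging.getLogger(__name__)


@runtime_checkable
class HasInterval(Protocol):
    element_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class Element:
    """Lightweight (id, interval) pair, e.g. a 5' UTR of a known copy."""

    element_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class BindingAssignment:
    tfbs: TFBS
    element_id: str
    overlap_bp: int


def _required_overlap(site_len: int, fraction: float) -> int:
    # smallest integer overlap satisfying overlap >= fraction * length,
    # guarding against float representation of e.g. 0.5 * 101
    return max(1, math.ceil(fraction * site_len - 1e-9))


def assign_tfbs(
    sites: Sequence[TFBS],
    elements: Sequence[HasInterval],
    fraction: float = 0.5,
) -> list[BindingAssignment]:
    """Assign each site to every element covering >= ``fraction`` of it.

    The fraction applies to the site, not the element; a tie at exactly
    the threshold is inclusive ("at least half").  One site may be
    assigned to several elements.  Output is ordered by input site,
    then by element genomic position.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    by_chrom: dict[str, list[HasInterval]] = {}
    for e in elements:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[HasInterval]]] = {}
    for chrom, elems in by_chrom.items():
        elems.sort(key=lambda e: (e.interval.start, e.interval.end, e.element_id))
        starts = np.array([e.interval.start for e in elems])
        ends = np.array([e.interval.end for e in elems])
        arrays[chrom] = (starts, ends, elems)
    out: list[BindingAssignment] = []
    for site in sites:
        iv = site.interval
        entry = arrays.get(iv.chrom)
        if entry is None:
            continue
        starts, ends, elems = entry
        need = _required_overlap(iv.length, fraction)
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        for j in np.nonzero(ov >= need)[0]:
            out.append(BindingAssignment(site, elems[j].element_id, int(ov[j])))
    return out


def format_percent(k: int, n: int) -> float:
    """Percentage k/n rounded to two decimals, the reporting convention
    for bound-fraction tables (305/306 -> 99.67)."""
    return round(100.0 * k / n, 2)


def bound_fraction(
    assignments: Iterable[BindingAssignment],
    elements_by_subfamily: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-subfamily bound fraction: elements with >= 1 site / all elements.

    Returns a DataFrame indexed by subfamily with columns
    ``total``, ``bound`` and ``percent`` (two-decimal percentage).
    """
    bound_ids = {a.element_id for a in assignments}
    rows = {}
    for subfam, members in elements_by_subfamily.items():
        if not members:
            raise ValueError(f"subfamily {subfam} has no elements")
        k = sum(1 for eid in members if eid in bound_ids)
        rows[subfam] = {
            "total": len(members),
            "bound": k,
            "percent": format_percent(k, len(members)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class BindingProfile:
    """Per-subfamily TF binding summary.

    ``frequencies`` is a subfamily x TF matrix of fractions with
    TF-bound elements as the denominator; subfamilies with zero bound
    elements carry NaN rows (undefined, excluded from clustering).
    """

    frequencies: pd.DataFrame
    bound_counts: pd.DataFrame
    bound_elements: pd.Series
    total_elements: pd.Series


def per_tf_binding_frequency(
    assignments: Sequence[BindingAssignment],
    elements_by_subfamily: Mapping[str, Sequence[str]],
) -> BindingProfile:
    """Binding frequency of each TF within each subfamily.

    frequency(subfamily, TF) = elements of the subfamily bound by the TF
    / elements of the subfamily bound by any TF.
    """
    member_of: dict[str, str] = {}
    for subfam, members in elements_by_subfamily.items():
        for eid in members:
            member_of[eid] = subfam
    tfs = sorted({a.tfbs.tf for a in assignments})
    subfams = list(elements_by_subfamily)
    bound_by_tf: dict[tuple[str, str], set[str]] = {}
    bound_any: dict[str, set[str]] = {s: set() for s in subfams}
    for a in assignments:
        subfam = member_of.get(a.element_id)
        if subfam is None:
            continue
        bound_by_tf.setdefault((subfam, a.tfbs.tf), set()).add(a.element_id)
        bound_any[subfam].add(a.element_id)
    counts = pd.DataFrame(
        [
            [len(bound_by_tf.get((s, tf), ())) for tf in tfs]
            for s in subfams
        ],
        index=subfams,
        columns=tfs,
        dtype=int,
    )
    n_bound = pd.Series({s: len(bound_any[s]) for s in subfams})
    n_total = pd.Series({s: len(elements_by_subfamily[s]) for s in subfams})
    freqs = counts.div(n_bound.replace(0, np.nan), axis=0)
    return BindingProfile(
        frequencies=freqs,
        bound_counts=counts,
        bound_elements=n_bound,
        total_elements=n_total,
    )


def project_to_consensus(site: TFBS, copy: TransposonCopy) -> float:
    """Project a site's genomic midpoint into consensus coordinates.

    The midpoint (integer floor of (start+end)/2, clipped into the
    copy's span) is mapped linearly between the copy's consensus-match
    endpoints; on the minus strand the mapping is reversed so that the
    copy's genomic 3' end corresponds to the consensus 3' end.  The
    result lies in [consensus_start, consensus_end].
    """
    iv, civ = site.interval, copy.interval
    if iv.chrom != civ.chrom or iv.overlap_bp(civ) == 0:
        raise ValueError(
            f"site {iv.chrom}:{iv.start}-{iv.end} does not overlap copy "
            f"{copy.element_id}"
        )
    mid = (iv.start + iv.end) // 2
    mid = min(max(mid, civ.start), civ.end)
    if civ.strand == "-":
        t = (civ.end - mid) / civ.length
    else:
        t = (mid - civ.start) / civ.length
    span = copy.consensus_end - copy.consensus_start
    return copy.consensus_start + t * span


@dataclass(frozen=True)
class ConsensusHistogram:
    subfamily: str
    bin_bp: int
    counts: np.ndarray
    discarded: int = 0

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.counts.size + 1) * self.bin_bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start": self.bin_edges[:-1], "count": self.counts}
        )


def consensus_histogram(
    positions: Sequence[float],
    subfamily: str = "",
    bin_bp: int = 5,
    max_bp: int = 6500,
) -> ConsensusHistogram:
    """Bin projected consensus positions into fixed-width bins over
    [0, max_bp].  Positions beyond ``max_bp`` are discarded and counted
    (and logged); a position exactly at ``max_bp`` falls in the last bin.
    """
    if max_bp % bin_bp != 0:
        raise ValueError("bin_bp must divide max_bp")
    n_bins = max_bp // bin_bp
    counts = np.zeros(n_bins, dtype=int)
    discarded = 0
    for p in positions:
        if p > max_bp or p < 0:
            discarded += 1
            continue
        counts[min(int(p // bin_bp), n_bins - 1)] += 1
    if discarded:
        logger.info(
            "consensus_histogram(%s): discarded %d positions beyond %d bp",
            subfamily,
            discarded,
            max_bp,
        )
    return ConsensusHistogram(
        subfamily=subfamily, bin_bp=bin_bp, counts=counts, discarded=discarded
    )
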