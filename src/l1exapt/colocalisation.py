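"""Windowed co-localisation of TF binding sites inside L1 subfamilies.

Two binding sites co-localise when their edge-to-edge gap is at most a
fixed window (500 bp by default; overlapping sites have gap 0).  For an
ordered TF pair (A = denominator, B = partner), the fraction of A sites
with a B partner within the window is compared between the sites lying
inside a given L1 subfamily (fractional-overlap assignment, >= half of
the site) and the remainder of the genome, with a one-tailed pooled
two-proportion z-test (upper tail = enrichment inside L1; depletion
shows as a negative z).  The per-test significance threshold follows a
Bonferroni correction rounded up at one significant figure
(0.05 / 102 tests -> 0.0005).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GenomicInterval, TransposonCopy
from .binding_profile import assign_tfbs
from .tfbs_catalog import TFBS

__all__ = [
    "ColocResult",
    "ZTestResult",
    "partition_sites",
    "coloc_indicator",
    "two_proportion_ztest",
    "bonferroni_threshold",
    "coloc_battery",
    "zscore_matrix",
]


def partition_sites(
    sites: Sequence[TFBS],
    subfamily_elements: Sequence[TransposonCopy],
    fraction: float = 0.5,
) -> tuple[list[TFBS], list[TFBS]]:
    """Split sites into (inside-subfamily, background) classes.

    A site belongs to the subfamily class iff it is assigned to at least
    one element under the fractional-overlap rule; every other site is
    background ("remainder of the genome").  The classes are disjoint
    and exhaustive.
    """
    assigned = assign_tfbs(sites, subfamily_elements, fraction=fraction)
    inside_keys = {id(a.tfbs) for a in assigned}
    l1_sites: list[TFBS] = []
    bg_sites: list[TFBS] = []
    for s in sites:
        (l1_sites if id(s) in inside_keys else bg_sites).append(s)
    return l1_sites, bg_sites


def _intervals(sites: Sequence[TFBS | GenomicInterval]) -> list[GenomicInterval]:
    return [s.interval if isinstance(s, TFBS) else s for s in sites]


def coloc_indicator(
    sites_a: Sequence[TFBS | GenomicInterval],
    sites_b: Sequence[TFBS | GenomicInterval],
    window_bp: int = 500,
) -> np.ndarray:
    """Boolean flag per A site: does any B site lie within ``window_bp``?

    Distance is the edge-to-edge gap on the same chromosome (overlap
    counts as gap 0).  When ``sites_a`` and ``sites_b`` are the *same
    list object* (one TF against itself), a site is not its own partner.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    same = sites_a is sites_b
    a_ivs = _intervals(sites_a)
    b_ivs = a_ivs if same else _intervals(sites_b)
    # Group B by chromosome, sorted by start.  Any partner must have
    # start <= a.end + window; among those, co-localisation holds iff the
    # maximum end reaches a.start - window.  Prefix top-2 end maxima (with
    # argmax) allow exact exclusion of the self site for same-list calls.
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    order_of: dict[str, dict[int, int]] = {}
    for chrom in {iv.chrom for iv in b_ivs}:
        idxs = [i for i, iv in enumerate(b_ivs) if iv.chrom == chrom]
        idxs.sort(key=lambda i: (b_ivs[i].start, b_ivs[i].end))
        starts = np.array([b_ivs[i].start for i in idxs])
        ends = np.array([b_ivs[i].end for i in idxs])
        m1 = np.empty(len(idxs))
        a1 = np.empty(len(idxs), dtype=int)
        m2 = np.empty(len(idxs))
        best, best_i, second = -np.inf, -1, -np.inf
        for pos, e in enumerate(ends):
            if e > best:
                second, best, best_i = best, float(e), pos
            elif e > second:
                second = float(e)
            m1[pos], a1[pos], m2[pos] = best, best_i, second
        by_chrom[chrom] = (starts, m1, m2, a1)
        order_of[chrom] = {i: p for p, i in enumerate(idxs)}
    flags = np.zeros(len(a_ivs), dtype=bool)
    for i, iv in enumerate(a_ivs):
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            continue
        starts, m1, m2, a1 = entry
        hi = int(np.searchsorted(starts, iv.end + window_bp, side="right"))
        if hi == 0:
            continue
        if same and a1[hi - 1] == order_of[iv.chrom][i]:
            best_end = m2[hi - 1]
        else:
            best_end = m1[hi - 1]
        flags[i] = best_end >= iv.start - window_bp
    return flags


class ZTestResult(NamedTuple):
    z: float
    p_one_tailed: float
    degenerate: bool = False


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> ZTestResult:
    """Pooled one-tailed two-proportion z-test (upper tail: class 1 greater).

    z = (k1/n1 - k2/n2) / sqrt(p(1-p)(1/n1 + 1/n2)) with pooled
    p = (k1+k2)/(n1+n2); p_one_tailed = 1 - Phi(z).  A degenerate pooled
    proportion (0 or 1) yields z = 0, p = 0.5, flagged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(0.0, 0.5, degenerate=True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return ZTestResult(z, float(norm.sf(z)), degenerate=False)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise ``alpha`` split over ``n_tests``, rounded *up* at one
    significant figure (0.05 / 102 -> 0.0005)."""
    if n_tests <= 0 or alpha <= 0:
        raise ValueError("alpha and n_tests must be positive")
    t = alpha / n_tests
    exponent = math.floor(math.log10(t))
    mantissa = t / 10**exponent
    return math.ceil(mantissa - 1e-12) * 10**exponent


@dataclass(frozen=True)
class ColocResult:
    """One directed TF pair x subfamily co-localisation test."""

    subfamily: str
    tf_denominator: str
    tf_partner: str
    n_l1: int
    k_l1: int
    n_bg: int
    k_bg: int
    z: float
    p_one_tailed: float
    significant: bool
    computable: bool = True
    degenerate: bool = False


def coloc_battery(
    catalogue: Mapping[str, Sequence[TFBS]],
    subfamilies: Mapping[str, Sequence[TransposonCopy]],
    window_bp: int = 500,
    p_threshold: float = 0.0005,
    fraction: float = 0.5,
) -> list[ColocResult]:
    """All ordered TF pairs x subfamilies co-localisation tests.

    For each subfamily: each TF's sites are partitioned into the
    subfamily class and the genomic background; for the ordered pair
    (A, B), the fraction of A sites with a B partner within the window
    is tested between the two classes.  TFs without any genome-wide
    site yield not-computable rows.
    """
    tfs = sorted(catalogue)
    if len(tfs) < 2:
        raise ValueError("co-localisation requires a panel of >= 2 TFs")
    results: list[ColocResult] = []
    for subfam, elements in subfamilies.items():
        partitions = {
            tf: partition_sites(catalogue[tf], list(elements), fraction=fraction)
            for tf in tfs
        }
        for tf_a in tfs:
            for tf_b in tfs:
                if tf_a == tf_b:
                    continue
                a_l1, a_bg = partitions[tf_a]
                b_all = catalogue[tf_b]
                if (not a_l1 and not a_bg) or not b_all or not a_l1 or not a_bg:
                    results.append(
                        ColocResult(
                            subfam, tf_a, tf_b,
                            len(a_l1), 0, len(a_bg), 0,
                            z=float("nan"), p_one_tailed=float("nan"),
                            significant=False, computable=False,
                        )
                    )
                    continue
                k_l1 = int(coloc_indicator(a_l1, b_all, window_bp).sum())
                k_bg = int(coloc_indicator(a_bg, b_all, window_bp).sum())
                test = two_proportion_ztest(k_l1, len(a_l1), k_bg, len(a_bg))
                results.append(
                    ColocResult(
                        subfam, tf_a, tf_b,
                        len(a_l1), k_l1, len(a_bg), k_bg,
                        z=test.z, p_one_tailed=test.p_one_tailed,
                        significant=bool(
                            not test.degenerate and test.p_one_tailed < p_threshold
                        ),
                        degenerate=test.degenerate,
                    )
                )
    return results


def zscore_matrix(results: Sequence[ColocResult], subfamily: str) -> pd.DataFrame:
    """Denominator x partner z-score matrix for one subfamily (heatmap
    input; positive = enrichment inside L1, negative = depletion)."""
    rows = [r for r in results if r.subfamily == subfamily]
    tfs = sorted({r.tf_denominator for r in rows} | {r.tf_partner for r in rows})
    mat = pd.DataFrame(np.nan, index=tfs, columns=tfs)
    for r in rows:
        mat.loc[r.tf_denominator, r.tf_partner] = r.z
    return mat


def results_frame(results: Sequence[ColocResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
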