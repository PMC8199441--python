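"""Differential TF binding between two cell lines.

Per (element, TF) pair — restricted to the TFs assayed in both cell
lines — binding is classified as present in both cell lines, in cell A
only (e.g. the cancer line), or in cell B only (e.g. the near-normal
line).  An element-level aggregate (bound by any shared TF in a given
cell line) supports the pooled comparison.  Counts are descriptive; no
test is attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .binding_profile import BindingAssignment

__all__ = [
    "DifferentialRecord",
    "classify_binding",
    "per_tf_counts",
    "element_level_counts",
]

BOTH = "both"
CELL_A_ONLY = "cell_a_only"
CELL_B_ONLY = "cell_b_only"


@dataclass(frozen=True)
class DifferentialRecord:
    element_id: str
    tf: str
    category: str
    subfamily: str


def _norm(tf: str) -> str:
    return tf.strip().upper()


def classify_binding(
    assignments_a: Sequence[BindingAssignment],
    assignments_b: Sequence[BindingAssignment],
    shared_tfs: Sequence[str],
    subfamily_of: Mapping[str, str],
) -> list[DifferentialRecord]:
    """Classify every (element, TF) pair bound in either cell line.

    Both assignment sets must come from the same element annotation and
    overlap rule.  Only TFs in ``shared_tfs`` (the panel assayed in both
    cell lines) are considered.  ``subfamily_of`` maps element ids to
    subfamily names; pairs on unknown elements are skipped.
    """
    shared = {_norm(t) for t in shared_tfs}
    if not shared:
        raise ValueError("shared_tfs must be non-empty")

    def pair_set(assignments: Sequence[BindingAssignment]) -> set[tuple[str, str]]:
        return {
            (a.element_id, _norm(a.tfbs.tf))
            for a in assignments
            if _norm(a.tfbs.tf) in shared and a.element_id in subfamily_of
        }

    in_a = pair_set(assignments_a)
    in_b = pair_set(assignments_b)
    records = []
    for eid, tf in sorted(in_a | in_b):
        if (eid, tf) in in_a and (eid, tf) in in_b:
            cat = BOTH
        elif (eid, tf) in in_a:
            cat = CELL_A_ONLY
        else:
            cat = CELL_B_ONLY
        records.append(
            DifferentialRecord(eid, tf, cat, subfamily_of[eid])
        )
    return records


def per_tf_counts(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Stacked counts per (TF, subfamily): both / cell_a_only / cell_b_only."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        return pd.DataFrame(columns=[BOTH, CELL_A_ONLY, CELL_B_ONLY])
    out = (
        df.groupby(["tf", "subfamily", "category"])
        .size()
        .unstack("category", fill_value=0)
        .reindex(columns=[BOTH, CELL_A_ONLY, CELL_B_ONLY], fill_value=0)
    )
    return out


def element_level_counts(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Pooled per-subfamily counts of elements bound by >= 1 shared TF.

    An element counts as ``both`` when it is bound by at least one
    shared TF in each cell line (not necessarily the same TF).
    """
    bound_a: set[str] = set()
    bound_b: set[str] = set()
    subfam: dict[str, str] = {}
    for r in records:
        subfam[r.element_id] = r.subfamily
        if r.category in (BOTH, CELL_A_ONLY):
            bound_a.add(r.element_id)
        if r.category in (BOTH, CELL_B_ONLY):
            bound_b.add(r.element_id)
    rows: dict[str, dict[str, int]] = {}
    for eid in bound_a | bound_b:
        row = rows.setdefault(
            subfam[eid], {BOTH: 0, CELL_A_ONLY: 0, CELL_B_ONLY: 0}
        )
        if eid in bound_a and eid in bound_b:
            row[BOTH] += 1
        elif eid in bound_a:
            row[CELL_A_ONLY] += 1
        else:
            row[CELL_B_ONLY] += 1
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
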