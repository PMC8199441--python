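"""Binding-site catalogue ingestion, per-TF merging and source combination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from l1exapt.annotation import GenomicInterval
from l1exapt.tfbs_catalog import (
    CHIPATLAS,
    CHIPATLAS_DIALECT,
    COMBINED,
    GTRD,
    GTRD_DIALECT,
    TFBS,
    combine_sources,
    filter_tf_whitelist,
    group_by_tf,
    merge_per_tf,
    read_tfbs_table,
)


def site(start, end, tf="ESR1", chrom="chr1", cell="MCF7", source=GTRD):
    return TFBS(GenomicInterval(chrom, start, end, "."), tf, cell, source)


class TestReadTfbsTable:
    def test_cell_line_filter(self, tmp_path):
        path = tmp_path / "gtrd.tsv"
        rows = [
            ("chr1", 100, 200, "ESR1", "MCF7"),
            ("chr1", 300, 400, "ESR1", "mcf7 "),  # case/space-insensitive match
            ("chr1", 500, 600, "MYC", "MCF7"),
            ("chr2", 100, 200, "ESR1", "K562"),
            ("chr2", 300, 400, "MYC", "K562"),
        ]
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        sites = read_tfbs_table(path, GTRD_DIALECT, "MCF7", GTRD)
        assert len(sites) == 3
        assert {s.cell_line for s in sites} == {"MCF7"}

    def test_alternate_chromosomes_dropped(self, tmp_path):
        path = tmp_path / "ca.bed"
        path.write_text(
            "chr14_GL000009v2_random\t10\t20\tESR1\t900\n"
            "chr14\t10\t20\tESR1\t900\n"
        )
        sites = read_tfbs_table(path, CHIPATLAS_DIALECT, "MCF7", CHIPATLAS)
        assert [s.interval.chrom for s in sites] == ["chr14"]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_tfbs_table(path, GTRD_DIALECT, "MCF7", GTRD) == []

    def test_non_numeric_coordinates_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr1\t100\t200\tESR1\tMCF7\nchr1\tzz\t300\tESR1\tMCF7\n")
        with pytest.raises(ValueError, match="line 2"):
            read_tfbs_table(path, GTRD_DIALECT, "MCF7", GTRD)


class TestMergePerTf:
    @pytest.mark.parametrize(
        "intervals, gap, expected",
        [
            ([(100, 200), (450, 600)], 300, [(100, 600)]),  # gap 250 <= 300
            ([(100, 200), (501, 600)], 300, [(100, 200), (501, 600)]),  # gap 301
            ([(100, 200), (200, 300)], 0, [(100, 300)]),  # book-ended
            ([(100, 200), (201, 300)], 0, [(100, 200), (201, 300)]),
        ],
    )
    def test_gap_semantics(self, intervals, gap, expected):
        merged = merge_per_tf([site(a, b) for a, b in intervals], gap)
        assert [(s.interval.start, s.interval.end) for s in merged] == expected

    def test_mixed_tfs_rejected(self):
        with pytest.raises(ValueError, match="single TF group"):
            merge_per_tf([site(0, 10), site(20, 30, tf="MYC")], 0)

    def test_idempotent(self, rng):
        sites = [
            site(int(s), int(s) + int(w))
            for s, w in zip(
                rng.integers(0, 5000, size=60), rng.integers(1, 400, size=60)
            )
        ]
        once = merge_per_tf(sites, 150)
        assert merge_per_tf(once, 150) == once

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(0, 2000), st.integers(1, 300)),
            min_size=1,
            max_size=50,
        ),
        gap=st.sampled_from([0, 1, 10, 300]),
    )
    def test_matches_transitive_closure_oracle(self, intervals, gap):
        """Sweep merging equals the O(n^2) transitive-closure union."""
        sites = [site(s, s + w) for s, w in intervals]
        merged = {(s.interval.start, s.interval.end) for s in merge_per_tf(sites, gap)}

        # oracle: union-find over all pairs with gap <= d, then envelope
        n = len(sites)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = sites[i].interval, sites[j].interval
                gap_ij = max(a.start, b.start) - min(a.end, b.end)
                if gap_ij <= gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(sites[i].interval)
        oracle = {
            (min(iv.start for iv in g), max(iv.end for iv in g))
            for g in groups.values()
        }
        assert merged == oracle

    def test_covered_bases_never_decrease(self, rng):
        sites = [
            site(int(s), int(s) + int(w))
            for s, w in zip(
                rng.integers(0, 3000, size=40), rng.integers(1, 200, size=40)
            )
        ]
        before = set()
        for s in sites:
            before.update(range(s.interval.start, s.interval.end))
        merged = merge_per_tf(sites, 50)
        after = set()
        for s in merged:
            after.update(range(s.interval.start, s.interval.end))
        assert before <= after


class TestWhitelist:
    def test_filters_non_whitelisted(self):
        sites = [site(0, 10, tf="ESR1"), site(20, 30, tf="GFP-CTRL")]
        assert [s.tf for s in filter_tf_whitelist(sites, {"esr1"})] == ["ESR1"]

    def test_superset_is_identity(self):
        sites = [site(0, 10, tf="ESR1"), site(20, 30, tf="MYC")]
        assert filter_tf_whitelist(sites, {"ESR1", "MYC", "CTCF"}) == sites

    def test_empty_sites(self):
        assert filter_tf_whitelist([], {"ESR1"}) == []


class TestCombineSources:
    def test_overlapping_sites_union(self):
        out = combine_sources(
            [site(100, 200, source=GTRD)],
            [site(150, 250, source=CHIPATLAS)],
        )
        assert [(s.interval.start, s.interval.end, s.source) for s in out] == [
            (100, 250, COMBINED)
        ]

    def test_disjoint_sites_retained(self):
        out = combine_sources(
            [site(100, 200, source=GTRD)], [site(300, 400, source=CHIPATLAS)]
        )
        assert len(out) == 2

    def test_single_source_tf_passes_through(self):
        out = combine_sources([site(100, 200, tf="CTCF", source=GTRD)], [])
        assert [(s.tf, s.source) for s in out] == [("CTCF", COMBINED)]

    def test_cell_line_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cell-line mismatch"):
            combine_sources([site(0, 10, cell="MCF7")], [site(0, 10, cell="K562")])

    def test_base_coverage_equals_union(self, rng):
        a = [
            site(int(s), int(s) + int(w), source=GTRD)
            for s, w in zip(rng.integers(0, 2000, 30), rng.integers(1, 150, 30))
        ]
        b = [
            site(int(s), int(s) + int(w), source=CHIPATLAS)
            for s, w in zip(rng.integers(0, 2000, 30), rng.integers(1, 150, 30))
        ]
        out = combine_sources(a, b)
        covered_in = set()
        for s in a + b:
            covered_in.update(range(s.interval.start, s.interval.end))
        covered_out = set()
        for s in out:
            covered_out.update(range(s.interval.start, s.interval.end))
        assert covered_in == covered_out
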