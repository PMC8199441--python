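"""Motif model parsing, log-odds scoring, exact p-values and scanning."""

import itertools

import numpy as np
import pytest

from l1exapt.annotation import reverse_complement
from l1exapt.motif_scan import (
    MotifFormatError,
    MotifModel,
    exact_pvalue_table,
    log_odds_matrix,
    occurrence_frequency,
    occurrence_matrix,
    prevalence_filter,
    read_motifs,
    scan_sequence,
)

import pandas as pd

JASPAR_TEXT = """>MA0001.1 TESTTF
A [ 10  0  0  2 ]
C [  0 10  0  2 ]
G [  0  0 10  2 ]
T [  0  0  0  4 ]
"""

MEME_TEXT = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF M1 TESTTF
letter-probability matrix: alength= 4 w= 6 nsites= 40 E= 0
 1.0 0.0 0.0 0.0
 0.0 1.0 0.0 0.0
 0.0 0.0 1.0 0.0
 0.0 0.0 0.0 1.0
 0.5 0.5 0.0 0.0
 0.25 0.25 0.25 0.25
"""


def motif_from_consensus(consensus, dominant=97, other=1, **kw):
    counts = np.array(
        [[dominant if c == l else other for l in "ACGT"] for c in consensus],
        dtype=float,
    )
    return MotifModel(tf="TEST", motif_id="TEST.1", counts=counts, **kw)


class TestReadMotifs:
    def test_jaspar(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT)
        (m,) = read_motifs(p, "jaspar_pfm")
        assert m.length == 4
        assert m.tf == "TESTTF"
        assert m.counts[0].tolist() == [10, 0, 0, 0]
        assert m.counts[3].tolist() == [2, 2, 2, 4]

    def test_meme_minimal_converts_probabilities_to_counts(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(MEME_TEXT)
        (m,) = read_motifs(p, "meme_minimal")
        assert m.length == 6
        # probabilities scaled by nsites=40
        assert m.counts[0].tolist() == [40, 0, 0, 0]
        assert m.counts[4].tolist() == [20, 20, 0, 0]

    def test_negative_count_rejected(self):
        with pytest.raises(MotifFormatError, match="negative"):
            MotifModel("X", "X.1", np.array([[1, -1, 0, 0]], dtype=float))

    def test_ragged_meme_rejected(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(MEME_TEXT.replace(" 0.25 0.25 0.25 0.25\n", ""))
        with pytest.raises(MotifFormatError, match="M1"):
            read_motifs(p, "meme_minimal")


class TestLogOdds:
    def test_single_letter_column_no_pseudocount(self):
        m = MotifModel("X", "X.1", np.array([[1.0, 0, 0, 0]]), pseudocount=0.0)
        row = log_odds_matrix(m)[0]
        assert row[0] == pytest.approx(2.0)  # log2(1 / 0.25)
        assert np.isneginf(row[1:]).all()

    def test_uniform_column_scores_zero(self):
        m = MotifModel("X", "X.1", np.array([[1.0, 1, 1, 1]]))
        assert log_odds_matrix(m)[0] == pytest.approx(np.zeros(4))

    def test_pseudocount_formula(self):
        # independently hand-evaluated: log2(((10 + 0.1*0.25)/10.1)/0.25)
        m = MotifModel("X", "X.1", np.array([[10.0, 0, 0, 0]]), pseudocount=0.1)
        expected = np.log2(((10 + 0.025) / 10.1) / 0.25)
        assert log_odds_matrix(m)[0, 0] == pytest.approx(expected)


def enumerate_null(motif, dist):
    """Exhaustive null distribution over all 4^L windows on the same
    integer lattice as the DP (independent oracle for the tail sums)."""
    L = motif.length
    bg = motif.background
    tail = {}
    outcomes = []
    for letters in itertools.product(range(4), repeat=L):
        prob = float(np.prod(bg[list(letters)]))
        s = dist.window_lattice_score(np.array(letters))
        outcomes.append((s, prob))
    return outcomes


class TestExactPvalues:
    def test_single_permitted_letter_per_column(self):
        m = MotifModel(
            "X", "X.1",
            np.array([[1.0, 0, 0, 0]] * 4),
            pseudocount=0.0,
        )
        dist = exact_pvalue_table(m)
        max_lattice = int(dist.lattice.max(axis=1).sum())
        assert dist.pvalue_from_lattice(max_lattice) == pytest.approx(0.25**4)

    def test_single_column_matches_background_mass(self):
        m = MotifModel("X", "X.1", np.array([[8.0, 4, 2, 1]]))
        dist = exact_pvalue_table(m)
        scores = dist.scores[0]
        for x in range(4):
            expected = sum(0.25 for y in range(4) if scores[y] >= scores[x])
            s = dist.window_lattice_score(np.array([x]))
            assert dist.pvalue_from_lattice(s) == pytest.approx(expected)

    @pytest.mark.parametrize("length", [3, 5])
    def test_dp_equals_enumeration(self, rng, length):
        counts = rng.integers(0, 30, size=(length, 4)).astype(float) + 0.5
        m = MotifModel("X", "X.1", counts)
        dist = exact_pvalue_table(m)
        outcomes = enumerate_null(m, dist)
        for s in {s for s, _ in outcomes}:
            brute = sum(p for t, p in outcomes if t >= s and t >= 0)
            assert dist.pvalue_from_lattice(s) == pytest.approx(brute, abs=1e-12)

    def test_monotone_nonincreasing_in_score(self):
        m = motif_from_consensus("ACGTAC")
        dist = exact_pvalue_table(m)
        ps = [dist.pvalue_from_lattice(s) for s in range(dist.tail.size - 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert dist.pvalue_from_lattice(0) == pytest.approx(1.0)


class TestScanSequence:
    def test_planted_motif_found_at_offset(self, rng):
        m = motif_from_consensus("AGGTCACGGTGA")
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seq = bg[:137] + "AGGTCACGGTGA" + bg[137:]
        hits = scan_sequence(m, seq, 1e-4)
        assert 137 in [h.offset for h in hits]
        # deterministic: identical repeat call gives identical hits
        assert scan_sequence(m, seq, 1e-4) == hits

    def test_all_n_sequence(self):
        m = motif_from_consensus("ACGTACGT")
        assert scan_sequence(m, "N" * 100, 1e-4) == []

    def test_reverse_strand_plant_not_found(self, rng):
        """Same-strand scanning: a motif present only on the reverse
        complement yields no hits."""
        consensus = "AGGTCACGGTGA"
        m = motif_from_consensus(consensus)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        seq = bg[:100] + reverse_complement(consensus) + bg[100:]
        hits = scan_sequence(m, seq, 1e-4)
        assert hits == []

    def test_sequence_shorter_than_motif(self):
        m = motif_from_consensus("ACGTACGT")
        assert scan_sequence(m, "ACG", 1e-4) == []

    def test_windows_containing_n_skipped(self):
        m = motif_from_consensus("AAAA", dominant=50)
        seq = "AANAAAA"  # windows 0-2 contain the N; only offset 3 is clean
        hits = scan_sequence(m, seq, 1.0)  # threshold 1: every scorable window
        assert [h.offset for h in hits] == [3]
        assert all(0 < h.p_value <= 1 for h in hits)


class TestOccurrence:
    def test_frequency(self):
        hits = {"e1": [1], "e2": [], "e3": [1], "e4": [1]}
        assert occurrence_frequency(hits, ["e1", "e2", "e3", "e4", "e5"] + list("abcde")) == 0.3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            occurrence_frequency({}, [])

    def test_prevalence_filter_strict_and_monotone(self):
        freq = pd.DataFrame(
            {"S1": [0.11, 0.10, 0.50], "S2": [0.02, 0.05, 0.99]},
            index=["m_above", "m_at", "m_high"],
        )
        assert prevalence_filter(freq, 0.10) == ["m_above", "m_high"]
        assert prevalence_filter(freq, 0.10, mode="all") == ["m_high"]
        # retained set shrinks as the threshold grows
        assert set(prevalence_filter(freq, 0.4)) <= set(prevalence_filter(freq, 0.1))
        assert prevalence_filter(freq, 0.999) == []
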