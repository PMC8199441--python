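"""Synthetic dataset generator: determinism, planted structure and
round-trip consistency."""

import hashlib
import json

import numpy as np
import pytest

from l1exapt.motif_scan import read_motifs, scan_sequence
from l1exapt.synthetic_data import (
    SyntheticConfig,
    build_subfamily_consensus,
    generate_dataset,
    generate_genome,
    generate_peaks,
)

SMALL = SyntheticConfig(copies_per_subfamily=10, n_chroms=2, chrom_len=250_000)


def file_hashes(ds):
    out = {}
    for p in sorted(ds.outdir.iterdir()):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        d1 = generate_dataset(tmp_path / "a", seed=5, config=SMALL)
        d2 = generate_dataset(tmp_path / "b", seed=5, config=SMALL)
        assert file_hashes(d1) == file_hashes(d2)

    def test_different_seed_differs(self, tmp_path):
        d1 = generate_dataset(tmp_path / "a", seed=5, config=SMALL)
        d2 = generate_dataset(tmp_path / "b", seed=6, config=SMALL)
        assert file_hashes(d1) != file_hashes(d2)

    def test_seed_recorded_in_truth(self, tmp_path):
        ds = generate_dataset(tmp_path / "a", seed=5, config=SMALL)
        assert json.loads(ds.truth_file.read_text())["seed"] == 5


class TestGenome:
    def test_gc_within_binomial_bound(self, rng):
        genome = generate_genome(rng, 1, 1_000_000, gc=0.5)
        arr = genome["chr1"]
        gc = np.isin(arr, [1, 2]).mean()
        assert abs(gc - 0.5) <= 3 * np.sqrt(0.25 / 1_000_000)

    def test_gc_one_only_gc_letters(self, rng):
        genome = generate_genome(rng, 1, 100_000, gc=1.0)
        assert set(np.unique(genome["chr1"])) <= {1, 2}


class TestConsensus:
    def test_young_slots_all_intact(self, rng):
        cfg = SMALL
        seq, slots = build_subfamily_consensus(rng, 0, cfg)
        assert all(s["intact"] for s in slots)
        assert seq.size == cfg.consensus_len

    def test_old_configured_slots_disrupted(self, rng):
        cfg = SMALL
        seq, slots = build_subfamily_consensus(rng, max(cfg.age_ranks), cfg)
        by_tf = {s["tf"]: s for s in slots if s["region"] == "5utr"}
        assert not by_tf["FOXA1"]["intact"]
        assert not by_tf["E2F1"]["intact"]
        three_prime = [s for s in slots if s["region"] == "3end"]
        assert three_prime and all(s["intact"] for s in three_prime)
        n_disrupted = sum(1 for s in slots if not s["intact"])
        assert seq.size == cfg.consensus_len + n_disrupted * cfg.disruption_insert_len

    def test_recorded_slot_sequence_matches_motif(self, rng):
        cfg = SMALL
        seq, slots = build_subfamily_consensus(rng, 0, cfg)
        motif_of = {s.tf: s.motif for s in cfg.slots}
        for slot in slots:
            planted = "".join("ACGT"[i] for i in seq[slot["start"] : slot["end"]])
            assert planted == motif_of[slot["tf"]]


class TestPlacedCopies:
    def test_truncated_copies_keep_three_prime_suffix(self, tiny_dataset):
        for rec in tiny_dataset.truth["copies"]:
            subfam = tiny_dataset.truth["subfamilies"][rec["subfamily"]]
            assert rec["consensus_end"] == subfam["consensus_len"]
            assert rec["end"] - rec["start"] == (
                rec["consensus_end"] - rec["consensus_start"]
            )

    def test_planted_intact_motifs_pass_scan_threshold(self, tiny_dataset):
        """Extracting a young full-length 5' UTR and scanning it finds
        the planted (intact) motifs at p < 1e-4."""
        from l1exapt.annotation import (
            GenomicInterval,
            extract_sequences,
        )

        motifs = {m.tf: m for m in read_motifs(tiny_dataset.motif_file)}
        young = tiny_dataset.truth["subfamilies"]["L1SYN1"]
        utr_slots = [s for s in young["slots"] if s["region"] == "5utr"]
        checked = 0
        for rec in tiny_dataset.truth["copies"]:
            if rec["subfamily"] != "L1SYN1" or rec["consensus_start"] != 0:
                continue
            iv = GenomicInterval(
                rec["chrom"], rec["start"], rec["end"], rec["strand"]
            )
            (seq,) = extract_sequences(tiny_dataset.genome_fasta, [iv])
            utr = seq[:1000]
            for slot in utr_slots:
                hits = scan_sequence(motifs[slot["tf"]], utr, 1e-4)
                assert any(abs(h.offset - slot["start"]) <= 1 for h in hits)
            checked += 1
            if checked >= 5:
                break
        assert checked > 0

    def test_disrupted_motif_not_found_in_old_consensus(self, tiny_dataset):
        from l1exapt.annotation import GenomicInterval, extract_sequences

        motifs = {m.tf: m for m in read_motifs(tiny_dataset.motif_file)}
        for rec in tiny_dataset.truth["copies"]:
            if rec["subfamily"] != "L1SYN3" or rec["consensus_start"] != 0:
                continue
            iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"])
            (seq,) = extract_sequences(tiny_dataset.genome_fasta, [iv])
            assert scan_sequence(motifs["E2F1"], seq[:1000], 1e-4) == []
            break


class TestPeaks:
    def test_full_occupancy_no_background(self, tmp_path):
        cfg = SyntheticConfig(
            copies_per_subfamily=10,
            n_chroms=2,
            chrom_len=250_000,
            occupancy=(1.0, 0.0),
            leak_prob=0.0,
            background_rate_per_mb=(0.0, 0.0),
        )
        ds = generate_dataset(tmp_path, seed=3, config=cfg)
        n_intact_slots = sum(
            1
            for rec in ds.truth["copies"]
            for slot in rec["slots"].values()
            if slot["present"] and slot["intact"]
        )
        cancer, normal = cfg.cell_lines
        n_cancer = sum(
            len(p.read_text().splitlines() if p.exists() else [])
            for p in [ds.gtrd_tables[cancer]]
        )
        # every peak goes to GTRD and/or ChIP-Atlas; union equals slots
        gtrd = {tuple(l.split("\t")[:3]) for l in ds.gtrd_tables[cancer].read_text().splitlines()}
        ca = {tuple(l.split("\t")[:3]) for l in ds.chipatlas_tables[cancer].read_text().splitlines()}
        assert len(gtrd | ca) == n_intact_slots
        assert ds.gtrd_tables[normal].read_text() == ""
        assert ds.chipatlas_tables[normal].read_text() == ""

    def test_occupancy_within_binomial_bound(self, tmp_path):
        cfg = SyntheticConfig(
            copies_per_subfamily=40,
            n_chroms=2,
            chrom_len=800_000,
            background_rate_per_mb=(0.0, 0.0),
            leak_prob=0.0,
        )
        ds = generate_dataset(tmp_path, seed=9, config=cfg)
        n_slots = sum(
            1
            for rec in ds.truth["copies"]
            for slot in rec["slots"].values()
            if slot["present"] and slot["intact"]
        )
        cancer = cfg.cell_lines[0]
        gtrd = {tuple(l.split("\t")[:3]) for l in ds.gtrd_tables[cancer].read_text().splitlines()}
        ca = {tuple(l.split("\t")[:3]) for l in ds.chipatlas_tables[cancer].read_text().splitlines()}
        n_peaks = len(gtrd | ca)
        q = cfg.occupancy[0]
        assert abs(n_peaks - q * n_slots) <= 3 * np.sqrt(n_slots * q * (1 - q))
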