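"""Synthetic genome, repeat annotation and ChIP peak catalogues with
planted ground truth.

The generator emulates the statistical structure the L1 exaptation
analysis rests on, at desk scale:

* L1-like subfamilies of graded evolutionary age.  Each subfamily has a
  ~6 kb consensus; copies are placed on a random background genome
  either full-length or 5'-truncated (a 3'-anchored suffix survives,
  reflecting target-primed reverse transcription), with truncation far
  more common and more severe in the older subfamilies.
* TF motif slots in the consensus.  The 5' UTR (first 1000 bp) carries
  binding-site slots for ESR1-, FOXA1- and E2F1-like motifs; in older
  subfamilies configured slots are disrupted by a small insertion inside
  the motif.  A 3'-end ESR1 slot near position 5900 is intact at every
  age, giving the old, truncated subfamilies an alternative binding mode.
* Cell-line-dependent occupancy.  Each carried, intact slot emits a
  ChIP peak with probability q(cell line) — high in the cancer-like
  line, low in the near-normal line; disrupted slots leak rarely.
  Poisson background peaks cover the rest of the genome.  Output is
  split into two partially overlapping source dialects (GTRD-style TSV
  and ChIP-Atlas-style BED) so catalogue combination is exercised.

All randomness flows from one seed; regenerating with the same seed and
configuration reproduces byte-identical files.  A truth JSON records
every planted parameter and per-copy slot for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SlotSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_genome",
    "build_subfamily_consensus",
    "place_copies",
    "generate_peaks",
    "generate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}


@dataclass(frozen=True)
class SlotSpec:
    """One motif slot in the consensus: TF label, nominal offset, the
    motif consensus string, the age rank from which the slot is
    disrupted (None = never), and the structural region it models."""

    tf: str
    offset: int
    motif: str
    disrupted_from_age: int | None
    region: str  # "5utr" or "3end"


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted study conditions.

    Defaults define the packaged fixture: 3 subfamilies x 200 copies,
    3 TFs, cancer occupancy 0.9 vs near-normal 0.15.
    """

    subfamilies: tuple[str, ...] = ("L1SYN1", "L1SYN2", "L1SYN3")
    age_ranks: tuple[int, ...] = (0, 1, 2)
    copies_per_subfamily: int = 200
    full_length_prob: tuple[float, ...] = (0.9, 0.5, 0.1)
    #: uniform range (lo, hi) of consensus_start for truncated copies
    trunc_start_range: tuple[tuple[int, int], ...] = (
        (500, 4500),
        (1500, 4800),
        (2500, 5000),
    )
    consensus_len: int = 6050
    utr5_len: int = 1000
    slots: tuple[SlotSpec, ...] = (
        SlotSpec("ESR1", 200, "AGGTCACGGTGA", None, "5utr"),
        SlotSpec("FOXA1", 420, "TGTTTACTTTGG", 2, "5utr"),
        SlotSpec("E2F1", 600, "TTTGGCGCCAAA", 1, "5utr"),
        SlotSpec("ESR1", 5900, "AGGTCACGGTGA", None, "3end"),
    )
    disruption_insert_len: int = 4
    substitution_rate_per_age: float = 0.01
    cell_lines: tuple[str, ...] = ("MCF7SYN", "MCF10ASYN")
    occupancy: tuple[float, ...] = (0.9, 0.15)  # per cell line
    leak_prob: float = 0.02
    background_rate_per_mb: tuple[float, ...] = (10.0, 5.0)  # per TF, per cell line
    peak_half_width: tuple[int, int] = (80, 120)
    peak_jitter: int = 50
    source_prob_gtrd: float = 0.8
    source_prob_chipatlas: float = 0.8
    n_chroms: int = 4
    chrom_len: int = 1_600_000
    gc: float = 0.41
    min_copy_gap: int = 2000

    def __post_init__(self) -> None:
        n = len(self.subfamilies)
        for name, tup in (
            ("age_ranks", self.age_ranks),
            ("full_length_prob", self.full_length_prob),
            ("trunc_start_range", self.trunc_start_range),
        ):
            if len(tup) != n:
                raise ValueError(f"{name} must have one entry per subfamily")
        if len(self.occupancy) != len(self.cell_lines):
            raise ValueError("occupancy must have one entry per cell line")
        for q in self.occupancy + (self.leak_prob,):
            if not (0 <= q <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.copies_per_subfamily < 1:
            raise ValueError("copies_per_subfamily must be >= 1")
        if self.chrom_len < 10 * self.consensus_len:
            raise ValueError("chrom_len must be >= 10x the consensus length")


@dataclass
class SyntheticDataset:
    """Paths of one generated dataset plus its in-memory truth."""

    outdir: Path
    genome_fasta: Path
    rmsk_table: Path
    gtrd_tables: dict[str, Path]
    chipatlas_tables: dict[str, Path]
    motif_file: Path
    whitelist_file: Path
    truth_file: Path
    truth: dict


def generate_genome(
    rng: np.random.Generator, n_chroms: int, chrom_len: int, gc: float
) -> dict[str, np.ndarray]:
    """I.i.d. background genome at the given GC, as base-index arrays."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": rng.choice(4, size=chrom_len, p=p).astype(np.int8)
        for i in range(n_chroms)
    }


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)


def build_subfamily_consensus(
    rng: np.random.Generator, age_rank: int, config: SyntheticConfig
) -> tuple[np.ndarray, list[dict]]:
    """Consensus sequence for one subfamily with slot bookkeeping.

    Slots overwrite background bases at their nominal offsets; a
    disrupted slot additionally carries a small insertion in the middle
    of the motif, shifting downstream coordinates.  Returns the base-
    index array and the realised slot table (actual offsets).
    """
    base = rng.choice(4, size=config.consensus_len).astype(np.int8)
    pieces: list[np.ndarray] = []
    slot_records: list[dict] = []
    cursor = 0
    shift = 0
    for slot in sorted(config.slots, key=lambda s: s.offset):
        motif = _encode(slot.motif)
        disrupted = (
            slot.disrupted_from_age is not None
            and age_rank >= slot.disrupted_from_age
        )
        pieces.append(base[cursor : slot.offset])
        start = slot.offset + shift
        if disrupted:
            half = len(motif) // 2
            insert = rng.choice(4, size=config.disruption_insert_len).astype(np.int8)
            planted = np.concatenate([motif[:half], insert, motif[half:]])
            shift += config.disruption_insert_len
        else:
            planted = motif
        pieces.append(planted)
        cursor = slot.offset + len(motif)
        slot_records.append(
            {
                "tf": slot.tf,
                "key": f"{slot.tf}@{slot.offset}",
                "start": int(start),
                "end": int(start + len(planted)),
                "intact": not disrupted,
                "region": slot.region,
            }
        )
    pieces.append(base[cursor:])
    return np.concatenate(pieces), slot_records


def _format_rep_triple(cs: int, ce: int, L: int, strand: str) -> tuple[str, str, str]:
    """rmsk-dialect (repStart, repEnd, repLeft) for a 3'-anchored match
    [cs, ce) of an L-bp consensus, following the strand convention of the
    dialect (the sign-marked field carries the unaligned remainder)."""
    left = L - ce
    if strand == "+":
        return str(cs), str(ce), f"-{left}"
    return f"-{left}", str(ce), str(cs)


def place_copies(
    genome: Mapping[str, np.ndarray],
    consensus_by_subfamily: Mapping[str, np.ndarray],
    slots_by_subfamily: Mapping[str, list[dict]],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[dict]]:
    """Plant transposon copies into the genome (in place).

    Each copy draws full-length vs truncated by its subfamily's
    probability; truncated copies keep a 3'-anchored consensus suffix.
    Strand is uniform; per-base substitutions (rate 0.01 x age rank)
    are applied outside slot spans.  Copies are separated by at least
    ``min_copy_gap``.  Returns (rmsk table rows, per-copy truth records).
    """
    jobs: list[int] = []
    for si in range(len(config.subfamilies)):
        jobs.extend([si] * config.copies_per_subfamily)
    rng.shuffle(jobs)
    chrom_names = list(genome)
    cursors = {c: int(rng.integers(1000, 3000)) for c in chrom_names}
    rows: list[str] = []
    truth_copies: list[dict] = []
    for si in jobs:
        subfam = config.subfamilies[si]
        age = config.age_ranks[si]
        cons = consensus_by_subfamily[subfam]
        slots = slots_by_subfamily[subfam]
        L = cons.size
        if rng.random() < config.full_length_prob[si]:
            cs = 0
        else:
            lo, hi = config.trunc_start_range[si]
            cs = int(rng.integers(lo, hi + 1))
        fragment = cons[cs:].copy()
        # substitutions outside slot spans
        rate = config.substitution_rate_per_age * age
        if rate > 0:
            protected = np.zeros(fragment.size, dtype=bool)
            for slot in slots:
                s, e = slot["start"] - cs, slot["end"] - cs
                if s >= 0:
                    protected[max(s, 0) : max(e, 0)] = True
            hit = (rng.random(fragment.size) < rate) & ~protected
            idx = np.nonzero(hit)[0]
            fragment[idx] = (
                fragment[idx] + 1 + rng.integers(0, 3, size=idx.size)
            ).astype(np.int8) % 4
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        placed = fragment if strand == "+" else (3 - fragment[::-1]).astype(np.int8)
        # choose the least-occupied chromosome with room left
        chrom = min(cursors, key=lambda c: cursors[c])
        start = cursors[chrom]
        end = start + placed.size
        if end > genome[chrom].size - 1000:
            raise ValueError(
                "genome too small for the requested copy density; "
                "increase chrom_len or n_chroms"
            )
        genome[chrom][start:end] = placed
        cursors[chrom] = end + config.min_copy_gap + int(rng.integers(0, 1000))
        rep_start, rep_end, rep_left = _format_rep_triple(cs, L, L, strand)
        rows.append(
            f"{chrom}\t{start}\t{end}\t{strand}\t{subfam}\t"
            f"{rep_start}\t{rep_end}\t{rep_left}"
        )
        element_id = f"{chrom}:{start}-{end}:{strand}:{subfam}"
        copy_slots = {}
        for slot in slots:
            present = slot["start"] >= cs
            mid = (slot["start"] + slot["end"]) // 2
            if strand == "+":
                gpos = start + (mid - cs)
            else:
                gpos = end - (mid - cs)
            copy_slots[slot["key"]] = {
                "tf": slot["tf"],
                "present": bool(present),
                "intact": bool(slot["intact"]),
                "region": slot["region"],
                "consensus_mid": int(mid),
                "genomic_mid": int(gpos) if present else None,
            }
        truth_copies.append(
            {
                "element_id": element_id,
                "subfamily": subfam,
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "consensus_start": int(cs),
                "consensus_end": int(L),
                "slots": copy_slots,
            }
        )
    rows_sorted = sorted(rows, key=lambda r: (r.split("\t")[0], int(r.split("\t")[1])))
    truth_sorted = sorted(truth_copies, key=lambda c: (c["chrom"], c["start"]))
    return rows_sorted, truth_sorted


def generate_peaks(
    truth_copies: Sequence[dict],
    cell_index: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    genome_sizes: Mapping[str, int],
) -> list[tuple[str, int, int, str]]:
    """Peak intervals (chrom, start, end, tf) for one cell line.

    Carried intact slots emit with the cell line's occupancy; disrupted
    slots with the leak probability; plus Poisson background peaks per
    TF across the genome.
    """
    q = config.occupancy[cell_index]
    hw_lo, hw_hi = config.peak_half_width
    peaks: list[tuple[str, int, int, str]] = []
    for copy in truth_copies:
        for slot in copy["slots"].values():
            if not slot["present"]:
                continue
            prob = q if slot["intact"] else config.leak_prob
            if rng.random() >= prob:
                continue
            center = slot["genomic_mid"] + int(
                rng.integers(-config.peak_jitter, config.peak_jitter + 1)
            )
            hw = int(rng.integers(hw_lo, hw_hi + 1))
            peaks.append((copy["chrom"], max(0, center - hw), center + hw, slot["tf"]))
    total_mb = sum(genome_sizes.values()) / 1e6
    rate = config.background_rate_per_mb[cell_index]
    tfs = sorted({s.tf for s in config.slots})
    chroms = sorted(genome_sizes)
    weights = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for tf in tfs:
        n_bg = int(rng.poisson(rate * total_mb))
        for _ in range(n_bg):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            hw = int(rng.integers(hw_lo, hw_hi + 1))
            center = int(rng.integers(hw, genome_sizes[chrom] - hw))
            peaks.append((chrom, center - hw, center + hw, tf))
    peaks.sort()
    return peaks


def _write_fasta(genome: Mapping[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = _BASES[genome[chrom]].tobytes().decode("ascii")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_motifs_jaspar(config: SyntheticConfig, path: Path) -> None:
    """JASPAR PFM file for the planted motifs (one record per TF)."""
    seen: dict[str, str] = {}
    for slot in config.slots:
        seen.setdefault(slot.tf, slot.motif)
    with open(path, "w") as fh:
        for k, (tf, motif) in enumerate(sorted(seen.items()), start=1):
            fh.write(f">SYN{k:04d}.1 {tf}\n")
            for letter in "ACGT":
                counts = [97 if c == letter else 1 for c in motif]
                fh.write(f"{letter} [ " + " ".join(f"{c:3d}" for c in counts) + " ]\n")


def generate_dataset(
    outdir: str | Path, seed: int, config: SyntheticConfig | None = None
) -> SyntheticDataset:
    """Generate the full synthetic dataset under ``outdir``.

    Emits genome FASTA, rmsk-dialect repeat table, GTRD- and
    ChIP-Atlas-dialect peak tables per cell line, a JASPAR motif file,
    a TF whitelist and the truth JSON.  Deterministic per (seed, config).
    """
    config = config or SyntheticConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_cons, rng_place, rng_peaks, rng_split = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    genome = generate_genome(rng_genome, config.n_chroms, config.chrom_len, config.gc)
    consensus: dict[str, np.ndarray] = {}
    slot_tables: dict[str, list[dict]] = {}
    for subfam, age in zip(config.subfamilies, config.age_ranks):
        consensus[subfam], slot_tables[subfam] = build_subfamily_consensus(
            rng_cons, age, config
        )
    rmsk_rows, truth_copies = place_copies(
        genome, consensus, slot_tables, config, rng_place
    )

    genome_sizes = {c: arr.size for c, arr in genome.items()}
    gtrd_tables: dict[str, Path] = {}
    chipatlas_tables: dict[str, Path] = {}
    for ci, cell in enumerate(config.cell_lines):
        peaks = generate_peaks(truth_copies, ci, config, rng_peaks, genome_sizes)
        gtrd_path = outdir / f"tfbs_gtrd_{cell}.tsv"
        ca_path = outdir / f"tfbs_chipatlas_{cell}.bed"
        with open(gtrd_path, "w") as gfh, open(ca_path, "w") as cfh:
            for chrom, start, end, tf in peaks:
                to_gtrd = rng_split.random() < config.source_prob_gtrd
                to_ca = rng_split.random() < config.source_prob_chipatlas
                if not (to_gtrd or to_ca):
                    to_gtrd = True
                if to_gtrd:
                    gfh.write(f"{chrom}\t{start}\t{end}\t{tf}\t{cell}\n")
                if to_ca:
                    cfh.write(f"{chrom}\t{start}\t{end}\t{tf}\t1000\n")
        gtrd_tables[cell] = gtrd_path
        chipatlas_tables[cell] = ca_path

    genome_fasta = outdir / "genome.fa"
    _write_fasta(genome, genome_fasta)
    rmsk_table = outdir / "rmsk.tsv"
    with open(rmsk_table, "w") as fh:
        fh.write("#chrom\tgenoStart\tgenoEnd\tstrand\trepName\trepStart\trepEnd\trepLeft\n")
        fh.write("\n".join(rmsk_rows) + "\n")
    motif_file = outdir / "motifs.jaspar"
    _write_motifs_jaspar(config, motif_file)
    whitelist_file = outdir / "tf_whitelist.txt"
    whitelist_file.write_text(
        "\n".join(sorted({s.tf for s in config.slots})) + "\n"
    )
    truth = {
        "seed": seed,
        "config": dataclasses.asdict(config),
        "subfamilies": {
            subfam: {
                "age_rank": age,
                "consensus_len": int(consensus[subfam].size),
                "n_copies": config.copies_per_subfamily,
                "full_length_prob": config.full_length_prob[i],
                "slots": slot_tables[subfam],
            }
            for i, (subfam, age) in enumerate(
                zip(config.subfamilies, config.age_ranks)
            )
        },
        "copies": truth_copies,
    }
    truth_file = outdir / "truth.json"
    truth_file.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return SyntheticDataset(
        outdir=outdir,
        genome_fasta=genome_fasta,
        rmsk_table=rmsk_table,
        gtrd_tables=gtrd_tables,
        chipatlas_tables=chipatlas_tables,
        motif_file=motif_file,
        whitelist_file=whitelist_file,
        truth_file=truth_file,
        truth=truth,
    )
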