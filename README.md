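# l1exapt

Transcription-factor binding and exaptation profiling of LINE-1 (L1)
transposon subfamilies.

## The problem

L1 retrotransposons occupy roughly 17% of the human genome. Their
ancestral sequences carry cis-regulatory elements — above all in the
~1 kb 5′ UTR, which hosts sense and antisense promoters — and in
epigenetically de-repressed states such as breast cancer these elements
are *exapted*: bound by host transcription factors (TFs) and recruited
into host gene regulation. Because L1 subfamilies (L1HS, L1PA2, …,
L1PA12; larger number = older) differ in age, 5′ truncation and motif
decay, they differ systematically in which TFs bind them and where.

`l1exapt` is a reusable pipeline for quantifying this, aimed at
regulatory genomicists working with repeat annotation and ChIP-derived
binding-site catalogues. It:

1. reads RepeatMasker-dialect repeat tables (UCSC `rmsk` flavour),
   derives full-length elements (length > 6000 bp) and 5′ UTRs (first
   1000 bp, strand-aware), and extracts strand-specific sequence;
2. ingests TF binding sites (TFBSs) from GTRD meta-cluster and
   ChIP-Atlas BED dialects, filters by cell line and a dbTF-style
   whitelist, merges per TF (bedtools `-d` semantics; GTRD at gap 300,
   ChIP-Atlas at 0) and combines sources into one catalogue per cell
   line;
3. scans sequences with log-odds position weight matrices (JASPAR PFM
   or MEME-minimal input) using *exact* p-values from a lattice dynamic
   program, same-strand only, at p < 10⁻⁴, and summarises motif
   occurrence frequencies per subfamily with a >10% prevalence filter;
4. assigns TFBSs to elements when ≥ half of the site overlaps the
   element, computes bound fractions and per-TF binding frequencies,
   and projects sites into consensus coordinates (via RepStart/RepEnd)
   for 5-bp positional histograms over 0–6500 bp;
5. clusters subfamily × TF frequency matrices (Manhattan distance,
   complete or ward.D2 linkage) with deterministic tie-breaking;
6. tests TFBS co-localisation (two sites within 500 bp, edge-to-edge)
   inside each subfamily against the genomic background with a
   one-tailed two-proportion z-test at p < 0.0005 (0.05/102, rounded up
   at one significant figure);
7. classifies per-element, per-TF binding as shared, cancer-only or
   normal-only between two cell lines.

A synthetic-data module generates a complete toy study — genome, repeat
annotation, motifs, two-dialect peak catalogues for a cancer-like and a
near-normal cell line — with planted ground truth, so every stage can
be validated end to end.

## The statistics, briefly

**PWM scoring.** A motif of length *L* with counts *c₍ᵢₓ₎*, pseudocount
*κ* (default 0.1, distributed by background *bₓ*, default uniform)
scores window *w* as

  S(w) = Σᵢ log₂[ (c₍ᵢ,wᵢ₎ + κ·b₍wᵢ₎) / (Σₓc₍ᵢₓ₎ + κ) / b₍wᵢ₎ ].

Per-position scores are discretised onto an integer lattice (1000
levels across the attainable range) and the exact null distribution of
the lattice total under *b* is computed by dynamic programming over
positions; the p-value of a window is the lattice tail P(S ≥ s). For
motifs of length ≤ 8 this is verified against exhaustive enumeration of
all 4ᴸ windows.

**Binding frequencies.** For subfamily *s*: bound fraction =
|elements with ≥1 TFBS| / |elements|; per-TF frequency f(s, t) =
|elements bound by t| / |elements bound by any TF|.

**Co-localisation.** For the ordered TF pair (A, B) and subfamily *s*,
let k₁/n₁ be the A sites inside *s* (≥ half-overlap rule) with a B site
within 500 bp, and k₂/n₂ the same for the remaining A sites. With
pooled p̂ = (k₁+k₂)/(n₁+n₂),

  z = (k₁/n₁ − k₂/n₂) / √[ p̂(1−p̂)(1/n₁ + 1/n₂) ],  p = 1 − Φ(z).

Positive z means enrichment of co-localisation inside the subfamily,
negative means depletion.

## Worked example

Generate a seeded synthetic study (3 subfamilies of graded age × 40
copies, 3 TFs, cancer vs near-normal occupancy 0.9 vs 0.15) and run
every stage:

```
l1exapt synth --outdir demo --seed 1 --copies 40
l1exapt run-all --config demo/config.yaml
```

`demo/results/bound_fraction_utr5.tsv` — almost every intact 5′ UTR is
TF-bound, least so in the oldest subfamily:

```
subfamily  total  bound  percent
L1SYN1     30     30     100.0
L1SYN2     16     16     100.0
L1SYN3      6      5      83.33
```

`demo/results/binding_frequency.tsv` — ESR1 binds all ages (it keeps a
3′-end site that survives truncation), while FOXA1 and E2F1 fall away
with age as their 5′ UTR motifs are disrupted and truncated:

```
subfamily  E2F1   ESR1  FOXA1
L1SYN1     0.757  1.0   0.730
L1SYN2     0.0    1.0   0.368
L1SYN3     0.0    1.0   0.0
```

`demo/results/coloc_results.tsv` — the FOXA1→E2F1 pair planted in the
young 5′ UTR co-localises far above background (26/30 of the young
subfamily's FOXA1 sites have an E2F1 site within 500 bp versus 1/81
elsewhere): z = 9.32, p = 6.0 × 10⁻²¹, significant at p < 0.0005.

`demo/results/differential_elements.tsv` — binding is cancer-skewed:
per subfamily, 18–25 elements are bound only in the cancer-like cell
line versus 0–1 only in the near-normal line.

The run directory also contains per-subfamily consensus-position
histograms (`histogram_<subfamily>.tsv`; the young subfamily's binding
mass sits below 1000 bp, the oldest subfamily's above 5000 bp), the
clustering merge table and leaf order, motif occurrence frequencies,
and a `manifest.json` with config snapshot, input checksums and stage
timings. Re-running with unchanged inputs skips all stages.

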