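# Methods

This note documents the models, conventions and numerical choices
behind `l1exapt`, and what the synthetic validation does and does not
demonstrate.

## Coordinates and annotation

All intervals are 0-based, half-open, the UCSC-table/BED convention.
"Main chromosomes" are chr1–chr22, chrX, chrY and chrM exactly;
anything else (`_alt`, `_random`, `chrUn…`) is excluded when the
main-chromosome filter is on.

A RepeatMasker-dialect row carries a (repStart, repEnd, repLeft)
triple whose sign convention differs between strands and between the
`.out` and UCSC-table dialects. Rather than hard-coding one dialect,
the reader applies the rule that the two non-negative fields delimit
the copy's aligned span in the subfamily consensus, while the
sign-marked field is the unaligned remainder; the sign character is
tested on the raw string so that "-0" (a zero remainder on the marked
side) is handled. If no field is sign-marked, the strand convention
(remainder in repLeft on '+', repStart on '-') breaks the tie. The
recovered span is ordered so consensus_start < consensus_end.

Full-length elements are those with genomic length strictly greater
than 6000 bp; the 5′ UTR is the first 1000 bp from the 5′ end
(leftmost on '+', rightmost on '-'). The 5′ UTR is derived purely from
genomic length, not from the copy's consensus_start; a copy that
passes the length filter is treated as having an intact 5′ end.
Element ids are `chrom:start-end:strand:subfamily`, a stable join key
across all stages.

## TFBS catalogues

Binding sites are unstranded. Merging uses the edge-to-edge gap
convention of the standard interval tools: two sites of the same TF
merge when their gap is ≤ d (overlapping and book-ended intervals
always merge; at d = 0 book-ended intervals union). GTRD meta-clusters
merge at d = 300 after cell-line filtering; ChIP-Atlas sites and the
combined catalogue merge at d = 0. Cell-line matching is exact after
case-folding and whitespace stripping; synonym resolution is out of
scope. The TF whitelist filter is case-insensitive.

The interval engines (merge, fractional-overlap assignment, windowed
co-localisation) are implemented as sorted sweeps with numpy, not via
an external interval library, because their exact boundary semantics
(inclusive half-overlap, gap-versus-window ties, self-exclusion in
same-TF co-localisation) are the analysis contract; each is tested for
exact agreement with a brute-force all-pairs oracle.

## Motif scanning

Scores are log₂ odds against the background with the pseudocount
distributed proportionally to the background (defaults: uniform
background, pseudocount 0.1 — the defaults of the standard FIMO-style
scanners). MEME-minimal probability matrices are converted to
pseudo-counts by multiplying by the recorded `nsites` (20 if absent).

P-values are exact under the background model: each position's scores
are mapped to an integer lattice with 1000 levels spanning the motif's
attainable score range, and a dynamic program over positions yields
the full null distribution of the lattice total. Scanning computes
each window's lattice score by table lookup, so scan decisions are
*identical* to what enumeration of all 4ᴸ windows would give (verified
for L ≤ 8). Letters that are impossible under the model (zero smoothed
probability, only possible at pseudocount 0) leave the finite lattice;
windows containing them, and windows containing any non-ACGT letter,
are never hits (p = 1). Scanning is same-strand only — the reverse
complement is never scored — because repeat promoters are oriented.

Motif prevalence ("binding motifs in over 10% of transposons") is a
strict inequality and is applied per subfamily; a motif is retained
when it exceeds the cut in *at least one* subfamily (configurable to
"every subfamily", which is the stricter reading of the same phrase).

## Binding profiles and consensus projection

A TFBS is assigned to an element when the shared bases are at least
`overlap_fraction` × site length (default one half, inclusive at the
boundary, applied to the site — the `-f` operand convention with the
site as query). The minimal required overlap is computed as
ceil(fraction × length) with a 10⁻⁹ guard against float artefacts at
exact ties. One site may be assigned to several elements; each
assignment contributes one projected position.

Projection to consensus coordinates interpolates linearly between the
copy's consensus-match endpoints: the site's genomic midpoint
(integer floor, clipped into the copy) at relative position t in the
copy maps to consensus_start + t·(consensus_end − consensus_start),
with t measured from the genomic right edge on '-' copies. Linear
interpolation absorbs small indels proportionally; no per-base
alignment is attempted since the annotation provides only the span
endpoints. Histograms use 5-bp bins over [0, 6500]; positions beyond
the range are discarded and counted in the log. Positional histograms
pool sites across TFs by default (per-TF histograms are a filter away,
as the assignment table carries the TF).

## Clustering

Distances are Manhattan (city-block) between frequency-matrix rows;
rows with undefined frequencies (subfamilies with zero bound elements)
must be dropped first. Agglomeration is Lance–Williams with two
linkages: complete, and "ward_on_distances" — the ward.D2 convention,
which squares the input distances internally and reports merge heights
on the unsquared scale (equivalent to scipy's `ward` on Euclidean
distances, checked in the tests). Ties are broken by the
lexicographically smallest pair of cluster indices, making merge order
fully deterministic; leaf order is the plain left-before-right reading
of the merge tree with no seriation.

## Co-localisation testing

Two sites co-localise when their edge-to-edge gap is ≤ 500 bp on the
same chromosome (overlap counts as gap 0; a site is not its own
partner when a TF is tested against itself). For each subfamily, a
TF's sites are partitioned into the subfamily class (assigned to ≥ 1
element under the half-overlap rule) and the background ("remainder of
the genome" — sites in other subfamilies included). The one-tailed
pooled two-proportion z-test takes "subfamily class greater" as the
upper tail, so depletion appears as negative z with p > 0.5. No
continuity correction is applied. A degenerate pooled proportion (0 or
1) is reported as z = 0, p = 0.5 and flagged rather than dividing by
zero. The per-test threshold follows a Bonferroni correction rounded
*up* at one significant figure: 0.05/102 → 0.0005.

The z-test assumes independent per-site indicators. In dense site
catalogues, neighbouring sites share partners and the indicators are
positively correlated, which makes the test anti-conservative; the
calibration check therefore uses site densities whose mean spacing is
an order of magnitude larger than the window. Results on dense real
catalogues should be read as enrichment scores more than exact
p-values — the same caveat applies to any pooled proportion test on
genomic windows.

## Differential binding

For the TFs assayed in both cell lines, each (element, TF) pair bound
in at least one cell line is classified as both / cell-A-only /
cell-B-only; the categories partition the bound pairs exactly.
Element-level aggregation counts an element as bound in a cell line
when ≥ 1 shared TF binds it there, so "both" does not require the same
TF in both lines. Elements bound in neither line are omitted from
records but retained in denominators when fractions are requested.
Counts are descriptive; no test is attached.

## Synthetic data: what it emulates

The generator plants the statistical structure the analysis assumes,
at desk scale. Defaults (the packaged study conditions): 3 subfamilies
of age rank 0/1/2 × 200 copies on a 4 × 1.6 Mb i.i.d. genome at GC
0.41; a ~6050 bp consensus per subfamily with motif slots ESR1 at
offset 200, FOXA1 at 420 and E2F1 at 600 in the 5′ UTR and an
always-intact ESR1 slot at 5900 modelling the 3′-end binding mode;
FOXA1 disrupted (4-bp insertion inside the motif) from age rank 2 and
E2F1 from age rank 1; full-length probability 0.9/0.5/0.1 by age with
truncated copies keeping a 3′-anchored suffix (consensus_start uniform
in [500, 4500] / [1500, 4800] / [2500, 5000]) — truncation is
5′-anchored loss only, reflecting target-primed reverse transcription;
per-base substitutions at 1% × age rank outside slots (slot content is
governed by the intact/disrupted flag); peak occupancy 0.9 in the
cancer-like line versus 0.15 in the near-normal line, leak 0.02 from
disrupted slots, peak half-width 80–120 bp with ≤ 50 bp centre jitter;
Poisson background peaks at 10 (cancer) / 5 (normal) per Mb per TF;
peaks split into GTRD- and ChIP-Atlas-dialect files with 80%/80%
inclusion so source combination is exercised. These rates were chosen
so that each planted contrast is unambiguous at n = 200 copies
(expected 5′-UTR histogram share ≈ 0.70 in the young subfamily,
3′-end share ≈ 0.85 in the oldest) while background peaks still
perturb every stage. All randomness flows from a single seed through
spawned generator streams; identical seed and configuration give
byte-identical files.

What the generator does *not* emulate: real L1 sequence content and
CpG structure, real motif matrices, nested/fragmented repeat
annotations, internal deletions, peak-width and occupancy differences
between TFs, and chromatin context. Passing the recovery tests
therefore shows the pipeline's logic and arithmetic are correct under
the stated model — not that the biological conclusions transfer to any
particular real dataset.

## Problem sizes used in validation

The test suite and the acceptance script run the synthetic fixture at
3 subfamilies × 200 copies with 3 TFs; interval and clustering engines
are checked against brute-force oracles on 200 random instances each
(n ≤ 100); PWM p-values on 20 random motifs of length 4–8 against full
4ᴸ enumeration; and z-test calibration on 2000 null replicates with
150 query and 800 partner sites on a 4 Mb genome. These sizes give
every check a comfortable statistical margin (3 binomial/Monte-Carlo
standard errors) while keeping a full run to a couple of minutes.

## Known limitations

* The rmsk reader treats each row as one copy; fragmented joins of one
  insertion event are profiled as separate elements.
* The 5′ UTR definition is purely length-based; a full-length element
  whose alignment starts mid-consensus would still contribute a "5′
  UTR" interval.
* Exact p-values are exact on the lattice; two windows whose real
  scores differ by less than one lattice step share a p-value
  (granularity 1000 keeps this far below any decision threshold used).
* The co-localisation background is "all sites of the TF not in the
  tested subfamily", so heavy binding in a *related* subfamily dilutes
  enrichment estimates.
* Differential classification is presence/absence; it does not model
  occupancy strength or replicate variability.
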