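"""Stage orchestration for the L1 TF-binding profiling pipeline.

Stages communicate through tab-separated files in the run directory, so
any stage can be re-run (or skipped) independently:

  annotate  -> elements.tsv, full_length.tsv, utr5.tsv (+ BED mirrors)
  catalogue -> catalogue_<cell>.tsv (combined GTRD + ChIP-Atlas)
  scan      -> motif_frequency.tsv, retained_motifs.txt, motif_hits.tsv
  profile   -> assignments_<cell>.tsv, bound_fraction_*.tsv,
               binding_frequency.tsv, histogram_<subfamily>.tsv
  cluster   -> cluster_merges.tsv, cluster_leaf_order.txt
  coloc     -> coloc_results.tsv, coloc_z_<subfamily>.tsv
  diff      -> differential_per_tf.tsv, differential_elements.tsv

A manifest (manifest.json) records the config snapshot, input file
checksums, stage timings and outputs; a stage is skipped on re-run when
its recorded input checksums still match and its outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import pandas as pd

from . import __version__
from .annotation import (
    GenomicInterval,
    TransposonCopy,
    derive_five_prime_utr,
    extract_sequences,
    full_length_filter,
    read_rmsk_table,
    write_bed,
)
from .binding_profile import (
    Element,
    assign_tfbs,
    bound_fraction,
    consensus_histogram,
    per_tf_binding_frequency,
    project_to_consensus,
)
from .cluster import agglomerate, manhattan_distances
from .colocalisation import coloc_battery, results_frame, zscore_matrix
from .config import PipelineConfig, load_config
from .differential import classify_binding, element_level_counts, per_tf_counts
from .motif_scan import (
    exact_pvalue_table,
    occurrence_matrix,
    prevalence_filter,
    read_motifs,
    scan_sequence,
)
from .tfbs_catalog import (
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

logger = logging.getLogger(__name__)

STAGE_ORDER = ("annotate", "catalogue", "scan", "profile", "cluster", "coloc", "diff")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


class RunContext:
    """Resolved configuration plus helpers shared by all stages."""

    def __init__(self, config: PipelineConfig, inputs: Mapping[str, Any], outdir: Path):
        self.cfg = config
        self.inputs = dict(inputs)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        for key in ("rmsk", "genome_fasta", "cell_lines"):
            if key not in self.inputs:
                raise ValueError(f"run configuration lacks required entry {key!r}")

    # ---- file helpers -------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    @property
    def cell_lines(self) -> dict[str, dict[str, str]]:
        return dict(self.inputs["cell_lines"])

    @property
    def primary_cell(self) -> str:
        return self.inputs.get("primary_cell_line") or next(iter(self.cell_lines))

    def write_elements(self, copies: Sequence[TransposonCopy], path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "element_id\tchrom\tstart\tend\tstrand\tsubfamily\t"
                "consensus_start\tconsensus_end\n"
            )
            for c in copies:
                iv = c.interval
                fh.write(
                    f"{c.element_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}"
                    f"\t{c.subfamily}\t{c.consensus_start}\t{c.consensus_end}\n"
                )

    def read_elements(self, path: Path) -> list[TransposonCopy]:
        df = pd.read_csv(path, sep="\t")
        return [
            TransposonCopy(
                interval=GenomicInterval(r.chrom, r.start, r.end, r.strand),
                subfamily=r.subfamily,
                consensus_start=r.consensus_start,
                consensus_end=r.consensus_end,
                element_id=r.element_id,
            )
            for r in df.itertuples()
        ]

    def write_catalogue(self, sites: Sequence[TFBS], path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\ttf\tcell_line\tsource\n")
            for s in sorted(
                sites, key=lambda s: (s.interval.chrom, s.interval.start, s.tf)
            ):
                iv = s.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.tf}\t{s.cell_line}\t{s.source}\n"
                )

    def read_catalogue(self, path: Path) -> list[TFBS]:
        df = pd.read_csv(path, sep="\t")
        return [
            TFBS(
                interval=GenomicInterval(r.chrom, r.start, r.end, "."),
                tf=r.tf,
                cell_line=r.cell_line,
                source=r.source,
            )
            for r in df.itertuples()
        ]

    def elements_by_subfamily(
        self, copies: Sequence[TransposonCopy]
    ) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {s: [] for s in self.cfg.subfamilies}
        for c in copies:
            groups.setdefault(c.subfamily, []).append(c.element_id)
        return {s: ids for s, ids in groups.items() if ids}


# ---- stages ----------------------------------------------------------


def stage_annotate(ctx: RunContext) -> tuple[list[Path], list[Path]]:
    cfg = ctx.cfg
    rmsk = Path(ctx.inputs["rmsk"])
    copies = read_rmsk_table(
        rmsk, cfg.subfamilies, main_chroms_only=cfg.main_chroms_only
    )
    logger.info("annotate: %d copies of %d subfamilies", len(copies), len(cfg.subfamilies))
    full = full_length_filter(copies, cfg.full_length_min_bp)
    utrs = [(c.element_id, derive_five_prime_utr(c, cfg.utr5_len_bp)) for c in full]
    ctx.write_elements(copies, ctx.path("elements.tsv"))
    ctx.write_elements(full, ctx.path("full_length.tsv"))
    with open(ctx.path("utr5.tsv"), "w") as fh:
        fh.write("element_id\tchrom\tstart\tend\tstrand\n")
        for eid, iv in utrs:
            fh.write(f"{eid}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")
    write_bed(copies, ctx.path("elements.bed"))
    write_bed(utrs, ctx.path("utr5.bed"))
    outputs = [
        ctx.path(n)
        for n in ("elements.tsv", "full_length.tsv", "utr5.tsv", "elements.bed", "utr5.bed")
    ]
    return [rmsk], outputs


def stage_catalogue(ctx: RunContext) -> tuple[list[Path], list[Path]]:
    cfg = ctx.cfg
    whitelist = None
    inputs: list[Path] = []
    if ctx.inputs.get("tf_whitelist"):
        wl_path = Path(ctx.inputs["tf_whitelist"])
        whitelist = [l.strip() for l in wl_path.read_text().splitlines() if l.strip()]
        inputs.append(wl_path)
    outputs = []
    for cell, paths in ctx.cell_lines.items():
        per_source: list[list[TFBS]] = []
        for source, dialect, gap, key in (
            (GTRD, GTRD_DIALECT, cfg.merge_gap_gtrd_bp, "gtrd"),
            (CHIPATLAS, CHIPATLAS_DIALECT, cfg.merge_gap_chipatlas_bp, "chipatlas"),
        ):
            if key not in paths:
                per_source.append([])
                continue
            path = Path(paths[key])
            inputs.append(path)
            sites = read_tfbs_table(
                path, dialect, cell, source, main_chroms_only=cfg.main_chroms_only
            )
            if whitelist:
                sites = filter_tf_whitelist(sites, whitelist)
            merged: list[TFBS] = []
            for tf in sorted(group_by_tf(sites)):
                merged.extend(merge_per_tf(group_by_tf(sites)[tf], gap))
            per_source.append(merged)
        combined = combine_sources(per_source[0], per_source[1])
        logger.info(
            "catalogue[%s]: %d combined sites, %d TFs",
            cell,
            len(combined),
            len({s.tf for s in combined}),
        )
        out = ctx.path(f"catalogue_{cell}.tsv")
        ctx.write_catalogue(combined, out)
        outputs.append(out)
    return inputs, outputs


def stage_scan(ctx: RunContext) -> tuple[list[Path], list[Path]]:
    cfg = ctx.cfg
    genome = Path(ctx.inputs["genome_fasta"])
    motif_spec = ctx.inputs.get("motifs") or {}
    motif_path = Path(motif_spec["path"])
    motif_fmt = motif_spec.get("format", "jaspar_pfm")
    full = ctx.read_elements(ctx.path("full_length.tsv"))
    if not full:
        raise PipelineError("scan", "no full-length elements; run annotate first")
    utr_ivs = [derive_five_prime_utr(c, cfg.utr5_len_bp) for c in full]
    seqs = extract_sequences(genome, utr_ivs)
    motifs = read_motifs(motif_path, motif_fmt)
    groups = ctx.elements_by_subfamily(full)
    hits_by_motif: dict[str, dict[str, list]] = {}
    all_hits = []
    for m in motifs:
        dist = exact_pvalue_table(m)
        per_seq = {}
        for c, seq in zip(full, seqs):
            hits = scan_sequence(
                m, seq, cfg.motif_p_threshold, sequence_id=c.element_id, dist=dist
            )
            per_seq[c.element_id] = hits
            all_hits.extend((m.motif_id, h) for h in hits)
        hits_by_motif[m.motif_id] = per_seq
    freq = occurrence_matrix(hits_by_motif, groups)
    retained = prevalence_filter(freq, cfg.prevalence_threshold, cfg.prevalence_mode)
    freq.rename_axis("motif_id").to_csv(ctx.path("motif_frequency.tsv"), sep="\t")
    ctx.path("retained_motifs.txt").write_text("".join(f"{m}\n" for m in retained))
    with open(ctx.path("motif_hits.tsv"), "w") as fh:
        fh.write("motif_id\tsequence_id\toffset\tscore\tp_value\n")
        for motif_id, h in all_hits:
            fh.write(
                f"{motif_id}\t{h.sequence_id}\t{h.offset}\t{h.score:.4f}\t{h.p_value:.3e}\n"
            )
    logger.info("scan: %d motifs, %d retained at >%.0f%% prevalence",
                len(motifs), len(retained), 100 * cfg.prevalence_threshold)
    inputs = [genome, motif_path, ctx.path("full_length.tsv")]
    outputs = [ctx.path(n) for n in ("motif_frequency.tsv", "retained_motifs.txt", "motif_hits.tsv")]
    return inputs, outputs


def stage_profile(ctx: RunContext) -> tuple[list[Path], list[Path]]:
    cfg = ctx.cfg
    copies = ctx.read_elements(ctx.path("elements.tsv"))
    full = ctx.read_elements(ctx.path("full_length.tsv"))
    cell = ctx.primary_cell
    cat_path = ctx.path(f"catalogue_{cell}.tsv")
    sites = ctx.read_catalogue(cat_path)
    copy_of = {c.element_id: c for c in copies}
    assignments = assign_tfbs(sites, copies, cfg.overlap_fraction)
    utr_elements = [
        Element(c.element_id, derive_five_prime_utr(c, cfg.utr5_len_bp)) for c in full
    ]
    utr_assignments = assign_tfbs(sites, utr_elements, cfg.overlap_fraction)
    outputs = []

    def write_assignments(assigns, name):
        path = ctx.path(name)
        with open(path, "w") as fh:
            fh.write("tf\tcell_line\tchrom\tstart\tend\telement_id\toverlap_bp\n")
            for a in assigns:
                iv = a.tfbs.interval
                fh.write(
                    f"{a.tfbs.tf}\t{a.tfbs.cell_line}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                    f"\t{a.element_id}\t{a.overlap_bp}\n"
                )
        outputs.append(path)

    write_assignments(assignments, f"assignments_{cell}.tsv")
    write_assignments(utr_assignments, f"assignments_utr5_{cell}.tsv")

    groups_all = ctx.elements_by_subfamily(copies)
    groups_full = ctx.elements_by_subfamily(full)
    bf_all = bound_fraction(assignments, groups_all)
    bf_all.rename_axis("subfamily").to_csv(
        ctx.path("bound_fraction_elements.tsv"), sep="\t"
    )
    outputs.append(ctx.path("bound_fraction_elements.tsv"))
    if groups_full:
        bf_utr = bound_fraction(utr_assignments, groups_full)
        bf_utr.rename_axis("subfamily").to_csv(
            ctx.path("bound_fraction_utr5.tsv"), sep="\t"
        )
        outputs.append(ctx.path("bound_fraction_utr5.tsv"))
    profile = per_tf_binding_frequency(assignments, groups_all)
    profile.frequencies.rename_axis("subfamily").to_csv(
        ctx.path("binding_frequency.tsv"), sep="\t"
    )
    outputs.append(ctx.path("binding_frequency.tsv"))

    # positional histograms: pooled over all TFs, one file per subfamily
    positions: dict[str, list[float]] = {s: [] for s in groups_all}
    for a in assignments:
        copy = copy_of[a.element_id]
        positions[copy.subfamily].append(project_to_consensus(a.tfbs, copy))
    for subfam, pos in positions.items():
        hist = consensus_histogram(pos, subfam, cfg.hist_bin_bp, cfg.hist_max_bp)
        path = ctx.path(f"histogram_{subfam}.tsv")
        hist.to_frame().to_csv(path, sep="\t", index=False)
        outputs.append(path)
    logger.info("profile[%s]: %d assignments on %d copies", cell, len(assignments), len(copies))
    inputs = [ctx.path("elements.tsv"), ctx.path("full_length.tsv"), cat_path]
    return inputs, outputs


def stage_cluster(ctx: RunContext) -> tuple[list[Path], list[Path]]:
    linkage = ctx.inputs.get("cluster_linkage", "complete")
    freq = pd.read_csv(ctx.path("binding_frequency.tsv"), sep="\t", index_col=0)
    freq = freq.dropna(how="any")
    if freq.shape[0] < 2:
        raise PipelineError("cluster", "need >= 2 subfamilies with defined frequencies")
    D = manhattan_distances(freq)
    dend = agglomerate(D, linkage=linkage, labels=list(freq.index))
    dend.to_frame().to_csv(ctx.path("cluster_merges.tsv"), sep="\t", index=False)
    ctx.path("cluster_leaf_order.txt").write_text(
        "".join(f"{l}\n" for l in dend.leaf_order)
    )
    inputs = [ctx.path("binding_frequency.tsv")]
    outputs = [ctx.path("cluster_merges.tsv"), ctx.path("cluster_leaf_order.txt")]
    return inputs, outputs


def stage_coloc(ctx: RunContext) -> tuple[list[Path], list[Path]]:
    cfg = ctx.cfg
    cell = ctx.primary_cell
    cat_path = ctx.path(f"catalogue_{cell}.tsv")
    sites = ctx.read_catalogue(cat_path)
    copies = ctx.read_elements(ctx.path("elements.tsv"))
    catalogue = group_by_tf(sites)
    panel = ctx.inputs.get("coloc_tfs") or sorted(catalogue)
    catalogue = {tf: catalogue.get(tf, []) for tf in panel}
    subfamilies: dict[str, list[TransposonCopy]] = {}
    for c in copies:
        subfamilies.setdefault(c.subfamily, []).append(c)
    results = coloc_battery(
        catalogue,
        subfamilies,
        window_bp=cfg.coloc_window_bp,
        p_threshold=cfg.coloc_p_threshold,
        fraction=cfg.overlap_fraction,
    )
    results_frame(results).to_csv(ctx.path("coloc_results.tsv"), sep="\t", index=False)
    outputs = [ctx.path("coloc_results.tsv")]
    for subfam in subfamilies:
        path = ctx.path(f"coloc_z_{subfam}.tsv")
        zscore_matrix(results, subfam).rename_axis("tf").to_csv(path, sep="\t")
        outputs.append(path)
    logger.info("coloc[%s]: %d tests", cell, len(results))
    return [ctx.path("elements.tsv"), cat_path], outputs


def stage_diff(ctx: RunContext) -> tuple[list[Path], list[Path]]:
    cfg = ctx.cfg
    cells = list(ctx.cell_lines)
    if len(cells) < 2:
        raise PipelineError("diff", "differential binding needs two cell lines")
    cell_a = ctx.primary_cell
    cell_b = ctx.inputs.get("secondary_cell_line") or next(
        c for c in cells if c != cell_a
    )
    copies = ctx.read_elements(ctx.path("elements.tsv"))
    subfamily_of = {c.element_id: c.subfamily for c in copies}
    cat_a = ctx.read_catalogue(ctx.path(f"catalogue_{cell_a}.tsv"))
    cat_b = ctx.read_catalogue(ctx.path(f"catalogue_{cell_b}.tsv"))
    shared = sorted({s.tf for s in cat_a} & {s.tf for s in cat_b})
    if not shared:
        raise PipelineError("diff", "no TFs shared between the two cell lines")
    assign_a = assign_tfbs(cat_a, copies, cfg.overlap_fraction)
    assign_b = assign_tfbs(cat_b, copies, cfg.overlap_fraction)
    records = classify_binding(assign_a, assign_b, shared, subfamily_of)
    per_tf_counts(records).to_csv(ctx.path("differential_per_tf.tsv"), sep="\t")
    element_level_counts(records).rename_axis("subfamily").to_csv(
        ctx.path("differential_elements.tsv"), sep="\t"
    )
    logger.info(
        "diff[%s vs %s]: %d (element, TF) pairs over %d shared TFs",
        cell_a, cell_b, len(records), len(shared),
    )
    inputs = [
        ctx.path("elements.tsv"),
        ctx.path(f"catalogue_{cell_a}.tsv"),
        ctx.path(f"catalogue_{cell_b}.tsv"),
    ]
    outputs = [ctx.path("differential_per_tf.tsv"), ctx.path("differential_elements.tsv")]
    return inputs, outputs


_STAGES: dict[str, Callable[[RunContext], tuple[list[Path], list[Path]]]] = {
    "annotate": stage_annotate,
    "catalogue": stage_catalogue,
    "scan": stage_scan,
    "profile": stage_profile,
    "cluster": stage_cluster,
    "coloc": stage_coloc,
    "diff": stage_diff,
}

_REQUIRES: dict[str, tuple[str, ...]] = {
    "scan": ("full_length.tsv",),
    "profile": ("elements.tsv",),
    "cluster": ("binding_frequency.tsv",),
    "coloc": ("elements.tsv",),
    "diff": ("elements.tsv",),
}


def run_pipeline(
    config_path: str | Path,
    stages: Sequence[str] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the requested stages in dependency order; returns the manifest.

    A stage whose recorded input checksums match and whose outputs all
    exist is skipped.  A stage whose upstream products are missing fails
    with an error naming the stage to run first.
    """
    config, inputs = load_config(config_path)
    run_dir = Path(outdir) if outdir else Path(inputs.get("outdir", "."))
    ctx = RunContext(config, inputs, run_dir)
    requested = list(stages) if stages else list(STAGE_ORDER)
    unknown = [s for s in requested if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    manifest_path = ctx.path("manifest.json")
    manifest: dict = {"stages": {}}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        manifest.setdefault("stages", {})
    manifest["tool_version"] = __version__
    manifest["config"] = config.to_dict()
    manifest["seed"] = inputs.get("seed")
    for name in STAGE_ORDER:
        if name not in requested:
            continue
        if name == "diff" and len(ctx.cell_lines) < 2:
            logger.info("diff: single cell line configured, skipping")
            continue
        if name == "scan" and not ctx.inputs.get("motifs"):
            logger.info("scan: no motif file configured, skipping")
            continue
        for req in _REQUIRES.get(name, ()):
            if not ctx.path(req).exists():
                raise PipelineError(
                    name,
                    f"missing upstream output {req}; run the producing stage first",
                )
        t0 = time.monotonic()
        probe_inputs, _ = _stage_inputs_probe(ctx, name)
        recorded = manifest["stages"].get(name)
        checks = {str(p): _sha256(Path(p)) for p in probe_inputs if Path(p).exists()}
        if (
            recorded
            and recorded.get("inputs") == checks
            and all(Path(p).exists() for p in recorded.get("outputs", []))
        ):
            logger.info("%s: inputs unchanged, skipping", name)
            manifest["stages"][name]["skipped"] = True
            continue
        in_paths, out_paths = _STAGES[name](ctx)
        elapsed = time.monotonic() - t0
        manifest["stages"][name] = {
            "inputs": {str(p): _sha256(Path(p)) for p in in_paths if Path(p).exists()},
            "outputs": [str(p) for p in out_paths],
            "elapsed_s": round(elapsed, 3),
            "skipped": False,
        }
        missing = [p for p in out_paths if not Path(p).exists()]
        if missing:
            raise PipelineError(name, f"declared outputs missing: {missing}")
    manifest["outputs"] = sorted(
        {p for s in manifest["stages"].values() for p in s.get("outputs", [])}
    )
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stage_inputs_probe(ctx: RunContext, name: str) -> tuple[list[Path], list[Path]]:
    """Input paths a stage would hash, without running it."""
    cfg_inputs = ctx.inputs
    if name == "annotate":
        return [Path(cfg_inputs["rmsk"])], []
    if name == "catalogue":
        paths = []
        if cfg_inputs.get("tf_whitelist"):
            paths.append(Path(cfg_inputs["tf_whitelist"]))
        for cell, sources in ctx.cell_lines.items():
            paths.extend(Path(p) for p in sources.values())
        return paths, []
    if name == "scan":
        paths = [Path(cfg_inputs["genome_fasta"]), ctx.path("full_length.tsv")]
        if cfg_inputs.get("motifs"):
            paths.append(Path(cfg_inputs["motifs"]["path"]))
        return paths, []
    if name == "profile":
        return [
            ctx.path("elements.tsv"),
            ctx.path("full_length.tsv"),
            ctx.path(f"catalogue_{ctx.primary_cell}.tsv"),
        ], []
    if name == "cluster":
        return [ctx.path("binding_frequency.tsv")], []
    if name == "coloc":
        return [ctx.path("elements.tsv"), ctx.path(f"catalogue_{ctx.primary_cell}.tsv")], []
    if name == "diff":
        cells = list(ctx.cell_lines)
        return [ctx.path("elements.tsv")] + [
            ctx.path(f"catalogue_{c}.tsv") for c in cells[:2]
        ], []
    raise ValueError(name)
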