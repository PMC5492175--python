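"""Stage orchestration: simulate -> preprocess -> dedup -> classify ->
junctions -> coverage -> enrich -> features -> metagene, driven by one
configuration, with a machine-readable run report.

Every stage reads its inputs from, and writes its outputs to, a fixed layout
under the output directory, so stages can be run one at a time (resuming
from prior outputs) or end-to-end via :func:`run_pipeline`; both routes
produce identical files for the same config and seed.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import AnnotatedGenome
from .config import PipelineConfig, SampleConfig
from .coverage import (
    Replicate,
    average_replicates,
    build_coverage,
    count_reads_per_feature,
    enrichment_track,
    feature_stats,
    normalize_rpm,
    scatter_table,
    write_bedgraph,
    CoverageTrack,
)
from .genomic import (
    FeatureIndex,
    JunctionCounts,
    LoadStats,
    classify_reads,
    count_junctions,
    deduplicate,
    load_alignments,
    splice_ratio,
    write_sam,
)
from .metagene import (
    anchored_matrix,
    expression_match,
    heatmap_export,
    metagene_profile,
    relative_metagene,
    signal_over_first_nt,
)
from .preprocess import TrimPolicy, demultiplex, preprocess_sample, read_fastq, write_fastq
from .synthetic import (
    BindingModel,
    LibrarySpec,
    SimulatedLibrary,
    SyntheticGenomeSpec,
    emit_truth_alignments,
    generate_genome,
    simulate_library,
)


def sample_seed(global_seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from the global seed (< 2^31)."""
    return (global_seed * 100_003 + 7919 * (index + 1)) % (2**31 - 1)


def _log(events: list[dict], outdir: Path, stage: str, **fields) -> None:
    event = {"stage": stage, **fields}
    events.append(event)
    print(f"[cracflow] {stage}: " + ", ".join(f"{k}={v}" for k, v in fields.items()),
          file=sys.stderr)
    with open(outdir / "events.jsonl", "a") as fh:
        fh.write(json.dumps(event) + "\n")


class Workspace:
    """File layout of one pipeline run."""

    def __init__(self, outdir: str | Path):
        self.root = Path(outdir)

    def path(self, *parts: str) -> Path:
        p = self.root.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    # canonical locations
    @property
    def genome_fasta(self): return self.path("genome.fasta")
    @property
    def annotation_gff3(self): return self.path("annotation.gff3")
    @property
    def fastq(self): return self.path("reads.fastq")
    def truth_tsv(self, s): return self.path("truth", f"{s}.truth.tsv")
    def truth_sam(self, s): return self.path("truth", f"{s}.sam")
    def collapsed_fastq(self, s): return self.path("preprocess", f"{s}.collapsed.fastq")
    def dedup_sam(self, s): return self.path("dedup", f"{s}.dedup.sam")


def _binding_model(sample: SampleConfig, genome: AnnotatedGenome) -> BindingModel:
    model = BindingModel(kind=sample.model, spliced_fraction=sample.spliced_fraction)
    if sample.weight_overrides:
        weights = model.resolved_weights(genome)
        for fid, factor in sample.weight_overrides.items():
            weights[fid] = weights.get(fid, 1.0) * factor
        model.weights = weights
    return model


def _library_spec(sample: SampleConfig, cfg: PipelineConfig, index: int) -> LibrarySpec:
    background = 1.0 if sample.role == "background" else sample.background_fraction
    return LibrarySpec(
        name=sample.name,
        barcode=sample.barcode,
        n_molecules=sample.n_molecules,
        tag_length=cfg.params.tag_length,
        adapter=cfg.params.adapter,
        dup_geom_p=sample.dup_geom_p,
        background_fraction=background,
        low_complexity_fraction=sample.low_complexity_fraction,
        seed=sample_seed(cfg.seed, index),
    )


def _load_genome(cfg: PipelineConfig, ws: Workspace) -> AnnotatedGenome:
    if cfg.simulate is not None:
        return AnnotatedGenome.load(ws.genome_fasta, ws.annotation_gff3)
    return AnnotatedGenome.load(cfg.paths.genome, cfg.paths.annotation)


def _alignment_path(cfg: PipelineConfig, ws: Workspace, sample: str) -> Path:
    if cfg.simulate is not None:
        return ws.truth_sam(sample)
    return Path(cfg.paths.alignments[sample])


# ------------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, ws: Workspace, events: list) -> None:
    if cfg.simulate is None:
        raise ValueError("config has no simulate section")
    gspec = SyntheticGenomeSpec(
        chrom_lengths=dict(cfg.simulate.chrom_lengths),
        gap_range=tuple(cfg.simulate.gap_range),
        seed=cfg.seed,
    )
    if cfg.simulate.class_counts:
        gspec.class_counts = dict(cfg.simulate.class_counts)
    genome = generate_genome(gspec)
    genome.write_fasta(ws.genome_fasta)
    genome.write_gff3(ws.annotation_gff3)
    n_reads = 0
    with open(ws.fastq, "w") as fh:
        for i, sample in enumerate(cfg.samples):
            sim = simulate_library(
                genome,
                _binding_model(sample, genome),
                _library_spec(sample, cfg, i),
                junction_overhang=cfg.params.min_overhang,
            )
            sim.write_truth(ws.truth_tsv(sample.name))
            emit_truth_alignments(sim, genome, ws.truth_sam(sample.name))
            for rid, seq, qual in sim.iter_reads():
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
                n_reads += 1
            _log(events, ws.root, "simulate", sample=sample.name,
                 molecules=sim.totals["molecules"], emitted=sim.totals["emitted_reads"])
    _log(events, ws.root, "simulate", features=len(genome.features), reads=n_reads)


def stage_preprocess(cfg: PipelineConfig, ws: Workspace, events: list) -> pd.DataFrame:
    fastq = ws.fastq if cfg.simulate is not None else Path(cfg.paths.fastq)
    policy = TrimPolicy(
        adapter=cfg.params.adapter,
        max_uncalled=cfg.params.max_uncalled,
        quality_threshold=cfg.params.quality_threshold,
        min_length=cfg.params.min_length,
        min_overlap=cfg.params.min_overlap,
    )
    res = demultiplex(
        read_fastq(fastq),
        {s.name: s.barcode for s in cfg.samples},
        tag_length=cfg.params.tag_length,
        max_mismatch=cfg.params.barcode_mismatch,
    )
    rows = []
    for sample in cfg.samples:
        collapsed, summary = preprocess_sample(
            res.by_sample[sample.name], sample.name, policy,
            lowcomp_before_collapse=cfg.params.lowcomp_before_collapse,
        )
        write_fastq(collapsed, ws.collapsed_fastq(sample.name))
        rows.append(vars(summary) | {"conserves": summary.conserves()})
        _log(events, ws.root, "preprocess", **vars(summary))
    df = pd.DataFrame(rows)
    df.insert(1, "input_total", res.counts["input"])
    df.insert(2, "unassigned", len(res.unassigned))
    df.to_csv(ws.path("preprocess", "summary.tsv"), sep="\t", index=False)
    return df


def stage_dedup(cfg: PipelineConfig, ws: Workspace, events: list) -> pd.DataFrame:
    genome = _load_genome(cfg, ws)
    rows = []
    for sample in cfg.samples:
        stats = LoadStats()
        segments = list(load_alignments(_alignment_path(cfg, ws, sample.name), stats=stats))
        unique = deduplicate(segments)
        write_sam(unique, genome, ws.dedup_sam(sample.name))
        rows.append({
            "sample": sample.name,
            "primary": stats.primary,
            "skipped_unmapped": stats.skipped_unmapped,
            "skipped_secondary": stats.skipped_secondary,
            "skipped_supplementary": stats.skipped_supplementary,
            "unique": len(unique),
        })
        _log(events, ws.root, "dedup", sample=sample.name,
             input=len(segments), unique=len(unique))
    df = pd.DataFrame(rows)
    df.to_csv(ws.path("dedup", "summary.tsv"), sep="\t", index=False)
    return df


def _dedup_segments(cfg, ws, sample: str):
    return list(load_alignments(ws.dedup_sam(sample)))


def stage_classify(cfg: PipelineConfig, ws: Workspace, events: list) -> pd.DataFrame:
    genome = _load_genome(cfg, ws)
    index = FeatureIndex(genome)
    rows = []
    for sample in cfg.samples:
        segments = _dedup_segments(cfg, ws, sample.name)
        cls = classify_reads(segments, genome, index=index)
        counts = count_reads_per_feature(cls.feature_ids)
        pd.Series(counts, name="reads").rename_axis("feature_id").to_csv(
            ws.path("classify", f"{sample.name}.feature_counts.tsv"), sep="\t"
        )
        rows.append({"sample": sample.name, "total": len(segments), **cls.class_counts})
        _log(events, ws.root, "classify", sample=sample.name, total=len(segments))
    df = pd.DataFrame(rows).fillna(0)
    num = df.columns.difference(["sample"])
    df[num] = df[num].astype(int)
    df.to_csv(ws.path("classify", "class_counts.tsv"), sep="\t", index=False)
    return df


def stage_junctions(cfg: PipelineConfig, ws: Workspace, events: list) -> pd.DataFrame:
    genome = _load_genome(cfg, ws)
    per_sample: dict[str, JunctionCounts] = {}
    rows = []
    for sample in cfg.samples:
        segments = _dedup_segments(cfg, ws, sample.name)
        jc, _ = count_junctions(segments, genome, min_overhang=cfg.params.min_overhang)
        per_sample[sample.name] = jc
        rows.append({"sample": sample.name, "EE": jc.ee, "EI": jc.ei, "IE": jc.ie,
                     "min_overhang": jc.min_overhang})
    pd.DataFrame(rows).to_csv(ws.path("junctions", "junctions.tsv"), sep="\t", index=False)
    ratio_rows = []
    for group, members in cfg.groups().items():
        reps = [per_sample[s.name] for s in members]
        mean, sd, ratios = splice_ratio(reps)
        ratio_rows.append({
            "group": group, "n_replicates": len(reps),
            "ratio_mean": mean, "ratio_sd": sd,
            "ratios": ",".join(f"{r:.6g}" for r in ratios),
        })
        _log(events, ws.root, "junctions", group=group, ratio=round(mean, 4))
    df = pd.DataFrame(ratio_rows)
    df.to_csv(ws.path("junctions", "splice_ratios.tsv"), sep="\t", index=False)
    return df


def stage_coverage(cfg: PipelineConfig, ws: Workspace, events: list) -> pd.DataFrame:
    genome = _load_genome(cfg, ws)
    rows = []
    group_tracks: dict[str, list] = {}
    for sample in cfg.samples:
        segments = _dedup_segments(cfg, ws, sample.name)
        raw, stats = build_coverage(
            segments, genome,
            exclusion_classes=cfg.params.exclusion_classes, sample=sample.name,
        )
        rpm = normalize_rpm(raw)
        write_bedgraph(rpm, ws.path("coverage", f"{sample.name}.rpm"))
        group_tracks.setdefault(sample.group, []).append(rpm)
        rows.append({"sample": sample.name, "group": sample.group,
                     "included": stats.included, "excluded": stats.excluded,
                     "library_size": raw.library_size})
        _log(events, ws.root, "coverage", sample=sample.name,
             included=stats.included, excluded=stats.excluded)
    for group, tracks in group_tracks.items():
        mean = average_replicates(tracks)
        write_bedgraph(mean, ws.path("coverage", f"{group}.mean.rpm"))
    df = pd.DataFrame(rows)
    df.to_csv(ws.path("coverage", "library_sizes.tsv"), sep="\t", index=False)
    return df


def _group_mean_track(cfg, ws, genome, group: str) -> CoverageTrack:
    members = [s for s in cfg.samples if s.group == group]
    tracks = []
    for s in members:
        raw, _ = build_coverage(
            _dedup_segments(cfg, ws, s.name), genome,
            exclusion_classes=cfg.params.exclusion_classes, sample=s.name,
        )
        tracks.append(normalize_rpm(raw))
    return average_replicates(tracks)


def stage_enrich(cfg: PipelineConfig, ws: Workspace, events: list) -> None:
    genome = _load_genome(cfg, ws)
    ref = _group_mean_track(cfg, ws, genome, cfg.reference_group)
    for group in cfg.groups("protein"):
        num = _group_mean_track(cfg, ws, genome, group)
        enr = enrichment_track(num, ref, pseudocount=cfg.params.pseudocount)
        write_bedgraph(enr, ws.path("enrich", f"{group}.log2"))
        _log(events, ws.root, "enrich", group=group, reference=cfg.reference_group)


def _group_replicates(cfg, ws, genome, index, group: str) -> list[Replicate]:
    reps = []
    for s in (x for x in cfg.samples if x.group == group):
        segments = _dedup_segments(cfg, ws, s.name)
        raw, _ = build_coverage(
            segments, genome, exclusion_classes=cfg.params.exclusion_classes,
            sample=s.name,
        )
        cls = classify_reads(segments, genome, index=index)
        reps.append(Replicate(
            sample=s.name,
            track=normalize_rpm(raw),
            feature_counts=count_reads_per_feature(cls.feature_ids),
        ))
    return reps


def stage_features(cfg: PipelineConfig, ws: Workspace, events: list) -> dict[str, pd.DataFrame]:
    genome = _load_genome(cfg, ws)
    index = FeatureIndex(genome)
    out: dict[str, pd.DataFrame] = {}
    ref_stats = feature_stats(
        _group_replicates(cfg, ws, genome, index, cfg.reference_group), genome,
        cv_max=cfg.params.cv_max, rpkm_min=cfg.params.rpkm_min,
    )
    ref_stats.to_csv(ws.path("features", f"{cfg.reference_group}.features.tsv"), sep="\t")
    out[cfg.reference_group] = ref_stats
    for group in cfg.groups("protein"):
        stats = feature_stats(
            _group_replicates(cfg, ws, genome, index, group), genome,
            cv_max=cfg.params.cv_max, rpkm_min=cfg.params.rpkm_min,
        )
        stats.to_csv(ws.path("features", f"{group}.features.tsv"), sep="\t")
        scatter = scatter_table(stats, ref_stats, pseudocount=cfg.params.pseudocount)
        scatter.to_csv(ws.path("features", f"{group}.scatter.tsv"), sep="\t")
        out[group] = stats
        _log(events, ws.root, "features", group=group,
             selected=int(stats["selected"].sum()), total=len(stats))
    return out


def stage_metagene(cfg: PipelineConfig, ws: Workspace, events: list) -> None:
    genome = _load_genome(cfg, ws)
    feats = genome.features_of_class(*cfg.params.metagene_classes)
    ref = _group_mean_track(cfg, ws, genome, cfg.reference_group)
    for group in cfg.groups("protein"):
        track = _group_mean_track(cfg, ws, genome, group)
        for anchor, window in (("tss", cfg.params.tss_window), ("pa", cfg.params.pa_window)):
            mat = anchored_matrix(track, feats, anchor=anchor, window=tuple(window),
                                  flank=cfg.params.flank)
            metagene_profile(mat, "sum").to_csv(
                ws.path("metagene", f"{group}.{anchor}_profile.tsv"), sep="\t")
            if anchor == "tss":
                heatmap_export(mat, ws.path("metagene", f"{group}.tss_matrix.tsv"))
        rel = relative_metagene(track, ref, feats, anchor="tss",
                                window=tuple(cfg.params.tss_window),
                                pseudocount=cfg.params.pseudocount,
                                flank=cfg.params.flank)
        rel.to_csv(ws.path("metagene", f"{group}.tss_relative.tsv"), sep="\t")
        _log(events, ws.root, "metagene", group=group,
             abs_argmax=int(metagene_profile(anchored_matrix(
                 track, feats, "tss", tuple(cfg.params.tss_window)), "sum").idxmax()))
    signals = {
        cls: signal_over_first_nt(ref, genome.features_of_class(cls), cfg.params.match_window)
        for cls in cfg.params.match_classes
    }
    matched = expression_match(signals, tolerance=cfg.params.match_tolerance)
    matched.to_csv(ws.path("metagene", "matched_subsets.tsv"), sep="\t", index=False)
    _log(events, ws.root, "metagene", matched_groups=len(matched))


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "dedup": stage_dedup,
    "classify": stage_classify,
    "junctions": stage_junctions,
    "coverage": stage_coverage,
    "enrich": stage_enrich,
    "features": stage_features,
    "metagene": stage_metagene,
}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order and write ``report.json``."""
    ws = Workspace(outdir)
    ws.root.mkdir(parents=True, exist_ok=True)
    (ws.root / "events.jsonl").write_text("")
    events: list[dict] = []
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    order = list(STAGES) if cfg.simulate is not None else list(STAGES)[1:]
    for name in order:
        t0 = time.perf_counter()
        STAGES[name](cfg, ws, events)
        report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
    report["params"] = cfg.params.model_dump()
    report["samples"] = [s.model_dump() for s in cfg.samples]
    with open(ws.root / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
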