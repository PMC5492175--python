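"""Strand-specific coverage tracks, RPM normalization with Pol I/III and
mitochondrial exclusion, replicate averaging, pseudocounted log2 enrichment,
and per-feature reproducibility/abundance statistics.

Coverage counts deduplicated segments: each included segment adds 1 to every
base of every aligned block on its strand.  The library size used for RPM is
the number of included segments (reads mapping to rRNA/tRNA/other PolIII
transcripts or to the mitochondrial genome contribute to neither the track
nor the library size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    DEFAULT_EXCLUSION_CLASSES,
    DEFAULT_MITO_CHROMS,
    AnnotatedGenome,
    Feature,
)
from .genomic import AlignedSegment

STRANDS = ("+", "-")


@dataclass
class CoverageTrack:
    """Per-base, per-strand signal with an explicit normalization state."""

    data: dict[tuple[str, str], np.ndarray]  # (chrom, strand) -> float array
    normalization: str = "raw"  # "raw" | "rpm"
    library_size: int = 0
    samples: tuple[str, ...] = ()

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)]

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    @classmethod
    def zeros(cls, chrom_lengths: Mapping[str, int], **kw) -> "CoverageTrack":
        data = {
            (c, s): np.zeros(n, dtype=np.float64)
            for c, n in chrom_lengths.items()
            for s in STRANDS
        }
        return cls(data=data, **kw)


@dataclass
class EnrichmentTrack:
    """Per-base log2((a + c) / (b + c)) between two RPM tracks."""

    data: dict[tuple[str, str], np.ndarray]
    pseudocount: float = 5.0
    numerator: tuple[str, ...] = ()
    denominator: tuple[str, ...] = ()

    def get(self, chrom: str, strand: str) -> np.ndarray:
        return self.data[(chrom, strand)]


@dataclass
class CoverageStats:
    included: int = 0
    excluded: int = 0


def _exclusion_prefix(
    genome: AnnotatedGenome,
    exclusion_classes: Sequence[str],
    mito_chroms: Sequence[str],
) -> dict[tuple[str, str], np.ndarray]:
    """Cumulative-sum mask of excluded-feature spans per (chrom, strand)."""
    want = set(exclusion_classes)
    marks = {
        (c, s): np.zeros(n + 1, dtype=np.int32)
        for c, n in genome.chrom_lengths.items()
        for s in STRANDS
    }
    for f in genome.features:
        if f.cls in want:
            m = marks[(f.chrom, f.strand)]
            m[f.start] += 1
            m[f.end] -= 1
    out = {}
    for key, m in marks.items():
        covered = np.cumsum(m[:-1]) > 0  # per-base excluded flag
        out[key] = np.concatenate(([0], np.cumsum(covered)))
    return out


def build_coverage(
    segments: Iterable[AlignedSegment],
    genome: AnnotatedGenome,
    exclusion_classes: Sequence[str] = DEFAULT_EXCLUSION_CLASSES,
    mito_chroms: Sequence[str] = DEFAULT_MITO_CHROMS,
    sample: str = "",
) -> tuple[CoverageTrack, CoverageStats]:
    """Accumulate raw per-base coverage from deduplicated segments.

    A segment is excluded when any of its blocks overlaps (sense) a feature
    of an exclusion class, or when it maps to a mitochondrial chromosome.
    """
    track = CoverageTrack.zeros(genome.chrom_lengths, samples=(sample,) if sample else ())
    prefix = _exclusion_prefix(genome, exclusion_classes, mito_chroms)
    mito = set(mito_chroms)
    stats = CoverageStats()
    for seg in segments:
        if (seg.chrom, seg.strand) not in track.data:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        if seg.chrom in mito:
            stats.excluded += 1
            continue
        pre = prefix[(seg.chrom, seg.strand)]
        if any(pre[e] - pre[s] > 0 for s, e in seg.blocks):
            stats.excluded += 1
            continue
        arr = track.data[(seg.chrom, seg.strand)]
        for s, e in seg.blocks:
            arr[s:e] += 1.0
        stats.included += 1
    track.library_size = stats.included
    return track, stats


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Scale every base by 1e6 / library size; marks the track as RPM."""
    if track.normalization == "rpm":
        raise ValueError("track is already RPM-normalized")
    if track.library_size <= 0:
        raise ValueError("cannot RPM-normalize with library size 0")
    scale = 1e6 / track.library_size
    return CoverageTrack(
        data={k: v * scale for k, v in track.data.items()},
        normalization="rpm",
        library_size=track.library_size,
        samples=track.samples,
    )


def average_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-base arithmetic mean of RPM replicate tracks."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if set(t.data) != set(first.data) or any(
            t.data[k].shape != first.data[k].shape for k in first.data
        ):
            raise ValueError("replicate tracks cover different genomes")
        if t.normalization != first.normalization:
            raise ValueError("mixing raw and RPM tracks")
    data = {
        k: np.mean([t.data[k] for t in tracks], axis=0) for k in first.data
    }
    return CoverageTrack(
        data=data,
        normalization=first.normalization,
        library_size=0,
        samples=tuple(s for t in tracks for s in t.samples),
    )


def enrichment_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    pseudocount: float = 5.0,
) -> EnrichmentTrack:
    """log2((numerator + c) / (denominator + c)) per base, finite everywhere."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    for t in (numerator, denominator):
        if t.normalization != "rpm":
            raise ValueError("enrichment requires RPM-normalized tracks")
    if set(numerator.data) != set(denominator.data):
        raise ValueError("tracks cover different genomes")
    data = {
        k: np.log2((numerator.data[k] + pseudocount) / (denominator.data[k] + pseudocount))
        for k in numerator.data
    }
    return EnrichmentTrack(
        data=data,
        pseudocount=pseudocount,
        numerator=numerator.samples,
        denominator=denominator.samples,
    )


# ----------------------------------------------------------------- bedGraph


def write_bedgraph(track: CoverageTrack | EnrichmentTrack, prefix: str | Path) -> None:
    """Write ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph`` (0-based)."""
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{suffix}.bedgraph", "w") as fh:
            for (chrom, s), arr in sorted(track.data.items()):
                if s != strand:
                    continue
                for start, end, value in _runs(arr):
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def _runs(arr: np.ndarray):
    """(start, end, value) runs of equal value, zero runs skipped."""
    if len(arr) == 0:
        return
    change = np.nonzero(np.diff(arr))[0] + 1
    bounds = np.concatenate(([0], change, [len(arr)]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = arr[s]
        if v != 0:
            yield int(s), int(e), float(v)


# ------------------------------------------------------------ feature stats


def feature_totals(track: CoverageTrack | EnrichmentTrack, feature: Feature) -> float:
    """Sum of the track over the feature's exonic bases on its strand."""
    arr = track.data[(feature.chrom, feature.strand)]
    return float(sum(arr[s:e].sum() for s, e in feature.exons))


@dataclass
class Replicate:
    """One replicate's inputs to feature statistics."""

    sample: str
    track: CoverageTrack  # RPM-normalized
    feature_counts: Mapping[str, int]  # reads assigned per feature id

    def __post_init__(self) -> None:
        if self.track.normalization != "rpm":
            raise ValueError("feature statistics need RPM tracks")


def count_reads_per_feature(
    feature_ids: Sequence[str | None],
) -> dict[str, int]:
    """Tally the per-read feature assignments from ``classify_reads``."""
    counts: dict[str, int] = {}
    for fid in feature_ids:
        if fid is not None:
            counts[fid] = counts.get(fid, 0) + 1
    return counts


def feature_stats(
    replicates: Sequence[Replicate],
    genome: AnnotatedGenome,
    cv_max: float = 0.5,
    rpkm_min: float = 30.0,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature reproducibility (CV) and abundance (RPKM) table.

    CV is the sample standard deviation (ddof=1) over replicate exonic
    coverage totals divided by their mean; RPKM is the mean over replicates
    of reads-per-kilobase-per-million from the per-replicate assigned read
    counts and included library sizes.  ``selected`` requires CV < cv_max
    and RPKM > rpkm_min (both strict).
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates for a coefficient of variation")
    feats = genome.features if classes is None else genome.features_of_class(*classes)
    rows = []
    for f in feats:
        length = f.exonic_length
        if length <= 0:
            raise ValueError(f"zero-length feature {f.feature_id}")
        totals = [feature_totals(r.track, f) for r in replicates]
        mean = float(np.mean(totals))
        sd = float(np.std(totals, ddof=1))
        cv = sd / mean if mean > 0 else math.inf
        rpkms = [
            r.feature_counts.get(f.feature_id, 0) * 1e9 / (r.track.library_size * length)
            for r in replicates
        ]
        rpkm = float(np.mean(rpkms))
        row = {
            "feature_id": f.feature_id,
            "cls": f.cls,
            "length": length,
            **{f"total_{r.sample or i}": t for i, (r, t) in enumerate(zip(replicates, totals))},
            "mean_total": mean,
            "cv": cv,
            "rpkm": rpkm,
            "passes_cv": cv < cv_max,
            "passes_rpkm": rpkm > rpkm_min,
        }
        row["selected"] = row["passes_cv"] and row["passes_rpkm"]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("feature_id")
    df.attrs["cv_max"] = cv_max
    df.attrs["rpkm_min"] = rpkm_min
    df.attrs["cv_ddof"] = 1
    return df


def scatter_table(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    pseudocount: float = 5.0,
) -> pd.DataFrame:
    """Feature-level comparison of factor A to reference B.

    Rows are the features *selected* in A; columns carry both mean coverage
    totals and their pseudocounted log2 enrichment.  Raises if B is missing
    any selected feature.
    """
    sel = stats_a[stats_a["selected"]]
    missing = sel.index.difference(stats_b.index)
    if len(missing):
        raise ValueError(f"features absent from reference stats: {list(missing)}")
    b = stats_b.loc[sel.index]
    out = pd.DataFrame(
        {
            "cls": sel["cls"],
            "coverage_a": sel["mean_total"],
            "coverage_b": b["mean_total"],
        },
        index=sel.index,
    )
    out["log2_enrichment"] = np.log2(
        (out["coverage_a"] + pseudocount) / (out["coverage_b"] + pseudocount)
    )
    return out
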