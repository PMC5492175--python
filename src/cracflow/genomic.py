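"""Alignment ingest, random-tag genomic deduplication, transcript-class
assignment and spliced/unspliced junction statistics.

All coordinates are 0-based half-open; the 5' genomic coordinate of a
segment is the leftmost block start on the + strand and the rightmost block
end − 1 on the − strand, matching how a cross-link maps to the read 5' end.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .annotation import AnnotatedGenome, Feature

_TAG_RE = re.compile(r"#TAG:(?P<tag>[ACGTN]*)(?:#N:(?P<mult>\d+))?$")

#: hierarchical class assignment order; earlier wins
DEFAULT_CLASS_PRIORITY = (
    "rRNA",
    "tRNA",
    "other-PolIII",
    "snoRNA",
    "snRNA",
    "mRNA",
    "SUT",
    "CUT",
    "XUT",
    "Ty",
    "IGS",
)

#: feature classes whose opposite-strand reads are labelled antisense
DEFAULT_ANTISENSE_CLASSES = frozenset({"mRNA"})


@dataclass(frozen=True)
class AlignedSegment:
    """A stranded placement with one or more aligned blocks.

    ``blocks`` are ascending, non-overlapping 0-based half-open intervals;
    an N-gap in the alignment separates consecutive blocks.
    """

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    tag: str = ""
    multiplicity: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("segment needs at least one block")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if not s1 < e1 <= s2 < e2:
                raise ValueError(f"blocks unsorted/overlapping: {self.blocks}")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read 5' end (cross-link proxy)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


# --------------------------------------------------------------------- load


_REF_CONSUMING_IN_BLOCK = {0, 2, 7, 8}  # M, D, =, X extend the current block


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    blocks: list[tuple[int, int]] = []
    cur = pos
    start = pos
    for op, length in cigartuples:
        if op in _REF_CONSUMING_IN_BLOCK:
            cur += length
        elif op == 3:  # N gap: close block
            if cur > start:
                blocks.append((start, cur))
            cur += length
            start = cur
    if cur > start:
        blocks.append((start, cur))
    return tuple(blocks)


@dataclass
class LoadStats:
    primary: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0
    skipped_unmapped: int = 0


def load_alignments(
    path: str | Path,
    require_tags: bool = True,
    stats: LoadStats | None = None,
) -> Iterator[AlignedSegment]:
    """Stream primary alignments from SAM/BAM as :class:`AlignedSegment`.

    The random tag is taken from the read-name suffix ``#TAG:...`` or a
    ``RX`` tag field.  With ``require_tags`` (default) a record without one
    is an error; pass ``False`` to run tag-less (deduplication is then
    meaningless and should be skipped).
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                if stats:
                    stats.skipped_unmapped += 1
                continue
            if rec.is_secondary:
                if stats:
                    stats.skipped_secondary += 1
                continue
            if rec.is_supplementary:
                if stats:
                    stats.skipped_supplementary += 1
                continue
            name = rec.query_name or ""
            tag, mult = "", 1
            m = _TAG_RE.search(name)
            if m:
                tag = m.group("tag")
                mult = int(m.group("mult") or 1)
                name = name[: m.start()]
            elif rec.has_tag("RX"):
                tag = str(rec.get_tag("RX"))
            if not tag and require_tags:
                raise ValueError(f"alignment {name!r} carries no random tag")
            if stats:
                stats.primary += 1
            yield AlignedSegment(
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=_blocks_from_cigar(rec.reference_start, rec.cigartuples),
                tag=tag,
                multiplicity=mult,
                name=name,
            )


def write_sam(
    segments: Iterable[AlignedSegment],
    genome: AnnotatedGenome,
    path: str | Path,
) -> int:
    """Write segments as primary SAM records (tag kept in name and RX)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in genome.chrom_lengths.items()],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, seg in enumerate(segments):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = f"{seg.name or f'seg{i}'}#TAG:{seg.tag}#N:{seg.multiplicity}"
            rec.flag = 16 if seg.strand == "-" else 0
            rec.reference_name = seg.chrom
            rec.reference_start = seg.start
            rec.mapping_quality = 255
            cig = ""
            for k, (s, e) in enumerate(seg.blocks):
                if k:
                    cig += f"{s - seg.blocks[k - 1][1]}N"
                cig += f"{e - s}M"
            rec.cigarstring = cig
            seq = "".join(genome.sequences[seg.chrom][s:e] for s, e in seg.blocks)
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            rec.set_tag("RX", seg.tag)
            fh.write(rec)
            n += 1
    return n


# -------------------------------------------------------------------- dedup


def deduplicate(segments: Iterable[AlignedSegment]) -> list[AlignedSegment]:
    """Collapse reads sharing (random tag, chromosome, strand, 5' coordinate).

    Keeps the first-seen representative in input order; idempotent.
    """
    seen: set[tuple[str, str, str, int]] = set()
    out: list[AlignedSegment] = []
    for seg in segments:
        key = (seg.tag, seg.chrom, seg.strand, seg.five_prime)
        if key not in seen:
            seen.add(key)
            out.append(seg)
    return out


# ----------------------------------------------------------- classification


class FeatureIndex:
    """Stranded interval index over feature spans for overlap queries."""

    def __init__(self, genome: AnnotatedGenome) -> None:
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for f in genome.features:
            tree = self.trees.setdefault((f.chrom, f.strand), IntervalTree())
            tree[f.start:f.end] = f

    def overlapping(self, seg: AlignedSegment, strand: str) -> list[Feature]:
        tree = self.trees.get((seg.chrom, strand))
        if tree is None:
            return []
        hits: dict[str, Feature] = {}
        for s, e in seg.blocks:
            for iv in tree.overlap(s, e):
                hits[iv.data.feature_id] = iv.data
        return list(hits.values())


@dataclass
class ClassifiedReads:
    labels: list[str]
    feature_ids: list[str | None]
    class_counts: Counter


def classify_reads(
    segments: Sequence[AlignedSegment],
    genome: AnnotatedGenome,
    priority: Sequence[str] = DEFAULT_CLASS_PRIORITY,
    antisense_classes: frozenset[str] = DEFAULT_ANTISENSE_CLASSES,
    index: FeatureIndex | None = None,
) -> ClassifiedReads:
    """Assign each read one transcript class by hierarchical sense overlap.

    A read takes the highest-priority class among same-strand features
    overlapping any of its blocks by >= 1 nt.  With no sense overlap it is
    ``antisense`` when an opposite-strand feature of an eligible class
    overlaps, else ``intergenic``.  Ties within a class go to the feature
    with the lexicographically smallest id.
    """
    if len(set(priority)) != len(priority):
        raise ValueError("priority classes must be unique")
    rank = {cls: i for i, cls in enumerate(priority)}
    unknown = {f.cls for f in genome.features} - set(priority)
    if unknown:
        raise ValueError(f"annotation classes missing from priority: {sorted(unknown)}")
    index = index or FeatureIndex(genome)
    labels: list[str] = []
    fids: list[str | None] = []
    counts: Counter = Counter()
    for seg in segments:
        sense = index.overlapping(seg, seg.strand)
        if sense:
            best = min(sense, key=lambda f: (rank[f.cls], f.feature_id))
            labels.append(best.cls)
            fids.append(best.feature_id)
        else:
            anti_strand = "-" if seg.strand == "+" else "+"
            anti = [
                f for f in index.overlapping(seg, anti_strand)
                if f.cls in antisense_classes
            ]
            labels.append("antisense" if anti else "intergenic")
            fids.append(None)
        counts[labels[-1]] += 1
    return ClassifiedReads(labels=labels, feature_ids=fids, class_counts=counts)


# ---------------------------------------------------------------- junctions


@dataclass
class JunctionCounts:
    """Counts of junction-informative reads at annotated splice junctions."""

    ee: int = 0
    ei: int = 0
    ie: int = 0
    min_overhang: int = 3

    def __add__(self, other: "JunctionCounts") -> "JunctionCounts":
        if self.min_overhang != other.min_overhang:
            raise ValueError("mixing junction counts with different overhangs")
        return JunctionCounts(
            self.ee + other.ee, self.ei + other.ei, self.ie + other.ie, self.min_overhang
        )


def _intron_table(genome: AnnotatedGenome):
    by_loc: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for f in genome.features:
        for istart, iend in f.introns:
            by_loc.setdefault((f.chrom, f.strand), []).append((istart, iend, f.feature_id))
    for lst in by_loc.values():
        lst.sort()
    return by_loc


def count_junctions(
    segments: Iterable[AlignedSegment],
    genome: AnnotatedGenome,
    min_overhang: int = 3,
) -> tuple[JunctionCounts, dict[str, JunctionCounts]]:
    """Count exon-exon (spliced) and exon-intron / intron-exon (unspliced) reads.

    EE: a gapped segment whose consecutive blocks exactly flank an annotated
    intron, with >= ``min_overhang`` aligned nt on each side.  EI/IE: a
    contiguous (single-block) segment crossing the intron's 5'/3' boundary
    (transcript orientation) with >= ``min_overhang`` nt on each side.  A
    segment counts at most once per junction.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    introns = _intron_table(genome)
    total = JunctionCounts(min_overhang=min_overhang)
    per_gene: dict[str, JunctionCounts] = {}

    def bump(gene: str, kind: str) -> None:
        nonlocal total
        jc = per_gene.setdefault(gene, JunctionCounts(min_overhang=min_overhang))
        setattr(jc, kind, getattr(jc, kind) + 1)
        setattr(total, kind, getattr(total, kind) + 1)

    for seg in segments:
        candidates = introns.get((seg.chrom, seg.strand))
        if not candidates:
            continue
        if len(seg.blocks) > 1:
            for (s1, e1), (s2, e2) in zip(seg.blocks, seg.blocks[1:]):
                for istart, iend, gene in candidates:
                    if e1 == istart and s2 == iend:
                        if e1 - s1 >= min_overhang and e2 - s2 >= min_overhang:
                            bump(gene, "ee")
                        break
        else:
            gs, ge = seg.blocks[0]
            for istart, iend, gene in candidates:
                if istart >= ge:
                    break
                crosses_left = gs <= istart - min_overhang and ge >= istart + min_overhang
                crosses_right = gs <= iend - min_overhang and ge >= iend + min_overhang
                if seg.strand == "+":
                    if crosses_left:
                        bump(gene, "ei")
                    if crosses_right:
                        bump(gene, "ie")
                else:
                    if crosses_right:
                        bump(gene, "ei")
                    if crosses_left:
                        bump(gene, "ie")
    return total, per_gene


def splice_ratio(replicates: Sequence[JunctionCounts]) -> tuple[float, float, list[float]]:
    """EE/(EI+IE) per replicate; returns (mean, across-replicate SD, ratios).

    Replicates with EI+IE == 0 are undefined (NaN in the ratio list) and are
    excluded from the mean/SD.
    """
    ratios = [
        jc.ee / (jc.ei + jc.ie) if (jc.ei + jc.ie) > 0 else float("nan")
        for jc in replicates
    ]
    valid = [r for r in ratios if not np.isnan(r)]
    if not valid:
        return float("nan"), float("nan"), ratios
    mean = float(np.mean(valid))
    sd = float(np.std(valid, ddof=1)) if len(valid) > 1 else 0.0
    return mean, sd, ratios
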