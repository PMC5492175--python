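"""Pre-alignment read processing: demultiplexing on the 5' linker, 3' adapter
and quality trimming, identical-sequence collapse, low-complexity filtering.

The linker layout is ``[random tag][sample barcode][insert]``; the tag and
barcode are stripped from the stored sequence and recorded on the read.
Collapsed reads keep a multiplicity and round-trip through FASTQ with the
name encoding ``@id#TAG:ACG#N:5``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pysam

_NAME_RE = re.compile(r"#TAG:(?P<tag>[ACGTN]*)(?:#N:(?P<mult>\d+))?$")


@dataclass
class LinkeredRead:
    """A read with its extracted linker components."""

    read_id: str
    seq: str
    qual: str  # Phred+33 ASCII, same length as seq
    tag: str = ""
    barcode: str = ""
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"seq/qual length mismatch for {self.read_id}")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class TrimPolicy:
    """3' trimming contract: adapter clip, quality clip, length/N gates.

    Defaults mirror a standard CRAC trimming call (max 3 uncalled bases,
    Phred 30 3' quality cutoff, 17 nt minimum length, 3 nt minimum adapter
    overlap).
    """

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    max_uncalled: int = 3
    quality_threshold: int = 30
    min_length: int = 17
    min_overlap: int = 3
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if min(self.max_uncalled, self.quality_threshold, self.min_overlap) < 0:
            raise ValueError("thresholds must be non-negative")


# ------------------------------------------------------------------ FASTQ IO


def read_fastq(path: str | Path) -> Iterator[LinkeredRead]:
    """Read FASTQ records, decoding any ``#TAG:..#N:..`` name suffix."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            name = rec.name
            tag, mult = "", 1
            m = _NAME_RE.search(name)
            if m:
                tag = m.group("tag")
                mult = int(m.group("mult") or 1)
                name = name[: m.start()]
            yield LinkeredRead(name, rec.sequence, rec.quality or "I" * len(rec.sequence),
                               tag=tag, multiplicity=mult)


def write_fastq(reads: Iterable[LinkeredRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            suffix = f"#TAG:{r.tag}#N:{r.multiplicity}" if r.tag or r.multiplicity > 1 else ""
            fh.write(f"@{r.read_id}{suffix}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


# --------------------------------------------------------------- demultiplex


@dataclass
class DemuxResult:
    by_sample: dict[str, list[LinkeredRead]]
    unassigned: list[LinkeredRead]
    counts: Counter = field(default_factory=Counter)


def demultiplex(
    reads: Iterable[LinkeredRead],
    samples: dict[str, str],
    tag_length: int = 3,
    max_mismatch: int = 0,
) -> DemuxResult:
    """Split a multiplexed stream on the sample barcode that follows the tag.

    ``samples`` maps sample name -> barcode.  Matching is exact by default;
    with ``max_mismatch`` > 0 the nearest barcode wins and Hamming-distance
    ties go to unassigned.  Reads too short to contain the linker are
    unassigned (counted separately).
    """
    barcodes = list(samples.values())
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in sample map")
    if len({len(b) for b in barcodes}) != 1:
        raise ValueError("barcodes must be equal length")
    bc_len = len(barcodes[0])
    by_barcode = {bc: sample for sample, bc in samples.items()}

    res = DemuxResult(by_sample={s: [] for s in samples}, unassigned=[])
    header = tag_length + bc_len
    for read in reads:
        res.counts["input"] += 1
        if len(read.seq) < header:
            res.unassigned.append(read)
            res.counts["too_short"] += 1
            continue
        tag, bc = read.seq[:tag_length], read.seq[tag_length:header]
        sample = by_barcode.get(bc)
        if sample is None and max_mismatch > 0:
            dists = sorted((sum(a != b for a, b in zip(bc, cand)), cand) for cand in barcodes)
            if dists[0][0] <= max_mismatch and (
                len(dists) == 1 or dists[1][0] > dists[0][0]
            ):
                sample = by_barcode[dists[0][1]]
        if sample is None:
            res.unassigned.append(read)
            res.counts["unassigned"] += 1
            continue
        res.by_sample[sample].append(
            replace(read, seq=read.seq[header:], qual=read.qual[header:],
                    tag=tag, barcode=bc)
        )
        res.counts[f"assigned:{sample}"] += 1
        res.counts["assigned"] += 1
    return res


# -------------------------------------------------------------------- trim


def find_adapter(seq: str, adapter: str, min_overlap: int) -> int:
    """Start of the best (longest) read-suffix / adapter-prefix match, or len(seq)."""
    n = len(seq)
    for i in range(n - min_overlap + 1):
        if adapter.startswith(seq[i:]):
            return i
    return n


def trim_read(read: LinkeredRead, policy: TrimPolicy) -> tuple[LinkeredRead | None, str]:
    """Adapter-clip then 3' quality-clip one read.

    Returns ``(trimmed read, "kept")`` or ``(None, reason)`` where reason is
    ``"short"`` (below minimum length) or ``"uncalled"`` (too many N).
    """
    cut = find_adapter(read.seq, policy.adapter, policy.min_overlap)
    seq, qual = read.seq[:cut], read.qual[:cut]
    thr = policy.quality_threshold + policy.phred_offset
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) < thr:
        end -= 1
    seq, qual = seq[:end], qual[:end]
    if len(seq) < policy.min_length:
        return None, "short"
    if seq.count("N") > policy.max_uncalled:
        return None, "uncalled"
    return replace(read, seq=seq, qual=qual), "kept"


# ----------------------------------------------------------------- collapse


def collapse_identical(reads: Iterable[LinkeredRead]) -> list[LinkeredRead]:
    """Collapse PCR duplicates: one record per distinct (tag, sequence) pair.

    Multiplicities add; first-occurrence order is preserved.  Idempotent.
    """
    seen: dict[tuple[str, str], int] = {}
    out: list[LinkeredRead] = []
    for r in reads:
        key = (r.tag, r.seq)
        if key in seen:
            kept = out[seen[key]]
            kept.multiplicity += r.multiplicity
        else:
            seen[key] = len(out)
            out.append(replace(r))
    return out


# ------------------------------------------------------------- low complexity


def filter_low_complexity(read: LinkeredRead, max_fraction: float = 0.8) -> bool:
    """Keep unless one of A/C/G/T makes up strictly more than ``max_fraction``.

    N counts toward the length but never as the majority base.
    """
    if not read.seq:
        raise ValueError(f"empty sequence for {read.read_id}")
    top = max(read.seq.count(b) for b in "ACGT")
    return top / len(read.seq) <= max_fraction


# ----------------------------------------------------------- sample pipeline


@dataclass
class PreprocessSummary:
    sample: str
    assigned: int = 0
    trim_discarded_short: int = 0
    trim_discarded_uncalled: int = 0
    low_complexity_dropped: int = 0
    kept_reads: int = 0
    kept_unique: int = 0

    def conserves(self) -> bool:
        return (
            self.assigned
            == self.kept_reads
            + self.trim_discarded_short
            + self.trim_discarded_uncalled
            + self.low_complexity_dropped
        )


def preprocess_sample(
    reads: Iterable[LinkeredRead],
    sample: str,
    policy: TrimPolicy | None = None,
    lowcomp_before_collapse: bool = True,
) -> tuple[list[LinkeredRead], PreprocessSummary]:
    """Trim, low-complexity-filter and collapse one demultiplexed stream.

    The low-complexity filter runs after trimming and before collapse by
    default; set ``lowcomp_before_collapse=False`` to filter the collapsed
    records instead (the summary then counts multiplicities of dropped
    records).
    """
    policy = policy or TrimPolicy()
    summary = PreprocessSummary(sample=sample)
    surviving: list[LinkeredRead] = []
    for read in reads:
        summary.assigned += 1
        trimmed, reason = trim_read(read, policy)
        if trimmed is None:
            if reason == "short":
                summary.trim_discarded_short += 1
            else:
                summary.trim_discarded_uncalled += 1
            continue
        if lowcomp_before_collapse and not filter_low_complexity(trimmed):
            summary.low_complexity_dropped += 1
            continue
        surviving.append(trimmed)
    collapsed = collapse_identical(surviving)
    if not lowcomp_before_collapse:
        kept = []
        for r in collapsed:
            if filter_low_complexity(r):
                kept.append(r)
            else:
                summary.low_complexity_dropped += r.multiplicity
        collapsed = kept
    summary.kept_reads = sum(r.multiplicity for r in collapsed)
    summary.kept_unique = len(collapsed)
    return collapsed, summary
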