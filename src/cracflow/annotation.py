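"""Annotated genome model: sequences plus classed, stranded transcript features.

Coordinates are 0-based half-open internally.  GFF3 is written/read 1-based
inclusive (pyranges converts on load), SAM is 1-based on write, bedGraph is
0-based half-open.  The GFF3 ``type`` column carries the transcript class
(mRNA, SUT, CUT, XUT, snoRNA, snRNA, rRNA, tRNA, other-PolIII, Ty, IGS);
multi-exon features carry child ``exon`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: transcript classes the pipeline knows about
KNOWN_CLASSES = (
    "mRNA",
    "SUT",
    "CUT",
    "XUT",
    "snoRNA",
    "snRNA",
    "rRNA",
    "tRNA",
    "other-PolIII",
    "Ty",
    "IGS",
)

#: RNAPII transcript classes (the signal classes for CRAC factors)
POLII_CLASSES = ("mRNA", "SUT", "CUT", "XUT", "snoRNA", "snRNA", "Ty", "IGS")

#: classes excluded from coverage tracks and library-size normalization
DEFAULT_EXCLUSION_CLASSES = ("rRNA", "tRNA", "other-PolIII")

#: chromosome names treated as mitochondrial for coverage exclusion
DEFAULT_MITO_CHROMS = ("chrM", "chrMT", "Mito", "chrMito")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A stranded transcript feature with exon structure.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order; single-exon features have one exon spanning the whole feature.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cls: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.feature_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval for {self.feature_id}")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        ex = self.exons
        if ex[0][0] != self.start or ex[-1][1] != self.end:
            raise ValueError(f"exons do not span feature {self.feature_id}")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if not s1 < e1 <= s2 < e2:
                raise ValueError(f"exons unsorted/overlapping in {self.feature_id}")

    @property
    def length(self) -> int:
        """Genomic span in nt (introns included)."""
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def pa(self) -> int:
        """Genomic coordinate of the last transcribed base (pA site)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals in ascending genomic order."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    def genomic_position(self, t: int) -> int:
        """Genomic coordinate of transcript-orientation offset ``t`` from the TSS.

        Offsets are in unspliced (genomic-span) coordinates; negative offsets
        reach upstream of the TSS.
        """
        return self.start + t if self.strand == "+" else self.end - 1 - t


@dataclass
class AnnotatedGenome:
    """Genome sequences plus transcript annotation."""

    sequences: dict[str, str]
    features: list[Feature]
    by_id: dict[str, Feature] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.by_id = {}
        for f in self.features:
            if f.feature_id in self.by_id:
                raise ValueError(f"duplicate feature id {f.feature_id}")
            if f.chrom not in self.sequences:
                raise ValueError(f"feature {f.feature_id} on unknown chromosome {f.chrom}")
            if f.end > len(self.sequences[f.chrom]):
                raise ValueError(f"feature {f.feature_id} extends beyond {f.chrom}")
            self.by_id[f.feature_id] = f

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def features_of_class(self, *classes: str) -> list[Feature]:
        want = set(classes)
        return [f for f in self.features if f.cls in want]

    def transcript_sequence(self, feature_id: str, spliced: bool = True) -> str:
        """5'->3' transcript sequence, mature (exons joined) or unspliced."""
        f = self.by_id[feature_id]
        chrom = self.sequences[f.chrom]
        if spliced:
            seq = "".join(chrom[s:e] for s, e in f.exons)
        else:
            seq = chrom[f.start:f.end]
        return seq if f.strand == "+" else reverse_complement(seq)

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for f in self.features:
                attrs = f"ID={f.feature_id};Name={f.feature_id}"
                fh.write(
                    f"{f.chrom}\tcracflow\t{f.cls}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\t{attrs}\n"
                )
                if len(f.exons) > 1:
                    for s, e in f.exons:
                        fh.write(
                            f"{f.chrom}\tcracflow\texon\t{s + 1}\t{e}\t.\t"
                            f"{f.strand}\t.\tParent={f.feature_id}\n"
                        )

    @classmethod
    def load(cls, fasta: str | Path, gff3: str | Path) -> "AnnotatedGenome":
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        features = load_gff3_features(gff3)
        return cls(sequences=sequences, features=features)


def load_gff3_features(gff3: str | Path) -> list[Feature]:
    """Read classed features (with exon children) from a GFF3 file."""
    import pyranges

    df = pyranges.read_gff3(str(gff3)).df
    exon_rows = df[df.Feature == "exon"]
    exons_by_parent: dict[str, list[tuple[int, int]]] = {}
    for _, row in exon_rows.iterrows():
        exons_by_parent.setdefault(str(row.Parent), []).append(
            (int(row.Start), int(row.End))
        )
    features: list[Feature] = []
    for _, row in df[df.Feature != "exon"].iterrows():
        fid = str(row.ID)
        ex = tuple(sorted(exons_by_parent.get(fid, [])))
        features.append(
            Feature(
                feature_id=fid,
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=str(row.Strand),
                cls=str(row.Feature),
                exons=ex,
            )
        )
    return features
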