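"""Synthetic CRAC study generator: miniature annotated genome, cross-linking
read libraries with known binding profiles, and ground-truth tables.

The generator emulates a UV cross-linking experiment over a small yeast-like
genome: a 5'-peaked factor ("Set1-like", bound from the TSS to +500 nt), a
body-distributed factor ("Set2-like", bound from +150 to 150 nt before the pA
site), a polymerase baseline (uniform along transcripts) and an untagged
background library.  Reads carry a 5' linker made of a 3-nt random tag
followed by a sample barcode; PCR duplication is modelled as a truncated
geometric copy count per unique molecule.  Everything is deterministic for a
fixed seed, and every emitted read is recorded in a truth table so each
downstream pipeline stage can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    POLII_CLASSES,
    AnnotatedGenome,
    Feature,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class PackingError(ValueError):
    """Requested features cannot be placed on the available chromosomes."""


# --------------------------------------------------------------------- specs


def _default_class_counts() -> dict[str, int]:
    return {
        "mRNA": 10,
        "mRNA_intron": 4,
        "SUT": 5,
        "CUT": 5,
        "XUT": 3,
        "snoRNA": 4,
        "rRNA": 2,
        "tRNA": 6,
        "Ty": 1,
        "IGS": 2,
    }


def _default_length_ranges() -> dict[str, tuple[int, int]]:
    return {
        "mRNA": (700, 2000),
        "SUT": (300, 800),
        "CUT": (250, 600),
        "XUT": (300, 800),
        "snoRNA": (80, 200),
        "rRNA": (800, 2000),
        "tRNA": (70, 90),
        "Ty": (1500, 3000),
        "IGS": (600, 1500),
    }


@dataclass
class SyntheticGenomeSpec:
    """Layout of the miniature annotated genome.

    ``class_counts`` uses the pseudo-class ``mRNA_intron`` for
    intron-containing mRNAs; they are written as class ``mRNA`` with two
    exons.  All features are placed without overlap (both strands), with
    intergenic gaps drawn from ``gap_range``.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 60_000, "chrII": 45_000}
    )
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    length_ranges: dict[str, tuple[int, int]] = field(default_factory=_default_length_ranges)
    first_exon_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (100, 400)
    gap_range: tuple[int, int] = (80, 300)
    seed: int = 0

    def validate(self) -> None:
        if self.intron_length_range[0] < 30:
            raise ValueError("intron length must be >= 30 nt")
        if self.gap_range[0] < 0 or self.gap_range[0] > self.gap_range[1]:
            raise ValueError("bad gap_range")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        unknown = set(self.class_counts) - set(_default_class_counts())
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_genome(spec: SyntheticGenomeSpec) -> AnnotatedGenome:
    """Generate sequences and a non-overlapping classed annotation.

    Deterministic for a fixed spec + seed.  Raises :class:`PackingError`,
    naming the fullest chromosome, when a feature cannot be placed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sequences = {c: _random_sequence(rng, n) for c, n in spec.chrom_lengths.items()}

    # draw per-feature structure first so placement failures are deterministic
    plan: list[tuple[str, int, tuple[int, ...]]] = []  # (cls, span, exon plan)
    counters: dict[str, int] = {}
    for key, count in spec.class_counts.items():
        for _ in range(count):
            if key == "mRNA_intron":
                e1 = int(rng.integers(*spec.first_exon_range, endpoint=True))
                intron = int(rng.integers(*spec.intron_length_range, endpoint=True))
                lo, hi = spec.length_ranges["mRNA"]
                e2 = max(200, int(rng.integers(lo, hi, endpoint=True)) - e1 - intron)
                plan.append(("mRNA", e1 + intron + e2, (e1, intron, e2)))
            else:
                lo, hi = spec.length_ranges[key]
                plan.append((key, int(rng.integers(lo, hi, endpoint=True)), ()))
            counters[key] = counters.get(key, 0) + 1

    order = rng.permutation(len(plan))
    strands = np.where(rng.random(len(plan)) < 0.5, "+", "-")
    cursors = {c: 0 for c in spec.chrom_lengths}
    idx_by_class: dict[str, int] = {}
    features: list[Feature] = []
    for j, i in enumerate(order):
        cls, span, exon_plan = plan[i]
        gap = int(rng.integers(*spec.gap_range, endpoint=True))
        # place on the chromosome with the most remaining room
        chrom = max(spec.chrom_lengths, key=lambda c: spec.chrom_lengths[c] - cursors[c])
        start = cursors[chrom] + gap
        if start + span > spec.chrom_lengths[chrom]:
            raise PackingError(
                f"cannot place {cls} feature of {span} nt on {chrom} "
                f"({spec.chrom_lengths[chrom] - cursors[chrom]} nt free)"
            )
        cursors[chrom] = start + span
        idx_by_class[cls] = idx_by_class.get(cls, 0) + 1
        fid = f"{cls}_{idx_by_class[cls]:03d}"
        if exon_plan:
            e1, intron, e2 = exon_plan
            exons = ((start, start + e1), (start + e1 + intron, start + span))
        else:
            exons = ((start, start + span),)
        features.append(
            Feature(fid, chrom, start, start + span, str(strands[i]), cls, exons)
        )
    features.sort(key=lambda f: (f.chrom, f.start))
    return AnnotatedGenome(sequences=sequences, features=features)


# ------------------------------------------------------------ binding models


@dataclass
class BindingModel:
    """Positional density of cross-linking sites along transcripts.

    kinds
    -----
    ``tss_peaked``
        uniform over ``tss_window`` nt downstream of the TSS (Set1-like).
    ``body``
        uniform from ``body_margin[0]`` after the TSS to ``body_margin[1]``
        before the pA site (Set2-like).
    ``uniform``
        uniform over the whole transcript (polymerase baseline).
    ``junction``
        every molecule spans the first intron's 5' splice junction; used to
        study spliced/unspliced read recovery.

    ``weights`` are relative transcription rates per feature id; ``None``
    means weight 1 for every RNAPII-class feature.  ``spliced_fraction``
    gives, per intron-containing gene (or globally when a float), the
    probability that a sampled molecule derives from the spliced transcript.
    """

    kind: str = "uniform"
    tss_window: tuple[int, int] = (0, 500)
    body_margin: tuple[int, int] = (150, 150)
    weights: dict[str, float] | None = None
    spliced_fraction: float | dict[str, float] = 0.5

    def validate(self, genome: AnnotatedGenome) -> None:
        if self.kind not in ("tss_peaked", "body", "uniform", "junction"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        for fid, w in (self.weights or {}).items():
            if fid not in genome.by_id:
                raise ValueError(f"weight for unknown feature {fid}")
            if w <= 0:
                raise ValueError(f"non-positive weight for {fid}")

    def resolved_weights(self, genome: AnnotatedGenome) -> dict[str, float]:
        if self.weights is not None:
            return dict(self.weights)
        if self.kind == "junction":
            return {
                f.feature_id: 1.0
                for f in genome.features
                if f.cls == "mRNA" and len(f.exons) > 1
            }
        return {f.feature_id: 1.0 for f in genome.features if f.cls in POLII_CLASSES}

    def spliced_p(self, fid: str) -> float:
        if isinstance(self.spliced_fraction, dict):
            return float(self.spliced_fraction.get(fid, 0.5))
        return float(self.spliced_fraction)

    def window(self, feature: Feature) -> tuple[int, int]:
        """Sampling window in unspliced transcript coordinates, clipped."""
        n = feature.length
        if self.kind == "tss_peaked":
            lo, hi = self.tss_window
            lo, hi = max(0, lo), min(n, hi)
        elif self.kind == "body":
            lo, hi = self.body_margin[0], n - self.body_margin[1]
        else:
            lo, hi = 0, n
        if hi - lo < 20:  # degenerate short feature: fall back to full span
            lo, hi = 0, n
        return lo, hi

    def mature_window(self, feature: Feature) -> tuple[int, int]:
        """Sampling window in mature (spliced) transcript coordinates."""
        n = feature.exonic_length
        if self.kind == "tss_peaked":
            lo, hi = max(0, self.tss_window[0]), min(n, self.tss_window[1])
        elif self.kind == "body":
            lo, hi = self.body_margin[0], n - self.body_margin[1]
        else:
            lo, hi = 0, n
        if hi - lo < 20:
            lo, hi = 0, n
        return lo, hi


@dataclass
class LibrarySpec:
    """One sequencing library: linker layout, depth and duplication.

    The emitted read layout is ``[random tag][barcode][insert][3' adapter]``
    truncated to ``read_length``; the insert maximum is capped so the whole
    insert is always sequenced, keeping preprocessing truth exact when
    sequencing errors are off.  ``dup_geom_p`` parameterizes the truncated
    geometric PCR copy-count distribution (mean ~1/p before truncation).
    """

    name: str
    barcode: str
    n_molecules: int
    tag_length: int = 3
    read_length: int = 100
    insert_range: tuple[int, int] = (20, 80)
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    dup_geom_p: float = 0.55
    dup_max: int = 10
    background_fraction: float = 0.02
    low_complexity_fraction: float = 0.005
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.tag_length < 1:
            raise ValueError("tag length must be >= 1")
        if set(self.barcode) - set("ACGT"):
            raise ValueError(f"bad barcode {self.barcode!r}")
        lo, hi = self.insert_range
        header = self.tag_length + len(self.barcode)
        if not 1 <= lo <= hi:
            raise ValueError("bad insert_range")
        if hi > self.read_length - header:
            raise ValueError(
                f"insert_range max {hi} exceeds read_length - linker ({self.read_length - header})"
            )
        for frac in (self.background_fraction, self.low_complexity_fraction, self.error_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if not 0.0 < self.dup_geom_p <= 1.0:
            raise ValueError("dup_geom_p must be in (0, 1]")


# ------------------------------------------------------------- trim oracle


def expected_trimmed(seq: str, adapter: str, min_overlap: int = 3) -> str:
    """Truth-side adapter trim: longest read suffix equal to an adapter prefix.

    Written independently of the preprocessing module so truth predictions
    can serve as an oracle for it.
    """
    n = len(seq)
    for i in range(n - min_overlap + 1):
        if adapter.startswith(seq[i:]):
            return seq[:i]
    return seq


def _max_base_fraction(seq: str) -> float:
    return max(seq.count(b) for b in "ACGT") / len(seq) if seq else 0.0


# ---------------------------------------------------------------- simulator


TRUTH_COLUMNS = [
    "molecule", "origin", "feature", "chrom", "strand",
    "start", "end", "start2", "end2",
    "tag", "dup", "spliced", "junc_ee", "junc_ei", "junc_ie", "insert",
]


@dataclass
class SimulatedLibrary:
    """A simulated library: per-molecule truth plus derived totals."""

    spec: LibrarySpec
    model: BindingModel
    truth: pd.DataFrame
    totals: dict[str, int]

    def emitted_read_count(self) -> int:
        return int(self.truth["dup"].sum())

    # ------------------------------------------------------------- outputs

    def iter_reads(self, rng: np.random.Generator | None = None):
        """Yield (read_id, sequence, quality) per emitted read copy."""
        spec = self.spec
        err = spec.error_rate
        if err > 0 and rng is None:
            rng = np.random.default_rng(spec.seed + 1)
        for row in self.truth.itertuples(index=False):
            full = row.tag + spec.barcode + row.insert + spec.adapter
            read = full[: spec.read_length]
            for copy in range(row.dup):
                seq = read
                if err > 0:
                    seq = _mutate(seq, err, rng)
                yield f"{spec.name}.{row.molecule}.{copy}", seq, "I" * len(seq)

    def write_fastq(self, path: str | Path, mode: str = "w") -> int:
        n = 0
        with open(path, mode) as fh:
            for rid, seq, qual in self.iter_reads():
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
                n += 1
        return n

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits):
        arr[hits] = _BASES[rng.integers(0, 4, size=len(hits))]
    return arr.tobytes().decode()


def simulate_library(
    genome: AnnotatedGenome,
    model: BindingModel,
    lib: LibrarySpec,
    junction_overhang: int = 3,
) -> SimulatedLibrary:
    """Sample unique molecules from the binding model and emulate PCR.

    Each unique molecule gets a random tag, a genomic origin drawn from the
    model's positional density over its feature, and a truncated-geometric
    duplicate count.  Junction flags (EE/EI/IE) are recorded with
    ``junction_overhang`` aligned nt required on each side of a splice
    boundary, mirroring the junction-counting contract downstream.
    """
    lib.validate()
    model.validate(genome)
    rng = np.random.default_rng(lib.seed)

    n = lib.n_molecules
    n_lc = int(round(n * lib.low_complexity_fraction))
    n_bg = min(int(round(n * lib.background_fraction)), n - n_lc)
    n_sig = n - n_lc - n_bg

    weights = model.resolved_weights(genome)
    if not weights:
        raise ValueError("binding model selects no features in this genome")
    w_ids = sorted(weights)
    w = np.array([weights[f] for f in w_ids], dtype=float)
    w /= w.sum()

    records: list[tuple] = []
    mol = 0

    def _sample_from_feature(
        f: Feature, count: int, uniform_full: bool
    ) -> None:
        nonlocal mol
        if count == 0:
            return
        lo, hi = lib.insert_range
        lengths = rng.integers(lo, hi, size=count, endpoint=True)
        intron_gene = len(f.exons) > 1
        p_spliced = model.spliced_p(f.feature_id) if intron_gene and not uniform_full else 0.0
        spliced = rng.random(count) < p_spliced
        for L, is_spliced in zip(lengths.tolist(), spliced.tolist()):
            rec = _sample_molecule(
                genome, f, int(L), bool(is_spliced), model, rng,
                uniform_full=uniform_full, overhang=junction_overhang,
            )
            if rec is None:
                continue
            records.append((mol,) + rec)
            mol += 1

    # signal molecules: multinomial over weighted features
    counts = rng.multinomial(n_sig, w)
    for fid, c in zip(w_ids, counts.tolist()):
        _sample_from_feature(genome.by_id[fid], c, uniform_full=False)

    # background: uniform over all annotated transcripts (untagged-strain-like)
    all_feats = genome.features
    bg_choice = rng.integers(0, len(all_feats), size=n_bg)
    bg_counts = np.bincount(bg_choice, minlength=len(all_feats))
    for f, c in zip(all_feats, bg_counts.tolist()):
        _sample_from_feature(f, int(c), uniform_full=True)

    # low-complexity contaminants: oligo(A) inserts with no genomic origin
    lo, hi = lib.insert_range
    for L in rng.integers(lo, hi, size=n_lc, endpoint=True).tolist():
        records.append(
            (mol, "lowcomp", "", "", ".", -1, -1, -1, -1, "", "A" * int(L))
        )
        mol += 1

    df = pd.DataFrame(
        records,
        columns=["molecule", "origin", "feature", "chrom", "strand",
                 "start", "end", "start2", "end2", "junction", "insert"],
    )
    # junction string -> boolean flags
    df["spliced"] = df["junction"].str.contains("S", regex=False)
    df["junc_ee"] = df["junction"].str.contains("EE", regex=False)
    df["junc_ei"] = df["junction"].str.contains("EI", regex=False)
    df["junc_ie"] = df["junction"].str.contains("IE", regex=False)
    df = df.drop(columns=["junction"])

    tags = _BASES[rng.integers(0, 4, size=(len(df), lib.tag_length))]
    df["tag"] = ["".join(t) for t in tags.astype(str)]
    dups = np.minimum(rng.geometric(lib.dup_geom_p, size=len(df)), lib.dup_max)
    df["dup"] = dups.astype(int)
    df = df[TRUTH_COLUMNS]

    totals = _truth_totals(df, lib)
    return SimulatedLibrary(spec=lib, model=model, truth=df, totals=totals)


def _sample_molecule(
    genome: AnnotatedGenome,
    f: Feature,
    L: int,
    spliced: bool,
    model: BindingModel,
    rng: np.random.Generator,
    uniform_full: bool,
    overhang: int,
):
    """Place one insert on feature ``f``; returns a truth record tuple."""
    if model.kind == "junction" and not uniform_full:
        return _sample_junction_molecule(genome, f, L, spliced, rng, overhang)
    if spliced:
        # mature coordinates, mapped back through the exon structure
        lo, hi = (0, f.exonic_length) if uniform_full else model.mature_window(f)
        L = min(L, hi - lo)
        m0 = lo + int(rng.integers(0, hi - lo - L + 1))
        return _mature_to_genomic(genome, f, m0, m0 + L, overhang)
    lo, hi = (0, f.length) if uniform_full else model.window(f)
    L = min(L, hi - lo)
    t0 = lo + int(rng.integers(0, hi - lo - L + 1))
    if f.strand == "+":
        gs, ge = f.start + t0, f.start + t0 + L
    else:
        ge = f.end - t0
        gs = ge - L
    junction = _unspliced_junction_label(f, gs, ge, overhang)
    insert = _genomic_insert(genome, f, ((gs, ge),))
    return ("signal" if not uniform_full else "background",
            f.feature_id, f.chrom, f.strand, gs, ge, -1, -1, junction, insert)


def _sample_junction_molecule(genome, f, L, spliced, rng, overhang):
    """Molecules forced to span the first intron's 5' splice junction."""
    if len(f.exons) < 2:
        return None
    if L < 2 * overhang + 2:
        L = 2 * overhang + 2
    e1len = _first_exon_len(f)
    if spliced:
        j = e1len  # junction position in mature coordinates
        m0 = j - L + overhang + int(rng.integers(0, L - 2 * overhang + 1))
        m0 = max(0, min(m0, f.exonic_length - L))
        return _mature_to_genomic(genome, f, m0, m0 + L, overhang)
    j = e1len  # 5' exon/intron boundary in unspliced coordinates
    t0 = j - L + overhang + int(rng.integers(0, L - 2 * overhang + 1))
    t0 = max(0, min(t0, f.length - L))
    if f.strand == "+":
        gs, ge = f.start + t0, f.start + t0 + L
    else:
        ge = f.end - t0
        gs = ge - L
    junction = _unspliced_junction_label(f, gs, ge, overhang)
    insert = _genomic_insert(genome, f, ((gs, ge),))
    return ("signal", f.feature_id, f.chrom, f.strand, gs, ge, -1, -1, junction, insert)


def _first_exon_len(f: Feature) -> int:
    """Length of the transcript's 5' exon (strand-aware)."""
    ex = f.exons if f.strand == "+" else f.exons[::-1]
    return ex[0][1] - ex[0][0]


def _mature_to_genomic(genome: AnnotatedGenome, f: Feature, m0: int, m1: int, overhang: int):
    """Map a mature-transcript interval to genomic block(s) for a 2-exon gene."""
    ex = f.exons if f.strand == "+" else f.exons[::-1]  # transcript order
    e1len = ex[0][1] - ex[0][0]
    if m1 <= e1len:  # fully in first exon
        blocks = [_exon_offset_interval(f, ex[0], m0, m1)]
        ee = False
    elif m0 >= e1len:  # fully in second exon
        blocks = [_exon_offset_interval(f, ex[1], m0 - e1len, m1 - e1len)]
        ee = False
    else:
        a = _exon_offset_interval(f, ex[0], m0, e1len)
        b = _exon_offset_interval(f, ex[1], 0, m1 - e1len)
        blocks = sorted([a, b])
        ee = e1len - m0 >= overhang and m1 - e1len >= overhang
    junction = ",".join((["EE"] if ee else []) + ["S"])
    (gs, ge) = blocks[0]
    (gs2, ge2) = blocks[1] if len(blocks) > 1 else (-1, -1)
    insert = _genomic_insert(genome, f, tuple(blocks))
    return ("signal", f.feature_id, f.chrom, f.strand, gs, ge, gs2, ge2, junction, insert)


def _exon_offset_interval(f: Feature, exon: tuple[int, int], a: int, b: int) -> tuple[int, int]:
    """Genomic interval for transcript-orientation offsets [a, b) within an exon."""
    s, e = exon
    if f.strand == "+":
        return (s + a, s + b)
    return (e - b, e - a)


def _unspliced_junction_label(f: Feature, gs: int, ge: int, overhang: int) -> str:
    if len(f.exons) < 2:
        return ""
    labels = []
    for istart, iend in f.introns:
        crosses_left = gs <= istart - overhang and ge >= istart + overhang
        crosses_right = gs <= iend - overhang and ge >= iend + overhang
        if f.strand == "+":
            if crosses_left:
                labels.append("EI")
            if crosses_right:
                labels.append("IE")
        else:
            if crosses_right:
                labels.append("EI")
            if crosses_left:
                labels.append("IE")
    return ",".join(labels)


def _genomic_insert(
    genome: AnnotatedGenome, f: Feature, blocks: tuple[tuple[int, int], ...]
) -> str:
    """cDNA insert sequence: spliced blocks joined, in read (5'->3') orientation."""
    seq = "".join(genome.sequences[f.chrom][s:e] for s, e in blocks)
    return seq if f.strand == "+" else reverse_complement(seq)


def _truth_totals(df: pd.DataFrame, lib: LibrarySpec) -> dict[str, int]:
    """Predict preprocessing outcomes from truth alone (errors-off oracle)."""
    header = lib.tag_length + len(lib.barcode)
    avail = lib.read_length - header
    kept_keys: set[tuple[str, str]] = set()
    kept_reads = trim_discarded = lowcomp = 0
    for row in df.itertuples(index=False):
        visible = (row.insert + lib.adapter)[:avail]
        trimmed = expected_trimmed(visible, lib.adapter)
        if len(trimmed) < 17 or trimmed.count("N") > 3:
            trim_discarded += row.dup
        elif _max_base_fraction(trimmed) > 0.8:
            lowcomp += row.dup
        else:
            kept_reads += row.dup
            kept_keys.add((row.tag, trimmed))
    emitted = int(df["dup"].sum())
    return {
        "molecules": int(len(df)),
        "emitted_reads": emitted,
        "predicted_assigned": emitted,
        "predicted_trim_discarded_reads": int(trim_discarded),
        "predicted_lowcomplexity_reads": int(lowcomp),
        "predicted_kept_reads": int(kept_reads),
        "predicted_kept_unique": len(kept_keys),
    }


# ------------------------------------------------------- truth -> alignments


def truth_to_segments(
    sim: "SimulatedLibrary | pd.DataFrame",
    per_read: bool = False,
) -> list:
    """Truth molecules as :class:`~cracflow.genomic.AlignedSegment` objects.

    With ``per_read`` each PCR copy becomes its own segment (multiplicity 1),
    matching what an aligner fed with un-collapsed reads would produce;
    otherwise one segment per unique molecule carries the duplicate count as
    its multiplicity.  Low-complexity contaminants have no genomic origin and
    are skipped.
    """
    from .genomic import AlignedSegment

    truth = sim.truth if isinstance(sim, SimulatedLibrary) else sim
    name = sim.spec.name if isinstance(sim, SimulatedLibrary) else "truth"
    out: list[AlignedSegment] = []
    for row in truth.itertuples(index=False):
        if row.origin == "lowcomp":
            continue
        blocks = ((int(row.start), int(row.end)),)
        if row.start2 >= 0:
            blocks = tuple(sorted([blocks[0], (int(row.start2), int(row.end2))]))
        if per_read:
            for copy in range(int(row.dup)):
                out.append(
                    AlignedSegment(
                        chrom=row.chrom, strand=row.strand, blocks=blocks,
                        tag=row.tag, multiplicity=1,
                        name=f"{name}.{row.molecule}.{copy}",
                    )
                )
        else:
            out.append(
                AlignedSegment(
                    chrom=row.chrom, strand=row.strand, blocks=blocks,
                    tag=row.tag, multiplicity=int(row.dup),
                    name=f"{name}.{row.molecule}",
                )
            )
    return out


def emit_truth_alignments(
    sim: "SimulatedLibrary",
    genome: AnnotatedGenome,
    path: str | Path,
    per_read: bool = True,
) -> int:
    """Write a SAM of truth placements, bypassing any external aligner.

    One primary alignment per emitted read (default) at its true locus;
    spliced molecules become two-block records with an N gap.  The random
    tag rides in the read-name suffix and an ``RX`` tag field.
    """
    from .genomic import write_sam

    return write_sam(truth_to_segments(sim, per_read=per_read), genome, path)
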