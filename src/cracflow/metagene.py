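"""TSS/pA-anchored matrices, metagene profiles, 2D heat-map export and
expression-matched transcript subsets.

Rows are features, columns are positions relative to the anchor in
transcript orientation (position 0 is the first transcribed base for the
TSS anchor and the last for the pA anchor; minus-strand features are
mirrored).  Cells further than a configurable flank outside the transcript
are masked and excluded from aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedGenome, Feature
from .coverage import CoverageTrack, EnrichmentTrack, enrichment_track

DEFAULT_TSS_WINDOW = (-100, 1500)
DEFAULT_PA_WINDOW = (-1500, 100)


@dataclass
class AnchoredMatrix:
    feature_ids: list[str]
    positions: np.ndarray  # relative positions, contiguous
    values: np.ndarray  # (n_features, n_positions)
    mask: np.ndarray  # True where the cell is outside the feature/chromosome
    anchor: str  # "tss" | "pa"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.mask, np.nan, self.values),
            index=self.feature_ids,
            columns=self.positions,
        )
        df.index.name = "feature_id"
        return df

    def row_totals(self) -> np.ndarray:
        return np.where(self.mask, 0.0, self.values).sum(axis=1)


def anchored_matrix(
    track: CoverageTrack | EnrichmentTrack,
    features: Sequence[Feature],
    anchor: str = "tss",
    window: tuple[int, int] | None = None,
    flank: int = 100,
) -> AnchoredMatrix:
    """Sample the track at anchor-relative positions for each feature.

    ``window`` is half-open [a, b) in nt relative to the anchor.  Cells more
    than ``flank`` nt outside the transcript, or off the chromosome, are
    masked.
    """
    if anchor not in ("tss", "pa"):
        raise ValueError(f"anchor must be 'tss' or 'pa', not {anchor!r}")
    if window is None:
        window = DEFAULT_TSS_WINDOW if anchor == "tss" else DEFAULT_PA_WINDOW
    a, b = window
    if a >= b:
        raise ValueError("empty anchor window")
    positions = np.arange(a, b)
    values = np.zeros((len(features), len(positions)))
    mask = np.ones_like(values, dtype=bool)
    for i, f in enumerate(features):
        arr = track.data[(f.chrom, f.strand)]
        n = len(arr)
        # transcript-orientation offset from the TSS for each column
        t = positions if anchor == "tss" else positions + (f.length - 1)
        g = f.start + t if f.strand == "+" else f.end - 1 - t
        inside = (t >= -flank) & (t < f.length + flank) & (g >= 0) & (g < n)
        idx = np.where(inside, g, 0)
        values[i] = arr[idx]
        mask[i] = ~inside
    values[mask] = 0.0
    return AnchoredMatrix(
        feature_ids=[f.feature_id for f in features],
        positions=positions,
        values=values,
        mask=mask,
        anchor=anchor,
    )


def metagene_profile(matrix: AnchoredMatrix, mode: str = "sum") -> pd.Series:
    """Aggregate unmasked cells per position (``sum`` or ``mean``).

    All-masked columns are reported as NaN.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', not {mode!r}")
    unmasked = ~matrix.mask
    counts = unmasked.sum(axis=0)
    sums = np.where(unmasked, matrix.values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = sums if mode == "sum" else sums / counts
    out = np.where(counts == 0, np.nan, out)
    s = pd.Series(out, index=matrix.positions, name=f"{matrix.anchor}_{mode}")
    s.index.name = "position"
    return s


def relative_metagene(
    protein: CoverageTrack,
    reference: CoverageTrack,
    features: Sequence[Feature],
    anchor: str = "tss",
    window: tuple[int, int] | None = None,
    pseudocount: float = 5.0,
    flank: int = 100,
) -> pd.Series:
    """Mean per-position log2 enrichment of protein over reference.

    Per-base enrichment is computed genome-wide first, then anchored and
    averaged — the mean of per-base log-ratios, not the log-ratio of means.
    """
    enr = enrichment_track(protein, reference, pseudocount=pseudocount)
    mat = anchored_matrix(enr, features, anchor=anchor, window=window, flank=flank)
    return metagene_profile(mat, mode="mean")


# ------------------------------------------------------- expression matching


def signal_over_first_nt(
    track: CoverageTrack,
    features: Sequence[Feature],
    n: int = 300,
) -> pd.Series:
    """Total track signal over [TSS, TSS+n) per feature (clipped, stranded)."""
    vals = {}
    for f in features:
        arr = track.data[(f.chrom, f.strand)]
        if f.strand == "+":
            s, e = f.start, min(f.start + n, f.end)
        else:
            s, e = max(f.start, f.end - n), f.end
        vals[f.feature_id] = float(arr[s:e].sum())
    out = pd.Series(vals, name="signal")
    out.index.name = "feature_id"
    return out


def expression_match(
    signals_by_class: Mapping[str, pd.Series],
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Greedy nearest-neighbour expression matching across classes.

    Features are matched without replacement on log10 of a reference signal
    (features with signal <= 0 are ineligible).  The class with the fewest
    eligible features anchors the matching; its features are visited in
    descending signal order (ties broken by lowest feature id), and a group
    is kept only when every class has an unused feature within ``tolerance``
    log10 units of the anchor.  Returns one row per matched group with
    ``<class>`` (feature id) and ``<class>_log10`` columns.
    """
    logs: dict[str, pd.Series] = {}
    for cls, sig in signals_by_class.items():
        eligible = sig[sig > 0]
        logs[cls] = np.log10(eligible).sort_values(kind="stable")
    if any(len(s) == 0 for s in logs.values()):
        return pd.DataFrame(
            columns=[c for cls in signals_by_class for c in (cls, f"{cls}_log10")]
        )
    anchor_cls = min(logs, key=lambda c: (len(logs[c]), c))
    others = [c for c in signals_by_class if c != anchor_cls]
    used: dict[str, set[str]] = {c: set() for c in others}
    anchor = logs[anchor_cls].sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    rows = []
    for fid, lv in anchor.items():
        group = {anchor_cls: fid, f"{anchor_cls}_log10": lv}
        ok = True
        for cls in others:
            cand = logs[cls][~logs[cls].index.isin(used[cls])]
            if cand.empty:
                ok = False
                break
            dist = (cand - lv).abs()
            best = dist[dist == dist.min()].index.min()  # tie -> lowest id
            if dist[best] > tolerance:
                ok = False
                break
            group[cls] = best
            group[f"{cls}_log10"] = float(cand[best])
        if ok:
            for cls in others:
                used[cls].add(group[cls])
            rows.append(group)
    cols = [c for cls in [anchor_cls] + others for c in (cls, f"{cls}_log10")]
    return pd.DataFrame(rows, columns=cols)


# ------------------------------------------------------------ heatmap export


def heatmap_export(
    matrix: AnchoredMatrix,
    path: str | Path,
    sort_key: str = "total",
    annotation: AnnotatedGenome | None = None,
    external: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Write a row-ordered TSV of the matrix (masked cells as NA).

    ``sort_key``: ``total`` (unmasked row sum), ``length`` (feature length,
    needs ``annotation``) or ``external`` (needs the ``external`` ranking).
    Rows are ordered descending; ties break on feature id for determinism.
    """
    if sort_key == "total":
        keys = dict(zip(matrix.feature_ids, matrix.row_totals()))
    elif sort_key == "length":
        if annotation is None:
            raise ValueError("length sort needs the annotation")
        keys = {fid: annotation.by_id[fid].length for fid in matrix.feature_ids}
    elif sort_key == "external":
        if external is None:
            raise ValueError("external sort needs a ranking")
        keys = {fid: external[fid] for fid in matrix.feature_ids}
    else:
        raise ValueError(f"unknown sort key {sort_key!r}")
    df = matrix.to_frame()
    order = sorted(df.index, key=lambda fid: (-keys[fid], fid))
    df = df.loc[order]
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
    return df
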