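"""Anchored matrices, metagene profiles, relative (enrichment) metagenes,
expression matching and heat-map export."""

import numpy as np
import pandas as pd
import pytest

from cracflow.annotation import AnnotatedGenome, Feature, reverse_complement
from cracflow.coverage import CoverageTrack, build_coverage, normalize_rpm
from cracflow.genomic import deduplicate
from cracflow.metagene import (
    anchored_matrix,
    expression_match,
    heatmap_export,
    metagene_profile,
    relative_metagene,
    signal_over_first_nt,
)
from cracflow.synthetic import BindingModel, LibrarySpec, simulate_library, truth_to_segments


def _track(toy_genome, fill=None, library_size=1_000_000):
    t = CoverageTrack.zeros(toy_genome.chrom_lengths, normalization="rpm",
                            library_size=library_size)
    if fill:
        for (chrom, strand, s, e), v in fill.items():
            t.data[(chrom, strand)][s:e] = v
    return t


class TestAnchoredMatrix:
    def test_uniform_transcript_masked_after_end(self, toy_genome):
        # mRNA_C: [7000,7500) +, 500 nt; flank 100
        t = _track(toy_genome, {("chrI", "+", 7000, 7500): 2.0})
        mat = anchored_matrix(t, [toy_genome.by_id["mRNA_C"]], "tss", (-100, 1500), flank=100)
        row, mask = mat.values[0], mat.mask[0]
        pos = mat.positions
        assert (row[(pos >= 0) & (pos < 500)] == 2.0).all()
        assert (~mask[(pos >= -100) & (pos < 600)]).all()
        assert mask[pos >= 600].all()  # > 100 nt past the pA

    def test_minus_strand_orientation(self, toy_genome):
        # gradient rising toward genomic right = falling along - transcript
        arr = np.zeros(10_000)
        arr[4000:5200] = np.arange(1200)
        t = _track(toy_genome)
        t.data[("chrI", "-")] = arr
        mat = anchored_matrix(t, [toy_genome.by_id["mRNA_B"]], "tss", (0, 1200), flank=0)
        row = mat.values[0]
        assert row[0] == 1199 and row[1199] == 0  # 5' end is genomic right

    def test_pa_anchor_position_zero_is_last_base(self, toy_genome):
        t = _track(toy_genome, {("chrI", "+", 7499, 7500): 9.0})
        mat = anchored_matrix(t, [toy_genome.by_id["mRNA_C"]], "pa", (-200, 100), flank=100)
        assert mat.values[0][mat.positions == 0] == 9.0

    def test_off_chromosome_masked_not_error(self, toy_genome):
        f = Feature("edge", "chrI", 0, 50, "+", "mRNA")
        g = AnnotatedGenome(toy_genome.sequences, toy_genome.features + [f])
        t = _track(g)
        mat = anchored_matrix(t, [g.by_id["edge"]], "tss", (-100, 100), flank=100)
        assert mat.mask[0][mat.positions < 0].all()

    def test_mirror_invariance(self, toy_genome):
        """Reverse-complementing the genome and all placements leaves the
        anchored matrix unchanged."""
        n = 10_000
        rng = np.random.default_rng(3)
        fwd = _track(toy_genome)
        fwd.data[("chrI", "+")] = rng.random(n)
        f = toy_genome.by_id["mRNA_C"]
        mirror_seq = reverse_complement(toy_genome.sequences["chrI"])
        f_m = Feature("mRNA_C", "chrI", n - f.end, n - f.start, "-", "mRNA")
        g_m = AnnotatedGenome({"chrI": mirror_seq}, [f_m])
        rev = _track(g_m)
        rev.data[("chrI", "-")] = fwd.data[("chrI", "+")][::-1].copy()
        for anchor in ("tss", "pa"):
            m1 = anchored_matrix(fwd, [f], anchor, (-50, 300))
            m2 = anchored_matrix(rev, [f_m], anchor, (-50, 300))
            np.testing.assert_array_equal(m1.values, m2.values)
            np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_truth_tss_peaked_row_maxima_in_window(self, small_genome):
        lib = LibrarySpec(name="s", barcode="ATCGA", n_molecules=30_000, seed=2,
                          background_fraction=0.0, low_complexity_fraction=0.0)
        sim = simulate_library(small_genome, BindingModel(kind="tss_peaked",
                                                          spliced_fraction=0.0), lib)
        track = normalize_rpm(build_coverage(
            deduplicate(truth_to_segments(sim)), small_genome)[0])
        mrnas = small_genome.features_of_class("mRNA")
        mat = anchored_matrix(track, mrnas, "tss", (0, 1500), flank=0)
        filled = mat.row_totals() > 0
        argmax = mat.positions[np.argmax(np.where(mat.mask, -1.0, mat.values), axis=1)]
        assert (argmax[filled] < 500).all()


class TestMetageneProfile:
    def test_single_row_identity(self, toy_genome):
        t = _track(toy_genome, {("chrI", "+", 7000, 7500): 3.0})
        mat = anchored_matrix(t, [toy_genome.by_id["mRNA_C"]], "tss", (0, 500), flank=0)
        prof = metagene_profile(mat, "sum")
        np.testing.assert_array_equal(prof.values, mat.values[0])

    def test_mean_of_two_rows(self, toy_genome):
        t = _track(toy_genome, {("chrI", "+", 1000, 2600): 1.0,
                                ("chrI", "+", 7000, 7500): 3.0})
        feats = [toy_genome.by_id["mRNA_A"], toy_genome.by_id["mRNA_C"]]
        prof = metagene_profile(anchored_matrix(t, feats, "tss", (0, 400), flank=0), "mean")
        assert (prof.values == 2.0).all()

    def test_constant_matrix_mean_is_constant(self, toy_genome):
        t = _track(toy_genome)
        for key in t.data:
            t.data[key][:] = 7.5
        feats = [f for f in toy_genome.features if f.cls == "mRNA"]
        prof = metagene_profile(anchored_matrix(t, feats, "tss", (0, 300), flank=0), "mean")
        assert (prof.values == 7.5).all()

    def test_all_masked_column_is_nan(self, toy_genome):
        mat = anchored_matrix(_track(toy_genome), [toy_genome.by_id["mRNA_C"]],
                              "tss", (0, 800), flank=0)
        prof = metagene_profile(mat, "sum")
        assert np.isnan(prof.loc[700])

    def test_mode_validation(self, toy_genome):
        mat = anchored_matrix(_track(toy_genome), [toy_genome.by_id["mRNA_C"]], "tss")
        with pytest.raises(ValueError, match="mode"):
            metagene_profile(mat, "median")


class TestRelativeMetagene:
    def test_equal_tracks_flat_zero(self, toy_genome):
        t = _track(toy_genome, {("chrI", "+", 7000, 7500): 8.0})
        prof = relative_metagene(t, t, [toy_genome.by_id["mRNA_C"]], "tss", (0, 400))
        assert (prof.values == 0.0).all()

    def test_twofold_closed_form(self, toy_genome):
        x = 100.0
        a = _track(toy_genome, {("chrI", "+", 7000, 7500): 2 * x})
        b = _track(toy_genome, {("chrI", "+", 7000, 7500): x})
        prof = relative_metagene(a, b, [toy_genome.by_id["mRNA_C"]], "tss", (0, 400))
        assert prof.values == pytest.approx(np.log2((2 * x + 5) / (x + 5)))

    def test_body_model_depleted_then_enriched(self, small_genome):
        def make(kind, seed):
            lib = LibrarySpec(name=kind, barcode="ATCGA", n_molecules=40_000, seed=seed,
                              background_fraction=0.0, low_complexity_fraction=0.0)
            sim = simulate_library(small_genome, BindingModel(kind=kind,
                                                              spliced_fraction=0.0), lib)
            return normalize_rpm(build_coverage(
                deduplicate(truth_to_segments(sim)), small_genome)[0])

        body, base = make("body", 21), make("uniform", 22)
        prof = relative_metagene(body, base, small_genome.features_of_class("mRNA"),
                                 "tss", (0, 600))
        assert prof.loc[0:120].mean() < 0
        assert prof.loc[400] > 0


class TestExpressionMatch:
    def test_identical_multisets_fully_matched(self):
        sig = pd.Series({"a1": 10.0, "a2": 100.0, "a3": 1000.0})
        out = expression_match({
            "mRNA": sig.rename(index=lambda s: "m_" + s),
            "SUT": sig.rename(index=lambda s: "s_" + s),
        })
        assert len(out) == 3
        assert (out["mRNA_log10"] - out["SUT_log10"]).abs().max() <= 0.05

    def test_disjoint_ranges_empty(self):
        out = expression_match({
            "mRNA": pd.Series({"m1": 1e6, "m2": 1e5}),
            "CUT": pd.Series({"c1": 10.0, "c2": 1.0}),
        })
        assert out.empty

    def test_tolerance_respected_on_noisy_lognormal(self):
        rng = np.random.default_rng(9)
        classes = {
            cls: pd.Series(10 ** rng.normal(3, 0.8, size=80),
                           index=[f"{cls}_{i}" for i in range(80)])
            for cls in ("mRNA", "SUT", "CUT")
        }
        out = expression_match(classes, tolerance=0.05)
        assert len(out)
        logs = out[[c for c in out.columns if c.endswith("_log10")]]
        assert (logs.max(axis=1) - logs.min(axis=1)).max() <= 2 * 0.05 + 1e-12
        means = logs.mean()
        assert means.max() - means.min() <= 0.05 + 1e-12
        for cls in classes:  # no feature reused
            assert out[cls].is_unique

    def test_zero_eligible_class_gives_empty(self):
        out = expression_match({
            "mRNA": pd.Series({"m1": 10.0}),
            "CUT": pd.Series({"c1": 0.0}),
        })
        assert out.empty


class TestHeatmapExport:
    def test_sort_by_total_descending(self, toy_genome, tmp_path):
        t = _track(toy_genome, {("chrI", "+", 1000, 2600): 1.0,
                                ("chrI", "+", 7000, 7500): 3.0})
        feats = [toy_genome.by_id["mRNA_A"], toy_genome.by_id["mRNA_C"]]
        mat = anchored_matrix(t, feats, "tss", (0, 200), flank=0)
        df = heatmap_export(mat, tmp_path / "h.tsv")
        assert list(df.index) == ["mRNA_C", "mRNA_A"]
        assert (tmp_path / "h.tsv").read_text().startswith("feature_id")

    def test_reexport_byte_identical(self, toy_genome, tmp_path):
        t = _track(toy_genome, {("chrI", "+", 7000, 7500): 3.0})
        mat = anchored_matrix(t, [toy_genome.by_id["mRNA_C"]], "tss", (0, 700), flank=50)
        heatmap_export(mat, tmp_path / "a.tsv")
        heatmap_export(mat, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_sort_by_length_matches_annotation(self, toy_genome, tmp_path):
        feats = [toy_genome.by_id[i] for i in ("mRNA_A", "mRNA_B", "mRNA_C")]
        mat = anchored_matrix(_track(toy_genome), feats, "tss", (0, 100), flank=0)
        df = heatmap_export(mat, tmp_path / "h.tsv", sort_key="length",
                            annotation=toy_genome)
        expected = [f.feature_id for f in
                    sorted(feats, key=lambda f: (-f.length, f.feature_id))]
        assert list(df.index) == expected

    def test_unknown_sort_key(self, toy_genome, tmp_path):
        mat = anchored_matrix(_track(toy_genome), [toy_genome.by_id["mRNA_C"]], "tss")
        with pytest.raises(ValueError, match="sort key"):
            heatmap_export(mat, tmp_path / "h.tsv", sort_key="alphabetical")


def test_signal_over_first_nt_stranded(toy_genome):
    t = _track(toy_genome)
    t.data[("chrI", "-")][5100:5200] = 2.0  # last 100 genomic nt = first 100 of mRNA_B
    sig = signal_over_first_nt(t, [toy_genome.by_id["mRNA_B"]], n=300)
    assert sig["mRNA_B"] == 200.0
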