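"""Coverage accumulation, exclusion classes, RPM normalization, replicate
averaging, pseudocounted enrichment and the feature CV/RPKM filter."""

import numpy as np
import pandas as pd
import pytest

from cracflow.coverage import (
    CoverageTrack,
    Replicate,
    average_replicates,
    build_coverage,
    count_reads_per_feature,
    enrichment_track,
    feature_stats,
    feature_totals,
    normalize_rpm,
    scatter_table,
    write_bedgraph,
)
from cracflow.genomic import AlignedSegment, classify_reads, deduplicate
from cracflow.synthetic import BindingModel, LibrarySpec, simulate_library, truth_to_segments


def seg(blocks, strand="+", tag="ACG", chrom="chrI"):
    return AlignedSegment(chrom=chrom, strand=strand, blocks=tuple(blocks), tag=tag)


def _rpm_track(values_by_key, length=10_000, library_size=1_000_000):
    data = {("chrI", "+"): np.zeros(length), ("chrI", "-"): np.zeros(length)}
    for key, arr in values_by_key.items():
        data[key] = np.asarray(arr, dtype=float)
    return CoverageTrack(data=data, normalization="rpm", library_size=library_size)


class TestBuildCoverage:
    def test_blockwise_accumulation(self, toy_genome):
        track, stats = build_coverage([seg([(1000, 1050)]), seg([(1000, 1050)], tag="T")],
                                      toy_genome)
        arr = track.get("chrI", "+")
        assert (arr[1000:1050] == 2).all() and arr[1050] == 0
        assert stats.included == 2 and track.library_size == 2

    def test_spliced_read_leaves_intron_empty(self, toy_genome):
        track, _ = build_coverage([seg([(1490, 1500), (1800, 1810)])], toy_genome)
        arr = track.get("chrI", "+")
        assert arr[1490:1500].sum() == 10 and arr[1800:1810].sum() == 10
        assert arr[1500:1800].sum() == 0

    def test_trna_read_excluded_from_track_and_library(self, toy_genome):
        track, stats = build_coverage([seg([(6010, 6060)]), seg([(1100, 1150)])], toy_genome)
        assert stats.excluded == 1 and track.library_size == 1
        assert track.get("chrI", "+")[6010:6060].sum() == 0

    def test_antisense_to_trna_included_by_default(self, toy_genome):
        track, stats = build_coverage([seg([(6010, 6060)], strand="-")], toy_genome)
        assert stats.included == 1

    def test_mito_chromosome_excluded(self, toy_genome):
        from cracflow.annotation import AnnotatedGenome, Feature

        g = AnnotatedGenome(
            dict(toy_genome.sequences, chrM="ACGT" * 500),
            list(toy_genome.features),
        )
        _, stats = build_coverage([seg([(10, 60)], chrom="chrM")], g)
        assert stats.excluded == 1

    def test_unknown_chromosome_is_error(self, toy_genome):
        with pytest.raises(ValueError, match="chrX"):
            build_coverage([seg([(0, 10)], chrom="chrX")], toy_genome)

    def test_raw_total_equals_block_lengths(self, small_genome):
        lib = LibrarySpec(name="s", barcode="ATCGA", n_molecules=2000, seed=3,
                          background_fraction=0.2)
        sim = simulate_library(small_genome, BindingModel(), lib)
        segs = deduplicate(truth_to_segments(sim))
        track, stats = build_coverage(segs, small_genome)
        cls = classify_reads(segs, small_genome)
        included_len = sum(
            s.aligned_length for s, c in zip(segs, cls.labels)
            if c not in ("rRNA", "tRNA", "other-PolIII")
        )
        assert track.total() == included_len
        assert stats.included + stats.excluded == len(segs)


class TestNormalizeRpm:
    def test_scaling(self, toy_genome):
        track, _ = build_coverage([seg([(1000, 1050)])], toy_genome)
        track.library_size = 2_000_000
        track.data[("chrI", "+")][1000:1050] = 4.0
        rpm = normalize_rpm(track)
        assert rpm.get("chrI", "+")[1000] == 2.0 and rpm.normalization == "rpm"

    def test_zero_library_is_error(self, toy_genome):
        empty = CoverageTrack.zeros(toy_genome.chrom_lengths)
        with pytest.raises(ValueError, match="library size 0"):
            normalize_rpm(empty)

    def test_duplication_invariance(self, toy_genome):
        segs = [seg([(1000 + 7 * i, 1040 + 7 * i)], tag=f"T{i}") for i in range(20)]
        one, _ = build_coverage(segs, toy_genome)
        two, _ = build_coverage(segs + segs, toy_genome)
        r1, r2 = normalize_rpm(one), normalize_rpm(two)
        for key in r1.data:
            np.testing.assert_array_equal(r1.data[key], r2.data[key])


class TestAverageReplicates:
    def test_single_track_identity(self):
        t = _rpm_track({("chrI", "+"): np.arange(10_000, dtype=float)})
        avg = average_replicates([t])
        np.testing.assert_array_equal(avg.get("chrI", "+"), t.get("chrI", "+"))

    def test_mean_and_commutativity(self):
        a = _rpm_track({("chrI", "+"): np.full(10_000, 1.0)})
        b = _rpm_track({("chrI", "+"): np.full(10_000, 3.0)})
        ab, ba = average_replicates([a, b]), average_replicates([b, a])
        assert ab.get("chrI", "+")[0] == 2.0
        np.testing.assert_array_equal(ab.get("chrI", "+"), ba.get("chrI", "+"))

    def test_shape_mismatch_is_error(self):
        a = _rpm_track({})
        b = _rpm_track({}, length=5_000)
        with pytest.raises(ValueError):
            average_replicates([a, b])


class TestEnrichment:
    def test_identical_tracks_exactly_zero(self):
        a = _rpm_track({("chrI", "+"): np.random.default_rng(1).random(10_000)})
        enr = enrichment_track(a, a)
        for arr in enr.data.values():
            assert (arr == 0.0).all()

    def test_pseudocount_arithmetic(self):
        a = _rpm_track({("chrI", "+"): np.full(10_000, 11.0)})
        b = _rpm_track({("chrI", "+"): np.full(10_000, 3.0)})
        enr = enrichment_track(a, b, pseudocount=5)
        assert enr.get("chrI", "+")[0] == pytest.approx(1.0)  # log2(16/8)

    def test_zero_coverage_is_zero_enrichment(self):
        a, b = _rpm_track({}), _rpm_track({})
        enr = enrichment_track(a, b)
        assert np.isfinite(enr.get("chrI", "+")).all()
        assert (enr.get("chrI", "+") == 0).all()

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = _rpm_track({("chrI", "+"): rng.random(10_000) * 50})
        b = _rpm_track({("chrI", "+"): rng.random(10_000) * 50})
        ab, ba = enrichment_track(a, b), enrichment_track(b, a)
        np.testing.assert_allclose(ab.get("chrI", "+"), -ba.get("chrI", "+"))

    def test_requires_rpm(self, toy_genome):
        raw, _ = build_coverage([seg([(0, 10)])], toy_genome)
        with pytest.raises(ValueError, match="RPM"):
            enrichment_track(raw, raw)

    def test_pseudocount_validation(self):
        with pytest.raises(ValueError, match="pseudocount"):
            enrichment_track(_rpm_track({}), _rpm_track({}), pseudocount=0)


class TestFeatureStats:
    def _reps(self, toy_genome, totals_per_rep, counts_per_rep, libsize=1_000_000):
        reps = []
        for i, (per_feature, counts) in enumerate(zip(totals_per_rep, counts_per_rep)):
            track = CoverageTrack.zeros(toy_genome.chrom_lengths, normalization="rpm",
                                        library_size=libsize)
            for fid, value in per_feature.items():
                f = toy_genome.by_id[fid]
                s, e = f.exons[0]
                track.data[(f.chrom, f.strand)][s] = value  # all signal on one base
            reps.append(Replicate(sample=f"rep{i}", track=track, feature_counts=counts))
        return reps

    def test_cv_zero_passes(self, toy_genome):
        reps = self._reps(toy_genome,
                          [{"mRNA_C": 10.0}] * 3, [{"mRNA_C": 100}] * 3)
        df = feature_stats(reps, toy_genome)
        row = df.loc["mRNA_C"]
        assert row["cv"] == 0.0 and row["passes_cv"]

    def test_rpkm_arithmetic(self, toy_genome):
        # 100 reads on a 500-nt feature at library 1e6 -> RPKM 200
        reps = self._reps(toy_genome, [{"mRNA_C": 5.0}] * 2, [{"mRNA_C": 100}] * 2)
        df = feature_stats(reps, toy_genome)
        assert df.loc["mRNA_C", "rpkm"] == pytest.approx(100 * 1e9 / (1e6 * 500))

    def test_high_cv_fails(self, toy_genome):
        reps = self._reps(
            toy_genome,
            [{"mRNA_C": 1.0}, {"mRNA_C": 10.0}, {"mRNA_C": 100.0}],
            [{"mRNA_C": 1}, {"mRNA_C": 10}, {"mRNA_C": 100}],
        )
        df = feature_stats(reps, toy_genome)
        assert df.loc["mRNA_C", "cv"] == pytest.approx(54.74485 / 37, rel=1e-4)
        assert not df.loc["mRNA_C", "selected"]

    def test_sample_sd_and_strict_threshold(self, toy_genome):
        reps = self._reps(toy_genome,
                          [{"mRNA_C": v} for v in [5.0, 15.0]],
                          [{"mRNA_C": 100}] * 2)
        df = feature_stats(reps, toy_genome)
        cv = np.std([5.0, 15.0], ddof=1) / 10.0  # sample SD, not population
        assert df.loc["mRNA_C", "cv"] == pytest.approx(cv)
        assert not df.loc["mRNA_C", "passes_cv"]  # 0.707 >= 0.5

    def test_needs_two_replicates(self, toy_genome):
        with pytest.raises(ValueError, match="replicates"):
            feature_stats(self._reps(toy_genome, [{}], [{}]), toy_genome)

    def test_exonic_totals_skip_intron(self, toy_genome):
        track = CoverageTrack.zeros(toy_genome.chrom_lengths, normalization="rpm",
                                    library_size=1)
        track.data[("chrI", "+")][1000:2600] = 1.0  # covers intron too
        assert feature_totals(track, toy_genome.by_id["mRNA_A"]) == 1300  # 500+800 exonic


class TestScatterTable:
    def _stats(self, toy_genome, means, selected):
        df = pd.DataFrame({
            "cls": ["mRNA"] * len(means),
            "mean_total": list(means.values()),
            "selected": selected,
        }, index=pd.Index(means.keys(), name="feature_id"))
        return df

    def test_restricted_to_selected_and_enrichment(self, toy_genome):
        a = self._stats(toy_genome, {"f1": 11.0, "f2": 50.0}, [True, False])
        b = self._stats(toy_genome, {"f1": 3.0, "f2": 50.0}, [True, True])
        out = scatter_table(a, b)
        assert list(out.index) == ["f1"]
        assert out.loc["f1", "log2_enrichment"] == pytest.approx(1.0)

    def test_antisymmetry_on_common_features(self, toy_genome):
        a = self._stats(toy_genome, {"f1": 40.0}, [True])
        b = self._stats(toy_genome, {"f1": 10.0}, [True])
        assert scatter_table(a, b).loc["f1", "log2_enrichment"] == pytest.approx(
            -scatter_table(b, a).loc["f1", "log2_enrichment"]
        )

    def test_missing_feature_is_error(self, toy_genome):
        a = self._stats(toy_genome, {"f1": 1.0}, [True])
        b = self._stats(toy_genome, {"f2": 1.0}, [True])
        with pytest.raises(ValueError, match="f1"):
            scatter_table(a, b)


def test_bedgraph_runs(tmp_path, toy_genome):
    track, _ = build_coverage(
        [seg([(100, 130)]), seg([(110, 140)], tag="T")], toy_genome
    )
    write_bedgraph(track, tmp_path / "x")
    lines = (tmp_path / "x.plus.bedgraph").read_text().splitlines()
    assert lines == ["chrI\t100\t110\t1", "chrI\t110\t130\t2", "chrI\t130\t140\t1"]
    assert (tmp_path / "x.minus.bedgraph").read_text() == ""
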