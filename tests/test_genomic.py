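"""Interval algebra for the feature universe, checked against a
per-base boolean oracle on toy chromosomes."""

import numpy as np
import pandas as pd
import pytest

from xcikin import genomic

CHROM_SIZE = 100_000


def as_bool_array(intervals, size=CHROM_SIZE, chrom="chr1"):
    """Per-base occupancy oracle for single-chromosome toy data."""
    arr = np.zeros(size, dtype=bool)
    for _, row in intervals.iterrows():
        if str(row["chrom"]) == chrom:
            arr[int(row["start"]): int(row["end"])] = True
    return arr


def iv(*triples):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e in triples]
    )


class TestReaders:
    def test_read_bed_minimal(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\npeak2\t0\t50\n".replace("peak2", "chr2"))
        df = genomic.read_bed(p)
        assert len(df) == 2
        assert df.loc[0, "start"] == 100 and df.loc[0, "end"] == 200

    def test_read_bed_invalid_interval_raises(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t300\t200\n")
        with pytest.raises(ValueError, match="start < end"):
            genomic.read_bed(p)

    def test_read_refflat_strand_aware_tss(self, tmp_path):
        p = tmp_path / "ann.refFlat"
        rows = [
            "geneA\ttxA\tchr1\t+\t1000\t5000\t1000\t5000\t2\t1000,3000,\t2000,5000,",
            "geneB\ttxB\tchr1\t-\t8000\t9000\t8000\t9000\t1\t8000,\t9000,",
        ]
        p.write_text("\n".join(rows) + "\n")
        tx = genomic.read_refflat(p)
        assert tx.loc[tx["gene"] == "geneA", "tss"].iloc[0] == 1000
        assert tx.loc[tx["gene"] == "geneB", "tss"].iloc[0] == 8999  # minus strand


class TestConsensusPeaks:
    def test_identical_replicates_give_the_set(self):
        peaks = iv(("chr1", 100, 500), ("chr1", 2000, 2600))
        out = genomic.consensus_peaks([peaks, peaks.copy()])
        np.testing.assert_array_equal(
            as_bool_array(out), as_bool_array(peaks)
        )

    def test_disjoint_replicates_empty_intersection(self):
        a = iv(("chr1", 0, 100))
        b = iv(("chr1", 200, 300))
        out = genomic.consensus_peaks([a, b])
        assert len(out) == 0

    def test_fold_change_filter_applied_first(self):
        a = iv(("chr1", 0, 100), ("chr1", 200, 300))
        b = iv(("chr1", 0, 100), ("chr1", 200, 300))
        out = genomic.consensus_peaks([a, b], fc_values=[[5.0, 2.0], [5.0, 5.0]])
        # the fc<3 peak in replicate 1 drops out of the consensus
        np.testing.assert_array_equal(as_bool_array(out), as_bool_array(iv(("chr1", 0, 100))))

    def test_k_of_n_matches_per_base_oracle(self):
        sets = [
            iv(("chr1", 0, 5000)),
            iv(("chr1", 3000, 8000)),
            iv(("chr1", 4000, 10_000)),
        ]
        out = genomic.consensus_peaks(sets, mode="k_of_n", k=2)
        coverage = np.zeros(CHROM_SIZE, dtype=int)
        for s in sets:
            coverage += as_bool_array(s).astype(int)
        np.testing.assert_array_equal(as_bool_array(out), coverage >= 2)

    def test_intersect_is_subset_of_every_replicate(self):
        rng = np.random.default_rng(0)
        sets = []
        for _ in range(3):
            starts = np.sort(rng.integers(0, CHROM_SIZE - 600, 25))
            sets.append(
                iv(*[("chr1", int(s), int(s + rng.integers(100, 500))) for s in starts])
            )
        out = genomic.consensus_peaks(sets)
        cons = as_bool_array(out)
        for s in sets:
            assert not (cons & ~as_bool_array(genomic.consensus_peaks([s]))).any()


@pytest.fixture()
def toy_annotation(tmp_path):
    rows = [
        "geneA\ttxA1\tchr1\t+\t10000\t50000\t10000\t50000\t1\t10000,\t50000,",
        "geneA\ttxA2\tchr1\t+\t11000\t52000\t11000\t52000\t1\t11000,\t52000,",
        "geneB\ttxB\tchr1\t-\t70000\t80000\t70000\t80000\t1\t70000,\t80000,",
        "geneC\ttxC\tchr1\t+\t90000\t95000\t90000\t95000\t1\t90000,\t95000,",
    ]
    p = tmp_path / "ann.refFlat"
    p.write_text("\n".join(rows) + "\n")
    return genomic.read_refflat(p)


class TestActiveGenes:
    def test_needs_both_marks(self, toy_annotation):
        k9 = iv(("chr1", 9500, 10_500), ("chr1", 89_000, 91_000))
        k4 = iv(("chr1", 9800, 10_200), ("chr1", 79_500, 80_500))
        genes = genomic.define_active_genes(toy_annotation, k9, k4)
        # geneA TSS 10000 in both; geneB TSS 79999 only in k4; geneC only in k9
        assert genes["gene"].tolist() == ["geneA"]

    def test_union_span_over_active_transcripts(self, toy_annotation):
        k9 = iv(("chr1", 9000, 12_000))
        k4 = iv(("chr1", 9000, 12_000))
        genes = genomic.define_active_genes(toy_annotation, k9, k4)
        row = genes.iloc[0]
        assert (row["start"], row["end"]) == (10_000, 52_000)  # min start, max end


class TestDefineFeatures:
    def _active(self, strand="+"):
        if strand == "+":
            return pd.DataFrame(
                [{"gene": "g", "chrom": "chr1", "start": 10_000, "end": 50_000,
                  "strand": "+"}]
            )
        return pd.DataFrame(
            [{"gene": "g", "chrom": "chr1", "start": 10_000, "end": 50_000,
              "strand": "-"}]
        )

    def test_promoter_is_tss_plus_minus_2kb(self):
        feats = genomic.define_features(self._active())
        p = feats["promoters"].iloc[0]
        assert (p["start"], p["end"]) == (8_000, 12_000)

    def test_gene_body_skips_first_2kb(self):
        feats = genomic.define_features(self._active())
        b = feats["gene_bodies"].iloc[0]
        assert (b["start"], b["end"]) == (12_000, 50_000)

    def test_minus_strand_mirror_symmetry(self):
        feats = genomic.define_features(self._active("-"))
        p = feats["promoters"].iloc[0]
        b = feats["gene_bodies"].iloc[0]
        # TSS at end-1 = 49,999
        assert (p["start"], p["end"]) == (47_999, 51_999)
        assert (b["start"], b["end"]) == (10_000, 48_000)

    def test_enhancer_requires_1kb_tss_clearance(self):
        active = self._active()
        tx = pd.DataFrame(
            [{"gene": "g", "transcript": "t", "chrom": "chr1", "strand": "+",
              "tx_start": 10_000, "tx_end": 50_000, "tss": 10_000}]
        )
        k27 = iv(("chr1", 10_400, 10_700), ("chr1", 60_000, 61_000))
        k4me1 = iv(("chr1", 10_300, 10_800), ("chr1", 60_200, 61_500))
        feats = genomic.define_features(
            active, transcripts=tx, h3k27ac_consensus=k27, h3k4me1_consensus=k4me1
        )
        enh = feats["enhancers"]
        # overlap at 10,400-10,700 sits < 1 kb from the TSS: rejected
        assert len(enh) == 1
        assert (enh.iloc[0]["start"], enh.iloc[0]["end"]) == (60_200, 61_000)

    def test_intergenic_windows_never_touch_genes_promoters_enhancers(self):
        active = self._active()
        k27 = iv(("chr1", 60_000, 61_000))
        k4me1 = iv(("chr1", 60_200, 61_500))
        feats = genomic.define_features(
            active, h3k27ac_consensus=k27, h3k4me1_consensus=k4me1,
            chrom_sizes={"chr1": CHROM_SIZE},
        )
        wins = feats["intergenic_windows"]
        assert len(wins) > 0
        occupied = (
            as_bool_array(feats["promoters"])
            | as_bool_array(pd.DataFrame(
                {"chrom": active["chrom"], "start": active["start"], "end": active["end"]}
            ))
            | as_bool_array(feats["enhancers"])
        )
        assert not (as_bool_array(wins) & occupied).any()


class TestTileWindows:
    def test_truncated_last_window(self):
        w = genomic.tile_windows({"chr1": 25_000}, width=10_000)
        assert w["end"].tolist() == [10_000, 20_000, 25_000]

    def test_partition_no_gaps_no_overlaps(self):
        w = genomic.tile_windows({"chr1": 95_001}, width=10_000)
        arr = np.zeros(95_001, dtype=int)
        for _, row in w.iterrows():
            arr[row["start"]: row["end"]] += 1
        assert (arr == 1).all()

    def test_nonpositive_width_raises(self):
        with pytest.raises(ValueError, match="width"):
            genomic.tile_windows({"chr1": 1000}, width=0)


class TestAnnotateDistances:
    def test_feature_on_anchor_distance_zero(self):
        feats = iv(("chr1", 5_000, 5_200))
        anchors = {"xist": iv(("chr1", 4_000, 6_000))}
        out = genomic.annotate_distances(feats, anchors=anchors)
        assert out["dist_xist"].iloc[0] == 0

    def test_empty_anchor_set_gives_missing(self):
        feats = iv(("chr1", 5_000, 5_200))
        out = genomic.annotate_distances(
            feats, anchors={"lad": pd.DataFrame(columns=["chrom", "start", "end"])}
        )
        assert np.isnan(out["dist_lad"].iloc[0])

    def test_density_matches_per_base_oracle(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.integers(0, CHROM_SIZE - 2000, 40))
        lines = iv(*[("chr1", int(s), int(s + rng.integers(200, 1500))) for s in starts])
        feats = iv(("chr1", 49_900, 50_100), ("chr1", 10_000, 10_200))
        out = genomic.annotate_distances(feats, densities={"line": lines}, window=20_000)
        occ = as_bool_array(lines)
        for i, (_, f) in enumerate(feats.iterrows()):
            mid = (f["start"] + f["end"]) // 2
            lo, hi = max(mid - 10_000, 0), mid + 10_000
            expected = occ[lo:hi].sum() / (hi - lo)
            assert out["density_line"].iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_entry_site_proximity_flag(self):
        feats = iv(("chr1", 5_000, 5_200), ("chr1", 90_000, 90_200))
        anchors = {"entry_site": iv(("chr1", 0, 1_000))}
        out = genomic.annotate_distances(feats, anchors=anchors, proximity=100_000)
        assert bool(out["near_entry_site"].iloc[0])
        # second feature ~89 kb away: still proximal under the 100-kb rule
        assert bool(out["near_entry_site"].iloc[1])
        out2 = genomic.annotate_distances(feats, anchors=anchors, proximity=50_000)
        assert not bool(out2["near_entry_site"].iloc[1])


class TestPeakContext:
    def _tx(self):
        return pd.DataFrame(
            [{"gene": "g", "transcript": "t", "chrom": "chr1", "strand": "+",
              "tx_start": 20_000, "tx_end": 60_000, "tss": 20_000}]
        )

    def _bodies(self):
        return pd.DataFrame(
            [{"gene": "g", "chrom": "chr1", "start": 22_000, "end": 60_000,
              "strand": "+"}]
        )

    def test_promoter_within_2kb_of_tss(self):
        peaks = iv(("chr1", 18_600, 18_900))  # 1,100 bp upstream of TSS
        out = genomic.annotate_peak_context(peaks, self._tx(), self._bodies())
        assert out["context"].iloc[0] == "promoter"

    def test_intragenic_peak_inside_body(self):
        peaks = iv(("chr1", 25_000, 25_400))  # 5 kb into the gene
        out = genomic.annotate_peak_context(peaks, self._tx(), self._bodies())
        assert out["context"].iloc[0] == "intragenic"

    def test_isolated_peak_intergenic(self):
        peaks = iv(("chr1", 90_000, 90_400))
        out = genomic.annotate_peak_context(peaks, self._tx(), self._bodies())
        assert out["context"].iloc[0] == "intergenic"
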