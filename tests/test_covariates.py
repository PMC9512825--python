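import numpy as np
import pandas as pd
import pytest

from breakclust.covariates import (CHROMATIN_STATES, annotate_breakpoints,
                                   classify_tad_segments, gc_content,
                                   gene_density, segment_tads_by_recurrence,
                                   tad_boundaries, tad_recurrence)
from breakclust.io import IntervalTrack


def tads(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestTadRecurrence:
    def test_identical_in_all_samples_is_one(self):
        q = tads(("chr1", 0, 1_000_000))
        sets = [q.copy() for _ in range(37)]
        assert tad_recurrence(sets, q)[0] == 1.0

    def test_singleton_tad(self):
        q = tads(("chr1", 0, 1_000_000))
        sets = [q.copy()] + [tads(("chr1", 5_000_000, 6_000_000))
                             for _ in range(36)]
        assert tad_recurrence(sets, q)[0] == pytest.approx(1 / 37)

    def test_exact_seventy_percent_boundary(self):
        # query of 1 Mb; staggered sample TADs overlapping exactly 700 kb
        q = tads(("chr1", 1_000_000, 2_000_000))
        exact = tads(("chr1", 1_300_000, 2_300_000))      # 700 kb overlap
        under = tads(("chr1", 1_300_001, 2_300_001))      # 699.999 kb
        sets = [exact] * 5 + [under] * 5
        assert tad_recurrence(sets, q)[0] == pytest.approx(0.5)

    def test_monotone_in_overlap_threshold(self, rng):
        q = tads(("chr1", 0, 2_000_000))
        sets = [tads(("chr1", int(rng.integers(0, 1_500_000)), 2_000_000))
                for _ in range(20)]
        r_strict = tad_recurrence(sets, q, overlap_fraction=0.9)[0]
        r_loose = tad_recurrence(sets, q, overlap_fraction=0.5)[0]
        assert r_loose >= r_strict

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            tad_recurrence([], tads(("chr1", 0, 10)))


class TestSegmentation:
    def test_nested_tads_give_three_segments(self):
        q = tads(("chr1", 0, 3_000_000), ("chr1", 1_000_000, 2_000_000))
        q["recurrence"] = [0.4, 0.8]
        seg = segment_tads_by_recurrence(q)
        assert len(seg) == 3
        assert seg["recurrence"].tolist() == [0.4, 0.8, 0.4]

    def test_disjoint_tads_pass_through(self):
        q = tads(("chr1", 0, 10), ("chr1", 20, 30))
        q["recurrence"] = [0.5, 0.5]
        seg = segment_tads_by_recurrence(q)
        assert seg[["start", "end"]].values.tolist() == [[0, 10], [20, 30]]

    def test_boundaries_are_subset_of_endpoints_and_cover_union(self, rng):
        rows = []
        for _ in range(20):
            s = int(rng.integers(0, 9_000_000))
            rows.append(("chr1", s, s + int(rng.integers(100_000, 2_000_000))))
        q = tads(*rows)
        q["recurrence"] = rng.random(len(q)).round(2)
        seg = segment_tads_by_recurrence(q)
        endpoints = set(q["start"]) | set(q["end"])
        assert set(seg["start"]).issubset(endpoints)
        assert set(seg["end"]).issubset(endpoints)
        # segments are disjoint, sorted, and cover exactly the union
        assert (seg["start"].to_numpy()[1:] >= seg["end"].to_numpy()[:-1]).all()
        total = sum(e - s for s, e in zip(seg["start"], seg["end"]))
        # exact union length by merging sorted intervals
        merged, union = [], 0
        for s, e in sorted(zip(q["start"], q["end"])):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        union = sum(e - s for s, e in merged)
        assert total == union


class TestClassification:
    def _track(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        return IntervalTrack(name="ChromMark", kind="factor", data=df,
                             levels=CHROMATIN_STATES)

    def test_pure_quiescent_and_active_segments(self):
        seg = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 100],
                            "end": [100, 200]})
        track = self._track([("chr1", 0, 100, "Quies"),
                             ("chr1", 100, 200, "TssA")])
        labels = classify_tad_segments(seg, track)
        assert list(labels) == ["quiescent", "active"]

    def test_planted_three_cluster_recovery(self, rng):
        # 60 segments with three well-separated chromatin profiles
        from sklearn.metrics import adjusted_rand_score
        rows, segs, truth = [], [], []
        pos = 0
        profiles = {"quiescent": "Quies", "active": "TssA", "low-active": "TxWk"}
        for i in range(60):
            lab = ["quiescent", "active", "low-active"][i % 3]
            length = 100_000
            state = profiles[lab]
            rows.append(("chr1", pos, pos + length, state))
            segs.append(("chr1", pos, pos + length))
            truth.append(lab)
            pos += length
        track = self._track(rows)
        seg = pd.DataFrame(segs, columns=["chrom", "start", "end"])
        labels = classify_tad_segments(seg, track, random_state=0)
        assert adjusted_rand_score(truth, list(labels)) > 0.95
        # label semantics also recovered
        assert labels[0] == "quiescent" and labels[1] == "active"


class TestGCContent:
    def test_all_g_window(self):
        fasta = {"chr1": "G" * 300}
        assert gc_content(fasta, "chr1", [150])[0] == 1.0

    def test_alternating_ac(self):
        fasta = {"chr1": "AC" * 200}
        assert gc_content(fasta, "chr1", [200])[0] == pytest.approx(0.5, abs=0.01)

    def test_matches_counting_oracle(self, rng, tmp_path):
        import pyfaidx
        seq = "".join(rng.choice(list("ACGTN"), size=1000))
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\n{seq}\n")
        fasta = pyfaidx.Fasta(str(fa))
        pos = 500
        window = seq[pos - 50:pos + 51].upper()
        gc = window.count("G") + window.count("C")
        acgt = gc + window.count("A") + window.count("T")
        assert gc_content(fasta, "chr1", [pos])[0] == pytest.approx(gc / acgt)

    def test_all_n_window_is_missing(self):
        fasta = {"chr1": "N" * 300}
        assert np.isnan(gc_content(fasta, "chr1", [150])[0])


class TestGeneDensity:
    def test_empty_annotation(self):
        genes = pd.DataFrame(columns=["chrom", "start", "end", "gene_symbol"])
        assert gene_density(genes, "chr1", [500_000])[0] == 0

    def test_five_genes_in_bin(self):
        genes = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(5) * 100_000,
                              "end": np.arange(5) * 100_000 + 50_000,
                              "gene_symbol": [f"G{i}" for i in range(5)]})
        assert gene_density(genes, "chr1", [500_000])[0] == 5

    def test_gene_spanning_two_bins_counts_in_both(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [900_000],
                              "end": [1_100_000], "gene_symbol": ["G"]})
        assert gene_density(genes, "chr1", [500_000])[0] == 1
        assert gene_density(genes, "chr1", [1_500_000])[0] == 1


class TestAnnotate:
    def test_point_lookups_and_reference_levels(self):
        bp = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [50, 150, 250],
                           "donor_id": "D", "sv_id": ["a", "b", "c"]})
        fs = IntervalTrack("FS", "binary", pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "value": [1]}))
        cov = annotate_breakpoints(bp, {"FS": fs})
        assert cov["FS"].tolist() == [1, 0, 0]
        assert cov["LAD"].tolist() == [0, 0, 0]       # no track: reference
        assert (cov["repClass"] == "none").all()

    def test_lookup_matches_linear_scan_oracle(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 10**6, 1000), 50, replace=False))
        ends = starts + rng.integers(100, 900, size=50)
        vals = rng.random(50).round(3)
        track = IntervalTrack("RT", "numeric", pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": ends, "value": vals}))
        pos = rng.integers(0, 10**6, size=1000)
        got = track.lookup("chr1", pos, default=np.nan).astype(float)
        for p, g in zip(pos, got):
            hit = [v for s, e, v in zip(starts, ends, vals) if s <= p < e]
            if hit:
                assert g == hit[0]
            else:
                assert np.isnan(g)

    def test_tad_boundaries_have_requested_width(self):
        b = tad_boundaries(tads(("chr1", 1_000_000, 2_000_000)), width=50_000)
        assert ((b["end"] - b["start"]) == 50_000).all()
        assert len(b) == 2
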