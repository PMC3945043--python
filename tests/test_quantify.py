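"""Counting, regulation thresholds, GSEA pre-ranking, metagene profiles."""

import numpy as np
import pandas as pd
import pytest

from nascentscan.hmm import TranscriptUnit
from nascentscan.intervals import GenomicInterval
from nascentscan.quantify import (
    apply_regulation_threshold,
    build_gsea_ranking,
    count_in_intervals,
    metagene,
)


def unit(chrom, start, end, strand, name):
    iv = GenomicInterval(chrom, start, end, strand, name)
    return TranscriptUnit(iv, 1.0, name)


def read(chrom, start, end, strand):
    return GenomicInterval(chrom, start, end, strand)


class TestCountInIntervals:
    UNITS = [unit("c", 1000, 2000, "+", "u1"), unit("c", 3000, 4000, "+", "u2"),
             unit("c", 1000, 2000, "-", "u3")]

    def test_same_strand_5prime_containment(self):
        reads = [read("c", 1100, 1150, "+"), read("c", 1500, 1550, "+"),
                 read("c", 1999, 2050, "+")]
        counts = count_in_intervals(reads, self.UNITS)
        assert counts["u1"] == 3 and counts["u2"] == 0

    def test_strand_mismatch_not_counted(self):
        counts = count_in_intervals([read("c", 1100, 1150, "-")], self.UNITS)
        # minus read 5' end is 1149, inside u3 but not u1
        assert counts["u1"] == 0 and counts["u3"] == 1

    def test_read_straddling_boundary_uses_5prime(self):
        counts = count_in_intervals([read("c", 950, 1050, "+")], self.UNITS)
        assert counts.sum() == 0  # 5' end 950 lies outside every unit

    def test_overlapping_units_rejected(self):
        bad = self.UNITS + [unit("c", 1500, 2500, "+", "u4")]
        with pytest.raises(ValueError, match="overlap"):
            count_in_intervals([], bad)

    def test_column_sums_invariant_under_unit_permutation(self):
        rng = np.random.default_rng(0)
        reads = [read("c", int(p), int(p) + 40, "+")
                 for p in rng.integers(0, 5000, 300)]
        a = count_in_intervals(reads, self.UNITS)
        b = count_in_intervals(reads, self.UNITS[::-1])
        assert a.sum() == b.sum()
        assert a.sort_index().equals(b.sort_index())


class TestRegulationThreshold:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["id", "lfc", "p", "q"])

    def test_strict_q_cutoff(self):
        t = self._table([("a", 1.0, 1e-5, 0.0005), ("b", 1.0, 1e-3, 0.001)])
        out = apply_regulation_threshold(t)
        assert list(out["regulated"]) == [True, False]  # q == cutoff fails

    def test_direction_from_lfc_sign(self):
        t = self._table([("a", -2.0, 1e-6, 1e-5)])
        out = apply_regulation_threshold(t)
        assert out.loc[0, "direction"] == "down"

    def test_q_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            apply_regulation_threshold(self._table([("a", 1.0, 0.5, 1.5)]))


class TestGseaRanking:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["id", "lfc", "p", "q"])

    def test_three_block_layout(self):
        t = self._table([
            ("A", 2.0, 1e-6, 1e-4),
            ("B", -1.0, 1e-6, 1e-4),
            ("C", 0.1, 0.4, 0.5),
        ])
        assert build_gsea_ranking(t) == ["A", "C", "B"]

    def test_all_significant_up_is_descending_lfc(self):
        t = self._table([(g, lfc, 1e-9, 1e-8)
                         for g, lfc in [("a", 1.0), ("b", 3.0), ("c", 2.0)]])
        assert build_gsea_ranking(t) == ["b", "c", "a"]

    def test_middle_blocks_order_by_p(self):
        t = self._table([
            ("up_strong", 0.5, 0.01, 0.1),
            ("up_weak", 0.5, 0.50, 0.6),
            ("dn_weak", -0.5, 0.50, 0.6),
            ("dn_strong", -0.5, 0.01, 0.1),
        ])
        assert build_gsea_ranking(t) == [
            "up_strong", "up_weak", "dn_weak", "dn_strong"]

    def test_empty_table_gives_empty_list(self):
        assert build_gsea_ranking(self._table([])) == []

    def test_output_is_a_permutation_of_input(self):
        rng = np.random.default_rng(1)
        n = 200
        t = pd.DataFrame({
            "id": [f"g{i}" for i in range(n)],
            "lfc": rng.normal(size=n),
            "p": rng.uniform(size=n),
            "q": rng.uniform(size=n),
        })
        out = build_gsea_ranking(t)
        assert sorted(out) == sorted(t["id"])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="'p'"):
            build_gsea_ranking(pd.DataFrame({"id": [], "lfc": [], "q": []}))


class TestMetagene:
    def test_read_downstream_of_plus_anchor(self):
        profiles = metagene([read("c", 5010, 5060, "+")],
                            [("c", 5000, "+")], flank=100, bin=25)
        p = profiles["sense"]
        assert p.mean_density[list(p.offsets).index(0)] == 1.0
        assert p.mean_density.sum() == 1.0

    def test_minus_anchor_mirrors_offsets(self):
        # same strand-relative geometry: read 5' end 10 bp downstream
        profiles = metagene([read("c", 4941, 4991, "-")],  # 5' end 4990
                            [("c", 5000, "-")], flank=100, bin=25)
        p = profiles["sense"]
        assert p.mean_density[list(p.offsets).index(0)] == 1.0

    def test_strand_mirror_symmetry_is_exact(self):
        rng = np.random.default_rng(2)
        C = 100_000
        reads, anchors = [], [("c", 20_000, "+"), ("c", 50_000, "+")]
        for pos in rng.integers(0, C - 200, 2000):
            reads.append(read("c", int(pos), int(pos) + 50, "+"))
        fwd = metagene(reads, anchors, flank=2000, bin=25)
        mirrored_reads = [
            GenomicInterval("c", C - 1 - r.end + 1, C - 1 - r.start + 1, "-")
            for r in reads
        ]
        mirrored_anchors = [("c", C - 1 - pos, "-") for _, pos, _ in anchors]
        rev = metagene(mirrored_reads, mirrored_anchors, flank=2000, bin=25)
        assert np.array_equal(fwd["sense"].mean_density,
                              rev["sense"].mean_density)
        assert np.array_equal(fwd["antisense"].mean_density,
                              rev["antisense"].mean_density)

    def test_unstranded_profile_combines_strands(self):
        reads = [read("c", 5010, 5060, "+"), read("c", 4941, 4991, "-")]
        profiles = metagene(reads, [("c", 5000, "+")], flank=100, bin=25,
                            stranded=False)
        assert set(profiles) == {"combined"}
        assert profiles["combined"].mean_density.sum() == 2.0

    def test_flank_must_be_bin_multiple(self):
        with pytest.raises(ValueError, match="multiple"):
            metagene([], [("c", 0, "+")], flank=110, bin=25)

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError, match="anchors"):
            metagene([], [], flank=100, bin=25)
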