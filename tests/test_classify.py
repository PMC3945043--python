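"""Functional classification: the eight rules, their thresholds and precedence."""

import random

import pytest

from nascentscan.classify import ClassifierConfig, classify, classify_all
from nascentscan.enhancers import pair_ernas
from nascentscan.hmm import TranscriptUnit
from nascentscan.intervals import AnnotationSet, GenomicInterval, overlap_fraction


def unit(chrom, start, end, strand, name=None):
    iv = GenomicInterval(chrom, start, end, strand, name or f"{chrom}:{start}")
    return TranscriptUnit(iv, 1.0, iv.name)


class TestOverlapFraction:
    def test_half_overlap(self):
        a = GenomicInterval("c", 0, 100)
        b = GenomicInterval("c", 50, 150)
        assert overlap_fraction(a, b) == 0.5

    def test_disjoint_and_cross_chromosome_are_zero(self):
        a = GenomicInterval("c", 0, 100)
        assert overlap_fraction(a, GenomicInterval("c", 200, 300)) == 0.0
        assert overlap_fraction(a, GenomicInterval("d", 0, 100)) == 0.0

    def test_containment_is_one(self):
        a = GenomicInterval("c", 10, 20)
        assert overlap_fraction(a, GenomicInterval("c", 0, 100)) == 1.0


def eight_class_fixture():
    """One canonical, non-boundary instance of each functional class.

    Each case lives on its own chromosome so the rules cannot interact.
    """
    ann = AnnotationSet()
    units = []
    expected = {}

    # protein_coding: full overlap with a coding gene, same strand
    ann.add(GenomicInterval("c1", 0, 5000, "+", "PC1"), "protein_coding")
    units.append(unit("c1", 0, 1000, "+", "t_pc"))
    expected["t_pc"] = "protein_coding"

    # non_coding: any same-strand overlap with an ncRNA gene
    ann.add(GenomicInterval("c2", 1000, 1100, "+", "TRNA1"), "short_ncRNA:tRNA")
    units.append(unit("c2", 1050, 1800, "+", "t_nc"))
    expected["t_nc"] = "non_coding"

    # divergent: antisense unit covering the promoter of a called 3-kb primary
    ann.add(GenomicInterval("c3", 500, 3500, "+", "PC2"), "protein_coding")
    units.append(unit("c3", 500, 3500, "+", "t_primary"))
    expected["t_primary"] = "protein_coding"
    units.append(unit("c3", 0, 400, "-", "t_div"))
    expected["t_div"] = "divergent"

    # antisense: unit covering half of a 2-kb coding gene, opposite strand
    ann.add(GenomicInterval("c4", 0, 2000, "+", "PC3"), "protein_coding")
    units.append(unit("c4", 0, 1000, "-", "t_as"))
    expected["t_as"] = "antisense"

    # repeat: 75% of the unit inside RepeatMasker regions, no gene near
    ann.add(GenomicInterval("c5", 100, 400, ".", "ALU1"), "repeat")
    ann.add(GenomicInterval("c5", 400, 850, ".", "L1_1"), "repeat")
    units.append(unit("c5", 100, 1100, "+", "t_rep"))
    expected["t_rep"] = "repeat"

    # intergenic: nothing anywhere near
    units.append(unit("c6", 10_000, 13_000, "+", "t_ig"))
    expected["t_ig"] = "intergenic"

    # eRNA: short overlapping opposite-strand pair in open space
    units.append(unit("c7", 1000, 3000, "+", "t_erna_p"))
    units.append(unit("c7", 500, 2500, "-", "t_erna_m"))
    expected["t_erna_p"] = expected["t_erna_m"] = "eRNA"

    # other_genic: touches a silent gene but only 10% of the unit matches
    ann.add(GenomicInterval("c8", 0, 3000, "+", "PC4"), "protein_coding")
    units.append(unit("c8", 2800, 4800, "+", "t_og"))
    expected["t_og"] = "other_genic"

    return units, ann, expected


class TestEightClasses:
    def test_each_canonical_instance_gets_its_class(self):
        units, ann, expected = eight_class_fixture()
        classified, counts = classify_all(units, ann)
        pair_ernas([ct for ct in classified if ct.cls == "intergenic"])
        got = {ct.unit.id: ct.cls for ct in classified}
        assert got == expected
        assert sum(counts.values()) == len(units)

    def test_order_independence_of_annotations(self):
        units, ann, expected = eight_class_fixture()
        rng = random.Random(0)
        for _ in range(3):
            shuffled = AnnotationSet(list(ann))
            rng.shuffle(shuffled.genes)
            classified, _ = classify_all(units, shuffled)
            pair_ernas([ct for ct in classified if ct.cls == "intergenic"])
            assert {ct.unit.id: ct.cls for ct in classified} == expected

    def test_empty_input(self):
        classified, counts = classify_all([], AnnotationSet())
        assert classified == [] and sum(counts.values()) == 0


class TestBoundaries:
    """The published thresholds are strict inequalities."""

    def test_exactly_20_percent_coding_overlap_is_not_protein_coding(self):
        ann = AnnotationSet()
        ann.add(GenomicInterval("c", 800, 5000, "+", "G"), "protein_coding")
        ct = classify(unit("c", 0, 1000, "+"), ann, [])
        assert ct.cls == "other_genic"  # 200/1000 == 0.20, not > 0.20

    def test_just_above_20_percent_is_protein_coding(self):
        ann = AnnotationSet()
        ann.add(GenomicInterval("c", 799, 5000, "+", "G"), "protein_coding")
        ct = classify(unit("c", 0, 1000, "+"), ann, [])
        assert ct.cls == "protein_coding"

    def test_below_threshold_overlap_is_other_genic_never_intergenic(self):
        ann = AnnotationSet()
        ann.add(GenomicInterval("c", 950, 5000, "+", "G"), "protein_coding")
        ct = classify(unit("c", 0, 1000, "+"), ann, [])
        assert ct.cls == "other_genic"

    def test_exactly_50_percent_repeat_overlap_is_not_repeat(self):
        ann = AnnotationSet()
        ann.add(GenomicInterval("c", 500, 1000, ".", "R"), "repeat")
        ct = classify(unit("c", 0, 1000, "+"), ann, [])
        assert ct.cls == "intergenic"  # repeats are not genes

    def test_divergent_size_ratio_is_strict(self):
        ann = AnnotationSet()
        ann.add(GenomicInterval("c", 500, 2500, "+", "G"), "protein_coding")
        primary = unit("c", 500, 2500, "+", "prim")  # 2000 bp
        # candidate exactly 50% of the primary: rule must not fire
        ct = classify(unit("c", 0, 1000, "-"), ann, [primary])
        assert ct.cls != "divergent"
        # shorter candidate passes
        ct = classify(unit("c", 0, 900, "-"), ann, [primary])
        assert ct.cls == "divergent"

    def test_noncoding_rule_has_no_size_or_quality_restriction(self):
        ann = AnnotationSet()
        ann.add(GenomicInterval("c", 0, 80, "+", "MIR1"), "short_ncRNA:miRNA")
        ct = classify(unit("c", 79, 9000, "+"), ann, [])  # 1-bp overlap
        assert ct.cls == "non_coding"


class TestConfigValidation:
    def test_fraction_thresholds_must_be_proper(self):
        with pytest.raises(ValueError):
            ClassifierConfig(protein_overlap_min=1.5)
        with pytest.raises(ValueError):
            ClassifierConfig(divergent_primary_min_len=0)
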