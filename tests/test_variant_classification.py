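"""Hard filtering, uniform/non-uniform classification and indel spacing."""

import pytest

from strainref.genomic_io import VariantRecord
from strainref.variant_classification import (
    ClassificationThresholds,
    HardFilterThresholds,
    classify_nonuniform,
    classify_uniform,
    downsample_classify,
    exclude_snps_overlapping_indels,
    hard_filter,
    indel_ref_span,
    remove_nearby_indels,
)

PASSING_ANN = {
    "QD": 20.0,
    "SOR": 1.0,
    "FS": 5.0,
    "MQ": 55.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
}


def site(
    pos=100,
    ref="A",
    alts=("G",),
    ac=(10,),
    an=10,
    qual=500.0,
    ann=None,
    contig="c1",
    genotypes=(),
):
    ac = list(ac)
    return VariantRecord(
        contig=contig,
        pos=pos,
        ref_allele=ref,
        alt_alleles=list(alts),
        qual=qual,
        site_annotations=dict(PASSING_ANN if ann is None else ann),
        genotypes=list(genotypes),
        ac=ac,
        an=an,
        af=[c / an for c in ac],
    )


class TestHardFilter:
    @pytest.mark.parametrize(
        "overrides,expect_pass",
        [
            ({}, True),
            ({"QD": 1.9}, False),
            ({"QD": 2.0}, True),  # strict <: the boundary passes
            ({"SOR": 3.1}, False),
            ({"SOR": 3.0}, True),
            ({"FS": 60.5}, False),
            ({"MQ": 39.9}, False),
            ({"MQRankSum": -13.0}, False),
            ({"ReadPosRankSum": -8.5}, False),
        ],
    )
    def test_snp_rules_fire_strictly(self, overrides, expect_pass):
        rec = site(ann={**PASSING_ANN, **overrides})
        passed, failed = hard_filter([rec], variant_class="snp")
        assert bool(passed) is expect_pass
        assert passed + failed == [rec]

    def test_low_qual_fails(self):
        passed, failed = hard_filter([site(qual=29.9)], variant_class="snp")
        assert not passed and len(failed) == 1

    def test_indel_rule_set(self):
        bad = site(ann={"QD": 20.0, "FS": 150.0, "ReadPosRankSum": -25.0})
        ok = site(ann={"QD": 20.0, "FS": 150.0, "ReadPosRankSum": -5.0})
        passed, failed = hard_filter([bad, ok], variant_class="indel")
        assert passed == [ok] and failed == [bad]
        # FS=150 passes the indel cutoff (200) but fails the SNP one (60)
        assert hard_filter([ok], variant_class="snp")[0] == []

    def test_missing_annotation_skips_subfilter(self):
        rec = site(ann={"QD": 20.0})  # no MQRankSum etc.
        passed, _ = hard_filter([rec], variant_class="snp")
        assert passed == [rec]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="variant class"):
            hard_filter([], variant_class="sv")


class TestClassification:
    def test_fixed_difference_is_uniform(self):
        assert classify_uniform([site(ac=[10])]) == [site(ac=[10])]

    def test_ac_boundary_is_strict(self):
        # af=0.82 passes but ac=5 is not > 5
        rec = site(ac=[5], an=6)
        rec.af = [0.82]
        assert classify_uniform([rec]) == []

    def test_triallelic_never_uniform(self):
        rec = site(alts=("G", "T"), ac=(9, 1), an=10)
        assert classify_uniform([rec]) == []

    def test_balanced_biallelic_is_nonuniform(self):
        rec = site(ac=[5], an=10)
        assert classify_nonuniform([rec]) == [rec]

    def test_af_lower_boundary_is_strict(self):
        rec = site(ac=[2], an=10)  # af = 0.2 exactly
        assert classify_nonuniform([rec]) == []

    def test_af_equal_080_is_nonuniform_not_uniform(self):
        rec = site(ac=[8], an=10)  # af = 0.8: inclusive on non-uniform side
        assert classify_uniform([rec]) == []
        assert classify_nonuniform([rec]) == [rec]

    def test_multiallelic_rule(self):
        rec = site(alts=("G", "T"), ac=(3, 2), an=8)
        assert classify_nonuniform([rec]) == [rec]  # 3/8 > 0.2, an=8 > 5
        low_an = site(alts=("G", "T"), ac=(2, 1), an=5)
        assert classify_nonuniform([low_an]) == []

    def test_outputs_disjoint(self):
        records = [site(pos=p, ac=[c], an=10) for p, c in zip(range(1, 40, 2), list(range(0, 11)) + [10] * 9)]
        uni = {(r.contig, r.pos) for r in classify_uniform(records)}
        non = {(r.contig, r.pos) for r in classify_nonuniform(records)}
        assert not (uni & non)

    def test_permutation_invariance(self):
        gts = [(0, 1), (1, 1), (0, 0), (1, 0), (1, 1)]
        a = site(genotypes=gts)
        b = site(genotypes=list(reversed(gts)))
        for rec in (a, b):
            rec.recompute_frequencies()
        assert classify_uniform([a]) == classify_uniform([b])
        assert [r.pos for r in classify_nonuniform([a])] == [
            r.pos for r in classify_nonuniform([b])
        ]


class TestIndelSpacing:
    def deletion(self, pos, ndel, contig="c1"):
        ref = "A" + "C" * ndel
        return site(pos=pos, ref=ref, alts=(ref[0],))

    def insertion(self, pos, nins):
        return site(pos=pos, ref="A", alts=("A" + "G" * nins,))

    def test_ref_span_normalisation(self):
        # deletion anchored at 1-based 100 removing 3 bases
        assert indel_ref_span(self.deletion(100, 3)) == (100, 103)
        assert indel_ref_span(self.insertion(103, 2)) == (103, 103)

    def test_touching_pair_both_dropped(self):
        dele = self.deletion(100, 3)  # span [100,103)
        ins = self.insertion(103, 2)  # point [103,103): gap 0
        assert remove_nearby_indels([dele, ins], min_spacing=1) == []

    def test_spaced_pair_kept(self):
        a = self.deletion(100, 3)  # [100,103)
        b = self.deletion(104, 1)  # [104,105): gap 1
        assert remove_nearby_indels([a, b], min_spacing=1) == [a, b]

    def test_single_indel_identity(self):
        a = self.deletion(100, 3)
        assert remove_nearby_indels([a]) == [a]

    def test_surviving_set_respects_spacing(self):
        indels = [self.deletion(p, 2) for p in (10, 12, 30, 50, 52, 54, 80)]
        kept = remove_nearby_indels(indels, min_spacing=1)
        spans = [indel_ref_span(r) for r in kept]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 >= 1
        assert [r.pos for r in kept] == [30, 80]


class TestSnpOverIndel:
    def test_snp_inside_deletion_removed(self):
        dele = site(pos=100, ref="ACCC", alts=("A",))
        snp_in = site(pos=101)
        snp_out = site(pos=104)
        kept = exclude_snps_overlapping_indels([snp_in, snp_out], [dele])
        assert kept == [snp_out]

    def test_empty_indel_list_identity(self):
        snps = [site(pos=p) for p in (5, 10)]
        assert exclude_snps_overlapping_indels(snps, []) == snps

    def test_insertion_anchor_base_counts(self):
        ins = site(pos=100, ref="A", alts=("ATT",))
        snp_at_anchor = site(pos=100)
        snp_next = site(pos=101)
        kept = exclude_snps_overlapping_indels([snp_at_anchor, snp_next], [ins])
        assert kept == [snp_next]


class TestDownsampling:
    def full_site(self, gts, pos=100, alts=("G",)):
        rec = site(pos=pos, alts=alts, genotypes=gts)
        rec.recompute_frequencies()
        return rec

    def test_subset_uniform_when_af_1(self):
        rec = self.full_site([(0, 1), (0, 1), (1, 1), (1, 1), (1, 1)])
        uni, non = downsample_classify([rec], [2, 3, 4], 3)
        assert len(uni) == 1 and non == []
        assert uni[0].af == [1.0] and uni[0].ac == [6]

    def test_af_drop_moves_site_to_nonuniform(self):
        # 4-mouse subset where af falls to 6/8 = 0.75 with ac=6 > 1
        rec = self.full_site([(0, 0), (1, 1), (1, 1), (1, 1), (0, 0)])
        uni, non = downsample_classify([rec], [0, 1, 2, 3], 4)
        assert uni == [] and len(non) == 1
        assert non[0].af == [0.75]

    def test_nonvariant_subset_dropped(self):
        rec = self.full_site([(0, 0), (0, 0), (1, 1), (1, 1), (1, 1)])
        uni, non = downsample_classify([rec], [0, 1], 2)
        assert uni == [] and non == []

    def test_unused_alternates_removed(self):
        rec = self.full_site(
            [(1, 1), (1, 1), (0, 2), (2, 2), (0, 0)], alts=("G", "T")
        )
        # subset of mice 0,1 only carries alt 1 -> becomes biallelic
        uni, non = downsample_classify([rec], [0, 1], 2)
        assert len(uni) == 1
        assert uni[0].alt_alleles == ["G"]
        assert uni[0].ac == [4] and uni[0].an == 4

    def test_unsupported_n_mice_rejected(self):
        with pytest.raises(ValueError, match="n_mice"):
            downsample_classify([], [0], 1)
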