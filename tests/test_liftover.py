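"""Liftover semantics: positions, intervals, VCF, GTF, chain algebra.

The independent oracle is ``naive_apply`` (character-by-character edit
replay producing a per-base map), against which block-based lifting is
checked on randomized edit plans.
"""

import pytest
from hypothesis import given, settings, strategies as st

from strainref.genomic_io import Genome, GtfRecord, Interval, VariantRecord
from strainref.genome_builder import Edit, apply_edits, resolve_conflicts
from strainref.liftover import (
    BASE_TO_EDITED,
    EDITED_TO_BASE,
    compose_chains,
    identity_chain,
    invert_chain,
    lift_gtf,
    lift_interval,
    lift_position,
    lift_vcf,
    validate_exon_sequences,
)
from strainref.synthetic_fixtures import simulate_edit_plan

from conftest import naive_apply


@pytest.fixture(scope="module")
def deletion_setup():
    genome = Genome(c1="ACGTACGT")
    plan = resolve_conflicts([Edit("c1", (2, 4), "", "indel")])
    edited, chains = apply_edits(genome, plan)
    return genome, edited, chains


class TestLiftPosition:
    def test_position_after_deletion_shifts(self, deletion_setup):
        _, _, chains = deletion_setup
        r = lift_position(chains, "c1", 5)
        assert r.mapped and r.pos == 3

    def test_position_in_gap_deleted(self, deletion_setup):
        _, _, chains = deletion_setup
        r = lift_position(chains, "c1", 2)
        assert not r.mapped and r.reason == "deleted"

    def test_unknown_contig_no_chain(self, deletion_setup):
        _, _, chains = deletion_setup
        r = lift_position(chains, "chrX", 5)
        assert not r.mapped and r.reason == "no_chain"

    def test_round_trip_identity_for_mappable(self, deletion_setup):
        _, edited, chains = deletion_setup
        for pos in range(len(edited["c1"])):
            back = lift_position(chains, "c1", pos, EDITED_TO_BASE)
            assert back.mapped
            fwd = lift_position(chains, "c1", back.pos, BASE_TO_EDITED)
            assert fwd.pos == pos


class TestLiftInterval:
    def test_interval_inside_block_shifts(self, deletion_setup):
        _, _, chains = deletion_setup
        out = lift_interval(chains, Interval("c1", 4, 8))
        assert out == Interval("c1", 2, 6)

    def test_interval_spanning_gap_strict_full_match(self, deletion_setup):
        _, _, chains = deletion_setup
        assert lift_interval(chains, Interval("c1", 0, 8), min_match=1.0) is None

    def test_partial_mode_trims_to_core(self, deletion_setup):
        _, _, chains = deletion_setup
        out = lift_interval(chains, Interval("c1", 1, 6), mode="partial")
        assert out == Interval("c1", 1, 4)


class TestLiftVcf:
    def test_downstream_snp_shifts_and_matches_ref(self, deletion_setup):
        genome, edited, chains = deletion_setup
        rec = VariantRecord("c1", 6, genome["c1"][5], ["T"], ac=[1], an=2, af=[0.5])
        mapped, rejected = lift_vcf(chains, [rec], edited)
        assert rejected == []
        assert mapped[0].pos == 4

    def test_snp_in_deleted_region_rejected(self, deletion_setup):
        genome, edited, chains = deletion_setup
        rec = VariantRecord("c1", 3, genome["c1"][2], ["T"], ac=[1], an=2, af=[0.5])
        mapped, rejected = lift_vcf(chains, [rec], edited)
        assert mapped == []
        assert rejected[0][1] == "deleted"

    def test_ref_mismatch_rejected(self, deletion_setup):
        genome, edited, chains = deletion_setup
        wrong_ref = "G" if genome["c1"][5] != "G" else "C"
        rec = VariantRecord("c1", 6, wrong_ref, ["T"], ac=[1], an=2, af=[0.5])
        mapped, rejected = lift_vcf(chains, [rec], edited)
        assert rejected[0][1] == "ref_mismatch"

    def test_round_trip_identity(self, genome_100kb):
        plan = resolve_conflicts(simulate_edit_plan(genome_100kb, 80, seed=5))
        edited, chains = apply_edits(genome_100kb, plan)
        recs = []
        for pos in range(100, 90_000, 1777):
            ref = genome_100kb["chr1"][pos]
            recs.append(
                VariantRecord(
                    "chr1", pos + 1, ref, ["A" if ref != "A" else "C"],
                    ac=[1], an=2, af=[0.5],
                )
            )
        for i, r in enumerate(recs):
            r.id = f"v{i}"
        fwd, _ = lift_vcf(chains, recs, edited)
        back, rejected = lift_vcf(chains, fwd, genome_100kb, EDITED_TO_BASE)
        assert rejected == []
        by_id = {r.id: r.pos for r in recs}
        assert len(back) == len(fwd) > 0
        for r in back:
            assert r.pos == by_id[r.id]


def _transcript(contig, exon_spans, tid="t1", gid="g1"):
    records = []
    for i, (s, e) in enumerate(exon_spans):
        records.append(
            GtfRecord(
                contig, "test", "exon", s, e, ".", "+", ".",
                {
                    "gene_id": gid,
                    "transcript_id": tid,
                    "exon_id": f"{tid}.ex{i}",
                },
            )
        )
    records.insert(
        0,
        GtfRecord(
            contig, "test", "transcript",
            min(s for s, _ in exon_spans), max(e for _, e in exon_spans),
            ".", "+", ".", {"gene_id": gid, "transcript_id": tid},
        ),
    )
    return records


class TestLiftGtf:
    def test_unedited_transcript_converts_with_shift(self, small_genome):
        plan = resolve_conflicts([Edit("chr1", (100, 110), "", "te_remove")])
        _, chains = apply_edits(small_genome, plan)
        gtf = _transcript("chr1", [(500, 600), (700, 800)])
        converted, failed, summary = lift_gtf(chains, gtf)
        assert failed == []
        exons = [r for r in converted if r.feature == "exon"]
        assert [(e.start, e.end) for e in exons] == [(490, 590), (690, 790)]
        assert all(e.strand == "+" for e in exons)
        assert summary["exon_fraction"] == 1.0

    def test_exon_in_removed_region_drops_transcript(self, small_genome):
        plan = resolve_conflicts([Edit("chr1", (680, 820), "", "te_remove")])
        _, chains = apply_edits(small_genome, plan)
        gtf = _transcript("chr1", [(500, 600), (700, 800)]) + _transcript(
            "chr1", [(1000, 1100)], tid="t2", gid="g2"
        )
        converted, failed, summary = lift_gtf(chains, gtf)
        assert failed == ["t1.ex1"]
        tids = {r.transcript_id for r in converted if r.feature == "exon"}
        assert tids == {"t2"}  # exclude_partial: whole t1 dropped
        assert summary["n_transcripts_converted"] == 1

    def test_exon_order_preserved(self, small_genome):
        plan = resolve_conflicts([Edit("chr1", (50, 60), "TTTT" * 5, "te_insert")])
        _, chains = apply_edits(small_genome, plan)
        gtf = _transcript("chr1", [(100, 200), (300, 400), (500, 600)])
        converted, _, _ = lift_gtf(chains, gtf)
        starts = [r.start for r in converted if r.feature == "exon"]
        assert starts == sorted(starts)


class TestValidateExonSequences:
    def test_edits_explained_and_nothing_else(self, small_genome):
        snp_pos, mask_pos = 520, 750
        ref_snp = small_genome["chr1"][snp_pos]
        alt = "A" if ref_snp != "A" else "G"
        plan = resolve_conflicts(
            [
                Edit("chr1", (snp_pos, snp_pos + 1), alt, "snp_sub", ref_snp),
                Edit("chr1", (mask_pos, mask_pos + 1), "N", "n_mask"),
                Edit("chr1", (2000, 2010), "", "indel"),
            ]
        )
        edited, chains = apply_edits(small_genome, plan)
        gtf = _transcript("chr1", [(500, 600), (700, 800), (1990, 2050)])
        report = validate_exon_sequences(
            small_genome, edited, chains, gtf, plan
        )
        assert report["unexplained"] == []
        assert report["n_explained_differences"] == 2  # snp + mask

    def test_unexplained_mismatch_detected(self, small_genome):
        edited = Genome(small_genome)
        chrom = edited["chr1"]
        # corrupt one exon base without recording any edit
        edited["chr1"] = chrom[:550] + ("A" if chrom[550] != "A" else "G") + chrom[551:]
        chains = [identity_chain("chr1", len(chrom))]
        gtf = _transcript("chr1", [(500, 600)])
        report = validate_exon_sequences(
            small_genome, edited, chains, gtf, resolve_conflicts([])
        )
        assert len(report["unexplained"]) == 1
        assert report["unexplained"][0][1] == 550


class TestChainAlgebra:
    def test_compose_identity_is_neutral(self, deletion_setup):
        _, edited, chains = deletion_setup
        ident = [identity_chain("c1", 8)]
        composed = compose_chains(ident, chains)
        assert [c.blocks for c in composed] == [c.blocks for c in chains]

    def test_invert_involutive(self, deletion_setup):
        _, _, chains = deletion_setup
        for c in chains:
            assert invert_chain(invert_chain(c)) == c

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_compose_equals_sequential_lifting(self, genome_100kb, seed):
        plan1 = resolve_conflicts(
            simulate_edit_plan(genome_100kb, 60, seed=seed)
        )
        mid, chain1 = apply_edits(genome_100kb, plan1)
        plan2 = resolve_conflicts(simulate_edit_plan(mid, 60, seed=seed + 100))
        final, chain2 = apply_edits(mid, plan2)
        composed = compose_chains(chain1, chain2)
        for pos in range(0, len(genome_100kb["chr1"]), 509):
            step1 = lift_position(chain1, "chr1", pos)
            if step1.mapped:
                step2 = lift_position(chain2, step1.contig, step1.pos)
                expected = step2.pos if step2.mapped else None
            else:
                expected = None
            got = lift_position(composed, "chr1", pos)
            assert (got.pos if got.mapped else None) == expected


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_edits=st.integers(1, 60))
def test_mappable_and_deleted_positions_partition_contig(seed, n_edits):
    """Every base position is exactly one of mappable / in-gap, and the
    counts reconcile with the chain's block and dt sums."""
    genome = Genome(c1="ACGTACGTGG" * 300)
    plan = resolve_conflicts(simulate_edit_plan(genome, n_edits, seed=seed))
    _, chains = apply_edits(genome, plan)
    from strainref.liftover import _ChainIndex

    index = _ChainIndex(chains, BASE_TO_EDITED)
    n_mapped = sum(
        index.lift("c1", p).mapped for p in range(len(genome["c1"]))
    )
    assert n_mapped == sum(
        size for c in chains for size, _, _ in c.blocks
    )


@pytest.mark.parametrize("seed", [31, 32, 33])
def test_per_base_lifting_matches_naive_oracle(genome_100kb, seed):
    plan = resolve_conflicts(simulate_edit_plan(genome_100kb, 120, seed=seed))
    edited, chains = apply_edits(genome_100kb, plan)
    _, mapping = naive_apply(genome_100kb["chr1"], plan.edits.get("chr1", []))
    from strainref.liftover import _ChainIndex

    index = _ChainIndex(chains, BASE_TO_EDITED)
    for pos in range(len(genome_100kb["chr1"])):
        r = index.lift("chr1", pos)
        assert (r.pos if r.mapped else None) == mapping[pos], pos


def test_strict_interval_lift_matches_per_base_oracle(genome_100kb):
    import numpy as np

    plan = resolve_conflicts(simulate_edit_plan(genome_100kb, 100, seed=41))
    edited, chains = apply_edits(genome_100kb, plan)
    _, mapping = naive_apply(genome_100kb["chr1"], plan.edits.get("chr1", []))
    rng = np.random.default_rng(42)
    from strainref.liftover import _ChainIndex

    index = _ChainIndex(chains, BASE_TO_EDITED)
    for _ in range(300):
        start = int(rng.integers(0, 99_000))
        length = int(rng.integers(1, 900))
        iv = Interval("chr1", start, start + length)
        got = lift_interval(index, iv, min_match=0.95, mode="strict")
        mapped = [mapping[p] for p in range(iv.start, iv.end)]
        present = [m for m in mapped if m is not None]
        if (
            mapped[0] is None
            or mapped[-1] is None
            or len(present) / len(mapped) < 0.95
        ):
            expected = None
        else:
            expected = Interval("chr1", mapped[0], mapped[-1] + 1)
        assert got == expected, iv
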