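"""Coordinate liftover through UCSC chain alignments.

A chain describes an alignment between a *target* (base) and *query*
(edited) assembly as ungapped blocks separated by target gaps (dt, bases
present only in the target) and query gaps (dq, bases present only in the
query).  Positions inside blocks map affinely; positions inside dt gaps
are deleted in the query and return an unmapped result rather than
raising.  Chain composition and inversion support the two-stage genome
build (base -> hybrid -> final).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .genomic_io import ChainAlignment, Genome, GtfRecord, Interval, VariantRecord

__all__ = [
    "LiftResult",
    "lift_position",
    "lift_interval",
    "lift_vcf",
    "lift_gtf",
    "validate_exon_sequences",
    "compose_chains",
    "invert_chain",
    "identity_chain",
    "chain_segments",
]

BASE_TO_EDITED = "base_to_edited"
EDITED_TO_BASE = "edited_to_base"


@dataclass(frozen=True)
class LiftResult:
    """Outcome of lifting a position: mapped coordinate or a reason."""

    contig: str | None
    pos: int | None
    reason: str | None = None  # None when mapped; "deleted" | "no_chain"

    @property
    def mapped(self) -> bool:
        return self.reason is None


def chain_segments(chain: ChainAlignment) -> list[tuple[int, int, int]]:
    """Aligned segments of a chain as (t_start, q_start, size) triples."""
    segs = []
    t, q = chain.t_start, chain.q_start
    for size, dt, dq in chain.blocks:
        segs.append((t, q, size))
        t += size + dt
        q += size + dq
    return segs


class _ChainIndex:
    """Per-contig block index for fast position lookup (forward strand)."""

    def __init__(self, chains: list[ChainAlignment], direction: str):
        self.direction = direction
        self.by_contig: dict[str, list[tuple[int, int, int]]] = {}
        self.q_contig: dict[str, str] = {}
        self.spans: dict[str, tuple[int, int]] = {}
        for chain in chains:
            if chain.t_strand != "+" or chain.q_strand != "+":
                chain = _to_forward(chain)
            if direction == EDITED_TO_BASE:
                chain = invert_chain(chain)
            segs = chain_segments(chain)
            self.by_contig.setdefault(chain.t_name, []).extend(segs)
            self.q_contig[chain.t_name] = chain.q_name
            lo, hi = self.spans.get(chain.t_name, (chain.t_start, chain.t_end))
            self.spans[chain.t_name] = (
                min(lo, chain.t_start),
                max(hi, chain.t_end),
            )
        for segs in self.by_contig.values():
            segs.sort()
        self.starts = {
            name: [s[0] for s in segs] for name, segs in self.by_contig.items()
        }

    def lift(self, contig: str, pos: int) -> LiftResult:
        segs = self.by_contig.get(contig)
        if segs is None:
            return LiftResult(None, None, "no_chain")
        starts = self.starts[contig]
        i = bisect_right(starts, pos) - 1
        if i >= 0:
            t0, q0, size = segs[i]
            if t0 <= pos < t0 + size:
                return LiftResult(self.q_contig[contig], q0 + (pos - t0), None)
        lo, hi = self.spans[contig]
        if lo <= pos < hi:
            return LiftResult(None, None, "deleted")
        # outside the aligned span: no chain covers it
        return LiftResult(None, None, "deleted")


def _to_forward(chain: ChainAlignment) -> ChainAlignment:
    """Normalise a - strand query chain to ++ by flipping query coordinates."""
    if chain.t_strand == "+" and chain.q_strand == "+":
        return chain
    if chain.t_strand != "+":
        raise ValueError("chains with - strand targets are not supported")
    # q coordinates in a -strand chain count from the reverse-complement
    # start; flip them onto the forward strand and reverse block order
    segs = chain_segments(chain)
    flipped = sorted(
        (t, chain.q_size - (q + size), size) for t, q, size in segs
    )
    return _segments_to_chain(
        flipped,
        chain.t_name,
        chain.t_size,
        chain.q_name,
        chain.q_size,
        chain.id,
    )


def _segments_to_chain(
    segs: list[tuple[int, int, int]],
    t_name: str,
    t_size: int,
    q_name: str,
    q_size: int,
    chain_id: int = 1,
) -> ChainAlignment | None:
    """Build a ++ chain from disjoint, sorted aligned segments."""
    segs = [s for s in segs if s[2] > 0]
    if not segs:
        return None
    # merge adjacent segments contiguous in both coordinates
    merged = [list(segs[0])]
    for t, q, size in segs[1:]:
        lt, lq, lsize = merged[-1]
        if t == lt + lsize and q == lq + lsize:
            merged[-1][2] += size
        else:
            merged.append([t, q, size])
    blocks = []
    for i, (t, q, size) in enumerate(merged[:-1]):
        nt, nq, _ = merged[i + 1]
        blocks.append((size, nt - (t + size), nq - (q + size)))
    blocks.append((merged[-1][2], 0, 0))
    chain = ChainAlignment(
        score=sum(s for s, _, _ in blocks),
        t_name=t_name,
        t_size=t_size,
        t_strand="+",
        t_start=merged[0][0],
        t_end=merged[-1][0] + merged[-1][2],
        q_name=q_name,
        q_size=q_size,
        q_strand="+",
        q_start=merged[0][1],
        q_end=merged[-1][1] + merged[-1][2],
        blocks=blocks,
        id=chain_id,
    )
    chain.validate()
    return chain


def identity_chain(name: str, length: int, chain_id: int = 1) -> ChainAlignment:
    """Single-block chain mapping a contig onto itself."""
    return ChainAlignment(
        score=length,
        t_name=name,
        t_size=length,
        t_strand="+",
        t_start=0,
        t_end=length,
        q_name=name,
        q_size=length,
        q_strand="+",
        q_start=0,
        q_end=length,
        blocks=[(length, 0, 0)],
        id=chain_id,
    )


def lift_position(
    chains: list[ChainAlignment],
    contig: str,
    pos: int,
    direction: str = BASE_TO_EDITED,
) -> LiftResult:
    """Map a single 0-based position through the chains."""
    return _ChainIndex(chains, direction).lift(contig, pos)


def lift_interval(
    chains: list[ChainAlignment] | _ChainIndex,
    interval: Interval,
    min_match: float = 0.95,
    mode: str = "strict",
    direction: str = BASE_TO_EDITED,
) -> Interval | None:
    """Lift an interval; strict mode mirrors classic liftOver semantics.

    strict: both end bases must map and at least ``min_match`` of the
    interval's bases must map, else None.  partial: trim to the mappable
    core (first to last mappable base), else None.
    """
    index = (
        chains
        if isinstance(chains, _ChainIndex)
        else _ChainIndex(chains, direction)
    )
    if mode not in ("strict", "partial"):
        raise ValueError(f"unknown mode {mode!r}")
    results = [
        index.lift(interval.contig, p)
        for p in range(interval.start, interval.end)
    ]
    mapped = [r for r in results if r.mapped]
    if not mapped:
        return None
    if mode == "strict":
        if not (results[0].mapped and results[-1].mapped):
            return None
        if len(mapped) / len(results) < min_match:
            return None
        return Interval(
            results[0].contig,
            results[0].pos,
            results[-1].pos + 1,
            interval.strand,
            interval.name,
            interval.score,
        )
    return Interval(
        mapped[0].contig,
        mapped[0].pos,
        mapped[-1].pos + 1,
        interval.strand,
        interval.name,
        interval.score,
    )


def lift_vcf(
    chains: list[ChainAlignment],
    records: list[VariantRecord],
    target_genome: Genome,
    direction: str = BASE_TO_EDITED,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Lift variant records; (mapped, rejected-with-reason) partitions input.

    The full REF allele span must map contiguously and the REF sequence
    must match the target genome at the lifted position; otherwise the
    record is rejected with reason "deleted" / "no_chain" / "ref_mismatch".
    """
    index = _ChainIndex(chains, direction)
    mapped, rejected = [], []
    for rec in records:
        s, e = rec.ref_interval()
        first = index.lift(rec.contig, s)
        if not first.mapped:
            rejected.append((rec, first.reason))
            continue
        last = index.lift(rec.contig, e - 1)
        if not last.mapped or last.pos - first.pos != e - 1 - s:
            rejected.append((rec, "deleted"))
            continue
        target_seq = target_genome.fetch(first.contig, first.pos, last.pos + 1)
        if target_seq.upper() != rec.ref_allele.upper():
            rejected.append((rec, "ref_mismatch"))
            continue
        out = VariantRecord(
            contig=first.contig,
            pos=first.pos + 1,
            ref_allele=rec.ref_allele,
            alt_alleles=list(rec.alt_alleles),
            qual=rec.qual,
            site_annotations=dict(rec.site_annotations),
            genotypes=list(rec.genotypes),
            af=list(rec.af),
            ac=list(rec.ac),
            an=rec.an,
            filter_status=rec.filter_status,
            id=rec.id,
            af_derived=rec.af_derived,
        )
        mapped.append(out)
    return mapped, rejected


def lift_gtf(
    chains: list[ChainAlignment],
    gtf_records: list[GtfRecord],
    min_match: float = 0.95,
    direction: str = BASE_TO_EDITED,
) -> tuple[list[GtfRecord], list[str], dict[str, float]]:
    """Lift an annotation; transcripts are kept only if every exon converts.

    Mirrors liftoff's -exclude_partial semantics.  Returns (converted
    records, failed exon ids, summary with exon/transcript conversion
    fractions).
    """
    index = _ChainIndex(chains, direction)
    exons = [r for r in gtf_records if r.feature == "exon"]
    failed_exons: list[str] = []
    lifted_by_id: dict[int, GtfRecord] = {}
    failed_transcripts: set[str] = set()
    for i, exon in enumerate(exons):
        new_iv = lift_interval(index, exon.interval(), min_match, "strict")
        if new_iv is None:
            failed_exons.append(
                exon.attributes.get(
                    "exon_id", f"{exon.transcript_id}:{exon.start}-{exon.end}"
                )
            )
            if exon.transcript_id:
                failed_transcripts.add(exon.transcript_id)
        else:
            lifted_by_id[i] = GtfRecord(
                contig=new_iv.contig,
                source=exon.source,
                feature=exon.feature,
                start=new_iv.start,
                end=new_iv.end,
                score=exon.score,
                strand=exon.strand,
                frame=exon.frame,
                attributes=dict(exon.attributes),
            )
    converted: list[GtfRecord] = []
    kept_transcripts: set[str] = set()
    for i, exon in enumerate(exons):
        tid = exon.transcript_id
        if tid in failed_transcripts:
            continue
        if i in lifted_by_id:
            converted.append(lifted_by_id[i])
            if tid:
                kept_transcripts.add(tid)
    all_transcripts = {r.transcript_id for r in exons if r.transcript_id}
    # regenerate transcript/gene envelope records from converted exons
    envelopes: list[GtfRecord] = []
    for rec in gtf_records:
        if rec.feature not in ("transcript", "gene"):
            continue
        if rec.feature == "transcript":
            if rec.transcript_id not in kept_transcripts:
                continue
            members = [
                e for e in converted if e.transcript_id == rec.transcript_id
            ]
        else:
            members = [e for e in converted if e.gene_id == rec.gene_id]
        if members:
            envelopes.append(
                GtfRecord(
                    contig=members[0].contig,
                    source=rec.source,
                    feature=rec.feature,
                    start=min(e.start for e in members),
                    end=max(e.end for e in members),
                    score=rec.score,
                    strand=rec.strand,
                    frame=rec.frame,
                    attributes=dict(rec.attributes),
                )
            )
    summary = {
        "n_exons": len(exons),
        "n_exons_converted": len(lifted_by_id),
        "exon_fraction": len(lifted_by_id) / len(exons) if exons else 1.0,
        "n_transcripts": len(all_transcripts),
        "n_transcripts_converted": len(kept_transcripts),
        "transcript_fraction": (
            len(kept_transcripts) / len(all_transcripts)
            if all_transcripts
            else 1.0
        ),
    }
    return envelopes + converted, failed_exons, summary


def validate_exon_sequences(
    base_genome: Genome,
    edited_genome: Genome,
    chains: list[ChainAlignment],
    gtf_records: list[GtfRecord],
    edit_plan=None,
) -> dict:
    """Check converted exon sequences base vs edited, base by base.

    Every mappable exon base must be identical between the two genomes
    unless the edit plan documents a substitution (alt base) or an N-mask
    at that position.  Returns a report with per-exon mismatch lists;
    an empty ``unexplained`` list is the expected outcome.
    """
    index = _ChainIndex(chains, BASE_TO_EDITED)
    expected: dict[tuple[str, int], str] = {}
    if edit_plan is not None:
        for contig, edits in edit_plan.edits.items():
            for e in edits:
                if len(e.alt_seq) == e.ref_interval[1] - e.ref_interval[0]:
                    for off, ch in enumerate(e.alt_seq):
                        expected[(contig, e.ref_interval[0] + off)] = ch
    unexplained = []
    explained = 0
    n_checked = 0
    for exon in gtf_records:
        if exon.feature != "exon":
            continue
        for p in range(exon.start, exon.end):
            r = index.lift(exon.contig, p)
            if not r.mapped:
                continue
            n_checked += 1
            b = base_genome.base_at(exon.contig, p).upper()
            q = edited_genome.base_at(r.contig, r.pos).upper()
            if b == q:
                continue
            want = expected.get((exon.contig, p))
            if want is not None and q == want.upper():
                explained += 1
            else:
                unexplained.append((exon.contig, p, b, q))
    return {
        "n_bases_checked": n_checked,
        "n_explained_differences": explained,
        "unexplained": unexplained,
    }


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap target and query (dt <-> dq); involutive."""
    inv = ChainAlignment(
        score=chain.score,
        t_name=chain.q_name,
        t_size=chain.q_size,
        t_strand=chain.q_strand,
        t_start=chain.q_start,
        t_end=chain.q_end,
        q_name=chain.t_name,
        q_size=chain.t_size,
        q_strand=chain.t_strand,
        q_start=chain.t_start,
        q_end=chain.t_end,
        blocks=[(size, dq, dt) for size, dt, dq in chain.blocks],
        id=chain.id,
    )
    inv.validate()
    return inv


def compose_chains(
    chain_ab: list[ChainAlignment], chain_bc: list[ChainAlignment]
) -> list[ChainAlignment]:
    """Compose A->B and B->C chains into A->C chains.

    The query space of ``chain_ab`` must be the target space of
    ``chain_bc``; aligned segments are intersected in B coordinates.
    """
    bc_by_contig: dict[str, list[ChainAlignment]] = {}
    for c in chain_bc:
        bc_by_contig.setdefault(c.t_name, []).append(c)
    out = []
    next_id = 1
    for ab in chain_ab:
        partners = bc_by_contig.get(ab.q_name, [])
        for bc in partners:
            if ab.q_size != bc.t_size:
                raise ValueError(
                    f"intermediate contig {ab.q_name}: size {ab.q_size} in "
                    f"A->B chain but {bc.t_size} in B->C chain"
                )
            ab_segs = chain_segments(ab)  # (a, b, size)
            bc_segs = chain_segments(bc)  # (b, c, size)
            pieces = []
            j = 0
            for a0, b0, size in ab_segs:
                for b1, c1, size1 in bc_segs:
                    lo = max(b0, b1)
                    hi = min(b0 + size, b1 + size1)
                    if hi > lo:
                        pieces.append(
                            (a0 + (lo - b0), c1 + (lo - b1), hi - lo)
                        )
            pieces.sort()
            chain = _segments_to_chain(
                pieces, ab.t_name, ab.t_size, bc.q_name, bc.q_size, next_id
            )
            if chain is not None:
                out.append(chain)
                next_id += 1
    return out
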