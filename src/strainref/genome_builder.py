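"""Apply a resolved edit plan to a base genome and emit the exact chain.

The edit vocabulary covers everything a strain-specific reference build
needs: TE consensus insertions and reference-TE removals, uniform SNP
substitutions and indels, and N-masks at segregating SNP positions.
Overlapping edits are resolved by kind priority
(te_remove = te_insert > indel > snp_sub > n_mask); the loser is dropped
and logged, mirroring the "uniform SNPs overlapping a uniform indel are
excluded" rule and extending it to every kind.

Chain semantics: equal-length replacements (substitutions, masks) are
mismatches *within* an ungapped block — chain blocks are alignments, not
identity runs — so only length-changing edits break blocks, contributing
dt = |ref interval| and dq = |alt| at the break.  Gaps at contig ends are
absorbed into the chain's t_start/t_end and q_start/q_end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genomic_io import ChainAlignment, Genome, VariantRecord
from .liftover import (
    BASE_TO_EDITED,
    _ChainIndex,
    _segments_to_chain,
    compose_chains,
)
from .variant_classification import indel_ref_span

logger = logging.getLogger(__name__)

__all__ = ["Edit", "EditPlan", "resolve_conflicts", "apply_edits", "build_reference"]

PRIORITY = {"te_remove": 4, "te_insert": 4, "indel": 3, "snp_sub": 2, "n_mask": 1}


@dataclass(frozen=True)
class Edit:
    """Replacement of a base-genome interval by an alternate sequence.

    ``ref_interval`` is 0-based half-open on the base genome; zero-length
    for pure insertions (the insertion lands *before* position start).
    ``ref_seq``, when provided, is checked against the genome on apply.
    """

    contig: str
    ref_interval: tuple[int, int]
    alt_seq: str
    kind: str
    ref_seq: str | None = None

    def __post_init__(self):
        if self.kind not in PRIORITY:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        s, e = self.ref_interval
        if s < 0 or e < s:
            raise ValueError(f"invalid ref_interval [{s},{e})")
        if self.kind in ("snp_sub", "n_mask") and not (
            e - s == 1 and len(self.alt_seq) == 1
        ):
            raise ValueError(
                f"{self.kind} edits must replace exactly one base"
            )

    @property
    def priority(self) -> int:
        return PRIORITY[self.kind]

    @property
    def start(self) -> int:
        return self.ref_interval[0]

    @property
    def end(self) -> int:
        return self.ref_interval[1]

    def is_length_preserving(self) -> bool:
        s, e = self.ref_interval
        return e - s == len(self.alt_seq) and e > s


@dataclass
class EditPlan:
    """Non-overlapping, per-contig sorted edits plus a log of casualties."""

    edits: dict[str, list[Edit]] = field(default_factory=dict)
    conflict_log: list[tuple[Edit, str]] = field(default_factory=list)

    def all_edits(self) -> list[Edit]:
        return [e for edits in self.edits.values() for e in edits]

    def counts(self) -> dict[str, dict[str, int]]:
        applied: dict[str, int] = {}
        dropped: dict[str, int] = {}
        for e in self.all_edits():
            applied[e.kind] = applied.get(e.kind, 0) + 1
        for e, _ in self.conflict_log:
            dropped[e.kind] = dropped.get(e.kind, 0) + 1
        return {"applied": applied, "dropped": dropped}


def _conflicts(a: Edit, b: Edit) -> bool:
    a_len = a.end - a.start
    b_len = b.end - b.start
    if a_len == 0 and b_len == 0:
        return a.start == b.start
    if a_len == 0:
        return b.start < a.start < b.end
    if b_len == 0:
        return a.start < b.start < a.end
    return a.start < b.end and b.start < a.end


def resolve_conflicts(raw_edits: list[Edit]) -> EditPlan:
    """Resolve overlapping edits by kind priority; deterministic.

    Higher-priority edits win; among equals the earlier (start, end,
    alt_seq) wins.  Two same-priority edits on the identical interval with
    different replacement sequences are a contradictory call set and
    raise.  Exact duplicates collapse silently into one edit.
    """
    plan = EditPlan()
    by_contig: dict[str, list[Edit]] = {}
    for e in raw_edits:
        by_contig.setdefault(e.contig, []).append(e)
    for contig in sorted(by_contig):
        candidates = sorted(
            by_contig[contig],
            key=lambda e: (-e.priority, e.start, e.end, e.alt_seq, e.kind),
        )
        accepted: list[Edit] = []
        seen: set[tuple] = set()
        for e in candidates:
            key = (e.start, e.end, e.alt_seq, e.kind)
            if key in seen:
                continue  # exact duplicate
            clash = next((a for a in accepted if _conflicts(e, a)), None)
            if clash is None:
                accepted.append(e)
                seen.add(key)
            else:
                if (
                    clash.priority == e.priority
                    and clash.ref_interval == e.ref_interval
                    and clash.alt_seq != e.alt_seq
                ):
                    raise ValueError(
                        f"contradictory {e.kind} calls at {contig}:"
                        f"{e.start}-{e.end}: {clash.alt_seq!r} vs {e.alt_seq!r}"
                    )
                reason = (
                    f"overlaps {clash.kind} at "
                    f"{contig}:{clash.start}-{clash.end}"
                )
                plan.conflict_log.append((e, reason))
                logger.info("dropped %s at %s:%d (%s)", e.kind, contig, e.start, reason)
        plan.edits[contig] = sorted(accepted, key=lambda e: (e.start, e.end))
    return plan


def apply_edits(
    genome: Genome, plan: EditPlan, query_suffix: str = ""
) -> tuple[Genome, list[ChainAlignment]]:
    """Apply a resolved plan; return the edited genome and one chain/contig.

    The edited contig is the concatenation of unedited segments and
    replacement sequences in order.  Contigs absent from the plan get an
    identity chain.
    """
    edited = Genome()
    chains: list[ChainAlignment] = []
    chain_id = 1
    for contig, seq in genome.items():
        edits = plan.edits.get(contig, [])
        parts: list[str] = []
        segs: list[tuple[int, int, int]] = []  # (t_start, q_start, size)
        t = 0
        q = 0
        for e in edits:
            s, end = e.ref_interval
            if end > len(seq):
                raise ValueError(
                    f"edit [{s},{end}) exceeds {contig} length {len(seq)}"
                )
            if e.ref_seq is not None:
                found = seq[s:end].upper()
                if found != e.ref_seq.upper():
                    raise ValueError(
                        f"{contig}:{s}: edit expects reference "
                        f"{e.ref_seq!r} but genome has {found!r}"
                    )
            if s < t:
                raise ValueError(
                    f"unresolved overlap at {contig}:{s} (cursor at {t})"
                )
            if s > t:
                parts.append(seq[t:s])
                segs.append((t, q, s - t))
                q += s - t
            if e.is_length_preserving():
                parts.append(e.alt_seq)
                segs.append((s, q, end - s))
                q += end - s
            else:
                parts.append(e.alt_seq)
                q += len(e.alt_seq)
            t = end
        if t < len(seq):
            parts.append(seq[t:])
            segs.append((t, q, len(seq) - t))
            q += len(seq) - t
        new_seq = "".join(parts)
        q_name = contig + query_suffix
        edited[q_name] = new_seq
        chain = _segments_to_chain(
            segs, contig, len(seq), q_name, len(new_seq), chain_id
        )
        if chain is not None:
            chains.append(chain)
            chain_id += 1
    return edited, chains


def variant_to_edit(rec: VariantRecord, kind: str | None = None) -> Edit:
    """Convert a biallelic VCF record to an Edit (minimal representation).

    SNPs become single-base substitutions.  Indels are normalised by
    stripping the shared leading anchor base, so the edit touches only
    the inserted/deleted bases.
    """
    alt = rec.alt_alleles[0]
    if rec.is_snp:
        return Edit(
            contig=rec.contig,
            ref_interval=(rec.start, rec.start + 1),
            alt_seq=alt,
            kind=kind or "snp_sub",
            ref_seq=rec.ref_allele,
        )
    s, e = indel_ref_span(rec)
    ref = rec.ref_allele
    if alt and ref and alt[0].upper() == ref[0].upper():
        alt_trimmed = alt[1:]
        ref_trimmed = ref[1:]
    else:
        alt_trimmed = alt
        ref_trimmed = ref
    return Edit(
        contig=rec.contig,
        ref_interval=(s, e),
        alt_seq=alt_trimmed,
        kind=kind or "indel",
        ref_seq=ref_trimmed or None,
    )


def build_reference(
    base_genome: Genome,
    te_insertions=None,
    te_absences=None,
    uniform_variants: list[VariantRecord] | None = None,
    nonuniform_snps: list[VariantRecord] | None = None,
    consensus_store: dict[str, str] | None = None,
) -> tuple[Genome, list[ChainAlignment], dict]:
    """Two-stage strain-reference build.

    Stage 1 inserts germline TE consensus sequences and removes
    reference TEs absent from the strain, yielding a hybrid genome and
    chain1.  Stage 2 lifts the SNP/indel/mask coordinates (all given in
    base-genome coordinates) through chain1, converts uniform variants to
    their strain alleles and N-masks segregating SNP positions, yielding
    the final genome and chain2.  The returned chain is
    compose(chain1, chain2): base -> final.

    Variants whose positions fall inside removed TEs are unmappable
    through chain1; they are dropped and counted, not fatal.
    """
    te_insertions = te_insertions or []
    te_absences = te_absences or []
    uniform_variants = uniform_variants or []
    nonuniform_snps = nonuniform_snps or []
    consensus_store = consensus_store or {}

    stage1_raw = []
    for call in te_insertions:
        seq = consensus_store.get(call.te_family)
        if seq is None:
            raise KeyError(
                f"no consensus sequence for TE family {call.te_family!r}"
            )
        stage1_raw.append(
            Edit(call.contig, (call.start, call.start), seq, "te_insert")
        )
    for call in te_absences:
        stage1_raw.append(
            Edit(call.contig, (call.start, call.end), "", "te_remove")
        )
    plan1 = resolve_conflicts(stage1_raw)
    hybrid, chain1 = apply_edits(base_genome, plan1)
    index1 = _ChainIndex(chain1, BASE_TO_EDITED)
    unmappable = 0
    stage2_raw = []

    def lift_edit(edit: Edit) -> Edit | None:
        nonlocal unmappable
        s, e = edit.ref_interval
        if s == e:  # pure insertion point
            r = index1.lift(edit.contig, s)
            if not r.mapped:
                unmappable += 1
                return None
            return Edit(r.contig, (r.pos, r.pos), edit.alt_seq, edit.kind, edit.ref_seq)
        first = index1.lift(edit.contig, s)
        if not first.mapped:
            unmappable += 1
            return None
        last = index1.lift(edit.contig, e - 1)
        if not last.mapped or last.pos - first.pos != e - 1 - s:
            unmappable += 1
            return None
        return Edit(
            first.contig,
            (first.pos, last.pos + 1),
            edit.alt_seq,
            edit.kind,
            edit.ref_seq,
        )

    for rec in uniform_variants:
        lifted = lift_edit(variant_to_edit(rec))
        if lifted is not None:
            stage2_raw.append(lifted)
    for rec in nonuniform_snps:
        edit = Edit(
            rec.contig, (rec.start, rec.start + 1), "N", "n_mask", rec.ref_allele
        )
        lifted = lift_edit(edit)
        if lifted is not None:
            stage2_raw.append(lifted)

    plan2 = resolve_conflicts(stage2_raw)
    final, chain2 = apply_edits(hybrid, plan2)
    chain = compose_chains(chain1, chain2)

    counts1, counts2 = plan1.counts(), plan2.counts()
    applied = {**counts1["applied"], **counts2["applied"]}
    dropped = {**counts1["dropped"], **counts2["dropped"]}
    reports = {
        "applied": applied,
        "dropped": dropped,
        "unmappable_through_stage1": unmappable,
        "n_masked": applied.get("n_mask", 0),
        "conflict_log": plan1.conflict_log + plan2.conflict_log,
    }
    return final, chain, reports
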