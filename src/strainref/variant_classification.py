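"""Cohort variant hard-filtering and uniform / non-uniform classification.

A *uniform* variant is a site where every sequenced cohort member carries
the same alternate allele, which differs from the base reference; a
*non-uniform* variant segregates within the cohort.  Classification
operates on whole VCF sites (multi-allelic records are never split) using
the alternate-allele frequency (AF), count (AC) and total called alleles
(AN):

* uniform: biallelic, AF > 0.8 and AC > ac_uniform (5 for a 5-mouse cohort);
* non-uniform: biallelic with 0.2 < AF <= 0.8 and AC > ac_nonuniform (2), or
  multi-allelic with AN > an_min (5) and the most frequent alternate allele
  making up > 0.2 of called alleles.

Upstream of classification, sites pass GATK-style hard filters (QD, QUAL,
SOR, FS, MQ, MQRankSum, ReadPosRankSum for SNPs; QD, QUAL, FS,
ReadPosRankSum for indels).  A missing annotation skips that sub-filter
rather than failing the site, mirroring how VariantFiltration treats
absent annotations (e.g. MQRankSum at sites with no heterozygotes).

Down-sampled cohorts (2-4 mice) reuse the same machinery with integer
thresholds scaled so the AC cutoffs keep roughly the same proportion of
the total allele count as in the 5-mouse design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .genomic_io import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HardFilterThresholds",
    "ClassificationThresholds",
    "DOWNSAMPLE_THRESHOLDS",
    "hard_filter",
    "classify_uniform",
    "classify_nonuniform",
    "remove_nearby_indels",
    "exclude_snps_overlapping_indels",
    "downsample_classify",
    "indel_ref_span",
]


@dataclass(frozen=True)
class HardFilterThresholds:
    """Per-class hard-filter cutoffs; a site fails if any inequality fires."""

    snp: dict[str, float] = field(
        default_factory=lambda: {
            "qd_min": 2.0,
            "qual_min": 30.0,
            "sor_max": 3.0,
            "fs_max": 60.0,
            "mq_min": 40.0,
            "mqranksum_min": -12.5,
            "readposranksum_min": -8.0,
        }
    )
    indel: dict[str, float] = field(
        default_factory=lambda: {
            "qd_min": 2.0,
            "qual_min": 30.0,
            "fs_max": 200.0,
            "readposranksum_min": -20.0,
        }
    )


@dataclass(frozen=True)
class ClassificationThresholds:
    """AF/AC/AN cutoffs for the uniform / non-uniform split.

    All comparisons on af/ac/an are strict except the non-uniform upper AF
    bound, which is inclusive (AF = 0.8 is non-uniform, not uniform).
    Integer thresholds default to the 5-mouse design.
    """

    uniform_af_min: float = 0.8  # exclusive
    uniform_ac_min: int = 5  # exclusive
    nonuniform_af_lo: float = 0.2  # exclusive
    nonuniform_af_hi: float = 0.8  # inclusive
    nonuniform_ac_min: int = 2  # exclusive
    multiallelic_an_min: int = 5  # exclusive
    multiallelic_topfreq_min: float = 0.2  # exclusive
    min_indel_spacing: int = 1


#: Integer-threshold replacements used when down-sampling to n mice.
DOWNSAMPLE_THRESHOLDS: dict[int, dict[str, int]] = {
    2: {"uniform_ac_min": 2, "nonuniform_ac_min": 0, "multiallelic_an_min": 2},
    3: {"uniform_ac_min": 3, "nonuniform_ac_min": 1, "multiallelic_an_min": 3},
    4: {"uniform_ac_min": 4, "nonuniform_ac_min": 1, "multiallelic_an_min": 4},
}

# (annotation key, threshold key, direction): fail when value < min / > max
_SNP_RULES = [
    ("QD", "qd_min", "lt"),
    ("SOR", "sor_max", "gt"),
    ("FS", "fs_max", "gt"),
    ("MQ", "mq_min", "lt"),
    ("MQRankSum", "mqranksum_min", "lt"),
    ("ReadPosRankSum", "readposranksum_min", "lt"),
]
_INDEL_RULES = [
    ("QD", "qd_min", "lt"),
    ("FS", "fs_max", "gt"),
    ("ReadPosRankSum", "readposranksum_min", "lt"),
]


def hard_filter(
    records: list[VariantRecord],
    thresholds: HardFilterThresholds | None = None,
    variant_class: str = "snp",
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition ``records`` into (pass, fail) under the hard filters.

    A record fails iff any stated inequality fires (strict comparisons);
    a missing annotation skips that sub-filter.
    """
    thresholds = thresholds or HardFilterThresholds()
    if variant_class == "snp":
        cuts, rules = thresholds.snp, _SNP_RULES
    elif variant_class == "indel":
        cuts, rules = thresholds.indel, _INDEL_RULES
    else:
        raise ValueError(f"unknown variant class {variant_class!r}")

    passed, failed = [], []
    for rec in records:
        fails = rec.qual is not None and rec.qual < cuts["qual_min"]
        for ann_key, cut_key, direction in rules:
            if fails:
                break
            value = rec.site_annotations.get(ann_key)
            if value is None:
                logger.debug(
                    "%s:%d missing %s; sub-filter skipped",
                    rec.contig,
                    rec.pos,
                    ann_key,
                )
                continue
            if direction == "lt":
                fails = value < cuts[cut_key]
            else:
                fails = value > cuts[cut_key]
        (failed if fails else passed).append(rec)
    return passed, failed


def classify_uniform(
    records: list[VariantRecord],
    thresholds: ClassificationThresholds | None = None,
) -> list[VariantRecord]:
    """Biallelic sites with AF > uniform_af_min and AC > uniform_ac_min."""
    t = thresholds or ClassificationThresholds()
    out = [
        r
        for r in records
        if r.is_biallelic
        and r.af
        and r.af[0] > t.uniform_af_min
        and r.ac[0] > t.uniform_ac_min
    ]
    return sorted(out, key=lambda r: (r.contig, r.pos))


def classify_nonuniform(
    records: list[VariantRecord],
    thresholds: ClassificationThresholds | None = None,
) -> list[VariantRecord]:
    """Segregating sites: balanced biallelic or common-top-allele multiallelic."""
    t = thresholds or ClassificationThresholds()
    out = []
    for r in records:
        if r.is_biallelic:
            if (
                r.af
                and t.nonuniform_af_lo < r.af[0] <= t.nonuniform_af_hi
                and r.ac[0] > t.nonuniform_ac_min
            ):
                out.append(r)
        elif r.n_alts > 1:
            if (
                r.an > t.multiallelic_an_min
                and r.an > 0
                and r.max_alt_ac / r.an > t.multiallelic_topfreq_min
            ):
                out.append(r)
    return sorted(out, key=lambda r: (r.contig, r.pos))


def indel_ref_span(rec: VariantRecord) -> tuple[int, int]:
    """0-based half-open span of the bases an indel adds/removes.

    The shared leading anchor base is stripped (VCF anchors indels on the
    preceding reference base): a deletion REF=ACGT ALT=A at pos p spans
    [p, p+3); an insertion REF=A ALT=ATT at pos p is the zero-length point
    [p, p).  For multi-allelic indels the span covers the REF minus anchor.
    """
    s, e = rec.ref_interval()
    # strip shared leading anchor base if every alt shares it
    if rec.alt_alleles and all(
        a and a[0].upper() == rec.ref_allele[0].upper()
        for a in rec.alt_alleles
    ):
        s += 1
    return s, max(s, e)


def remove_nearby_indels(
    indels: list[VariantRecord], min_spacing: int = 1
) -> list[VariantRecord]:
    """Drop every indel involved in a pair closer than ``min_spacing``.

    The gap between two indels is measured between their half-open
    reference spans (start of the later minus end of the earlier); with
    spacing 1 only touching or overlapping pairs are removed.  Both
    members of an offending pair are dropped.
    """
    items = sorted(indels, key=lambda r: (r.contig, r.pos))
    spans = [indel_ref_span(r) for r in items]
    drop = [False] * len(items)
    for i in range(len(items) - 1):
        j = i + 1
        while j < len(items) and items[j].contig == items[i].contig:
            gap = spans[j][0] - spans[i][1]
            if gap < min_spacing:
                drop[i] = drop[j] = True
                j += 1
            else:
                break
    return [r for r, d in zip(items, drop) if not d]


def exclude_snps_overlapping_indels(
    snps: list[VariantRecord], indels: list[VariantRecord]
) -> list[VariantRecord]:
    """Remove SNPs whose reference base lies within an indel's span.

    For pure insertions (zero-length span) the single anchor base counts
    as the span.
    """
    spans_by_contig: dict[str, list[tuple[int, int]]] = {}
    for ind in indels:
        s, e = indel_ref_span(ind)
        if s == e:  # pure insertion: anchor base
            s, e = max(0, s - 1), s
        spans_by_contig.setdefault(ind.contig, []).append((s, e))
    for spans in spans_by_contig.values():
        spans.sort()
    out = []
    for snp in snps:
        pos0 = snp.start
        hit = any(
            s <= pos0 < e
            for s, e in spans_by_contig.get(snp.contig, ())
        )
        if not hit:
            out.append(snp)
    return out


def _subset_record(
    rec: VariantRecord, sample_indices: list[int]
) -> VariantRecord | None:
    """Restrict a record to a sample subset, GATK SelectVariants style.

    Recomputes AC/AN/AF from the subset genotypes, drops sites that are
    non-variant in the subset (``--exclude-non-variants``) and removes
    unused alternate alleles, re-indexing genotypes
    (``--remove-unused-alternates``).
    """
    genotypes = [rec.genotypes[i] for i in sample_indices]
    called = [a for gt in genotypes for a in gt if a is not None]
    if not called or all(a == 0 for a in called):
        return None
    used = sorted({a for a in called if a > 0})
    index_map = {0: 0, **{old: new + 1 for new, old in enumerate(used)}}
    new_alts = [rec.alt_alleles[a - 1] for a in used]
    new_gts = [
        tuple(None if a is None else index_map[a] for a in gt)
        for gt in genotypes
    ]
    sub = replace(
        rec,
        alt_alleles=new_alts,
        genotypes=new_gts,
        af=[],
        ac=[],
        an=0,
    )
    sub.recompute_frequencies()
    return sub


def downsample_classify(
    records: list[VariantRecord],
    sample_subset: list[int],
    n_mice: int,
    hard_thresholds: HardFilterThresholds | None = None,
    variant_class: str = "snp",
    restrict_to: set[tuple[str, int]] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Re-run classification on a sample subset with scaled thresholds.

    ``sample_subset`` holds genotype-column indices for the retained mice.
    Returns (uniform, nonuniform).  ``restrict_to`` optionally limits the
    analysis to sites (contig, pos) that belonged to the full-cohort
    uniform/non-uniform sets.
    """
    if n_mice not in DOWNSAMPLE_THRESHOLDS:
        raise ValueError(
            f"n_mice={n_mice} unsupported; expected one of "
            f"{sorted(DOWNSAMPLE_THRESHOLDS)}"
        )
    if len(sample_subset) != n_mice:
        raise ValueError("sample_subset size must equal n_mice")
    subset = []
    for rec in records:
        if restrict_to is not None and (rec.contig, rec.pos) not in restrict_to:
            continue
        sub = _subset_record(rec, sample_subset)
        if sub is not None:
            subset.append(sub)
    passed, _ = hard_filter(subset, hard_thresholds, variant_class)
    t = ClassificationThresholds(**DOWNSAMPLE_THRESHOLDS[n_mice])
    return classify_uniform(passed, t), classify_nonuniform(passed, t)
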