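"""Synthetic, desk-scale inputs with the statistical structure the
toolkit assumes.

Every generator is a pure function of its parameters and a seed, and
returns truth labels alongside the data, so recall/precision of every
downstream filter can be computed exactly without external datasets.
Genotypes are drawn allele-by-allele (independent draws at the site's
population frequency — the same Hardy-Weinberg assumption the bias model
makes); site annotations are sampled inside the hard-filter passing
ranges unless a failing injection is requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import Genome, Interval, VariantRecord
from .region_qc import CountMatrix
from .te_germline import TECall, TEFilterParams

__all__ = [
    "simulate_genome",
    "simulate_cohort_variants",
    "simulate_te_calls",
    "simulate_count_matrix",
    "simulate_edit_plan",
    "SiteSpec",
]

_BASES = np.array(list("ACGT"))


def simulate_genome(
    contig_lengths: dict[str, int], gc_content: float = 0.42, seed: int = 0
) -> Genome:
    """I.i.d. nucleotides with P(G) + P(C) = ``gc_content``."""
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0,1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    probs = [at, gc, gc, at]  # A C G T
    genome = Genome()
    for name, length in contig_lengths.items():
        if length < 1:
            raise ValueError(f"contig {name}: length must be >= 1")
        genome[name] = "".join(
            _BASES[rng.choice(4, size=length, p=probs)]
        )
    return genome


@dataclass(frozen=True)
class SiteSpec:
    """Blueprint for one planted variant site.

    kind: "snp" | "deletion" | "insertion"; ``length`` is the number of
    inserted/deleted bases (ignored for SNPs).  ``pop_freq`` is the
    population frequency of the alternate allele; ``fail_filter`` plants
    a hard-filter-failing annotation (QD below threshold).
    """

    kind: str = "snp"
    pop_freq: float = 0.5
    length: int = 1
    fail_filter: bool = False


_PASSING_RANGES = {
    "QD": (10.0, 35.0),
    "SOR": (0.5, 2.5),
    "FS": (0.0, 30.0),
    "MQ": (50.0, 60.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
}


def _draw_annotations(rng, fail_filter: bool) -> dict[str, float]:
    ann = {
        key: float(rng.uniform(lo, hi))
        for key, (lo, hi) in _PASSING_RANGES.items()
    }
    if fail_filter:
        ann["QD"] = float(rng.uniform(0.0, 1.9))
    return ann


def _other_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base.upper()]
    return choices[rng.integers(0, len(choices))]


def simulate_cohort_variants(
    genome: Genome,
    n_mice: int,
    site_specs: list[SiteSpec],
    seed: int = 0,
    min_spacing: int = 10,
) -> tuple[list[VariantRecord], list[dict]]:
    """Plant variant sites on a genome and draw cohort genotypes.

    Returns (records, truth) where ``truth[i]`` records the planted spec,
    position and the drawn alternate-allele count.  2 x n_mice alleles
    are drawn i.i.d. Bernoulli(pop_freq) per site; AF/AC/AN are computed
    from the draws.  Sites are placed without overlap (``min_spacing``
    bp apart) on contigs chosen round-robin by available space.
    """
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    truth: list[dict] = []
    # reserve disjoint slots per contig up front
    contigs = list(genome)
    slot = max(
        (
            spec.length if spec.kind != "snp" else 1
            for spec in site_specs
        ),
        default=1,
    ) + min_spacing + 2
    total_slots = sum(
        (len(genome[c]) - 2) // slot for c in contigs
    )
    if total_slots < len(site_specs):
        raise ValueError(
            f"cannot place {len(site_specs)} sites with spacing "
            f"{min_spacing} on this genome"
        )
    positions: list[tuple[str, int]] = []
    for c in contigs:
        n_here = (len(genome[c]) - 2) // slot
        positions.extend(
            (c, 1 + i * slot) for i in range(n_here)
        )
    chosen = rng.choice(len(positions), size=len(site_specs), replace=False)
    chosen.sort()
    for spec, idx in zip(site_specs, chosen):
        contig, pos0 = positions[int(idx)]
        seq = genome[contig]
        alleles = (rng.random(2 * n_mice) < spec.pop_freq).astype(int)
        genotypes = [
            (int(alleles[2 * i]), int(alleles[2 * i + 1]))
            for i in range(n_mice)
        ]
        ac = int(alleles.sum())
        an = 2 * n_mice
        if spec.kind == "snp":
            ref = seq[pos0]
            alt = _other_base(rng, ref)
            pos = pos0 + 1
        elif spec.kind == "deletion":
            ref = seq[pos0 : pos0 + 1 + spec.length]
            alt = seq[pos0]
            pos = pos0 + 1
        elif spec.kind == "insertion":
            ref = seq[pos0]
            ins = "".join(_BASES[rng.integers(0, 4, size=spec.length)])
            alt = ref + ins
            pos = pos0 + 1
        else:
            raise ValueError(f"unknown site kind {spec.kind!r}")
        rec = VariantRecord(
            contig=contig,
            pos=pos,
            ref_allele=ref,
            alt_alleles=[alt],
            qual=float(rng.uniform(100.0, 2000.0)),
            site_annotations=_draw_annotations(rng, spec.fail_filter),
            genotypes=genotypes,
            ac=[ac],
            an=an,
            af=[ac / an],
        )
        records.append(rec)
        truth.append(
            {
                "spec": spec,
                "contig": contig,
                "pos": pos,
                "ac": ac,
                "an": an,
            }
        )
    return records, truth


def simulate_edit_plan(
    genome: Genome,
    n_edits: int = 100,
    seed: int = 0,
    max_indel: int = 12,
    max_te: int = 40,
) -> list:
    """Random raw edits of every kind for build/liftover property checks.

    Returns an *unresolved* edit list (overlaps possible by design, so
    conflict resolution is exercised too).  Edit positions avoid the
    first and last 2 bases of each contig.
    """
    from .genome_builder import Edit  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    kinds = ["snp_sub", "n_mask", "indel_del", "indel_ins", "te_insert", "te_remove"]
    weights = np.array([0.3, 0.25, 0.15, 0.15, 0.075, 0.075])
    contigs = list(genome)
    sizes = np.array([len(genome[c]) for c in contigs], dtype=float)
    edits = []
    for _ in range(n_edits):
        contig = contigs[rng.choice(len(contigs), p=sizes / sizes.sum())]
        length = len(genome[contig])
        kind = kinds[rng.choice(len(kinds), p=weights)]
        pos = int(rng.integers(2, length - max_te - 2))
        if kind == "snp_sub":
            ref = genome[contig][pos]
            edits.append(
                Edit(contig, (pos, pos + 1), _other_base(rng, ref), "snp_sub", ref)
            )
        elif kind == "n_mask":
            edits.append(
                Edit(contig, (pos, pos + 1), "N", "n_mask", genome[contig][pos])
            )
        elif kind == "indel_del":
            n = int(rng.integers(1, max_indel + 1))
            edits.append(Edit(contig, (pos, pos + n), "", "indel"))
        elif kind == "indel_ins":
            n = int(rng.integers(1, max_indel + 1))
            ins = "".join(_BASES[rng.integers(0, 4, size=n)])
            edits.append(Edit(contig, (pos, pos), ins, "indel"))
        elif kind == "te_insert":
            n = int(rng.integers(10, max_te + 1))
            ins = "".join(_BASES[rng.integers(0, 4, size=n)])
            edits.append(Edit(contig, (pos, pos), ins, "te_insert"))
        else:
            n = int(rng.integers(10, max_te + 1))
            edits.append(Edit(contig, (pos, pos + n), "", "te_remove"))
    return edits


def simulate_te_calls(
    genome: Genome,
    n_insertions: int = 20,
    n_absences: int = 10,
    n_samples: int = 5,
    passing_fraction: float = 0.7,
    te_length: int = 60,
    seed: int = 0,
    params: TEFilterParams | None = None,
) -> dict:
    """TE insertion/absence call tables with planted pass/fail labels.

    Returns a dict with per_sample, pooled, absence call lists, the
    consensus store (family -> sequence) and parallel truth labels
    ("pass" / "fail") recording which calls were generated inside the
    filter-passing ranges.
    """
    p = params or TEFilterParams()
    rng = np.random.default_rng(seed)
    contigs = list(genome)
    families = [f"TE{i % 5 + 1}" for i in range(max(n_insertions, 1))]
    consensus = {
        fam: "".join(_BASES[rng.integers(0, 4, size=te_length)])
        for fam in set(families)
    }
    per_sample, pooled, absence = [], [], []
    ins_truth, abs_truth = [], []
    used: set[tuple[str, int]] = set()

    def fresh_position(span: int) -> tuple[str, int]:
        for _ in range(1000):
            contig = contigs[rng.integers(0, len(contigs))]
            limit = len(genome[contig]) - span - 1
            if limit <= 1:
                continue
            start = int(rng.integers(1, limit))
            if all(
                c != contig or abs(start - s) > 2 * p.match_tolerance_bp
                for c, s in used
            ):
                used.add((contig, start))
                return contig, start
        raise RuntimeError("could not place TE call")

    for i in range(n_insertions):
        passing = rng.random() < passing_fraction
        contig, start = fresh_position(0)
        fam = families[i]
        if passing:
            sample_af = float(rng.uniform(p.candidate_af_min, 1.0))
            reads = int(rng.integers(p.candidate_reads_min, 30))
            pooled_af = float(rng.uniform(p.pooled_af_min, 1.0))
        else:
            sample_af = float(rng.uniform(0.0, p.candidate_af_min - 0.005))
            reads = int(rng.integers(p.candidate_reads_min, 30))
            pooled_af = float(rng.uniform(p.pooled_af_min, 1.0))
        sample = f"mouse{int(rng.integers(1, n_samples + 1))}"
        jitter = int(rng.integers(-5, 6))
        per_sample.append(
            TECall(contig, start, start, fam, sample_af, reads, sample)
        )
        pooled.append(
            TECall(
                contig,
                max(0, start + jitter),
                max(0, start + jitter),
                fam,
                pooled_af,
                reads,
                "pooled",
            )
        )
        ins_truth.append("pass" if passing else "fail")

    for _ in range(n_absences):
        passing = rng.random() < passing_fraction
        contig, start = fresh_position(te_length)
        fam = families[int(rng.integers(0, len(families)))]
        if passing:
            reads = int(rng.integers(p.absence_reads_min, 60))
            popfreq = p.absence_popfreq
        else:
            reads = int(rng.integers(0, p.absence_reads_min))
            popfreq = p.absence_popfreq
        absence.append(
            TECall(
                contig, start, start + te_length, fam, popfreq, reads, "pooled"
            )
        )
        abs_truth.append("pass" if passing else "fail")

    return {
        "per_sample": per_sample,
        "pooled": pooled,
        "absence": absence,
        "consensus": consensus,
        "insertion_truth": ins_truth,
        "absence_truth": abs_truth,
    }


def simulate_count_matrix(
    intervals: list[Interval],
    n_replicates: int = 2,
    reproducible_fraction: float = 0.8,
    library_size: int = 10_000_000,
    low: float = 0.5,
    high: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, list[bool]]:
    """Counts over intervals with a planted irreproducible subset.

    Reproducible intervals draw correlated negative-binomial counts
    around a common per-interval mean well above the ``high`` RPKM
    threshold; irreproducible ones get one replicate below ``low`` RPKM
    and one above ``high``.  Returns (matrix, truth) with truth[i] True
    when interval i was planted irreproducible.
    """
    if not 0.0 <= reproducible_fraction <= 1.0:
        raise ValueError("reproducible_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    n = len(intervals)
    lib = np.full(n_replicates, float(library_size))
    truth = list(rng.random(n) >= reproducible_fraction)
    counts = np.zeros((n, n_replicates), dtype=int)
    for i, iv in enumerate(intervals):
        kb = len(iv) / 1e3
        per_rpkm = kb * library_size / 1e6  # counts per unit RPKM
        if truth[i]:
            low_rpkm = rng.uniform(0.0, low * 0.8)
            high_rpkm = rng.uniform(high * 1.2, high * 4)
            # floor/ceil so integer counts stay on the planted side
            counts[i] = np.floor(low_rpkm * per_rpkm)
            counts[i, rng.integers(0, n_replicates)] = np.ceil(
                high_rpkm * per_rpkm
            )
        else:
            mean_rpkm = rng.uniform(high * 1.5, high * 6)
            mu = mean_rpkm * per_rpkm
            # NB with moderate overdispersion, shared mean across reps
            size = 50.0
            p_nb = size / (size + mu)
            counts[i] = rng.negative_binomial(size, p_nb, size=n_replicates)
    return CountMatrix(list(intervals), counts, lib), truth
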