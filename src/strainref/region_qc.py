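"""Peak reproducibility, shuffled controls, enrichment and SNP hotspots.

Utilities for the QC side of a strain survey: RPKM quantification over
merged peak sets, irreproducible-peak selection (strong signal in one
replicate, background in another), placement of shuffled control regions
that avoid a repeat/exclusion set, Fisher's exact test with a star-ladder
annotation, and a Poisson-scan SNP hotspot test with Benjamini-Hochberg
correction.  The hotspot statistic is a genome-wide-rate Poisson upper
tail — a deliberately simple scan; the >= min_snps count filter and the
FDR cutoff are the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genomic_io import Interval

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "rpkm",
    "irreproducible_regions",
    "shuffle_controls",
    "overlap_enrichment",
    "reciprocal_overlap",
    "snp_hotspots",
]


@dataclass
class CountMatrix:
    """Read counts over intervals x replicates plus per-replicate depths."""

    intervals: list[Interval]
    counts: np.ndarray  # shape (n_intervals, n_replicates)
    library_sizes: np.ndarray  # shape (n_replicates,)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.intervals), len(self.library_sizes)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.intervals)} intervals x "
                f"{len(self.library_sizes)} replicates"
            )
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")


@dataclass(frozen=True)
class QCThresholds:
    irreproducible_low: float = 0.5  # 1.0 for the ATAC-style two-replicate set
    irreproducible_high: float = 2.0
    shuffle_max_overlap: float = 0.5
    star_levels: dict[float, str] = field(
        default_factory=lambda: {
            1e-2: "*",
            1e-3: "**",
            1e-5: "***",
            1e-10: "****",
        }
    )
    hotspot_min_snps: int = 50
    hotspot_fdr: float = 0.05


def rpkm(count_matrix: CountMatrix) -> np.ndarray:
    """Reads per kilobase of interval per million mapped reads."""
    lengths = np.array([len(iv) for iv in count_matrix.intervals], dtype=float)
    if (lengths == 0).any():
        bad = count_matrix.intervals[int(np.argmin(lengths))]
        raise ValueError(f"zero-length interval {bad.contig}:{bad.start}")
    length_kb = lengths / 1e3
    per_million = count_matrix.library_sizes / 1e6
    return count_matrix.counts / length_kb[:, None] / per_million[None, :]


def irreproducible_regions(
    intervals: list[Interval],
    rpkm_matrix: np.ndarray,
    low: float = 0.5,
    high: float = 2.0,
) -> list[Interval]:
    """Intervals with min RPKM strictly below ``low`` AND max strictly above ``high``."""
    rpkm_matrix = np.asarray(rpkm_matrix)
    if rpkm_matrix.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    mins = rpkm_matrix.min(axis=1)
    maxs = rpkm_matrix.max(axis=1)
    mask = (mins < low) & (maxs > high)
    return [iv for iv, m in zip(intervals, mask) if m]


def shuffle_controls(
    intervals: list[Interval],
    contig_sizes: dict[str, int],
    excluded: list[Interval] | None = None,
    max_overlap: float = 0.5,
    seed: int = 0,
    max_tries: int = 1000,
) -> list[Interval]:
    """Place length-matched random control regions, avoiding an exclusion set.

    Rejection sampling: each interval keeps its length, is dropped
    uniformly onto a random contig (weighted by placeable span) and is
    rejected while it overlaps the excluded set by more than
    ``max_overlap`` of its own length.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    excluded = excluded or []
    excl_by_contig: dict[str, list[Interval]] = {}
    for iv in excluded:
        excl_by_contig.setdefault(iv.contig, []).append(iv)
    names = list(contig_sizes)
    out = []
    for iv in intervals:
        length = len(iv)
        candidates = [n for n in names if contig_sizes[n] >= length]
        if not candidates:
            raise ValueError(
                f"no contig can hold interval of length {length}"
            )
        weights = np.array(
            [contig_sizes[n] - length + 1 for n in candidates], dtype=float
        )
        weights /= weights.sum()
        placed = None
        for _ in range(max_tries):
            contig = candidates[rng.choice(len(candidates), p=weights)]
            start = int(rng.integers(0, contig_sizes[contig] - length + 1))
            cand = Interval(contig, start, start + length, iv.strand, iv.name)
            overlap = sum(
                cand.overlap(x) for x in excl_by_contig.get(contig, ())
            )
            if overlap <= max_overlap * length:
                placed = cand
                break
        if placed is None:
            raise RuntimeError(
                f"could not place control for {iv.contig}:{iv.start}-{iv.end} "
                f"after {max_tries} tries"
            )
        out.append(placed)
    return out


def _stars(p: float, star_levels: dict[float, str]) -> str:
    """Most significant star whose threshold strictly exceeds p."""
    best = ""
    for cutoff in sorted(star_levels, reverse=True):
        if p < cutoff:
            best = star_levels[cutoff]
    return best


def overlap_enrichment(
    hits_in_test: int,
    n_test: int,
    hits_in_control: int,
    n_control: int,
    star_levels: dict[float, str] | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float, str]:
    """Fisher's exact test on [[hits_t, miss_t], [hits_c, miss_c]].

    Returns (odds_ratio, p_value, stars).  Two-sided by default.
    """
    if hits_in_test > n_test or hits_in_control > n_control:
        raise ValueError("hits cannot exceed totals")
    table = [
        [hits_in_test, n_test - hits_in_test],
        [hits_in_control, n_control - hits_in_control],
    ]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    levels = (
        star_levels
        if star_levels is not None
        else QCThresholds().star_levels
    )
    return float(odds), float(p), _stars(float(p), levels)


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """Overlap as a fraction of ``a``'s length (bedtools -f semantics)."""
    if len(a) == 0:
        return 0.0
    return a.overlap(b) / len(a)


def snp_hotspots(
    regions: list[Interval],
    snp_positions: dict[str, np.ndarray] | list[tuple[str, int]],
    genome_size: int,
    min_snps: int = 50,
    fdr: float = 0.05,
) -> list[tuple[Interval, int, float, float]]:
    """Poisson scan for regions carrying excess SNPs.

    The background rate is |SNPs| / genome_size; each (pre-merged,
    non-overlapping) region gets an upper-tail Poisson p-value at its
    observed count, then Benjamini-Hochberg correction across regions.
    Significant hotspots need count >= ``min_snps`` and q < ``fdr``.
    Returns (region, count, p, q) for the significant regions.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if isinstance(snp_positions, dict):
        pos_by_contig = {
            c: np.sort(np.asarray(p)) for c, p in snp_positions.items()
        }
    else:
        pos_by_contig = {}
        for contig, pos in snp_positions:
            pos_by_contig.setdefault(contig, []).append(pos)
        pos_by_contig = {
            c: np.sort(np.asarray(p)) for c, p in pos_by_contig.items()
        }
    n_snps = sum(len(p) for p in pos_by_contig.values())
    lam = n_snps / genome_size
    counts = []
    pvals = []
    for region in regions:
        pos = pos_by_contig.get(region.contig)
        if pos is None:
            count = 0
        else:
            count = int(
                np.searchsorted(pos, region.end, side="left")
                - np.searchsorted(pos, region.start, side="left")
            )
        counts.append(count)
        mu = lam * len(region)
        # upper tail P(X >= count) under Poisson(mu)
        pvals.append(float(stats.poisson.sf(count - 1, mu)))
    if not regions:
        return []
    qvals = stats.false_discovery_control(pvals, method="bh")
    return [
        (region, count, p, float(q))
        for region, count, p, q in zip(regions, counts, pvals, qvals)
        if count >= min_snps and q < fdr
    ]
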