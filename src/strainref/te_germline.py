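"""Germline transposable-element (TE) call filtering.

Raw TE insertion/absence calls (TEMP2-style tables) are reduced to
germline sets in three steps:

1. *candidate* germline insertions — per-sample calls with allele
   frequency >= 0.495 (a germline TE is fully present on at least one of
   the two alleles; 0.495 leaves room for sequencing error below 50%) and
   at least two supporting reads, deduplicated across samples;
2. *germline* insertions — pooled-cohort calls with population allele
   frequency >= just under 10% (one germline allele among ten, minus
   error slack) that match a candidate by family and position window;
3. *germline absences* — pooled reference-TE absence calls with at least
   10 supporting reads and an estimated population frequency of 100%.

Breakpoint estimates jitter between runs, so candidate <-> pooled matching
uses a configurable bp window rather than exact coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TECall",
    "TEFilterParams",
    "candidate_germline_insertions",
    "germline_insertions",
    "germline_absences",
    "read_te_table",
    "write_te_table",
]

_ABS_TOL = 1e-9


@dataclass(frozen=True)
class TECall:
    """One TE insertion or absence call.

    ``start``/``end`` span the affected reference interval (0-based
    half-open); for insertion calls ``start == end`` is the insertion
    point.  ``sample_id`` is "pooled" for cohort-merged calls.
    """

    contig: str
    start: int
    end: int
    te_family: str
    allele_frequency: float
    supporting_reads: int
    sample_id: str

    def __post_init__(self):
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(
                f"allele_frequency {self.allele_frequency} outside [0,1]"
            )
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be >= 0")


@dataclass(frozen=True)
class TEFilterParams:
    candidate_af_min: float = 0.495
    candidate_reads_min: int = 2
    pooled_af_min: float = 0.0995  # "just under 10%"
    absence_reads_min: int = 10
    absence_popfreq: float = 1.0
    match_tolerance_bp: int = 50


def _matches(a: TECall, b: TECall, tol: int) -> bool:
    return (
        a.contig == b.contig
        and a.te_family == b.te_family
        and abs(a.start - b.start) <= tol
    )


def candidate_germline_insertions(
    per_sample_calls: list[TECall], params: TEFilterParams | None = None
) -> list[TECall]:
    """Per-sample calls passing the AF and read-support floors, deduplicated.

    Calls from different samples that agree on (contig, family) and lie
    within ``match_tolerance_bp`` of each other count as one candidate;
    the first call in (contig, start) order represents the group.
    """
    p = params or TEFilterParams()
    passing = sorted(
        (
            c
            for c in per_sample_calls
            if c.sample_id != "pooled"
            and c.allele_frequency >= p.candidate_af_min
            and c.supporting_reads >= p.candidate_reads_min
        ),
        key=lambda c: (c.contig, c.start, c.te_family, c.sample_id),
    )
    kept: list[TECall] = []
    for call in passing:
        if not any(_matches(call, k, p.match_tolerance_bp) for k in kept):
            kept.append(call)
    return kept


def germline_insertions(
    pooled_calls: list[TECall],
    candidates: list[TECall],
    params: TEFilterParams | None = None,
) -> list[TECall]:
    """Pooled calls above the population-AF floor with a candidate witness."""
    p = params or TEFilterParams()
    out = []
    for call in pooled_calls:
        if call.sample_id != "pooled":
            raise ValueError(
                f"pooled call expected, got sample_id={call.sample_id!r}"
            )
        if call.allele_frequency < p.pooled_af_min:
            continue
        if any(_matches(call, c, p.match_tolerance_bp) for c in candidates):
            out.append(call)
    return sorted(out, key=lambda c: (c.contig, c.start))


def germline_absences(
    pooled_absence_calls: list[TECall], params: TEFilterParams | None = None
) -> list[TECall]:
    """Reference-TE absence calls fixed in the cohort with strong support."""
    p = params or TEFilterParams()
    return sorted(
        (
            c
            for c in pooled_absence_calls
            if c.supporting_reads >= p.absence_reads_min
            and abs(c.allele_frequency - p.absence_popfreq) <= _ABS_TOL
        ),
        key=lambda c: (c.contig, c.start),
    )


_TE_COLUMNS = ["contig", "start", "end", "family", "af", "reads", "sample"]


def read_te_table(path) -> list[TECall]:
    """Read a BED-like TE call TSV (contig start end family af reads sample)."""
    df = pd.read_csv(path, sep="\t", names=_TE_COLUMNS, comment="#")
    return [
        TECall(
            contig=str(r.contig),
            start=int(r.start),
            end=int(r.end),
            te_family=str(r.family),
            allele_frequency=float(r.af),
            supporting_reads=int(r.reads),
            sample_id=str(r.sample),
        )
        for r in df.itertuples()
    ]


def write_te_table(calls: list[TECall], path) -> None:
    df = pd.DataFrame(
        [
            (
                c.contig,
                c.start,
                c.end,
                c.te_family,
                c.allele_frequency,
                c.supporting_reads,
                c.sample_id,
            )
            for c in calls
        ],
        columns=_TE_COLUMNS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)
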