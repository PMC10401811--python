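"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from strainref.genomic_io import Genome
from strainref.synthetic_fixtures import simulate_genome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return simulate_genome({"chr1": 5000, "chr2": 3000}, gc_content=0.42, seed=11)


@pytest.fixture(scope="session")
def genome_100kb() -> Genome:
    return simulate_genome({"chr1": 100_000}, gc_content=0.42, seed=13)


def naive_apply(seq: str, edits):
    """Character-by-character replay of a resolved, sorted edit list.

    Independent oracle for apply_edits/liftover: returns the edited
    sequence and a per-base map base index -> edited index (None when the
    base is deleted or covered by a length-changing replacement).
    """
    out: list[str] = []
    mapping: dict[int, int | None] = {}
    t = 0
    for e in edits:
        s, en = e.ref_interval
        while t < s:
            mapping[t] = len(out)
            out.append(seq[t])
            t += 1
        if en > s and len(e.alt_seq) == en - s:
            # length-preserving replacement: bases stay aligned
            for i, ch in enumerate(e.alt_seq):
                mapping[s + i] = len(out)
                out.append(ch)
        else:
            for i in range(s, en):
                mapping[i] = None
            out.extend(e.alt_seq)
        t = en
    while t < len(seq):
        mapping[t] = len(out)
        out.append(seq[t])
        t += 1
    return "".join(out), mapping
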