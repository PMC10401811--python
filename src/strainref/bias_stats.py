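"""Probability models for genotype-configuration bias and SNP discovery.

Three small models quantify how segregating (non-uniform) variants and
finite cohort sizes limit what a strain survey can see:

**Genotype-configuration bias.**  At a biallelic site with alleles a/b at
frequency f (independent allele draws, Hardy-Weinberg), an experiment
with ``n_treatment`` and ``n_control`` animals is *biased* when every
animal in one group shares a homozygous genotype that no animal in the
other group carries (in either direction).  Uniformly heterozygous groups
are deliberately not part of the event: the enumeration underlying the
published constant 0.0009250641 = 970 x 0.5^20 for the 5 + 5, f = 0.5
design counts shared *homozygous* genotypes only.  The closed form is an
inclusion-exclusion over the four single-direction events

    A1 = {treatment all aa, no control aa}   f^(2nt) (1 - f^2)^nc
    A2 = {treatment all bb, no control bb}   g^(2nt) (1 - g^2)^nc
    B1 = {control all aa, no treatment aa}   f^(2nc) (1 - f^2)^nt
    B2 = {control all bb, no treatment bb}   g^(2nc) (1 - g^2)^nt

with g = 1 - f, minus the two jointly realisable cross terms
A1 & B2 = f^(2nt) g^(2nc) and A2 & B1 = g^(2nt) f^(2nc) (all other
pairwise intersections are empty).  A brute-force enumeration over all
4^(nt+nc) ordered genotype assignments serves as the independent oracle.

**Allele detection power.**  The chance that a cohort of n animals holds
no copy of an allele at population frequency q is (1-q)^(2n) over the 2n
independently drawn alleles.

**SNP-discovery saturation.**  Discovered-variant counts as a function of
cohort size x follow the asymptotic curve N(x) = a - (a-c) exp(-b (x-x0)),
which approaches a as x grows and equals c at the anchor x0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BiasModelParams",
    "SaturationModel",
    "biased_config_probability",
    "biased_config_prob_bruteforce",
    "expected_biased_regions",
    "near_gene_biased_estimate",
    "detection_miss_probability",
    "eval_saturation",
    "fit_saturation",
]


@dataclass(frozen=True)
class BiasModelParams:
    n_treatment: int = 5
    n_control: int = 5
    allele_freq: float = 0.5

    def __post_init__(self):
        if self.n_treatment < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(
                f"allele_freq must lie in (0,1), got {self.allele_freq}"
            )


@dataclass(frozen=True)
class SaturationModel:
    """Parameters of N(x) = a - (a-c) exp(-b (x - x0))."""

    a: float
    b: float
    c: float
    x0: float = 3.0

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("rate b must be positive")


def biased_config_probability(params: BiasModelParams) -> float:
    """P(one group uniformly homozygous for a genotype absent in the other).

    Closed-form inclusion-exclusion; reduces to 970 x 0.5^20 for the
    symmetric 5 + 5 design at f = 0.5.
    """
    f = params.allele_freq
    g = 1.0 - f
    nt, nc = params.n_treatment, params.n_control
    a1 = f ** (2 * nt) * (1 - f * f) ** nc
    a2 = g ** (2 * nt) * (1 - g * g) ** nc
    b1 = f ** (2 * nc) * (1 - f * f) ** nt
    b2 = g ** (2 * nc) * (1 - g * g) ** nt
    cross = f ** (2 * nt) * g ** (2 * nc) + g ** (2 * nt) * f ** (2 * nc)
    return a1 + a2 + b1 + b2 - cross


def biased_config_prob_bruteforce(params: BiasModelParams) -> float:
    """Exhaustive enumeration over all 4^(nt+nc) ordered genotype draws.

    Each animal independently draws an ordered genotype from
    {aa, ab, ba, bb} with probabilities {f^2, fg, gf, g^2}.  Kept as the
    independent verification oracle for the closed form; refuses designs
    past desk scale.
    """
    nt, nc = params.n_treatment, params.n_control
    n = nt + nc
    if n > 12:
        raise ValueError(
            f"{n} animals means 4^{n} configurations; use the closed form"
        )
    f = params.allele_freq
    g = 1.0 - f
    # genotype codes 0=aa 1=ab 2=ba 3=bb
    probs = np.array([f * f, f * g, g * f, g * g])
    configs = np.array(
        list(itertools.product(range(4), repeat=n)), dtype=np.int8
    )
    p_config = probs[configs].prod(axis=1)
    treat, ctrl = configs[:, :nt], configs[:, nt:]
    t_aa = (treat == 0).all(axis=1)
    t_bb = (treat == 3).all(axis=1)
    c_aa = (ctrl == 0).all(axis=1)
    c_bb = (ctrl == 3).all(axis=1)
    c_no_aa = ~(ctrl == 0).any(axis=1)
    c_no_bb = ~(ctrl == 3).any(axis=1)
    t_no_aa = ~(treat == 0).any(axis=1)
    t_no_bb = ~(treat == 3).any(axis=1)
    event = (
        (t_aa & c_no_aa)
        | (t_bb & c_no_bb)
        | (c_aa & t_no_aa)
        | (c_bb & t_no_bb)
    )
    return float(p_config[event].sum())


def expected_biased_regions(
    n_variants: int, params: BiasModelParams | None = None
) -> int:
    """Expected count of biased sites: round(n x P(bias)), half-up."""
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    p = biased_config_probability(params or BiasModelParams())
    return int(math.floor(n_variants * p + 0.5))


def near_gene_biased_estimate(
    counts: list[int], near_gene_fraction: float
) -> int:
    """floor(sum(counts) x fraction): biased regions expected near genes."""
    if not 0.0 <= near_gene_fraction <= 1.0:
        raise ValueError("fraction must lie in [0,1]")
    return int(math.floor(sum(counts) * near_gene_fraction))


def detection_miss_probability(n_mice: int, pop_freq: float) -> float:
    """P(no copy of an allele at frequency ``pop_freq`` in 2 x n alleles)."""
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    if not 0.0 <= pop_freq <= 1.0:
        raise ValueError("pop_freq must lie in [0,1]")
    return (1.0 - pop_freq) ** (2 * n_mice)


def eval_saturation(model: SaturationModel, x) -> float:
    """Evaluate N(x) = a - (a-c) exp(-b (x - x0))."""
    return model.a - (model.a - model.c) * np.exp(-model.b * (x - model.x0))


def fit_saturation(
    xs, counts, x0: float = 3.0, max_iter: int = 5000
) -> SaturationModel:
    """Nonlinear least squares fit of the saturation curve.

    Start values follow the original fitting recipe: c0 = count at the
    smallest x, b0 = 1, a0 solved from the model equation at the largest
    x.  With exactly three distinct points the 3-parameter fit
    interpolates them to solver tolerance.
    """
    xs = np.asarray(xs, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(np.unique(xs)) < 3:
        raise ValueError("need at least 3 distinct x values")
    order = np.argsort(xs)
    xs, counts = xs[order], counts[order]
    c0 = counts[0]
    b0 = 1.0
    decay = math.exp(-b0 * (xs[-1] - x0))
    a0 = (counts[-1] - c0 * decay) / (1.0 - decay)

    def residuals(theta):
        a, b, c = theta
        return a - (a - c) * np.exp(-b * (xs - x0)) - counts

    result = least_squares(
        residuals,
        x0=[a0, b0, c0],
        max_nfev=max_iter,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not result.success:
        raise RuntimeError(
            f"saturation fit did not converge: {result.message}; "
            f"last iterate a={result.x[0]:g} b={result.x[1]:g} c={result.x[2]:g}"
        )
    a, b, c = result.x
    return SaturationModel(a=float(a), b=float(b), c=float(c), x0=x0)
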