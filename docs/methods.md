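# Methods

This note documents the models, the default parameters and the numerical
choices behind `strainref`, and what the synthetic-data generators do and
do not emulate.

## Coordinate conventions

All in-memory coordinates are 0-based half-open. VCF (1-based) and GTF
(1-based, inclusive ends) are converted at the I/O boundary and nowhere
else; the converters are inverses and round-trip tested. Soft-masked
(lowercase) bases are preserved on read/write but treated as their
uppercase nucleotide in all comparisons.

## Variant classification

Sites first pass GATK-style hard filters. Defaults, all strict
inequalities on the *fail* side:

| class | fail when |
| --- | --- |
| SNP | QD < 2.0, QUAL < 30.0, SOR > 3.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5, ReadPosRankSum < −8.0 |
| indel | QD < 2.0, QUAL < 30.0, FS > 200.0, ReadPosRankSum < −20.0 |

A missing annotation skips that sub-filter instead of failing the site.
This mirrors how GATK VariantFiltration behaves when an annotation is
absent (e.g. MQRankSum is only emitted at sites with heterozygotes), and
the skip is logged.

Classification, for a 5-animal cohort (AN = 10 when fully called):

* **uniform**: biallelic, AF > 0.8 and AC > 5 — every animal carries the
  alternate allele and more than half the cohort's alleles were seen.
* **non-uniform**: biallelic with 0.2 < AF ≤ 0.8 and AC > 2, or
  multi-allelic with AN > 5 and the most frequent alternate allele
  exceeding 20% of called alleles.

Boundary behaviour is exactly as stated: AF = 0.8 falls on the
non-uniform side, AC = 5 is not uniform. "Allele frequency" means the
single alt-allele frequency for biallelic sites and the
most-frequent-alt fraction for multi-allelic ones; ties in the top
allele count give the same fraction either way, so no tie-break is
needed.

Down-sampled cohorts reuse the machinery with integer thresholds scaled
to keep the AC cutoffs at roughly the same fraction of the allele total:
uniform AC > {2, 3, 4} and non-uniform biallelic AC > {0, 1, 1}, with
multi-allelic AN > {2, 3, 4}, for 2, 3, 4 animals. The AC > 0 rule at
n = 2 admits any non-reference allele; that is the documented intent of
the proportional scaling, kept as quoted even though it is permissive.

Nearby-indel removal measures the gap between half-open reference spans
after stripping the shared VCF anchor base; with the default spacing of
1, exactly the touching/overlapping pairs are removed, and both members
of an offending pair are dropped. SNPs whose base lies inside a
surviving indel's span (for pure insertions, the anchor base) are then
excluded.

## Germline TE filters

Candidate insertions need per-sample allele frequency ≥ 0.495 (a
germline TE is fully present on at least one of two alleles; the 0.005
slack absorbs sequencing error) and ≥ 2 supporting reads. Pooled calls
need population AF ≥ 0.0995 ("just under" one allele in ten) *and* a
candidate witness with the same family within a 50 bp window — TE
breakpoint estimates jitter between runs, so exact-coordinate matching
would be wrong; the window is configurable. Reference-TE absences need
≥ 10 supporting reads and a population frequency of exactly 100%
(compared with 1e-9 tolerance). All three filters are monotone in their
thresholds.

## Genome building and chains

Edits carry a kind with priority te_remove = te_insert > indel >
snp_sub > n_mask. Overlap resolution is greedy in (priority, start,
end, alt) order, hence deterministic under input permutation; losers are
logged with the winning edit. Two same-priority edits on the identical
interval with different replacements are a contradictory call set and
raise. Pure insertions anchor *before* their position; an insertion at
an interval boundary does not conflict with that interval.

The build runs in two stages, TEs first, because applying TEs changes
all downstream coordinates: stage 1 produces the TE-hybrid genome and
chain₁; stage 2 lifts every SNP/indel/mask coordinate through chain₁
(variants falling inside removed TEs are dropped and counted, not
fatal), applies them, and yields chain₂. The returned chain is
compose(chain₁, chain₂). Reversing the stage order would silently
corrupt coordinates; this ordering is part of the contract.

Chain semantics: blocks are *alignments*, not identity runs, so
equal-length replacements (substitutions, N-masks) stay inside ungapped
blocks, exactly as UCSC chains represent mismatches. Only
length-changing edits break blocks, contributing dt = |ref| and
dq = |alt| at the break. Edits at contig ends that would create leading
or trailing gaps are absorbed into the chain's start/end offsets (a
chain need not cover a full contig). The chain score is the sum of
block sizes (uninterpreted by liftover); ids are sequential.

Length conservation (|edited| − |base| = Σ|alt| − Σ|ref| per contig) and
the N-count identity (Ns introduced = applied masks, given an N-free
base) are exact invariants, tested against a character-by-character
replay oracle on randomized edit plans.

## Liftover

Positions inside blocks map affinely; positions in dt gaps report
`deleted`; unknown contigs report `no_chain`. Interval lifting in strict
mode requires both end bases mappable and ≥ 95% of bases mappable
(min_match = 0.95, the classic liftOver default — configurable); partial
mode trims to the mappable core. VCF lifting requires the whole REF
span to map contiguously and to match the target sequence; rejects are
returned with reasons rather than dropped, and on self-built chains the
ref-mismatch count is zero by construction (mapping is exact, not
re-aligned). GTF lifting converts each exon strictly and keeps a
transcript only if *all* its exons convert (exclude-partial semantics);
failed exon ids and conversion fractions are reported.

Chain composition intersects aligned segments in the shared middle
coordinate system; inversion swaps target/query and dt/dq. Both are
checked against sequential per-position lifting on randomized two-stage
plans. The builder only emits + strand chains; the reader accepts −
strand query chains from external sources and normalises them to
forward coordinates.

Exon-sequence validation walks every converted exon base through the
chain and demands base-for-base identity between assemblies except where
the edit plan documents a substitution (the alt base) or a mask (`N`);
the expected outcome, asserted in tests over 50 random plans, is zero
unexplained differences.

## Probability models

**Bias model.** Alleles are drawn independently per chromosome
(Hardy–Weinberg, no relatedness). The biased event is: one group
uniformly *homozygous* for a genotype no member of the other group
carries, in either direction. A uniformly heterozygous group is
deliberately excluded — the enumeration behind the published constant
counts homozygous splits only, and including the het case would change
the number. Closed form (g = 1 − f):

    P = f^2nt (1−f²)^nc + g^2nt (1−g²)^nc
      + f^2nc (1−f²)^nt + g^2nc (1−g²)^nt
      − f^2nt g^2nc − g^2nt f^2nc

The two subtracted terms are the only jointly realisable intersections
(one group all-aa while the other is all-bb). At (5, 5, 0.5) this equals
970·0.5²⁰ = 0.0009250641. A 4^(nt+nc) enumeration oracle (vectorised,
refused above 12 animals) agrees to < 1e-12 across the tested grid.
One empirical note: the f-profile is symmetric about 0.5 but is *not*
maximised at f = 0.5 for the 5 + 5 design — skewed frequencies make
"one group all major-homozygous" easier; the maximum sits near
f ≈ 0.3/0.7. Expected biased-region counts round half-up
(925.06 → 925, 231.27 → 231; truncation would give the same values
here), and the near-gene estimate floors the product.

**Detection power.** (1 − q)^2n over 2n independent alleles. At
(12, 0.1) this is 0.9²⁴ ≈ 0.0798 → 0.08. At 20 animals the formula
gives 0.9⁴⁰ ≈ 0.0148, which rounds to 0.01 only at one decimal; the
formula is reported as-is.

**Saturation curve.** N(x) = a − (a−c)·exp(−b(x−x₀)), anchored at
x₀ = 3 by default (the smallest cohort size with stable allele-frequency
granularity). Fitting is Levenberg–Marquardt-style least squares
(scipy `least_squares`, max 5000 evaluations, tolerances 1e-14) with the
original start-value recipe: c₀ = count at the smallest x, b₀ = 1, a₀
solved from the model at the largest x. Three distinct x values are
required; with exactly three the fit interpolates. Non-convergence
raises with the last iterate. The published parameter sets
(a = 2.117e6, b = 0.5501, c = 2.892e6 and a = 4.174e6, b = 0.8065,
c = 2.978e6) evaluated at x = 5 reproduce the 5-animal discovery totals
to ~3e-5 relative.

## Region QC

RPKM is counts / (interval kb × library millions). Irreproducible peaks
have min RPKM strictly below the low threshold *and* max strictly above
the high one (defaults 0.5/2.0 for multi-replicate ChIP-style sets;
1.0/2.0 is the documented alternative for two-replicate ATAC-style
sets). Shuffled controls are rejection-sampled uniformly (contig chosen
proportional to placeable span) until overlap with the exclusion set is
≤ 50% of the interval's own length, with a bounded retry count;
placement is deterministic per seed. Enrichment is two-sided Fisher's
exact (one-sided available by flag) with the star ladder
p < .01 / .001 / 1e-5 / 1e-10, strict comparisons, most significant
level reported.

The SNP hotspot scan is a Poisson test: background rate λ = total SNPs /
genome size, per-region upper-tail p at the observed count under
Poisson(λ·length), Benjamini–Hochberg across regions, and significance
requires count ≥ 50 *and* q < 0.05. This is deliberately simpler than
exact locus-level permutation statistics; the count and FDR filters are
the reproducible contract, and the null false-positive rate on uniform
scatter is verified ≤ 5% over 200 seeded simulations.

## Synthetic data

Generators are pure functions of (parameters, seed). The cohort
generator draws 2n alleles i.i.d. at each site's population frequency —
the same independence assumption the bias model makes — and stores the
drawn allele counts as truth, so downstream recall is exactly
predictable: for balanced sites, P(classified non-uniform) is the
Binomial(10, 0.5) mass on 3 ≤ AC ≤ 8, ≈ 0.9346. A consequence worth
stating: ~1/1024 of balanced sites draw AC = 10 and are then *correctly*
classified uniform by the rule; planted truth refers to the generating
frequency, not the draw. Site annotations are sampled uniformly inside
the hard-filter passing ranges; filter behaviour is tested with explicit
failing injections (QD below cutoff), not by modelling caller annotation
distributions. Count matrices plant irreproducible peaks by placing one
replicate below 0.8× the low RPKM threshold and one above 1.2× the high
one, with floor/ceil rounding so integer counts stay on the planted
side; reproducible peaks share a negative-binomial mean well above the
high threshold.

What the generators do **not** emulate: linkage between sites,
relatedness within the cohort, sequencing error, alignment artefacts,
caller-specific annotation distributions, or realistic TE breakpoint
uncertainty beyond a ±5 bp jitter. Passing tests therefore demonstrate
the correctness of the *rules and transforms*, not robustness to
real-data noise upstream of the VCF/tables.

## Problem sizes

The default verification workloads are desk-scale by design: 100 kb
contigs with ~120-edit plans (50 seeded plans in the structural checks),
1,000 + 1,000 planted cohort sites, and 200 hotspot null simulations of
30,000 SNPs over 1 Mb. All structural assertions (length conservation,
chain sums, round trips, exon identity) are exact at any scale; the
sizes only bound the sampling noise of the statistical checks.

## Known limitations

* Chains with − strand *targets* are not supported (never produced by
  the builder; rare in external chains).
* A contig whose every base is edited by length-changing edits has no
  aligned segment and gets no chain (all positions unmapped).
* The hotspot test assumes pre-merged, non-overlapping regions and a
  homogeneous background rate; regional mutation-rate variation will
  inflate calls, as with any genome-wide-λ scan.
* `lift_interval` is per-base and intended for annotation-scale
  intervals, not whole-chromosome spans.
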