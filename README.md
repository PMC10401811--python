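# strainref

Toolkit for building and interrogating **strain-specific reference
genomes** for outbred laboratory populations (the motivating case is an
outbred mouse stock sequenced against the mm10 assembly, but nothing is
mouse-specific).

## The problem

Genomics experiments on outbred animals are usually analysed against a
reference genome from a different, inbred strain. Two classes of genetic
difference then corrupt downstream analyses:

* **uniform variants** — sites where every animal of the stock carries
  the same allele, which differs from the reference. Reads mismatch the
  reference systematically, costing mappability and producing false
  methylation/peak calls.
* **non-uniform variants** — sites segregating *within* the stock.
  These are worse: different animals carry different alleles, so
  treatment/control comparisons can be confounded purely by which
  genotypes were randomised into which group, and allele-specific
  mapping bias varies per animal.

The fix implemented here: call variants on a cohort, substitute the
uniform alleles into the reference, and replace each non-uniform SNP
position with `N` so aligners neither reward nor penalise any allele
there (**N-masking**). Germline transposable-element (TE) insertions and
absences are applied the same way. Exact UCSC **chain files** relating
the old and new coordinate systems are emitted as a by-product of the
edit, so positions, VCFs and gene annotations can be lifted between
assemblies with zero alignment error.

## What is in the box

| module | contents |
| --- | --- |
| `strainref.genomic_io` | FASTA / VCF 4.x / BED / GTF / UCSC chain readers and writers; internal coordinates are uniformly 0-based half-open |
| `strainref.variant_classification` | GATK-style hard filters (QD, QUAL, SOR, FS, MQ, MQRankSum, ReadPosRankSum), uniform / non-uniform AF–AC rules, nearby-indel removal, SNP-over-indel exclusion, cohort down-sampling |
| `strainref.te_germline` | germline TE insertion/absence filters (per-sample AF ≥ 0.495 with ≥ 2 reads; pooled AF ≥ ~10% with a candidate witness; absences with ≥ 10 reads at 100% population frequency) |
| `strainref.genome_builder` | edit-plan conflict resolution, two-stage genome editing (TEs first, then SNPs/indels/masks), exact chain generation |
| `strainref.liftover` | position/interval/VCF/GTF liftover, chain composition and inversion, exon-sequence validation |
| `strainref.bias_stats` | genotype-configuration bias probability (closed form + enumeration oracle), allele-detection power, saturation-curve fit N(x) = a − (a−c)·e^(−b(x−x₀)) |
| `strainref.region_qc` | RPKM, irreproducible-peak selection, shuffled controls with repeat exclusion, Fisher enrichment with star ladder, Poisson SNP-hotspot scan with BH correction |
| `strainref.synthetic_fixtures` | seeded generators for genomes, cohorts, TE calls, count matrices and edit plans, all with truth labels |
| `strainref.cli` | `strainref` command: `classify`, `te-filter`, `build`, `lift`, `stats`, `qc`, `simulate` |

## The core statistics

At a balanced biallelic site (alleles a/b, frequency f, Hardy–Weinberg),
an experiment with n_t treatment and n_c control animals is *biased*
when one whole group shares a homozygous genotype absent from the other
group. With g = 1 − f:

P = f^2nₜ(1−f²)^nᶜ + g^2nₜ(1−g²)^nᶜ + f^2nᶜ(1−f²)^nₜ + g^2nᶜ(1−g²)^nₜ
    − f^2nₜ g^2nᶜ − g^2nₜ f^2nᶜ

For the 5 + 5 design at f = 0.5 this is 970·0.5²⁰ = 0.0009250641, i.e.
~925 expected biased regions per 10⁶ balanced SNPs. The package verifies
the closed form against exhaustive enumeration of all 4¹⁰ ordered
genotype configurations.

A cohort of n animals misses an allele at population frequency q with
probability (1−q)^2n, and variant discovery as a function of cohort size
x follows the saturation curve N(x) = a − (a−c)·exp(−b(x−x₀)).

## Worked example

```python
from strainref.bias_stats import (BiasModelParams, biased_config_probability,
                                  expected_biased_regions, detection_miss_probability)
from strainref.genomic_io import Genome, VariantRecord
from strainref.genome_builder import build_reference

p = biased_config_probability(BiasModelParams(n_treatment=5, n_control=5, allele_freq=0.5))
print(f"P(biased genotype split) = {p:.10f}")
print(f"expected biased regions per 1e6 balanced SNPs = {expected_biased_regions(10**6)}")
print(f"P(12-mouse cohort misses a 10% allele) = {detection_miss_probability(12, 0.1):.4f}")

base = Genome(chr1="ACGTACGTACGTACGTACGT")
uniform = [VariantRecord("chr1", 3, "G", ["T"], ac=[10], an=10, af=[1.0])]      # fixed difference
nonuniform = [VariantRecord("chr1", 10, "C", ["A"], ac=[5], an=10, af=[0.5])]   # segregating
final, chain, reports = build_reference(base, uniform_variants=uniform,
                                        nonuniform_snps=nonuniform)
print("base  :", base["chr1"])
print("strain:", final["chr1"])
print("chain blocks:", chain[0].blocks)
```

prints

```
P(biased genotype split) = 0.0009250641
expected biased regions per 1e6 balanced SNPs = 925
P(12-mouse cohort misses a 10% allele) = 0.0798
base  : ACGTACGTACGTACGTACGT
strain: ACTTACGTANGTACGTACGT
chain blocks: [(20, 0, 0)]
```

The uniform SNP at position 3 became a `T` in the strain reference, the
segregating SNP at position 10 became `N`, and because both edits
preserve length the chain is a single ungapped 20-bp block (chain blocks
are alignments, not identity runs; substitutions stay inside blocks).

The same pipeline from a shell:

```
strainref simulate --out fixtures/ --seed 1
strainref classify --vcf fixtures/cohort.vcf --out-prefix work/cls
strainref build --base fixtures/genome.fa --uniform work/cls.uniform.vcf \
    --nonuniform work/cls.nonuniform.vcf --out work/build
strainref lift pos --chain work/build/base_to_strain.chain --contig chr1 --pos 1234
strainref stats bias-prob --n-treat 5 --n-ctrl 5 --freq 0.5
```

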