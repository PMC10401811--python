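"""Readers and writers for the standard formats the toolkit touches.

All in-memory coordinates are 0-based half-open.  Conversion to the
1-based conventions of VCF and GTF happens only at the I/O boundary, so
interval arithmetic everywhere else uses a single convention.

Formats handled: FASTA (via Bio.SeqIO), VCF 4.x (read via pysam, written
directly), BED3+, GTF (UCSC refFlat/ncbiRefSeq attribute style, parsed
with gffutils), and the UCSC chain format (hand-rolled: no installed
library reads, writes or composes chains, and the chain algebra is a core
part of this toolkit).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "Genome",
    "Interval",
    "VariantRecord",
    "GtfRecord",
    "ChainAlignment",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_gtf",
    "write_gtf",
    "read_chain",
    "write_chain",
]

_NUC_RE = re.compile(r"^[ACGTUNRYSWKMBDHVacgtunryswkmbdhv]*$")

SITE_ANNOTATION_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


class Genome(dict):
    """Ordered map of contig name -> nucleotide string (case preserved).

    A thin dict subclass so plain ``genome["chr1"]`` access works; helper
    methods cover the common queries.
    """

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self[contig]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {contig} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def base_at(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos + 1)


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Length of the overlap with ``other`` (0 if disjoint/other contig)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class VariantRecord:
    """One VCF site: alleles, per-sample genotypes and site annotations.

    ``pos`` is the 1-based reference position exactly as in the VCF column;
    ``ref_interval()`` exposes the 0-based half-open span of the REF allele.
    Multi-allelic sites stay single records; ``af``/``ac`` are parallel to
    ``alt_alleles``.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    qual: float | None = None
    site_annotations: dict[str, float] = field(default_factory=dict)
    genotypes: list[tuple[int | None, int | None]] = field(default_factory=list)
    af: list[float] = field(default_factory=list)
    ac: list[int] = field(default_factory=list)
    an: int = 0
    filter_status: str = "PASS"
    id: str = "."
    af_derived: bool = False

    @property
    def n_alts(self) -> int:
        return len(self.alt_alleles)

    @property
    def is_biallelic(self) -> bool:
        return self.n_alts == 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    @property
    def start(self) -> int:
        """0-based start of the REF allele."""
        return self.pos - 1

    def ref_interval(self) -> tuple[int, int]:
        return self.start, self.start + len(self.ref_allele)

    @property
    def max_alt_af(self) -> float:
        return max(self.af) if self.af else 0.0

    @property
    def max_alt_ac(self) -> int:
        return max(self.ac) if self.ac else 0

    def recompute_frequencies(self) -> None:
        """Recompute AC/AN/AF from genotypes (marks them genotype-derived)."""
        alleles = [
            a for gt in self.genotypes for a in gt if a is not None
        ]
        self.an = len(alleles)
        self.ac = [alleles.count(i + 1) for i in range(self.n_alts)]
        self.af = [
            (c / self.an if self.an > 0 else 0.0) for c in self.ac
        ]
        self.af_derived = True

    def validate(self, genome: Genome | None = None) -> None:
        for c in self.ac:
            if c > self.an:
                raise ValueError(
                    f"{self.contig}:{self.pos}: AC={c} exceeds AN={self.an}"
                )
        if self.genotypes and self.an > 2 * len(self.genotypes):
            raise ValueError(
                f"{self.contig}:{self.pos}: AN={self.an} exceeds "
                f"2 x {len(self.genotypes)} samples"
            )
        if genome is not None:
            s, e = self.ref_interval()
            found = genome.fetch(self.contig, s, e).upper()
            if found != self.ref_allele.upper():
                raise ValueError(
                    f"{self.contig}:{self.pos}: REF {self.ref_allele} does not "
                    f"match genome sequence {found}"
                )


@dataclass
class GtfRecord:
    """One GTF feature; interval stored 0-based half-open in memory."""

    contig: str
    source: str
    feature: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    score: str
    strand: str
    frame: str
    attributes: dict[str, str]

    @property
    def gene_id(self) -> str | None:
        return self.attributes.get("gene_id")

    @property
    def transcript_id(self) -> str | None:
        return self.attributes.get("transcript_id")

    def interval(self) -> Interval:
        return Interval(self.contig, self.start, self.end, self.strand)


@dataclass
class ChainAlignment:
    """A UCSC chain: ungapped blocks relating target and query assemblies.

    ``blocks`` is a list of (size, dt, dq); the final block has dt = dq = 0
    (the chain file's last line carries the size only).  Target = base
    genome, query = edited genome for chains produced by this toolkit.
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]
    id: int = 1

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError(f"chain {self.id}: no alignment blocks")
        t_span = sum(size + dt for size, dt, _ in self.blocks)
        q_span = sum(size + dq for size, _, dq in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.id}: block target span {t_span} != "
                f"t_end - t_start = {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.id}: block query span {q_span} != "
                f"q_end - q_start = {self.q_end - self.q_start}"
            )
        last = self.blocks[-1]
        if last[1] != 0 or last[2] != 0:
            raise ValueError(f"chain {self.id}: final block must carry size only")
        for size, dt, dq in self.blocks:
            if size <= 0 or dt < 0 or dq < 0:
                raise ValueError(
                    f"chain {self.id}: invalid block (size={size}, dt={dt}, dq={dq})"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Genome:
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig name: {rec.id}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for contig {rec.id}")
        m = _NUC_RE.match(seq)
        if not m or m.end() != len(seq):
            bad = next(
                i for i, ch in enumerate(seq) if not _NUC_RE.match(ch)
            )
            raise ValueError(
                f"contig {rec.id}: non-nucleotide character "
                f"{seq[bad]!r} at offset {bad}"
            )
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Genome, path, line_width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, genome: Genome | None = None) -> list[VariantRecord]:
    """Read a VCF 4.x file into :class:`VariantRecord` objects.

    AF/AC/AN come from INFO when present; otherwise they are recomputed
    from the genotypes and the record is flagged ``af_derived``.  If a
    ``genome`` is given, REF alleles are checked against it.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            ann = {
                k: float(site.info[k])
                for k in SITE_ANNOTATION_KEYS
                if k in site.info
            }
            genotypes = [
                tuple(a for a in sample["GT"])
                for sample in site.samples.values()
            ]
            rec = VariantRecord(
                contig=site.chrom,
                pos=site.pos,
                ref_allele=site.ref,
                alt_alleles=list(site.alts or ()),
                qual=site.qual,
                site_annotations=ann,
                genotypes=genotypes,
                filter_status=";".join(site.filter.keys()) or "PASS",
                id=site.id or ".",
            )
            info = site.info
            if "AC" in info and "AN" in info:
                ac = info["AC"]
                rec.ac = list(ac) if isinstance(ac, tuple) else [ac]
                rec.an = int(info["AN"])
                if "AF" in info:
                    af = info["AF"]
                    rec.af = list(af) if isinstance(af, tuple) else [af]
                else:
                    rec.af = [
                        c / rec.an if rec.an else 0.0 for c in rec.ac
                    ]
            elif "AF" in info and not genotypes:
                af = info["AF"]
                rec.af = list(af) if isinstance(af, tuple) else [af]
                rec.ac = []
                rec.an = 0
            else:
                rec.recompute_frequencies()
            rec.validate(genome)
            records.append(rec)
    return records


def _fmt_info_val(v: float) -> str:
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        # keep integers unpadded but floats readable
        return f"{v:g}"
    return f"{v:g}" if isinstance(v, float) else str(v)


def write_vcf(
    records: list[VariantRecord],
    path,
    sample_names: list[str] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records as uncompressed VCF 4.2 with AF/AC/AN in INFO."""
    n_samples = max((len(r.genotypes) for r in records), default=0)
    if sample_names is None:
        sample_names = [f"sample{i+1}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(r.contig for r in records):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n'
            '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n'
            '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">\n'
        )
        for key in SITE_ANNOTATION_KEYS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_names:
            cols += ["FORMAT"] + list(sample_names)
        fh.write("\t".join(cols) + "\n")
        for r in records:
            info_parts = []
            if r.ac:
                info_parts.append("AC=" + ",".join(str(c) for c in r.ac))
            if r.an:
                info_parts.append(f"AN={r.an}")
            if r.af:
                info_parts.append(
                    "AF=" + ",".join(f"{x:.6g}" for x in r.af)
                )
            for key in SITE_ANNOTATION_KEYS:
                if key in r.site_annotations:
                    info_parts.append(
                        f"{key}={_fmt_info_val(r.site_annotations[key])}"
                    )
            fields = [
                r.contig,
                str(r.pos),
                r.id,
                r.ref_allele,
                ",".join(r.alt_alleles) if r.alt_alleles else ".",
                "." if r.qual is None else f"{r.qual:g}",
                r.filter_status or "PASS",
                ";".join(info_parts) or ".",
            ]
            if sample_names:
                fields.append("GT")
                for i in range(len(sample_names)):
                    if i < len(r.genotypes):
                        gt = r.genotypes[i]
                        fields.append(
                            "/".join(
                                "." if a is None else str(a) for a in gt
                            )
                        )
                    else:
                        fields.append("./.")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line with < 3 fields: {line!r}")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = (
                float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            )
            strand = parts[5] if len(parts) > 5 else "."
            intervals.append(Interval(contig, start, end, strand, name, score))
    return intervals


def write_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name if iv.name is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else ".",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path) -> list[GtfRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = feature_from_line(line.rstrip("\n"))
            attrs = {k: v[0] for k, v in f.attributes.items() if v}
            records.append(
                GtfRecord(
                    contig=f.seqid,
                    source=f.source,
                    feature=f.featuretype,
                    start=f.start - 1,  # GTF is 1-based inclusive
                    end=f.end,
                    score=f.score,
                    strand=f.strand,
                    frame=f.frame,
                    attributes=attrs,
                )
            )
    return records


def write_gtf(records: list[GtfRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            attr_str = " ".join(
                f'{k} "{v}";' for k, v in r.attributes.items()
            )
            fh.write(
                "\t".join(
                    [
                        r.contig,
                        r.source,
                        r.feature,
                        str(r.start + 1),
                        str(r.end),
                        r.score,
                        r.strand,
                        r.frame,
                        attr_str,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain


def read_chain(path) -> list[ChainAlignment]:
    chains = []
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    current: list[str] | None = None
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def finish():
        if header is None:
            return
        (
            _,
            score,
            t_name,
            t_size,
            t_strand,
            t_start,
            t_end,
            q_name,
            q_size,
            q_strand,
            q_start,
            q_end,
            chain_id,
        ) = header
        chain = ChainAlignment(
            score=float(score),
            t_name=t_name,
            t_size=int(t_size),
            t_strand=t_strand,
            t_start=int(t_start),
            t_end=int(t_end),
            q_name=q_name,
            q_size=int(q_size),
            q_strand=q_strand,
            q_start=int(q_start),
            q_end=int(q_end),
            blocks=list(blocks),
            id=int(chain_id),
        )
        chain.validate()
        chains.append(chain)

    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("chain"):
            finish()
            header = line.split()
            if len(header) != 13:
                raise ValueError(f"malformed chain header: {line!r}")
            blocks = []
        else:
            parts = line.split()
            if len(parts) == 3:
                blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
            elif len(parts) == 1:
                blocks.append((int(parts[0]), 0, 0))
            else:
                raise ValueError(f"malformed chain block line: {line!r}")
    finish()
    return chains


def write_chain(chains: list[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            c.validate()
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")
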