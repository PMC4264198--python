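"""SNP records, gene models, and pseudo-genome construction.

Internal coordinates are 1-based inclusive (VCF convention). BED input is
converted on load; GFF3 is used as-is. A pseudo-genome is a copy of the
reference with the second parent's allele substituted at every SNP, which
lets hybrid reads be assigned to either parental haplotype without mapping
bias at SNP sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class GenomeError(ValueError):
    """Raised on malformed genomic inputs or coordinate inconsistencies."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNV distinguishing the two parental genomes.

    ``allele1`` is the parent-1 (reference) base on the forward strand,
    ``allele2`` the parent-2 base. ``pos`` is 1-based. A SNP inside two
    overlapping genes yields one record per gene.
    """

    chrom: str
    pos: int
    allele1: str
    allele2: str
    gene_id: str | None = None
    exonic: bool = False

    def __post_init__(self) -> None:
        if self.allele1 not in _VALID_BASES or self.allele2 not in _VALID_BASES:
            raise GenomeError(
                f"alleles must be A/C/G/T, got {self.allele1!r}/{self.allele2!r}"
            )
        if self.allele1 == self.allele2:
            raise GenomeError(f"alleles identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise GenomeError(f"position must be 1-based positive, got {self.pos}")

    @property
    def snp_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with exons; 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise GenomeError(
                f"bad interval for {self.gene_id}: {self.start}-{self.end}"
            )
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))

    @property
    def length(self) -> int:
        """Union-exon length in bp."""
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


class GeneIndex:
    """Point-overlap lookup over gene models, per chromosome."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end))

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        return [g for g in self._by_chrom.get(chrom, []) if g.contains(pos)]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise GenomeError(f"no sequences found in {path}")
    return seqs


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed line width (default 60)."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Gene models


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED6 (0-based half-open) or GFF3 (1-based).

    Format is chosen by extension: ``.bed`` vs ``.gff``/``.gff3``.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _load_bed(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _load_gff3(path)
    raise GenomeError(f"unrecognized gene-model format: {path.name}")


def _load_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GenomeError(f"{path.name}:{ln}: expected >=4 BED columns")
            chrom, start0, end0, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            # BED is 0-based half-open; internal coords are 1-based inclusive
            genes.append(
                GeneModel(gene_id=name, chrom=chrom, start=int(start0) + 1,
                          end=int(end0), strand=strand)
            )
    return genes


def _gff3_attrs(s: str) -> dict[str, str]:
    out = {}
    for kv in s.strip().split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _load_gff3(path: Path) -> list[GeneModel]:
    raw_genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeError(f"{path.name}:{ln}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            a = _gff3_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise GenomeError(f"{path.name}:{ln}: gene without ID attribute")
                raw_genes[gid] = dict(chrom=chrom, start=int(start), end=int(end),
                                      strand=strand)
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent is not None:
                    exons.setdefault(parent, []).append((int(start), int(end)))
    return [
        GeneModel(gene_id=gid, exons=tuple(sorted(exons.get(gid, []))), **info)
        for gid, info in raw_genes.items()
    ]


def write_gene_models_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\thybrase\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\thybrase\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# VCF


def load_snps(
    vcf_path: str | Path,
    gene_models: Sequence[GeneModel] | None = None,
) -> list[SnpRecord]:
    """Load biallelic SNVs from a VCF and annotate gene/exon membership.

    Multi-allelic sites and indels are skipped (the count is logged).
    A SNP overlapping several genes produces one record per gene; SNPs
    outside any gene carry ``gene_id=None``.
    """
    index = GeneIndex(gene_models) if gene_models else None
    records: list[SnpRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            if rec.ref not in _VALID_BASES or alts[0] not in _VALID_BASES:
                n_skipped += 1
                continue
            base = SnpRecord(chrom=rec.chrom, pos=rec.pos,
                             allele1=rec.ref, allele2=alts[0])
            if index is None:
                records.append(base)
                continue
            hits = index.overlapping(rec.chrom, rec.pos)
            if not hits:
                records.append(base)
            else:
                for g in hits:
                    records.append(replace(base, gene_id=g.gene_id,
                                           exonic=g.exonic(rec.pos)))
    if n_skipped:
        logger.info("load_snps: skipped %d non-SNV/multi-allelic records", n_skipped)
    return records


def write_snps_vcf(
    snps: Sequence[SnpRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNPs as a minimal VCF v4.2 (REF = parent-1, ALT = parent-2)."""
    seen: set[str] = set()
    uniq = []
    for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        if s.snp_id not in seen:  # collapse per-gene duplicates
            seen.add(s.snp_id)
            uniq.append(s)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in uniq:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.allele1}\t{s.allele2}"
                     f"\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Pseudo-genome


def build_pseudogenome(
    reference: Mapping[str, str], snps: Iterable[SnpRecord]
) -> dict[str, str]:
    """Substitute ``allele2`` at every SNP position of the reference.

    Every SNP's ``allele1`` must match the reference base at (chrom, pos);
    a mismatch signals a coordinate-convention bug and raises listing all
    offending positions. Sequence lengths are preserved.
    """
    out = {name: bytearray(seq, "ascii") for name, seq in reference.items()}
    mismatches: list[str] = []
    for s in snps:
        if s.chrom not in out:
            mismatches.append(f"{s.snp_id} (missing contig)")
            continue
        seq = out[s.chrom]
        if s.pos > len(seq):
            mismatches.append(f"{s.snp_id} (beyond contig end {len(seq)})")
            continue
        ref_base = chr(seq[s.pos - 1])
        if ref_base != s.allele1:
            mismatches.append(f"{s.snp_id} (ref={ref_base}, allele1={s.allele1})")
            continue
        seq[s.pos - 1] = ord(s.allele2)
    if mismatches:
        shown = ", ".join(mismatches[:20])
        raise GenomeError(
            f"{len(mismatches)} SNP(s) disagree with the reference: {shown}"
        )
    return {name: seq.decode("ascii") for name, seq in out.items()}
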