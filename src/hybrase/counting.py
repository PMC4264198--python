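"""Per-SNP allelic read counting from alignments and informative-SNP filtering.

Counting is unstranded and against parent-1 coordinates: at each SNP the
pileup base of every qualifying read is compared with the two known
parental alleles. "Uniquely mapped" means NH tag == 1 when present,
otherwise mapping quality >= ``min_mapq``. Reads spanning several SNPs are
counted at every spanned SNP; an optional per-gene read-deduplication mode
counts each read once per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import SnpRecord

logger = logging.getLogger(__name__)


class CountingError(ValueError):
    pass


@dataclass(frozen=True)
class AllelicCount:
    snp_id: str
    sample_id: str
    n_allele1: int
    n_allele2: int
    n_other: int = 0

    def __post_init__(self) -> None:
        if min(self.n_allele1, self.n_allele2, self.n_other) < 0:
            raise CountingError("allelic counts must be non-negative")


@dataclass(frozen=True)
class InformativeFilterConfig:
    """Thresholds defining a SNP with "sufficient parental reads".

    A SNP is informative when each parental sample shows at least
    ``min_parent_depth`` allelic reads of which at least
    ``min_parent_concordance`` carry that parent's own allele (guards
    against collapsed paralogs), both hybrids reach ``min_hybrid_depth``
    total allelic reads, and (optionally) the SNP is exonic.
    """

    min_parent_depth: int = 10
    min_parent_concordance: float = 0.9
    require_exonic: bool = True
    min_hybrid_depth: int = 10

    def __post_init__(self) -> None:
        if self.min_parent_depth < 0 or self.min_hybrid_depth < 0:
            raise CountingError("depth thresholds must be >= 0")
        if not 0.0 <= self.min_parent_concordance <= 1.0:
            raise CountingError("concordance must be in [0,1]")


@dataclass(frozen=True)
class FilterSummary:
    """Kept/total bookkeeping for the informative-SNP filter."""

    n_total: int
    n_kept: int

    @property
    def percent(self) -> float:
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_kept / self.n_total, 2)

    def as_dict(self) -> dict:
        return dict(n_total=self.n_total, n_kept=self.n_kept, percent=self.percent)


# ---------------------------------------------------------------------------
# Pileup counting


def _read_is_unique(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality >= min_mapq


def count_alleles_from_alignment(
    alignment_path: str | Path,
    snps: Sequence[SnpRecord],
    sample_id: str,
    min_base_quality: int = 13,
    min_mapq: int = 20,
    per_gene_dedup: bool = False,
) -> pd.DataFrame:
    """Tally allelic read support at every SNP of a sorted, indexed alignment.

    Reads that are unmapped, secondary, supplementary, duplicate-flagged,
    non-unique, or below the base-quality floor at the SNP are excluded;
    reads with a deletion spanning the SNP contribute to no counter. SNPs on
    contigs absent from the alignment get zero counts with a warning.

    Returns a long table: snp_id, chrom, pos, gene_id, sample, n_allele1,
    n_allele2, n_other.
    """
    af = pysam.AlignmentFile(str(alignment_path))
    try:
        if not af.has_index():
            raise CountingError(
                f"{alignment_path}: alignment must be coordinate-sorted and indexed"
            )
    except (AttributeError, ValueError) as exc:
        raise CountingError(
            f"{alignment_path}: alignment must be coordinate-sorted and indexed"
        ) from exc

    valid_contigs = set(af.references)
    # unique sites; per-gene duplicates of a SNP share one tally
    sites: dict[str, SnpRecord] = {}
    for s in snps:
        sites.setdefault(s.snp_id, s)

    tallies: dict[str, tuple[int, int, int]] = {}
    seen_per_gene: set[tuple[str, str | None]] = set()
    missing_contigs = set()
    for snp_id, s in sites.items():
        if s.chrom not in valid_contigs:
            missing_contigs.add(s.chrom)
            tallies[snp_id] = (0, 0, 0)
            continue
        n1 = n2 = no = 0
        for read in af.fetch(s.chrom, s.pos - 1, s.pos):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or not _read_is_unique(read, min_mapq)
            ):
                continue
            qpos = None
            for q, r in read.get_aligned_pairs():
                if r == s.pos - 1:
                    qpos = q
                    break
            if qpos is None:  # deletion or ref-skip over the SNP
                continue
            quals = read.query_qualities
            if quals is not None and quals[qpos] < min_base_quality:
                continue
            if per_gene_dedup:
                key = (read.query_name, s.gene_id)
                if key in seen_per_gene:
                    continue
                seen_per_gene.add(key)
            base = read.query_sequence[qpos].upper()
            if base == s.allele1:
                n1 += 1
            elif base == s.allele2:
                n2 += 1
            else:
                no += 1
        tallies[snp_id] = (n1, n2, no)
    af.close()
    if missing_contigs:
        logger.warning(
            "contigs absent from alignment (zero counts): %s",
            ", ".join(sorted(missing_contigs)),
        )

    rows = []
    for s in snps:  # one row per (snp, gene) record, sharing the site tally
        n1, n2, no = tallies[s.snp_id]
        rows.append(
            dict(snp_id=s.snp_id, chrom=s.chrom, pos=s.pos, gene_id=s.gene_id,
                 sample=sample_id, n_allele1=n1, n_allele2=n2, n_other=no)
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "gene_id", "sample",
                       "n_allele1", "n_allele2", "n_other"]
    )


# ---------------------------------------------------------------------------
# Informative-SNP filter


def _depth_table(counts: pd.DataFrame) -> pd.DataFrame:
    t = counts.groupby("snp_id")[["n_allele1", "n_allele2"]].first()
    t["depth"] = t["n_allele1"] + t["n_allele2"]
    return t


def filter_informative_snps(
    snps: Sequence[SnpRecord],
    parent1_counts: pd.DataFrame,
    parent2_counts: pd.DataFrame,
    hybrid_counts: Mapping[str, pd.DataFrame],
    cfg: InformativeFilterConfig | None = None,
) -> tuple[list[SnpRecord], FilterSummary]:
    """Select SNPs with sufficient, concordant parental reads.

    ``parent1_counts``/``parent2_counts`` and each entry of
    ``hybrid_counts`` are long allelic-count tables for one sample. SNPs
    with no row in a table are treated as zero depth. Returns the kept
    SnpRecord subset (all per-gene records of a kept site) and a summary
    with kept/total counts and percentage.
    """
    if cfg is None:
        cfg = InformativeFilterConfig()
    if len(hybrid_counts) == 0:
        raise CountingError("hybrid counts are required (both reciprocal hybrids)")
    for name, df in [("parent1", parent1_counts), ("parent2", parent2_counts)]:
        if df is None or df.empty:
            raise CountingError(f"missing allelic counts for {name} sample")

    site_ids = sorted({s.snp_id for s in snps})
    idx = pd.Index(site_ids, name="snp_id")

    p1 = _depth_table(parent1_counts).reindex(idx).fillna(0)
    p2 = _depth_table(parent2_counts).reindex(idx).fillna(0)

    with np.errstate(invalid="ignore", divide="ignore"):
        conc1 = np.where(p1["depth"] > 0, p1["n_allele1"] / p1["depth"], 0.0)
        conc2 = np.where(p2["depth"] > 0, p2["n_allele2"] / p2["depth"], 0.0)
    keep = (
        (p1["depth"].to_numpy() >= cfg.min_parent_depth)
        & (conc1 >= cfg.min_parent_concordance)
        & (p2["depth"].to_numpy() >= cfg.min_parent_depth)
        & (conc2 >= cfg.min_parent_concordance)
    )
    for hyb_id, df in hybrid_counts.items():
        h = _depth_table(df).reindex(idx).fillna(0)
        keep &= h["depth"].to_numpy() >= cfg.min_hybrid_depth

    kept_sites = set(idx[keep])
    if cfg.require_exonic:
        kept = [s for s in snps if s.snp_id in kept_sites and s.exonic]
    else:
        kept = [s for s in snps if s.snp_id in kept_sites]
    kept_site_count = len({s.snp_id for s in kept})
    summary = FilterSummary(n_total=len(site_ids), n_kept=kept_site_count)
    logger.info(
        "informative-SNP filter: kept %d of %d (%.2f%%)",
        summary.n_kept, summary.n_total, summary.percent,
    )
    return kept, summary


# ---------------------------------------------------------------------------
# Gene-level aggregation


def aggregate_gene_counts(
    counts: pd.DataFrame, snps: Sequence[SnpRecord]
) -> pd.DataFrame:
    """Sum allelic counts over each gene's SNPs, per sample.

    SNPs assigned to several genes contribute to each of them. Genes with
    no counted SNPs are absent from the output.
    """
    gene_map = pd.DataFrame(
        [(s.snp_id, s.gene_id) for s in snps if s.gene_id is not None],
        columns=["snp_id", "gene_id"],
    ).drop_duplicates()
    df = counts.drop(columns=["gene_id"], errors="ignore").merge(
        gene_map, on="snp_id", how="inner"
    )
    out = (
        df.groupby(["gene_id", "sample"], sort=True)[["n_allele1", "n_allele2"]]
        .sum()
        .reset_index()
    )
    return out
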