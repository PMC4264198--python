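"""Synthetic fixtures with known truth for the whole analysis chain.

Everything downstream — pseudo-genome construction, allelic counting,
ASE/imprinting calling, differential expression, expression breadth — can
be exercised offline against planted truth labels. Counts are simulated
directly at the SNP level (the inference consumes allelic depths, not
reads); a small SAM emitter exists so the pileup counter can be tested
end-to-end.

One seed drives everything: each stage derives its own generator from
``(seed, stage offset)``, so stages are independently reproducible and a
fixed config yields byte-identical fixture files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ase import CrossDesign
from .genome import (
    GeneModel,
    SnpRecord,
    write_fasta,
    write_gene_models_bed,
    write_snps_vcf,
)
from .expression import CountMatrix

logger = logging.getLogger(__name__)

GENE_CLASSES = (
    "biallelic",
    "ase_parent1",
    "ase_parent2",
    "imprinted_maternal",
    "imprinted_paternal",
)

# fixed RNG sub-stream offsets per stage
_STREAM_TRUTH = 0
_STREAM_GENOME = 1
_STREAM_ALLELIC = 2
_STREAM_EXPRESSION = 3
_STREAM_READS = 4


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    gene_length_bp: tuple[int, int] = (500, 2000)
    snps_per_gene: float = 3.0          # Poisson mean
    frac_ase: float = 0.1
    frac_imprinted_maternal: float = 0.0
    frac_imprinted_paternal: float = 0.0
    bias_level: float = 0.9             # major-allele fraction for biased genes
    mean_snp_depth: float = 100.0
    depth_dispersion: float = 0.1       # NB dispersion of per-SNP depth
    parent_error_rate: float = 0.005    # cross-allele reads in parental samples
    frac_de: float = 0.1
    de_log2fc: float = 2.0
    expr_mean: float = 500.0            # lognormal location of gene base means
    expr_sigma: float = 1.0             # lognormal sigma (natural log)
    expr_dispersion: float = 0.05       # NB dispersion of expression counts
    n_tissues: int = 11
    frac_tissue_specific: float = 0.2
    tissue_concentration: float = 0.95  # mass in home tissue for specific genes
    seed: int = 0

    def validate(self) -> None:
        fracs = dict(
            frac_ase=self.frac_ase,
            frac_imprinted_maternal=self.frac_imprinted_maternal,
            frac_imprinted_paternal=self.frac_imprinted_paternal,
            frac_de=self.frac_de,
            frac_tissue_specific=self.frac_tissue_specific,
        )
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0,1], got {v}")
        s = self.frac_ase + self.frac_imprinted_maternal + self.frac_imprinted_paternal
        if s > 1.0 + 1e-12:
            raise SimulationConfigError(
                f"class proportions sum to {s:.3f} > 1"
            )
        if not 0.5 < self.bias_level <= 1.0:
            raise SimulationConfigError(
                f"bias_level must be in (0.5, 1], got {self.bias_level}"
            )
        if self.n_genes < 1 or self.n_tissues < 1:
            raise SimulationConfigError("n_genes and n_tissues must be positive")
        lo, hi = self.gene_length_bp
        if lo < 1 or hi < lo:
            raise SimulationConfigError(f"bad gene_length_bp range {lo}-{hi}")
        for name in ("snps_per_gene", "mean_snp_depth", "depth_dispersion",
                     "parent_error_rate", "expr_dispersion"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def default_crosses() -> tuple[CrossDesign, CrossDesign]:
    """The canonical reciprocal pair over genotypes parent1/parent2."""
    return (
        CrossDesign("hybrid_p1xp2", mother="parent1", father="parent2"),
        CrossDesign("hybrid_p2xp1", mother="parent2", father="parent1"),
    )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Truth


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-gene truth labels with the configured class proportions.

    Columns: gene_id, gene_class, allele1_frac_m1 / allele1_frac_m2 (true
    allele-1 fraction in the hybrid whose mother is parent-1 / parent-2),
    de_status, log2fc, breadth_class. For ASE genes the allele-1 fraction is
    the same in both hybrids; for imprinted genes the *maternal* fraction is
    the same, so the allele-1 fraction flips between crosses.
    """
    config.validate()
    rng = config.rng(_STREAM_TRUTH)
    n = config.n_genes
    b = config.bias_level

    probs = np.array(
        [
            config.frac_ase / 2.0,
            config.frac_ase / 2.0,
            config.frac_imprinted_maternal,
            config.frac_imprinted_paternal,
        ]
    )
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    classes = rng.choice(
        ["ase_parent1", "ase_parent2", "imprinted_maternal", "imprinted_paternal",
         "biallelic"],
        size=n,
        p=probs / probs.sum(),
    )

    frac_m1 = np.full(n, 0.5)
    frac_m2 = np.full(n, 0.5)
    frac_m1[classes == "ase_parent1"] = b
    frac_m2[classes == "ase_parent1"] = b
    frac_m1[classes == "ase_parent2"] = 1 - b
    frac_m2[classes == "ase_parent2"] = 1 - b
    frac_m1[classes == "imprinted_maternal"] = b
    frac_m2[classes == "imprinted_maternal"] = 1 - b
    frac_m1[classes == "imprinted_paternal"] = 1 - b
    frac_m2[classes == "imprinted_paternal"] = b

    de = rng.random(n) < config.frac_de
    sign = rng.choice([-1.0, 1.0], size=n)
    log2fc = np.where(de, sign * config.de_log2fc, 0.0)
    breadth = np.where(
        rng.random(n) < config.frac_tissue_specific, "tissue_specific", "broad"
    )

    return pd.DataFrame(
        dict(
            gene_id=_gene_ids(n),
            gene_class=classes,
            allele1_frac_m1=frac_m1,
            allele1_frac_m2=frac_m2,
            de_status=de,
            log2fc=log2fc,
            breadth_class=breadth,
        )
    )


# ---------------------------------------------------------------------------
# Genomes


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[SnpRecord], list[GeneModel]]:
    """Random reference, SNPs inside gene bodies, and gene models.

    Genes are laid head-to-tail on one chromosome with 100 bp spacers;
    every SNP's allele1 equals the reference base at its position.
    """
    config.validate()
    rng = config.rng(_STREAM_GENOME)
    bases = np.array(list("ACGT"))
    spacer = 100
    lo, hi = config.gene_length_bp

    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    total = spacer + int((lengths + spacer).sum())
    seq = rng.choice(bases, size=total)

    genes: list[GeneModel] = []
    snps: list[SnpRecord] = []
    cursor = spacer + 1  # 1-based
    ids = _gene_ids(config.n_genes)
    for gid, glen in zip(ids, lengths):
        start, end = cursor, cursor + int(glen) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=gid, chrom="chr1", start=start, end=end,
                               strand=strand))
        k = int(rng.poisson(config.snps_per_gene))
        if k > glen:
            logger.info("gene %s too short for %d SNPs; reduced to %d", gid, k, glen)
            k = int(glen)
        if k > 0:
            offsets = np.sort(rng.choice(int(glen), size=k, replace=False))
            for off in offsets:
                pos = start + int(off)
                a1 = seq[pos - 1]
                a2 = rng.choice(bases[bases != a1])
                snps.append(
                    SnpRecord(chrom="chr1", pos=pos, allele1=str(a1), allele2=str(a2),
                              gene_id=gid, exonic=True)
                )
        cursor = end + spacer + 1

    return {"chr1": "".join(seq)}, snps, genes


# ---------------------------------------------------------------------------
# Allelic counts


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float,
              size: int) -> np.ndarray:
    """Gamma-Poisson depths with Var = mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam).astype(np.int64)


def simulate_allelic_counts(
    config: SimulationConfig,
    truth: pd.DataFrame,
    snps: Sequence[SnpRecord],
    crosses: Sequence[CrossDesign] | None = None,
) -> pd.DataFrame:
    """Per-SNP allelic counts for both parents and both reciprocal hybrids.

    Depth is NB(mean_snp_depth, depth_dispersion) independently per SNP and
    sample. Hybrid allele-1 counts are Binomial(depth, f) with f taken from
    the truth table for the SNP's gene. Parental samples are homozygous up
    to a flat ``parent_error_rate`` of cross-allele reads.

    Returns a long table: snp_id, gene_id, sample, n_allele1, n_allele2,
    n_other.
    """
    config.validate()
    if crosses is None:
        crosses = default_crosses()
    if len(crosses) != 2:
        raise SimulationConfigError("exactly two reciprocal crosses are required")
    mothers = {c.mother for c in crosses}
    if mothers != {"parent1", "parent2"}:
        raise SimulationConfigError(
            "crosses must cover mothers parent1 and parent2; "
            f"got {sorted(mothers)}"
        )
    m1 = next(c for c in crosses if c.mother == "parent1")
    m2 = next(c for c in crosses if c.mother == "parent2")

    tt = truth.set_index("gene_id")
    missing = {s.gene_id for s in snps if s.gene_id is not None} - set(tt.index)
    if missing:
        raise SimulationConfigError(
            f"truth table does not cover genes: {sorted(missing)[:5]}"
        )

    rng = config.rng(_STREAM_ALLELIC)
    snp_ids = [s.snp_id for s in snps]
    gene_ids = [s.gene_id for s in snps]
    n = len(snps)
    f_m1 = np.array(
        [tt.at[g, "allele1_frac_m1"] if g is not None else 0.5 for g in gene_ids]
    )
    f_m2 = np.array(
        [tt.at[g, "allele1_frac_m2"] if g is not None else 0.5 for g in gene_ids]
    )

    frames = []
    specs = [
        ("parent1", np.full(n, 1.0 - config.parent_error_rate)),
        ("parent2", np.full(n, config.parent_error_rate)),
        (m1.hybrid_id, f_m1),
        (m2.hybrid_id, f_m2),
    ]
    for sample, f in specs:
        depth = _nb_depth(rng, config.mean_snp_depth, config.depth_dispersion, n)
        n1 = rng.binomial(depth, f)
        frames.append(
            pd.DataFrame(
                dict(
                    snp_id=snp_ids,
                    gene_id=gene_ids,
                    sample=sample,
                    n_allele1=n1,
                    n_allele2=depth - n1,
                    n_other=np.zeros(n, dtype=np.int64),
                )
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Expression matrices


def simulate_expression_matrix(
    config: SimulationConfig,
    truth: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
) -> tuple[CountMatrix, CountMatrix]:
    """NB count matrices over the 4 genotypes and over ``n_tissues`` tissues.

    Gene base means are lognormal around ``expr_mean``. DE genes carry a
    2**log2fc shift in parent-2; hybrids take the parental midpoint.
    Tissue-specific genes put ``tissue_concentration`` of their expression
    in one tissue; broad genes are uniform.
    """
    config.validate()
    rng = config.rng(_STREAM_EXPRESSION)
    n = len(truth)
    genes = truth["gene_id"].tolist()
    if gene_lengths is None:
        lo, hi = config.gene_length_bp
        gene_lengths = pd.Series(
            rng.integers(lo, hi + 1, size=n), index=genes, name="length"
        )
    else:
        gene_lengths = gene_lengths.reindex(genes)

    base = rng.lognormal(
        mean=np.log(config.expr_mean) - config.expr_sigma**2 / 2.0,
        sigma=config.expr_sigma,
        size=n,
    )
    fc = np.power(2.0, truth["log2fc"].to_numpy())
    mu_p1 = base
    mu_p2 = base * fc
    mu_hyb = (mu_p1 + mu_p2) / 2.0

    geno_samples = ["parent1", "parent2", "hybrid_p1xp2", "hybrid_p2xp1"]
    geno = np.column_stack(
        [
            _nb_counts(rng, mu, config.expr_dispersion)
            for mu in (mu_p1, mu_p2, mu_hyb, mu_hyb)
        ]
    )
    geno_cm = CountMatrix(
        counts=pd.DataFrame(geno, index=genes, columns=geno_samples),
        lengths=gene_lengths,
    )

    T = config.n_tissues
    c = config.tissue_concentration
    home = rng.integers(0, T, size=n)
    props = np.full((n, T), 1.0 / T)
    spec_mask = truth["breadth_class"].to_numpy() == "tissue_specific"
    if T > 1:
        props[spec_mask] = (1.0 - c) / (T - 1)
        props[spec_mask, home[spec_mask]] = c
    mu_tissue = base[:, None] * T * props
    tissue = np.column_stack(
        [_nb_counts(rng, mu_tissue[:, t], config.expr_dispersion) for t in range(T)]
    )
    tissue_cm = CountMatrix(
        counts=pd.DataFrame(
            tissue, index=genes, columns=[f"tissue{t + 1:02d}" for t in range(T)]
        ),
        lengths=gene_lengths,
    )
    return geno_cm, tissue_cm


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# Bundled run + fixtures on disk


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: pd.DataFrame
    reference: dict[str, str]
    snps: list[SnpRecord]
    genes: list[GeneModel]
    allelic_counts: pd.DataFrame
    crosses: tuple[CrossDesign, CrossDesign]
    genotype_counts: CountMatrix
    tissue_counts: CountMatrix


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every stage of the simulator with one config."""
    truth = simulate_truth(config)
    reference, snps, genes = simulate_genomes(config)
    crosses = default_crosses()
    allelic = simulate_allelic_counts(config, truth, snps, crosses)
    lengths = pd.Series({g.gene_id: g.length for g in genes}, name="length")
    geno_cm, tissue_cm = simulate_expression_matrix(config, truth, lengths)
    return SimulatedDataset(
        config=config,
        truth=truth,
        reference=reference,
        snps=snps,
        genes=genes,
        allelic_counts=allelic,
        crosses=crosses,
        genotype_counts=geno_cm,
        tissue_counts=tissue_cm,
    )


def write_fixtures(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write all fixtures as plain-text files; deterministic byte-for-byte."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": d / "reference.fasta",
        "snps": d / "snps.vcf",
        "genes": d / "genes.bed",
        "allelic_counts": d / "allelic_counts.tsv",
        "genotype_counts": d / "counts_genotypes.tsv",
        "tissue_counts": d / "counts_tissues.tsv",
        "gene_lengths": d / "gene_lengths.tsv",
        "truth": d / "truth.tsv",
        "crosses": d / "crosses.tsv",
        "config": d / "config.yaml",
    }
    write_fasta(dataset.reference, paths["reference"])
    write_snps_vcf(
        dataset.snps,
        paths["snps"],
        contig_lengths={k: len(v) for k, v in dataset.reference.items()},
    )
    write_gene_models_bed(dataset.genes, paths["genes"])
    dataset.allelic_counts.to_csv(paths["allelic_counts"], sep="\t", index=False)
    dataset.genotype_counts.counts.to_csv(
        paths["genotype_counts"], sep="\t", index_label="gene_id"
    )
    dataset.tissue_counts.counts.to_csv(
        paths["tissue_counts"], sep="\t", index_label="gene_id"
    )
    dataset.genotype_counts.lengths.rename("length").to_csv(
        paths["gene_lengths"], sep="\t", index_label="gene_id"
    )
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame([asdict(c) for c in dataset.crosses]).to_csv(
        paths["crosses"], sep="\t", index=False
    )
    import yaml

    cfg = asdict(dataset.config)
    cfg["gene_length_bp"] = list(cfg["gene_length_bp"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_allelic_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_crosses(path: str | Path) -> tuple[CrossDesign, CrossDesign]:
    df = pd.read_csv(path, sep="\t")
    crosses = tuple(
        CrossDesign(r.hybrid_id, r.mother, r.father) for r in df.itertuples()
    )
    if len(crosses) != 2:
        raise SimulationConfigError("cross-design file must define two hybrids")
    return crosses  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Optional read emitter (non-core): SAM covering each SNP with exact counts


def emit_sam(
    dataset: SimulatedDataset,
    sample: str,
    path: str | Path,
    read_length: int = 50,
) -> None:
    """Write a SAM file whose pileup reproduces the sample's allelic counts.

    Each SNP gets n_allele1 reads carrying allele1, n_allele2 carrying
    allele2 and n_other carrying a third base, all uniquely mapped
    (NH:i:1, MAPQ 60), so the pileup counter must recover the planted
    counts exactly.
    """
    ref = dataset.reference
    counts = dataset.allelic_counts
    sub = counts[counts["sample"] == sample]
    if sub.empty:
        raise SimulationConfigError(f"no allelic counts for sample {sample!r}")
    snp_info = {s.snp_id: s for s in dataset.snps}
    rows = (
        sub.groupby("snp_id")[["n_allele1", "n_allele2", "n_other"]].first()
    )

    # reads are clipped so they never span a neighboring SNP, making the
    # pileup recovery of planted counts exact
    pos_by_chrom: dict[str, list[int]] = {}
    for s in snp_info.values():
        pos_by_chrom.setdefault(s.chrom, []).append(s.pos)
    for lst in pos_by_chrom.values():
        lst.sort()

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in ref.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        i = 0
        for snp_id in sorted(rows.index, key=lambda sid: snp_info[sid].pos):
            s = snp_info[snp_id]
            chrom_seq = ref[s.chrom]
            positions = pos_by_chrom[s.chrom]
            k = positions.index(s.pos)
            lo = positions[k - 1] + 1 if k > 0 else 1
            hi = positions[k + 1] - 1 if k + 1 < len(positions) else len(chrom_seq)
            start = max(lo, s.pos - read_length // 2)
            end = min(hi, start + read_length - 1)
            rl = end - start + 1
            offset = s.pos - start
            template = list(chrom_seq[start - 1 : end])
            qual = "I" * rl
            third = next(b for b in "ACGT" if b not in (s.allele1, s.allele2))
            r = rows.loc[snp_id]
            for base, cnt in (
                (s.allele1, int(r["n_allele1"])),
                (s.allele2, int(r["n_allele2"])),
                (third, int(r["n_other"])),
            ):
                template[offset] = base
                seq_str = "".join(template)
                for _ in range(cnt):
                    i += 1
                    fh.write(
                        f"r{i:07d}\t0\t{s.chrom}\t{start}\t60\t{rl}M\t*"
                        f"\t0\t0\t{seq_str}\t{qual}\tNH:i:1\n"
                    )
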