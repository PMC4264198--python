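# hybrase

Analysis toolkit for reciprocal F1 hybrid RNA-seq: allele-specific
expression (ASE) and imprinting calling from SNP-level allelic read counts,
negative-binomial exact-test differential expression for designs without
replicates, Shannon-entropy expression breadth, and hypergeometric gene-set
enrichment. A synthetic-data generator with planted truth labels drives the
whole chain, so everything is testable offline.

## How it works

The reciprocal-cross design (A×B and B×A) separates two signals that look
identical in a single hybrid:

- **ASE**: the same *genomic* allele is favored in both hybrids.
- **Imprinting**: the same *parental role* (maternal or paternal) is
  favored, so the favored genomic allele flips between the crosses.

Per SNP, both hybrids must show a significant departure from the 1:1
allelic ratio (exact binomial test vs 0.5 by default, Fisher's exact
against pooled parental counts as an option; p < 0.05) **and** more than
80% of reads from the favored allele. A gene is called ASE (imprinted) if
it carries at least one SNP with the corresponding pattern.

Modules (under `src/hybrase/`):

| module          | contents |
| --------------- | -------- |
| `simulate`      | truth labels, random genomes/SNPs/gene models, NB allelic counts, genotype & multi-tissue count matrices, fixture I/O, SAM emitter |
| `genome`        | `SnpRecord`/`GeneModel`, FASTA/VCF/BED/GFF3 I/O, pseudo-genome construction |
| `counting`      | pileup allelic counting from indexed alignments, informative-SNP filter, per-gene aggregation |
| `ase`           | bias tests, SNP pattern classification, gene-level ASE/imprinting calls, allelic-ratio summaries |
| `expression`    | median-of-ratios size factors, local-regression dispersion fit, conditioned NB exact test, BH, DEG calls & overlaps, FPKM, Shannon entropy, detected-gene sets |
| `enrichment`    | hypergeometric over/under-representation, TF-family cross-tabulation |
| `cli`, `report` | subcommand pipeline, JSON run summaries, alignment-statistics arithmetic |

## CLI

```bash
# generate fixtures with planted truth
hybrase simulate --n-genes 200 --frac-ase 0.1 --seed 7 --outdir fx/

# substitute parent-2 alleles into the reference
hybrase pseudogenome --ref fx/reference.fasta --vcf fx/snps.vcf --out pseudo.fasta

# count alleles at SNPs from a sorted+indexed BAM
hybrase count-alleles --alignment hyb.bam --vcf fx/snps.vcf \
    --genes fx/genes.bed --sample hybrid_p1xp2 --out counts.tsv

# informative-SNP filter, then ASE + imprinting calls
hybrase filter-snps --vcf fx/snps.vcf --genes fx/genes.bed \
    --counts fx/allelic_counts.tsv --parent1 parent1 --parent2 parent2 \
    --hybrids hybrid_p1xp2,hybrid_p2xp1 --out kept.vcf --summary filter.summary.json
hybrase call-ase --counts fx/allelic_counts.tsv --crosses fx/crosses.tsv --outdir ase/

# expression layer
hybrase deg --counts fx/counts_genotypes.tsv --cond-a parent1 --cond-b parent2 --out deg.tsv
hybrase fpkm --counts fx/counts_tissues.tsv --lengths fx/gene_lengths.tsv --out fpkm.tsv
hybrase entropy --fpkm fpkm.tsv --out entropy.tsv
hybrase enrich --study study.txt --background bg.txt --annotation go.tsv --out enrich.tsv

# collate summaries / recompute alignment-rate arithmetic
hybrase report --indir ase/ --alignment-stats stats.tsv --out report.json
```

A YAML config can preset simulation parameters (`--config cfg.yaml`);
explicit flags override it. Every threshold that influences calls is echoed
into the JSON summaries. Same config + seed gives byte-identical outputs.

## Notes

- With one library per condition, the DE dispersion is estimated by pooling
  the compared samples as pseudo-replicates ("blind"). This is conservative:
  genuine differences inflate the fitted variance. When a compared condition
  has replicates, the fit automatically switches to pooled within-condition
  variances.
- SNP-level bias tests use raw p < 0.05 (no multiple-testing correction),
  with BH available in the expression and enrichment layers.
- Reads spanning several SNPs count at every spanned SNP; a per-gene
  read-deduplication mode is available (`per_gene_dedup=True`).
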