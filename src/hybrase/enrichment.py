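"""Gene-set over/under-representation and TF-family cross-tabulation.

The test is the exact hypergeometric: for each term, the study set's term
count is compared against the background with both one-sided tails; the
reported direction is the smaller tail. Annotation input is a flat
gene -> terms mapping (GO-slim, co-expression module ids, TF families —
anything categorical).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .expression import adjust_bh


class EnrichmentError(ValueError):
    pass


def load_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (gene_id, term) into gene -> {terms}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def enrich_terms(
    study: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    adjust: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of every term in the study set.

    The study set must be a subset of the background; genes without
    annotation still count toward the totals. An empty study set yields an
    empty result. Columns: term, study_count, study_size, background_count,
    background_size, fold_enrichment, direction, p_value, adjusted_p,
    significant.
    """
    study = set(study)
    background = set(background)
    if not study <= background:
        extra = sorted(study - background)[:5]
        raise EnrichmentError(f"study genes missing from background: {extra}")
    cols = ["term", "study_count", "study_size", "background_count",
            "background_size", "fold_enrichment", "direction", "p_value",
            "adjusted_p", "significant"]
    if not study:
        return pd.DataFrame(columns=cols)

    N = len(background)
    n = len(study)
    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    rows = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_study.get(term, 0)
        p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_under = float(stats.hypergeom.cdf(k, N, K, n))
        direction = "over" if p_over <= p_under else "under"
        p = min(p_over, p_under)
        fold = (k / n) / (K / N)
        rows.append(
            dict(term=term, study_count=k, study_size=n, background_count=K,
                 background_size=N, fold_enrichment=fold, direction=direction,
                 p_value=min(p, 1.0))
        )
    df = pd.DataFrame(rows, columns=cols[:-2])
    df["adjusted_p"] = adjust_bh(df["p_value"].to_numpy()) if adjust else df["p_value"]
    df["significant"] = df["adjusted_p"] < alpha
    return df


def tf_family_crosstab(
    ase_genes: Iterable[str], tf_table: pd.DataFrame
) -> pd.Series:
    """Per-family counts of ASE transcription factors.

    ``tf_table`` needs columns gene_id and family (externally supplied TF
    annotation). Returns family -> count over the intersection of the ASE
    gene set with the TF table, sorted by descending count then name.
    """
    for col in ("gene_id", "family"):
        if col not in tf_table.columns:
            raise EnrichmentError(f"tf_table lacks required column {col!r}")
    ase = set(ase_genes)
    sub = tf_table[tf_table["gene_id"].isin(ase)].drop_duplicates("gene_id")
    counts = sub.groupby("family").size()
    counts = counts.sort_values(ascending=False)
    counts = counts.loc[
        sorted(counts.index, key=lambda fam: (-counts[fam], fam))
    ]
    counts.name = "n_ase_tfs"
    return counts
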