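"""Allele-specific expression and imprinting calls from reciprocal hybrids.

The reciprocal-cross design is what separates the two signals: an
allele-specific gene favors the same *genomic* allele in both hybrids,
while an imprinted gene favors the same *parental role* (maternal or
paternal), so its favored genomic allele flips between the two crosses.

Per-SNP criteria (both hybrids must satisfy both):
  1. significant departure from the expected 1:1 allelic ratio
     (two-sided exact test, p < alpha);
  2. the favored allele carries more than ``threshold`` of the reads
     (default 0.8), measured on the genomic allele for ASE and on the
     maternal/paternal allele for imprinting.

Gene calls are made from SNP-level patterns: a gene is ASE (imprinted) if
it has at least one ASE-pattern (imprinting-pattern) SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PATTERNS = (
    "ase_allele1",
    "ase_allele2",
    "imprinted_maternal",
    "imprinted_paternal",
    "biallelic",
)

BiasMethod = Literal["binomial", "fisher"]


class AseError(ValueError):
    pass


@dataclass(frozen=True)
class CrossDesign:
    """Assignment of parental roles for one hybrid sample."""

    hybrid_id: str
    mother: str
    father: str

    def __post_init__(self) -> None:
        if self.mother == self.father:
            raise AseError(f"{self.hybrid_id}: mother and father are identical")


def reciprocal_pair(crosses: Sequence[CrossDesign]) -> tuple[CrossDesign, CrossDesign]:
    """Validate that two crosses form a reciprocal pair and return them."""
    if len(crosses) != 2:
        raise AseError(f"expected exactly 2 crosses, got {len(crosses)}")
    a, b = crosses
    if a.mother != b.father or a.father != b.mother:
        raise AseError(
            f"crosses {a.hybrid_id} and {b.hybrid_id} do not swap parental roles"
        )
    return a, b


@dataclass(frozen=True)
class BiasTestResult:
    snp_id: str
    hybrid_id: str
    allele1_fraction: float
    p_value: float
    total_depth: int
    testable: bool = True


# ---------------------------------------------------------------------------
# Bias test


def binom_test_two_sided(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial test against p=0.5.

    Because the null pmf is symmetric, the minimum-likelihood two-sided
    p-value reduces to ``min(1, 2 * P(X <= min(k, n-k)))``; n=0 yields 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    kmin = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.binom.cdf(kmin, np.maximum(n, 1), 0.5)
    p = np.where(n == 0, 1.0, np.minimum(p, 1.0))
    return p


def allelic_bias_test(
    n_allele1: int,
    n_allele2: int,
    method: BiasMethod = "binomial",
    snp_id: str = "",
    hybrid_id: str = "",
    parent_counts: tuple[int, int] | None = None,
) -> BiasTestResult:
    """Test one SNP's hybrid allelic counts for departure from 1:1.

    Default is the exact binomial test against proportion 1/2. The
    ``fisher`` alternative tests the hybrid counts against pooled parental
    allelic counts in a 2x2 table (``parent_counts`` required).
    """
    total = n_allele1 + n_allele2
    if total == 0:
        return BiasTestResult(snp_id, hybrid_id, float("nan"), 1.0, 0, testable=False)
    frac = n_allele1 / total
    if method == "binomial":
        p = float(binom_test_two_sided(np.array(n_allele1), np.array(total)))
    elif method == "fisher":
        if parent_counts is None:
            raise AseError("fisher method requires pooled parental counts")
        _, p = stats.fisher_exact(
            [[n_allele1, n_allele2], [parent_counts[0], parent_counts[1]]]
        )
        p = float(p)
    else:
        raise AseError(f"unknown bias-test method: {method}")
    return BiasTestResult(snp_id, hybrid_id, frac, p, total)


# ---------------------------------------------------------------------------
# SNP classification


def classify_snps(
    table: pd.DataFrame,
    alpha: float = 0.05,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Classify SNPs given reciprocal-hybrid counts (vectorized).

    ``table`` needs columns ``a1_m1, a2_m1, a1_m2, a2_m2``: allele-1 and
    allele-2 counts in the hybrid whose mother is parent-1 (``_m1``) and in
    the reciprocal hybrid (``_m2``). Index or ``snp_id`` column identifies
    SNPs. Returns the table plus per-hybrid fractions/p-values and a
    ``pattern`` column. Threshold comparisons are strict (>, <), matching
    "more than 80%" and "p < 0.05". SNPs with zero depth in either hybrid
    are untestable and reported biallelic with ``testable=False``.
    """
    a1m1 = table["a1_m1"].to_numpy(np.int64)
    a2m1 = table["a2_m1"].to_numpy(np.int64)
    a1m2 = table["a1_m2"].to_numpy(np.int64)
    a2m2 = table["a2_m2"].to_numpy(np.int64)
    n1 = a1m1 + a2m1
    n2 = a1m2 + a2m2
    testable = (n1 > 0) & (n2 > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(n1 > 0, a1m1 / np.maximum(n1, 1), np.nan)
        f2 = np.where(n2 > 0, a1m2 / np.maximum(n2, 1), np.nan)
    p1 = binom_test_two_sided(a1m1, n1)
    p2 = binom_test_two_sided(a1m2, n2)

    sig = (p1 < alpha) & (p2 < alpha) & testable
    ase1 = sig & (f1 > threshold) & (f2 > threshold)
    ase2 = sig & ((1 - f1) > threshold) & ((1 - f2) > threshold)
    # maternal allele is allele1 in the mother=parent1 hybrid, allele2 in
    # the reciprocal; the genomic allele flips, the parental role does not
    imp_mat = sig & (f1 > threshold) & ((1 - f2) > threshold)
    imp_pat = sig & ((1 - f1) > threshold) & (f2 > threshold)

    pattern = np.full(len(table), "biallelic", dtype=object)
    pattern[imp_pat] = "imprinted_paternal"
    pattern[imp_mat] = "imprinted_maternal"
    pattern[ase2] = "ase_allele2"
    pattern[ase1] = "ase_allele1"

    out = table.copy()
    out["frac1_m1"] = f1
    out["frac1_m2"] = f2
    out["p_m1"] = p1
    out["p_m2"] = p2
    out["testable"] = testable
    out["pattern"] = pattern
    return out


def classify_snp(
    results: Mapping[str, BiasTestResult],
    crosses: Sequence[CrossDesign],
    parent1: str,
    alpha: float = 0.05,
    threshold: float = 0.8,
) -> str:
    """Classify a single SNP from per-hybrid bias-test results.

    ``results`` maps hybrid id to its BiasTestResult; ``crosses`` is the
    reciprocal pair; ``parent1`` names the genotype carrying allele 1.
    """
    a, b = reciprocal_pair(crosses)
    m1 = a if a.mother == parent1 else b
    m2 = b if m1 is a else a
    if m1.mother != parent1:
        raise AseError(f"no hybrid with mother {parent1!r} in the cross pair")
    for c in (m1, m2):
        if c.hybrid_id not in results:
            raise AseError(f"missing bias result for hybrid {c.hybrid_id!r}")
    r1, r2 = results[m1.hybrid_id], results[m2.hybrid_id]
    if not (r1.testable and r2.testable):
        return "biallelic"
    if not (r1.p_value < alpha and r2.p_value < alpha):
        return "biallelic"
    f1, f2 = r1.allele1_fraction, r2.allele1_fraction
    if f1 > threshold and f2 > threshold:
        return "ase_allele1"
    if (1 - f1) > threshold and (1 - f2) > threshold:
        return "ase_allele2"
    if f1 > threshold and (1 - f2) > threshold:
        return "imprinted_maternal"
    if (1 - f1) > threshold and f2 > threshold:
        return "imprinted_paternal"
    return "biallelic"


def build_reciprocal_table(
    counts: pd.DataFrame,
    crosses: Sequence[CrossDesign],
    parent1: str,
) -> pd.DataFrame:
    """Pivot long allelic counts into the reciprocal wide layout.

    ``counts`` columns: snp_id, sample, n_allele1, n_allele2 (optionally
    gene_id, carried through). Only the two hybrid samples are used.
    """
    a, b = reciprocal_pair(crosses)
    m1 = a if a.mother == parent1 else b
    m2 = b if m1 is a else a
    if m1.mother != parent1:
        raise AseError(f"no hybrid with mother {parent1!r}")
    for c in (m1, m2):
        if c.hybrid_id not in set(counts["sample"]):
            raise AseError(f"no counts for hybrid sample {c.hybrid_id!r}")

    keys = ["snp_id"] + (["gene_id"] if "gene_id" in counts.columns else [])
    h1 = (
        counts[counts["sample"] == m1.hybrid_id]
        .set_index(keys)[["n_allele1", "n_allele2"]]
        .rename(columns={"n_allele1": "a1_m1", "n_allele2": "a2_m1"})
    )
    h2 = (
        counts[counts["sample"] == m2.hybrid_id]
        .set_index(keys)[["n_allele1", "n_allele2"]]
        .rename(columns={"n_allele1": "a1_m2", "n_allele2": "a2_m2"})
    )
    wide = h1.join(h2, how="outer").fillna(0).astype(np.int64).reset_index()
    return wide


# ---------------------------------------------------------------------------
# Gene-level calls


def _call_genes(
    patterns: pd.DataFrame, wanted: tuple[str, str], status_names: tuple[str, str]
) -> tuple[pd.DataFrame, dict]:
    if "gene_id" not in patterns.columns:
        raise AseError("patterns table lacks gene_id; aggregate needs SNP->gene map")
    pat = patterns.dropna(subset=["gene_id"])
    tested_genes = pat.loc[pat["testable"], "gene_id"].unique()
    rows = []
    for gene_id, grp in pat.groupby("gene_id", sort=True):
        n_a = int((grp["pattern"] == wanted[0]).sum())
        n_b = int((grp["pattern"] == wanted[1]).sum())
        if n_a == 0 and n_b == 0:
            continue
        status = status_names[0] if n_a >= n_b else status_names[1]
        conflicting = n_a > 0 and n_b > 0
        rows.append(
            dict(
                gene_id=gene_id,
                status=status,
                n_supporting_snps=max(n_a, n_b),
                n_conflicting_snps=min(n_a, n_b) if conflicting else 0,
                flag="conflicting" if conflicting else "consistent",
            )
        )
    calls = pd.DataFrame(
        rows, columns=["gene_id", "status", "n_supporting_snps",
                       "n_conflicting_snps", "flag"]
    )
    n_tested = int(len(tested_genes))
    n_called = int(len(calls))
    summary = dict(
        n_genes_tested=n_tested,
        n_genes_called=n_called,
        percent=round(100.0 * n_called / n_tested, 2) if n_tested else 0.0,
    )
    return calls, summary


def call_ase_genes(patterns: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Gene-level ASE calls: >=1 ASE-pattern SNP makes the gene ASE.

    Genes carrying SNPs of both directions stay ASE but are flagged
    ``conflicting``. The summary reports called/tested counts and the
    exact percentage over genes with testable SNPs.
    """
    return _call_genes(
        patterns, ("ase_allele1", "ase_allele2"), ("ase_allele1", "ase_allele2")
    )


def call_imprinted_genes(patterns: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Gene-level imprinting calls; same aggregation rule as ASE."""
    return _call_genes(
        patterns,
        ("imprinted_maternal", "imprinted_paternal"),
        ("imprinted_maternal", "imprinted_paternal"),
    )


# ---------------------------------------------------------------------------
# Descriptive summary


def allelic_ratio_summary(
    counts: pd.DataFrame,
    cross: CrossDesign,
    parent1: str,
    bins: int = 20,
) -> dict:
    """Distribution of per-SNP maternal-allele fractions for one hybrid.

    Descriptive only (mean, SD, skewness, histogram); under biallelic
    expression the distribution centers at 0.5.
    """
    sub = counts[counts["sample"] == cross.hybrid_id]
    tot = (sub["n_allele1"] + sub["n_allele2"]).to_numpy(float)
    with np.errstate(invalid="ignore"):
        f1 = sub["n_allele1"].to_numpy(float) / tot
    f1 = f1[tot > 0]
    maternal = f1 if cross.mother == parent1 else 1.0 - f1
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, _ = np.histogram(maternal, bins=edges)
    sd = float(np.std(maternal, ddof=0)) if maternal.size else float("nan")
    skewness = (
        float(stats.skew(maternal)) if maternal.size > 2 and sd > 0 else float("nan")
    )
    return dict(
        hybrid_id=cross.hybrid_id,
        n_snps=int(maternal.size),
        mean=float(np.mean(maternal)) if maternal.size else float("nan"),
        sd=sd,
        skewness=skewness,
        histogram=[
            dict(lo=float(edges[i]), hi=float(edges[i + 1]), n=int(hist[i]))
            for i in range(bins)
        ],
        fractions=maternal,
    )
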