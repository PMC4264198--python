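"""Count-based expression analyses.

Implements the classic negative-binomial exact-test pipeline for designs
without replicates: median-of-ratios size factors, a mean-variance
relationship fitted by local regression over genes (pooling the compared
samples "blind" as pseudo-replicates, which is conservative for truly
changing genes), and a conditioned two-sided exact test on each gene's
count split. Also FPKM, Shannon-entropy expression breadth, detected-gene
sets, and DEG overlap summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.nonparametric.smoothers_lowess import lowess


class ExpressionError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with gene lengths (bp)."""

    counts: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ExpressionError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ExpressionError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise ExpressionError("lengths missing for some genes")
            if (self.lengths <= 0).any():
                raise ExpressionError("gene lengths must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


# ---------------------------------------------------------------------------
# Normalization


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over genes (restricted to
    genes with a positive geometric mean across samples) of
    ``count_ij / geometric_mean_i``.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(arr)
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ExpressionError(
            "no gene has nonzero counts in every sample; cannot normalize"
        )
    ratios = np.exp(log_counts[usable] - log_geomean[usable, None])
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=df.columns, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersion / variance model


class DispersionModel:
    """Raw-variance function v(q) fitted by local regression over genes.

    Per gene the mean ``q`` and sample variance ``w`` of size-factor
    normalized counts are computed across the pooled samples; ``w`` is
    smoothed against ``log q`` (plain local linear regression, no robust
    reweighting, so the fit estimates the conditional mean of the skewed
    variance estimates). The raw (extra-Poisson) variance is
    ``v(q) = max(fit(q) - q * mean(1/s_j), floor)`` and the full variance of
    counts in a sample with size factor s is ``s q + s^2 v(q)``.
    """

    def __init__(self, log_q: np.ndarray, fitted_w: np.ndarray, xim: float,
                 floor: float = 1e-8):
        order = np.argsort(log_q)
        self._x = log_q[order]
        self._y = fitted_w[order]
        self.xim = float(xim)
        self.floor = float(floor)

    @classmethod
    def fit(
        cls,
        counts: CountMatrix | pd.DataFrame,
        size_factors_: pd.Series,
        frac: float = 0.3,
        conditions: Mapping[str, str] | None = None,
    ) -> "DispersionModel":
        """Fit the variance model from normalized counts.

        With ``conditions`` (sample -> condition) and at least one
        replicated condition, the per-gene variance is the pooled
        within-condition variance, so true between-condition differences do
        not inflate the fit. Without replicates all samples are pooled
        "blind" as pseudo-replicates — conservative, since genuine changes
        then count as noise.
        """
        df = counts.counts if isinstance(counts, CountMatrix) else counts
        if df.shape[1] < 2:
            raise ExpressionError("need >=2 samples to estimate dispersion")
        sf = size_factors_.reindex(df.columns).to_numpy(dtype=float)
        norm = df.to_numpy(dtype=float) / sf
        q = norm.mean(axis=1)

        groups: list[np.ndarray] = []
        if conditions is not None:
            by_cond: dict[str, list[int]] = {}
            for j, s in enumerate(df.columns):
                by_cond.setdefault(conditions.get(s, s), []).append(j)
            groups = [np.array(ix) for ix in by_cond.values() if len(ix) >= 2]
        if groups:
            ss = np.zeros(df.shape[0])
            dof = 0
            for ix in groups:
                sub = norm[:, ix]
                ss += sub.var(axis=1, ddof=1) * (len(ix) - 1)
                dof += len(ix) - 1
            w = ss / dof
        else:
            w = norm.var(axis=1, ddof=1)
        sel = q > 0  # all-zero genes are excluded from the fit
        if sel.sum() < 10:
            raise ExpressionError("too few expressed genes to fit dispersion")
        xim = float(np.mean(1.0 / sf))
        lx = np.log(q[sel])
        smoothed = lowess(
            w[sel], lx, frac=frac, it=0, delta=0.01 * (lx.max() - lx.min()),
            return_sorted=True,
        )
        # collapse duplicate x for interpolation
        xs, idx = np.unique(smoothed[:, 0], return_index=True)
        ys = smoothed[idx, 1]
        return cls(xs, ys, xim)

    @classmethod
    def from_function(
        cls, raw_variance: Callable[[np.ndarray], np.ndarray], xim: float = 1.0
    ) -> "DispersionModel":
        """Wrap an explicit raw-variance function (mainly for testing)."""
        model = cls.__new__(cls)
        model._fn = raw_variance  # type: ignore[attr-defined]
        model._x = None
        model.xim = float(xim)
        model.floor = 1e-8
        return model

    def raw_variance(self, q):
        q = np.asarray(q, dtype=float)
        if getattr(self, "_x", None) is None:
            v = np.asarray(self._fn(q), dtype=float)  # type: ignore[attr-defined]
        else:
            fit_w = np.interp(np.log(np.maximum(q, 1e-300)), self._x, self._y)
            v = fit_w - q * self.xim
        return np.maximum(v, self.floor)

    def full_variance(self, q, s):
        """Variance of raw counts at normalized mean q and size factor s."""
        q = np.asarray(q, dtype=float)
        s = np.asarray(s, dtype=float)
        return s * q + s**2 * self.raw_variance(q)


estimate_dispersions = DispersionModel.fit


# ---------------------------------------------------------------------------
# NB exact test


def _nb_logpmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    """NB log-pmf by moment matching; Poisson when var <= mean."""
    if var <= mean or mean <= 0:
        return stats.poisson.logpmf(x, max(mean, 1e-300))
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(x, r, p)


def nb_exact_test(
    kA: int,
    kB: int,
    size_factors_a: Sequence[float],
    size_factors_b: Sequence[float],
    variance_model: DispersionModel,
) -> float:
    """Conditioned two-sided exact test of a count split between conditions.

    Under the null the two condition sums are NB with means ``s_A q0`` /
    ``s_B q0`` (q0 the pooled normalized mean) and variances from the
    fitted model. The p-value is the total probability, conditioned on the
    overall sum, of all splits no more likely than the observed one.
    Accumulation is in log space.
    """
    kA, kB = int(kA), int(kB)
    if kA < 0 or kB < 0:
        raise ExpressionError("counts must be non-negative")
    ks = kA + kB
    if ks == 0:
        return 1.0
    sA = float(np.sum(size_factors_a))
    sB = float(np.sum(size_factors_b))
    q0 = ks / (sA + sB)
    muA, muB = sA * q0, sB * q0
    varA = float(variance_model.full_variance(q0, sA))
    varB = float(variance_model.full_variance(q0, sB))

    a = np.arange(ks + 1)
    logp = _nb_logpmf(a, muA, varA) + _nb_logpmf(a[::-1], muB, varB)
    log_obs = logp[kA]
    keep = logp <= log_obs + 1e-10
    num = logsumexp(logp[keep])
    den = logsumexp(logp)
    p = float(np.exp(num - den))
    return min(max(p, np.finfo(float).tiny), 1.0)


# ---------------------------------------------------------------------------
# Multiple testing


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ExpressionError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Differential expression


def call_degs(
    counts: CountMatrix | pd.DataFrame,
    cond_a: Sequence[str],
    cond_b: Sequence[str],
    alpha: float = 0.05,
    min_fold: float = 2.0,
    size_factors_: pd.Series | None = None,
    variance_model: DispersionModel | None = None,
    lowess_frac: float = 0.3,
) -> pd.DataFrame:
    """Exact-test DE between two sample groups.

    A gene is DE iff its BH-adjusted p < ``alpha`` and its fold change
    (on normalized means, pseudo-count 1) is at least ``min_fold`` in
    either direction. With one library per condition the variance model is
    fitted blind by pooling the compared samples.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    for s in itertools.chain(cond_a, cond_b):
        if s not in df.columns:
            raise ExpressionError(f"unknown sample/condition id: {s!r}")
    pair = df[list(cond_a) + list(cond_b)]
    if size_factors_ is None:
        size_factors_ = size_factors(pair)
    if variance_model is None:
        conditions = {s: "A" for s in cond_a} | {s: "B" for s in cond_b}
        variance_model = DispersionModel.fit(
            pair, size_factors_, frac=lowess_frac, conditions=conditions
        )

    sfA = size_factors_.reindex(list(cond_a)).to_numpy(dtype=float)
    sfB = size_factors_.reindex(list(cond_b)).to_numpy(dtype=float)
    kA = df[list(cond_a)].sum(axis=1).to_numpy(np.int64)
    kB = df[list(cond_b)].sum(axis=1).to_numpy(np.int64)

    p = np.ones(len(df))
    for i in range(len(df)):
        if kA[i] + kB[i] > 0:
            p[i] = nb_exact_test(kA[i], kB[i], sfA, sfB, variance_model)
    padj = adjust_bh(p)

    mean_a = kA / sfA.sum()
    mean_b = kB / sfB.sum()
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    is_de = (padj < alpha) & (np.abs(log2fc) >= np.log2(min_fold))
    return pd.DataFrame(
        dict(
            gene_id=df.index,
            mean_a=mean_a,
            mean_b=mean_b,
            log2fc=log2fc,
            p_value=p,
            adjusted_p=padj,
            is_de=is_de,
        )
    ).set_index("gene_id")


def all_pairwise_degs(
    counts: CountMatrix | pd.DataFrame,
    conditions: Mapping[str, Sequence[str]] | None = None,
    **kwargs,
) -> dict[tuple[str, str], pd.DataFrame]:
    """DE for every unordered pair of conditions (6 pairs for 4 genotypes)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if conditions is None:
        conditions = {s: [s] for s in df.columns}
    out = {}
    for a, b in itertools.combinations(conditions, 2):
        out[(a, b)] = call_degs(counts, conditions[a], conditions[b], **kwargs)
    return out


def pairwise_deg_summary(deg_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Intersection sizes and containment percentages for all set pairs."""
    sets = {k: set(v) for k, v in deg_sets.items()}
    rows = []
    for a, b in itertools.combinations(sets, 2):
        inter = len(sets[a] & sets[b])
        rows.append(
            dict(
                set_a=a,
                set_b=b,
                n_a=len(sets[a]),
                n_b=len(sets[b]),
                n_intersection=inter,
                pct_a_in_b=round(100.0 * inter / len(sets[a]), 2) if sets[a] else 0.0,
                pct_b_in_a=round(100.0 * inter / len(sets[b]), 2) if sets[b] else 0.0,
            )
        )
    return pd.DataFrame(rows)


def overlap_containment(
    set_a: Iterable[str], set_b: Iterable[str], reference: Iterable[str]
) -> dict:
    """|A ∩ B| and the percentage of that intersection found in a third set."""
    inter = set(set_a) & set(set_b)
    ref = set(reference)
    n_in_ref = len(inter & ref)
    return dict(
        n_intersection=len(inter),
        n_in_reference=n_in_ref,
        pct_in_reference=round(100.0 * n_in_ref / len(inter), 2) if inter else 0.0,
    )


# ---------------------------------------------------------------------------
# FPKM and expression breadth


def compute_fpkm(
    counts: CountMatrix | pd.DataFrame,
    lengths: pd.Series | None = None,
    mapped_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length_bp * total_mapped_reads).

    ``mapped_totals`` defaults to per-sample column sums.
    """
    if isinstance(counts, CountMatrix):
        if lengths is None:
            lengths = counts.lengths
        counts = counts.counts
    if lengths is None:
        raise ExpressionError("gene lengths are required for FPKM")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive for all genes")
    if mapped_totals is None:
        mapped_totals = counts.sum(axis=0)
    mapped_totals = mapped_totals.reindex(counts.columns)
    if (mapped_totals <= 0).any():
        raise ExpressionError("per-sample mapped totals must be positive")
    vals = (
        counts.to_numpy(dtype=float)
        * 1e9
        / (lengths.to_numpy(dtype=float)[:, None]
           * mapped_totals.to_numpy(dtype=float)[None, :])
    )
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def shannon_entropy(expression: pd.DataFrame) -> pd.Series:
    """Per-gene Shannon entropy (bits) of expression shares across tissues.

    p_t = x_t / sum(x); H = -sum p_t log2 p_t over positive shares; genes
    with no expression anywhere are undefined (NaN).
    """
    arr = expression.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ExpressionError("expression values must be non-negative")
    totals = arr.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = arr / totals[:, None]
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    h = -terms.sum(axis=1)
    h[totals <= 0] = np.nan
    return pd.Series(h, index=expression.index, name="shannon_entropy")


def breadth_profile(
    fpkm: pd.DataFrame, min_fpkm: float = 1.0
) -> pd.Series:
    """Entropy restricted to genes with FPKM > min_fpkm in >=1 tissue."""
    keep = (fpkm > min_fpkm).any(axis=1)
    return shannon_entropy(fpkm.loc[keep])


# ---------------------------------------------------------------------------
# Detected-gene sets


def detected_gene_sets(
    counts: CountMatrix | pd.DataFrame, min_reads: int = 1
) -> tuple[dict[str, set[str]], dict[tuple[str, ...], int], int]:
    """Per-sample detected-gene sets plus exclusive Venn region counts.

    Returns (sets, regions, union size) where ``regions`` maps each
    non-empty sample combination (sorted tuple) to the number of genes
    detected in exactly those samples; region counts partition the union.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    sets = {s: set(df.index[df[s] >= min_reads]) for s in df.columns}
    membership: dict[str, tuple[str, ...]] = {}
    for s, genes in sets.items():
        for g in genes:
            membership[g] = membership.get(g, ()) + (s,)
    regions: dict[tuple[str, ...], int] = {}
    for combo in membership.values():
        key = tuple(sorted(combo))
        regions[key] = regions.get(key, 0) + 1
    union = len(membership)
    return sets, regions, union
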