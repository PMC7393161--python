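"""Extreme-quartile pooled-sequencing association scan and filter cascade.

Individuals ranked by phenotype are split into four quartile pools; allele
frequencies are estimated from pooled read counts, and per-SNP association
between the extreme pools (Q1 vs Q4) is tested with a two-sided Fisher
exact test on the 2x2 read-count table, followed by Bonferroni correction.

The candidate-variant cascade then applies, in order: a per-pool coverage
band (central 68.2% of sites), a mean +/- 3 s.d. coverage mask on parental
re-sequencing data, exclusion of variants with conflicting parental read
support, the Fisher/Bonferroni scan, a directionality filter (reference
allele more frequent in the high pool), a phylogenetic-consistency filter
(outgroup species carry the alternative allele), and intersection with an
independently significant SNP set.

SNP tables are pandas DataFrames with columns ``chrom, pos, ref, alt`` and
per-pool count columns ``{pool}_ref`` / ``{pool}_alt``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "quartile_partition",
    "coverage_band",
    "fisher_exact_2x2",
    "fisher_scan",
    "bonferroni_filter",
    "mask_extreme_coverage",
    "exclude_shared_variants",
    "directional_filter",
    "phylo_consistency_filter",
    "intersect_snp_sets",
    "pool_coverage",
    "pool_ref_frequency",
]

KEY_COLS = ["chrom", "pos", "ref", "alt"]


def quartile_partition(values) -> list[np.ndarray]:
    """Split individuals into four phenotype quartiles Q1..Q4 (ascending).

    The extreme quartiles receive the larger share first: Q1 and Q4 each
    get ceil(n/4) individuals, the remainder is split between Q2 and Q3
    (Q2 rounded up).  For n = 157 this yields sizes (40, 39, 38, 40).
    Ties are broken by stable sort on input order.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 individuals")
    order = np.argsort(values, kind="stable")
    q14 = math.ceil(n / 4)
    rem = n - 2 * q14
    q2 = math.ceil(rem / 2)
    sizes = [q14, q2, rem - q2, q14]
    out, start = [], 0
    for s in sizes:
        out.append(order[start:start + s])
        start += s
    return out


def coverage_band(site_coverages, central_fraction: float = 0.682,
                  rounding: str = "nearest") -> tuple[int, int, np.ndarray]:
    """Integer coverage interval holding the central fraction of sites.

    The band is the empirical quantile interval
    [(1-f)/2, 1-(1-f)/2] (0.159 and 0.841 for f = 0.682), with the bounds
    rounded to integers (``"nearest"`` by default, ``"outward"`` for a
    guaranteed-coverage band).  Returns ``(lo, hi, keep_mask)``.
    """
    cov = np.asarray(site_coverages, dtype=float)
    if cov.size == 0:
        raise ValueError("empty coverage input")
    if cov.size < 10:
        raise ValueError("need at least 10 sites to estimate a band")
    alpha = (1.0 - central_fraction) / 2.0
    qlo, qhi = np.quantile(cov, [alpha, 1.0 - alpha])
    if rounding == "nearest":
        lo, hi = int(round(qlo)), int(round(qhi))
    elif rounding == "outward":
        lo, hi = int(math.floor(qlo)), int(math.ceil(qhi))
    else:
        raise ValueError("rounding must be 'nearest' or 'outward'")
    keep = (cov >= lo) & (cov <= hi)
    return lo, hi, keep


# ---------------------------------------------------------------------------
# Fisher exact scan


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(a, b, c, d) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for tables [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with
    the same margins whose probability does not exceed that of the observed
    table (to within a small relative tolerance, matching the usual
    convention).  Rows with an empty margin get p = 1.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    r1 = a + b
    r2 = c + d
    c1 = a + c
    n = r1 + r2
    kmin = np.maximum(0, c1 - r2)
    kmax = np.minimum(r1, c1)
    width = int((kmax - kmin).max()) + 1
    k = kmin[:, None] + np.arange(width)[None, :]
    valid = k <= kmax[:, None]
    kc = np.where(valid, k, kmin[:, None])
    logpmf = (
        _log_binom(r1[:, None], kc)
        + _log_binom(r2[:, None], c1[:, None] - kc)
        - _log_binom(n[:, None], c1[:, None])
    )
    logpmf = np.where(valid, logpmf, -np.inf)
    obs = (
        _log_binom(r1, a) + _log_binom(r2, c) - _log_binom(n, c1)
    )
    include = logpmf <= obs[:, None] + 1e-7
    p = np.exp(logpmf, where=np.isfinite(logpmf), out=np.zeros_like(logpmf))
    pvals = (p * include).sum(axis=1)
    pvals = np.clip(pvals, 0.0, 1.0)
    empty = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c1 == n)
    pvals[empty] = 1.0
    return pvals


def pool_coverage(snps: pd.DataFrame, pool: str) -> np.ndarray:
    return (snps[f"{pool}_ref"] + snps[f"{pool}_alt"]).to_numpy()


def pool_ref_frequency(snps: pd.DataFrame, pool: str) -> np.ndarray:
    ref = snps[f"{pool}_ref"].to_numpy(dtype=float)
    alt = snps[f"{pool}_alt"].to_numpy(dtype=float)
    tot = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, ref / tot, np.nan)


def fisher_scan(snps: pd.DataFrame, pool_a: str, pool_b: str) -> pd.Series:
    """Two-sided Fisher exact p per SNP for pool_a vs pool_b read counts.

    Sites with zero total count in either pool are skipped (p = NaN) and
    should be logged/excluded by the caller; they do not count toward the
    Bonferroni test number.
    """
    a = snps[f"{pool_a}_ref"].to_numpy(dtype=np.int64)
    b = snps[f"{pool_a}_alt"].to_numpy(dtype=np.int64)
    c = snps[f"{pool_b}_ref"].to_numpy(dtype=np.int64)
    d = snps[f"{pool_b}_alt"].to_numpy(dtype=np.int64)
    p = fisher_exact_2x2(a, b, c, d)
    skip = ((a + b) == 0) | ((c + d) == 0)
    p = p.astype(float)
    p[skip] = np.nan
    return pd.Series(p, index=snps.index, name="fisher_p")


def bonferroni_filter(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Keep p <= alpha/m, with m the number of tests actually performed.

    NaN p-values (skipped sites) are neither counted in m nor kept.
    Returns ``(significant_mask, threshold)``.
    """
    p = np.asarray(pvals, dtype=float)
    m = int(np.isfinite(p).sum())
    if m < 1:
        raise ValueError("need at least one test")
    thr = alpha / m
    mask = np.where(np.isfinite(p), p <= thr, False)
    return mask, thr


# ---------------------------------------------------------------------------
# cascade filters


def mask_extreme_coverage(coverages, n_sd: float = 3.0) -> np.ndarray:
    """Keep sites with coverage within mean +/- n_sd standard deviations."""
    cov = np.asarray(coverages, dtype=float)
    mu, sd = cov.mean(), cov.std(ddof=0)
    return (cov >= mu - n_sd * sd) & (cov <= mu + n_sd * sd)


def exclude_shared_variants(nov_ref_support, am_alt_support,
                            mode: str = "or") -> np.ndarray:
    """Keep-mask dropping sites with conflicting parental read support.

    A clean fixed difference has zero reads supporting the reference allele
    in the non-reference parent (D. novamexicana) and zero supporting the
    alternative allele in the reference strain (D. americana SF12).
    ``mode="or"`` (default, conservative) drops a site when either parent
    shows conflicting support; ``mode="and"`` requires both.
    """
    nov = np.asarray(nov_ref_support, dtype=float)
    am = np.asarray(am_alt_support, dtype=float)
    if mode == "or":
        drop = (nov > 0) | (am > 0)
    elif mode == "and":
        drop = (nov > 0) & (am > 0)
    else:
        raise ValueError("mode must be 'or' or 'and'")
    return ~drop


def directional_filter(freq_hi, freq_lo) -> np.ndarray:
    """Keep sites with strictly higher reference-allele frequency in the
    high-phenotype pool than in the low-phenotype pool."""
    return np.asarray(freq_hi, dtype=float) > np.asarray(freq_lo, dtype=float)


def phylo_consistency_filter(snps: pd.DataFrame, nov_allele, vir_allele) -> np.ndarray:
    """Keep sites where both outgroup strains carry the alternative allele.

    The reference strain carries ref by construction; a variant consistent
    with the phylogenetic scenario has the alternative allele shared by
    D. novamexicana and D. virilis.  Missing outgroup calls drop the site.
    """
    alt = snps["alt"].to_numpy()
    nov = np.asarray(nov_allele, dtype=object)
    vir = np.asarray(vir_allele, dtype=object)
    called = pd.notna(nov) & pd.notna(vir)
    return called & (nov == alt) & (vir == alt)


def intersect_snp_sets(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """Exact intersection on (chrom, pos, ref, alt) with per-chromosome counts.

    Duplicate keys within either set raise an error.  The returned frame
    carries the columns of ``set_a`` plus a ``per_chrom`` attribute-style
    companion is available via ``.groupby('chrom').size()``.
    """
    for name, df in (("set_a", set_a), ("set_b", set_b)):
        if df.duplicated(subset=KEY_COLS).any():
            raise ValueError(f"duplicate SNP keys in {name}")
    merged = set_a.merge(set_b[KEY_COLS], on=KEY_COLS, how="inner")
    return merged
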