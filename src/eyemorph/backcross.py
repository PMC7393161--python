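"""Per-chromosome genotype-phenotype association in a backcross design.

In a backcross of F1 hybrid females to males of the recurrent parental
line, each chromosome segregates as a two-level factor: homozygous for the
recurrent parent ("hom") versus heterozygous ("het").  Chromosome effects
on a phenotype are therefore estimated with simple linear models using the
chromosome factor, and epistasis is probed by adding interaction terms.

Marker bookkeeping: chromosomes may carry several linked markers; because
essentially no recombination is expected between tightly linked markers,
individuals with discordant calls within a linked pair are flagged as
recombinants and excluded, as are individuals with genotypes impossible
under the backcross design (homozygous for the donor parent).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

HOM = "hom_nov"     # homozygous recurrent (D. novamexicana) parent
HET = "het"
IMPOSSIBLE = "hom_am"  # donor-parent homozygote: impossible in a backcross
MISSING = "missing"

__all__ = [
    "HOM", "HET", "IMPOSSIBLE", "MISSING",
    "filter_recombinants",
    "chromosome_effect",
    "ChromosomeEffect",
    "epistasis_test",
    "genotype_class_summary",
    "class_contrast",
]


def filter_recombinants(genotypes: pd.DataFrame, linked_pairs,
                        marker_cols=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop recombinants within linked marker pairs and impossible genotypes.

    ``genotypes`` is one row per individual with marker call columns.
    Returns ``(cleaned, exclusion_log)``; the log has one row per excluded
    individual with the reason.
    """
    df = genotypes.copy()
    if marker_cols is None:
        marker_cols = [c for c in df.columns if c != "individual_id"]
    log_rows = []
    drop = pd.Series(False, index=df.index)
    for idx, row in df.iterrows():
        ind = row.get("individual_id", idx)
        impossible = [m for m in marker_cols if row[m] == IMPOSSIBLE]
        if impossible:
            log_rows.append({"individual_id": ind, "reason": "impossible_genotype",
                             "markers": ",".join(impossible)})
            drop[idx] = True
            continue
        for a, b in linked_pairs:
            ca, cb = row[a], row[b]
            if MISSING in (ca, cb):
                continue
            if ca != cb:
                log_rows.append({"individual_id": ind, "reason": "recombinant",
                                 "markers": f"{a},{b}"})
                drop[idx] = True
                break
    log = pd.DataFrame(log_rows, columns=["individual_id", "reason", "markers"])
    return df[~drop].reset_index(drop=True), log


@dataclass
class ChromosomeEffect:
    effect_pct: float      # het-class mean relative to hom-class mean, in %
    p_value: float
    r_squared: float
    mean_hom: float
    mean_het: float
    n_hom: int
    n_het: int


def _het_indicator(genotype) -> np.ndarray:
    g = np.asarray(genotype)
    if g.dtype.kind in "OU":
        valid = np.isin(g, [HOM, HET])
        if not valid.all():
            raise ValueError("genotype contains calls other than hom/het; filter first")
        return (g == HET).astype(float)
    return g.astype(float)


def chromosome_effect(phenotype, genotype) -> ChromosomeEffect:
    """Linear model phenotype ~ chromosome genotype (hom vs het).

    The effect is reported as the percent change of the heterozygous class
    mean relative to the homozygous (recurrent-parent) class mean; for a
    two-level factor this equals the model coefficient divided by the hom
    mean.  R² and the coefficient p-value come from the same model.
    """
    y = np.asarray(phenotype, dtype=float)
    x = _het_indicator(genotype)
    n_het = int(x.sum())
    n_hom = int(len(x) - n_het)
    if n_het == 0 or n_hom == 0:
        raise ValueError("both genotype classes must be present")
    mean_hom = y[x == 0].mean()
    mean_het = y[x == 1].mean()
    if np.ptp(y) == 0:  # constant phenotype: no variation to explain
        return ChromosomeEffect(0.0, 1.0, 0.0, float(mean_hom),
                                float(mean_het), n_hom, n_het)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return ChromosomeEffect(
        effect_pct=float(100.0 * (mean_het - mean_hom) / mean_hom),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        mean_hom=float(mean_hom),
        mean_het=float(mean_het),
        n_hom=n_hom,
        n_het=n_het,
    )


def epistasis_test(phenotype, genotypes: pd.DataFrame, chromosome_sets) -> pd.DataFrame:
    """Interaction p-values for the listed chromosome combinations.

    For each set of chromosomes a linear model with all main effects and
    the full interaction structure is fitted; the returned table has one
    row per interaction term.  Sets with an empty joint genotype cell are
    reported with a warning and no p-value rather than fitted.
    """
    y = np.asarray(phenotype, dtype=float)
    rows = []
    for chroms in chromosome_sets:
        cols = {c: _het_indicator(genotypes[c]) for c in chroms}
        joint = np.stack(list(cols.values()), axis=1).astype(int)
        cell_ids = joint @ (2 ** np.arange(len(chroms)))
        occupied = len(np.unique(cell_ids))
        if occupied < 2 ** len(chroms):
            rows.append({"chromosomes": "x".join(chroms), "term": None,
                         "coefficient": np.nan, "p_value": np.nan,
                         "warning": "empty genotype cell; term skipped"})
            continue
        df = pd.DataFrame(cols)
        df["y"] = y
        formula = "y ~ " + " * ".join(chroms)
        fit = sm.OLS.from_formula(formula, data=df).fit()
        for name in fit.params.index:
            if ":" in name:
                rows.append({"chromosomes": "x".join(chroms), "term": name,
                             "coefficient": float(fit.params[name]),
                             "p_value": float(fit.pvalues[name]),
                             "warning": ""})
    return pd.DataFrame(rows)


def genotype_class_summary(phenotype, genotypes: pd.DataFrame,
                           chromosomes=None) -> pd.DataFrame:
    """Mean ± SEM of the phenotype per joint genotype class.

    Classes are labelled by concatenating per-chromosome calls, e.g.
    ``het/het/hom_nov``.  Empty classes are simply absent from the table.
    """
    if chromosomes is None:
        chromosomes = [c for c in genotypes.columns if c != "individual_id"]
    y = np.asarray(phenotype, dtype=float)
    key = genotypes[list(chromosomes)].agg("/".join, axis=1)
    out = (
        pd.DataFrame({"class": key, "y": y})
        .groupby("class")["y"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n="size")
        .reset_index()
    )
    return out


def class_contrast(summary: pd.DataFrame, class_a: str, class_b: str) -> float | None:
    """Percent difference of class_a mean relative to class_b mean.

    Returns None (reported as missing) if either class is absent.
    """
    s = summary.set_index("class")
    if class_a not in s.index or class_b not in s.index:
        return None
    return float(100.0 * (s.loc[class_a, "mean"] - s.loc[class_b, "mean"])
                 / s.loc[class_b, "mean"])
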