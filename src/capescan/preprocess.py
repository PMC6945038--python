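"""Genotype filtering/coding, trait normalization and cohort diagnostics.

Implements the standard preparation steps for a dominant-model epistasis
scan: a minor-allele-frequency filter, dominant recoding (any copy of the
minor allele -> 1), rank-based inverse-normal (rank-Z) transformation of
quantitative traits, descriptive group tests between binary factors and
quantitative traits, and a genomic-control style QQ/inflation diagnostic
for population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import DOMINANT, DOSAGE, GenotypeMatrix, TraitTable

#: median of the chi-square distribution with 1 df
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


def compute_maf(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor-allele frequency min(f, 1-f) from dosage counts."""
    if genotypes.coding != DOSAGE:
        raise ValueError("MAF is defined on dosage-coded genotypes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        f = np.nanmean(genotypes.values, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def maf_filter(genotypes: GenotypeMatrix, min_maf: float,
               max_missing: float = 0.05,
               drop_high_missing: bool = True) -> GenotypeMatrix:
    """Retain markers with minor-allele frequency >= ``min_maf``.

    The boundary is inclusive, but strictly monomorphic markers (MAF
    exactly 0) are always dropped — they carry no information, so a zero
    threshold keeps exactly the polymorphic markers.  Markers whose
    missing-call fraction exceeds ``max_missing`` are either dropped
    (default) or cause an error.  Marker order is preserved.
    """
    if genotypes.coding != DOSAGE:
        raise ValueError("maf_filter expects dosage-coded genotypes")
    miss = np.mean(~np.isfinite(genotypes.values), axis=0)
    too_missing = miss > max_missing
    if too_missing.any() and not drop_high_missing:
        bad = genotypes.marker_ids[too_missing][0]
        raise ValueError(f"marker {bad!r} exceeds missingness limit {max_missing}")
    maf = compute_maf(genotypes)
    keep = np.flatnonzero(~too_missing & np.isfinite(maf)
                          & (maf >= min_maf) & (maf > 0))
    return genotypes.select_markers(keep)


def dominant_code(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Recode dosages dominantly: homozygous major -> 0, else -> 1.

    The major allele is determined per marker from its sample frequency.
    For markers where allele 1 is the minor allele this maps dosage
    (0, 1, 2) -> (0, 1, 1); where allele 1 is the major allele the roles
    flip, so dosage 2 (homozygous major) maps to 0.  Idempotent: applying
    to an already dominant-coded matrix is a no-op with a warning.
    """
    if genotypes.coding == DOMINANT:
        warnings.warn("genotypes already dominant-coded; returning unchanged",
                      stacklevel=2)
        return genotypes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f1 = np.nanmean(genotypes.values, axis=0) / 2.0
    minor_is_allele1 = f1 <= 0.5
    carrier = np.where(minor_is_allele1[None, :],
                       genotypes.values > 0,       # any copy of allele 1
                       genotypes.values < 2)       # any copy of allele 0
    values = np.where(np.isfinite(genotypes.values), carrier.astype(float), np.nan)
    return GenotypeMatrix(values=values, coding=DOMINANT,
                          marker_ids=genotypes.marker_ids,
                          individual_ids=genotypes.individual_ids,
                          marker_meta=genotypes.marker_meta)


def rank_z(values, offset: str = "half") -> np.ndarray:
    """Rank-based inverse-normal transform of a numeric vector.

    Maps average ranks r to standard-normal quantiles.  ``offset='half'``
    uses Phi^-1((r - 0.5) / n); ``offset='blom'`` uses the Blom constant
    Phi^-1((r - 3/8) / (n + 1/4)).  Order-preserving; ties receive
    identical outputs.  NaNs propagate.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("rank_z needs at least 3 non-missing values")
    if np.ptp(x[ok]) == 0:
        raise ValueError("rank_z is undefined for an all-equal input")
    ranks = stats.rankdata(x[ok], method="average")
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown rank offset {offset!r}")
    out[ok] = stats.norm.ppf(q)
    return out


@dataclass
class TraitAssociationResult:
    """Descriptive test tables: group t-tests and 2x2 factor interactions."""

    t_tests: pd.DataFrame
    interactions: pd.DataFrame


def trait_association_tests(traits: TraitTable, welch: bool = False
                            ) -> TraitAssociationResult:
    """Descriptive associations between binary factors and quantitative traits.

    For each (binary factor, quantitative trait): a two-tailed two-sample
    Student's t-test (pooled variance by default; Welch behind a flag).
    For each unordered pair of binary factors and each quantitative trait:
    the p-value of the interaction term in the linear model
    ``trait ~ f1 + f2 + f1:f2``.  Cells with a group of fewer than two
    members are reported as not estimable.
    """
    factors = list(traits.binary_traits()) + [
        c for c in traits.covariates.columns
        if traits.covariates[c].dropna().isin([0, 1]).all()
    ]
    quants = traits.quantitative_traits()
    if not factors or not quants:
        raise ValueError("need at least one binary factor and one "
                         "quantitative trait")
    both = pd.concat([traits.values, traits.covariates], axis=1)

    rows = []
    for f in factors:
        for q in quants:
            sub = both[[f, q]].dropna()
            a = sub.loc[sub[f] == 1, q].to_numpy()
            b = sub.loc[sub[f] == 0, q].to_numpy()
            if len(a) < 2 or len(b) < 2:
                rows.append({"factor": f, "trait": q, "t": np.nan, "p": np.nan,
                             "mean_diff": np.nan, "estimable": False})
                continue
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
            rows.append({"factor": f, "trait": q, "t": float(t), "p": float(p),
                         "mean_diff": float(a.mean() - b.mean()),
                         "estimable": True})
    t_tests = pd.DataFrame(rows)

    rows = []
    for f1, f2 in combinations(factors, 2):
        for q in quants:
            sub = both[[f1, f2, q]].dropna()
            cells = sub.groupby([f1, f2])[q].size()
            if len(cells) < 4 or (cells < 2).any():
                rows.append({"factor1": f1, "factor2": f2, "trait": q,
                             "p_interaction": np.nan, "estimable": False})
                continue
            X = sm.add_constant(np.column_stack([
                sub[f1], sub[f2], sub[f1] * sub[f2]]))
            fit = sm.OLS(sub[q].to_numpy(), X).fit()
            rows.append({"factor1": f1, "factor2": f2, "trait": q,
                         "p_interaction": float(fit.pvalues[3]),
                         "estimable": True})
    interactions = pd.DataFrame(rows)
    return TraitAssociationResult(t_tests=t_tests, interactions=interactions)


@dataclass
class QQDiagnostic:
    """Genomic-control inflation factor and paired -log10(p) quantiles."""

    lambda_gc: float
    observed: np.ndarray   # sorted observed -log10 p, ascending
    expected: np.ndarray   # matching uniform quantiles on the -log10 scale


def qq_inflation(pvalues) -> QQDiagnostic:
    """Population-structure diagnostic from a set of association p-values.

    lambda = median(chi2_1 quantile of p) / median(chi2_1); lambda near 1
    indicates no systematic inflation of association statistics.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("qq_inflation requires a nonempty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / _CHI2_1_MEDIAN)
    observed = np.sort(-np.log10(p))
    n = p.size
    expected = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))
    return QQDiagnostic(lambda_gc=lam, observed=observed, expected=expected)
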