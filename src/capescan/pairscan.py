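"""Exhaustive pairwise interaction scanning over dominant-coded markers.

For every unordered marker pair (i < j) and a quantitative response y the
scan tests the interaction term of the full two-locus linear model

    y = b0 + b1*x1 + b2*x2 + b12*x1*x2 + e

With binary (dominant-coded) predictors this model is saturated over the
four two-locus genotype cells, so the OLS interaction estimate is the
cell-mean contrast

    b12 = ybar_11 - ybar_10 - ybar_01 + ybar_00,
    Var(b12) = sigma^2 * (1/n_00 + 1/n_01 + 1/n_10 + 1/n_11),

with sigma^2 the residual mean square on n - 4 degrees of freedom.  All
cell counts and cell sums for all pairs are obtained from a handful of
matrix products (A'A, A'diag(y)A), which makes the exhaustive scan run in
matrix-multiplication time while remaining numerically identical to the
per-pair OLS t-test (the contract checked against the brute-force route).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import DOMINANT, GenotypeMatrix

_TINY = np.finfo(float).tiny


@dataclass
class PairTestResult:
    beta12: float
    se: float
    t: float
    p: float
    estimable: bool


def brute_force_pair_test(x1, x2, y) -> PairTestResult:
    """Single-pair interaction t-test by explicit OLS (the slow route).

    Fits the full interaction model with statsmodels and returns the
    two-sided p-value of the interaction coefficient on n - 4 df.  A
    rank-deficient design (e.g. a constant interaction column) or a
    degenerate residual yields a not-estimable result, never an exception.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x1) == len(x2) == len(y)):
        raise ValueError("x1, x2 and y must have equal lengths")
    if len(y) < 5:
        raise ValueError("need at least 5 observations (n - 4 df)")
    X = np.column_stack([np.ones_like(y), x1, x2, x1 * x2])
    if np.linalg.matrix_rank(X) < 4:
        return PairTestResult(np.nan, np.nan, np.nan, np.nan, False)
    fit = sm.OLS(y, X).fit()
    sst = float(np.sum((y - y.mean()) ** 2))
    if not np.isfinite(fit.bse[3]) or fit.ssr <= 1e-12 * max(sst, 1.0):
        return PairTestResult(float(fit.params[3]), np.nan, np.nan, np.nan, False)
    p = float(np.clip(fit.pvalues[3], _TINY, 1.0))
    return PairTestResult(float(fit.params[3]), float(fit.bse[3]),
                          float(fit.tvalues[3]), p, True)


def pair_interaction_scan(genotypes: GenotypeMatrix, trait,
                          alpha_filter: float | None = None,
                          chunk_pairs: int = 100_000) -> pd.DataFrame:
    """Interaction test for every unordered marker pair against one trait.

    Parameters
    ----------
    genotypes
        Dominant-coded genotype matrix with complete calls.
    trait
        Numeric response aligned to the individuals.
    alpha_filter
        If given, only rows with estimable p < ``alpha_filter`` are kept
        (bounds output size for genome-scale scans).
    chunk_pairs
        Pairs processed per block; results are identical regardless.

    Returns
    -------
    DataFrame with columns ``marker_i, marker_j, beta12, se, t, p,
    estimable``, one row per pair (i < j) unless filtered.
    """
    if genotypes.coding != DOMINANT:
        raise ValueError("pair_interaction_scan expects dominant-coded genotypes")
    A = np.asarray(genotypes.values, dtype=float)
    y = np.asarray(trait, dtype=float)
    n, M = A.shape
    if len(y) != n:
        raise ValueError("trait length does not match individual count")
    if not np.isfinite(A).all() or not np.isfinite(y).all():
        raise ValueError("scan requires complete genotype and trait data")

    cols = ["marker_i", "marker_j", "beta12", "se", "t", "p", "estimable"]
    if M < 2:
        return pd.DataFrame(columns=cols)

    na = A.sum(axis=0)                      # carriers per marker
    N11 = A.T @ A                           # joint carrier counts
    s1y = A.T @ y                           # per-marker carrier trait sums
    S11y = (A * y[:, None]).T @ A           # joint carrier trait sums
    sy = y.sum()
    syy = float(y @ y)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse_tol = 1e-12 * max(sst, 1.0)
    df = n - 4

    iu, ju = np.triu_indices(M, k=1)
    ids = genotypes.marker_ids.to_numpy()
    frames = []
    for start in range(0, len(iu), chunk_pairs):
        i = iu[start:start + chunk_pairs]
        j = ju[start:start + chunk_pairs]
        n11 = N11[i, j]
        n10 = na[i] - n11
        n01 = na[j] - n11
        n00 = n - na[i] - na[j] + n11
        s11 = S11y[i, j]
        s10 = s1y[i] - s11
        s01 = s1y[j] - s11
        s00 = sy - s1y[i] - s1y[j] + s11

        ok = (n00 > 0) & (n01 > 0) & (n10 > 0) & (n11 > 0) & (df > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta12 = s11 / n11 - s10 / n10 - s01 / n01 + s00 / n00
            fitted_ss = (s11 ** 2 / n11 + s10 ** 2 / n10
                         + s01 ** 2 / n01 + s00 ** 2 / n00)
            sse = syy - fitted_ss
            ok &= sse > sse_tol
            sigma2 = sse / df
            se = np.sqrt(sigma2 * (1.0 / n00 + 1.0 / n01 + 1.0 / n10 + 1.0 / n11))
            t = beta12 / se
        p = np.full(len(i), np.nan)
        p[ok] = np.clip(2.0 * stats.t.sf(np.abs(t[ok]), df), _TINY, 1.0)
        beta12[~ok] = np.nan
        se[~ok] = np.nan
        t[~ok] = np.nan

        block = pd.DataFrame({
            "marker_i": ids[i], "marker_j": ids[j],
            "beta12": beta12, "se": se, "t": t, "p": p, "estimable": ok,
        })
        if alpha_filter is not None:
            block = block[block["estimable"] & (block["p"] < alpha_filter)]
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def scan_all_traits(genotypes: GenotypeMatrix, traits,
                    alpha_filter: float | None = None,
                    chunk_pairs: int = 100_000) -> dict:
    """Run :func:`pair_interaction_scan` for each column of a trait frame."""
    traits = pd.DataFrame(traits)
    return {
        name: pair_interaction_scan(genotypes, traits[name].to_numpy(),
                                    alpha_filter=alpha_filter,
                                    chunk_pairs=chunk_pairs)
        for name in traits.columns
    }
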