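"""Permutation significance, FDR control and influence-network assembly.

The null distribution of the standardized influence statistics m/SE is
built by permuting the eigentrait rows jointly relative to the genotype
rows — breaking every genotype–trait association while preserving the
trait covariance — and re-running the pairwise scan and the delta/m
reparametrization.  Statistics from both influence directions are pooled
(they are exchangeable under permutation).  Empirical two-sided p-values
use the add-one rule, Benjamini–Hochberg controls the FDR across all
candidate directed edges, and surviving edges form a directed network in
which a positive influence coefficient is an *enhancing* interaction and
a negative one *suppressing* (less-than-additive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cape import PreparedPairScan, influence_batch

ENHANCING = "enhancing"
SUPPRESSING = "suppressing"


@dataclass
class NullDistribution:
    """Pooled standardized influence statistics from permuted cohorts."""

    values: np.ndarray
    n_permutations: int
    seed: int

    def __len__(self) -> int:
        return len(self.values)


def permutation_null(scan: PreparedPairScan, eigentraits: np.ndarray,
                     n_values: int, seed: int) -> NullDistribution:
    """Generate >= ``n_values`` null statistics by row permutation.

    Each permutation shuffles the ET score rows relative to the genotypes
    (which stay fixed, as do genotype-side covariates), refits every
    enumerated pair, and contributes the finite standardized statistics of
    both influence directions.  Whole permutation batches are collected,
    so the result holds between ``n_values`` and ``n_values`` plus one
    batch of values.  Deterministic under ``seed``.
    """
    if n_values < 1000:
        warnings.warn("fewer than 1000 null values gives unstable tail "
                      "estimates", stacklevel=2)
    Y = np.asarray(eigentraits, dtype=float)
    rng = np.random.default_rng(seed)
    collected: list = []
    total = 0
    n_perm = 0
    while total < n_values:
        perm = rng.permutation(Y.shape[0])
        beta, cov, ok = scan.fit(Y[perm])
        res = influence_batch(beta, cov, ok)
        vals = res["stat"].ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0 and n_perm > 10:
            raise RuntimeError("permutations produce no estimable statistics")
        collected.append(vals)
        total += vals.size
        n_perm += 1
    values = np.concatenate(collected) if collected else np.empty(0)
    return NullDistribution(values=values, n_permutations=n_perm, seed=seed)


def empirical_p(stat, null: NullDistribution) -> np.ndarray | float:
    """Two-sided empirical p-value(s) with the add-one correction.

    p = (1 + #{|null| >= |stat|}) / (N + 1); never zero, monotone
    non-increasing in |stat|, and p = 1 at stat = 0 (every |null| >= 0).
    """
    if len(null) == 0:
        raise ValueError("null distribution is empty")
    sorted_abs = np.sort(np.abs(null.values))
    n = len(sorted_abs)
    s = np.abs(np.asarray(stat, dtype=float))
    idx = np.searchsorted(sorted_abs, s, side="left")
    p = (1.0 + (n - idx)) / (n + 1.0)
    out = np.where(np.isfinite(s), p, np.nan)
    return float(out) if np.isscalar(stat) or out.ndim == 0 else out


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, in (0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Attach the enhancing/suppressing class from the sign of m."""
    edges = edges.copy()
    edges["class"] = np.where(edges["m"] > 0, ENHANCING, SUPPRESSING)
    return edges


def build_network(edges: pd.DataFrame, q_threshold: float = 0.05,
                  marker_meta: pd.DataFrame | None = None,
                  trait_effects: dict | None = None) -> nx.DiGraph:
    """Directed influence network of edges significant at q < threshold.

    ``edges`` holds one row per candidate directed edge with columns
    ``source, target, m, se, stat, p, q``.  Node attributes come from
    ``marker_meta`` (indexed by marker ID); ``trait_effects`` may map
    (source, target) to a per-trait effect mapping attached to the edge.
    The result is invariant to the input row order.
    """
    g = nx.DiGraph()
    if len(edges) == 0:
        return g
    q = pd.to_numeric(edges["q"], errors="coerce")
    sig = edges[np.isfinite(q) & (q < q_threshold)]
    sig = classify_edges(sig).sort_values(["source", "target"])
    for _, row in sig.iterrows():
        source, target = row["source"], row["target"]
        for node in (source, target):
            if node not in g:
                attrs = {}
                if marker_meta is not None and node in marker_meta.index:
                    attrs = {k: v for k, v in marker_meta.loc[node].items()
                             if pd.notna(v)}
                g.add_node(node, **attrs)
        attrs = {"m": float(row["m"]), "se": float(row["se"]),
                 "stat": float(row["stat"]), "p": float(row["p"]),
                 "q": float(row["q"]), "class": row["class"]}
        if trait_effects is not None:
            effects = trait_effects.get((source, target), {})
            for trait, value in effects.items():
                attrs[f"effect_{trait}"] = float(value)
        g.add_edge(source, target, **attrs)
    return g


@dataclass
class AdditivePrediction:
    """Observed two-locus group summaries vs the additive expectation.

    The additive prediction for the double-alternate group is the sum of
    the two main-effect coefficients of the interaction model (intercept
    subtracted from every term, i.e. measured relative to the
    double-reference group); its error band is the sum of the standard
    errors of the four genotype-group means.  A double-alternate group
    mean falling outside the band signals an interaction.
    """

    group_means: dict
    group_sems: dict
    group_counts: dict
    coefficients: np.ndarray      # (b0, b1, b2, b12)
    predicted_additive: float     # b1 + b2, relative to the reference group
    observed_double: float        # ybar_11 - b0
    error_band: float             # sum of the four group-mean SEs
    estimable: bool

    @property
    def within_band(self) -> bool:
        return bool(abs(self.observed_double - self.predicted_additive)
                    <= self.error_band)


def additive_prediction(trait, x1, x2) -> AdditivePrediction:
    """Compare the double-alternate genotype group with additivity.

    Fits ``y = b0 + b1 x1 + b2 x2 + b12 x1 x2`` on the raw trait and
    summarizes the four two-locus genotype groups (means, SEs, counts —
    the bar-plot ingredients).  Groups are keyed '00', '01', '10', '11'
    by (x1, x2).  Any empty group, or a group too small for a standard
    error, renders the comparison not estimable.
    """
    y = np.asarray(trait, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    means, sems, counts = {}, {}, {}
    ok = True
    for a in (0, 1):
        for b in (0, 1):
            key = f"{a}{b}"
            sel = (x1 == a) & (x2 == b)
            counts[key] = int(sel.sum())
            if counts[key] == 0:
                means[key] = np.nan
                sems[key] = np.nan
                ok = False
                continue
            means[key] = float(y[sel].mean())
            sems[key] = (float(y[sel].std(ddof=1) / np.sqrt(counts[key]))
                         if counts[key] > 1 else np.nan)
            ok &= counts[key] > 1
    if not ok:
        return AdditivePrediction(means, sems, counts,
                                  np.full(4, np.nan), np.nan, np.nan,
                                  np.nan, False)
    X = np.column_stack([np.ones_like(y), x1, x2, x1 * x2])
    coef = sm.OLS(y, X).fit().params
    predicted = float(coef[1] + coef[2])
    observed = float(means["11"] - coef[0])
    band = float(sum(sems.values()))
    return AdditivePrediction(means, sems, counts, np.asarray(coef),
                              predicted, observed, band, True)


def export_network(graph: nx.DiGraph, edge_tsv=None, graphml=None) -> None:
    """Write the influence network as an edge-list TSV and/or GraphML.

    GraphML preserves all node and edge attributes and re-imports
    losslessly via :func:`import_network`; the TSV uses pandas quoting so
    attribute values containing tabs survive a round trip.
    """
    if edge_tsv is not None:
        rows = [{"source": u, "target": v, **d}
                for u, v, d in graph.edges(data=True)]
        cols = ["source", "target", "m", "se", "stat", "p", "q", "class"]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = pd.Series(dtype=float)
        extra = [c for c in df.columns if c not in cols]
        df[cols + extra].to_csv(edge_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(graph, graphml)


def import_network(graphml) -> nx.DiGraph:
    return nx.read_graphml(graphml)
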