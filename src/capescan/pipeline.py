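"""End-to-end influence analysis: traits -> eigentraits -> directed network.

``run_cape`` glues the stages together the way the full study design runs
them: rank-Z normalization of quantitative traits, eigentrait
decomposition, LD-aware pair enumeration over candidate markers plus the
sex pseudo-marker, pairwise regressions on the two leading eigentraits,
the delta/m reparametrization with Taylor standard errors, a permutation
null for the standardized statistics, empirical p-values, BH FDR, and
network assembly with back-rotated trait-space interaction effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import cape, significance
from .data import DOSAGE, GenotypeMatrix, TraitTable
from .eigentraits import EigentraitDecomposition, back_rotate, decompose_traits, \
    select_eigentraits
from .preprocess import dominant_code, rank_z
from .significance import NullDistribution


@dataclass
class CapeResult:
    """Everything the pipeline computed, plus stage counts for reporting."""

    decomposition: EigentraitDecomposition
    enumeration: cape.PairEnumeration
    edges: pd.DataFrame              # one row per candidate directed edge
    null: NullDistribution
    network: nx.DiGraph
    singlescan: pd.DataFrame
    counts: dict = field(default_factory=dict)


def run_cape(genotypes: GenotypeMatrix, traits: TraitTable,
             candidates=None, *, use_sex: bool = True,
             n_eigentraits: int = 2, ld_max: float = 0.5,
             n_perm_values: int = 100_000, q_threshold: float = 0.05,
             rank_z_quantitative: bool = True, seed: int = 0) -> CapeResult:
    """Run the combined pleiotropy/epistasis analysis on one cohort.

    Parameters
    ----------
    genotypes
        Dosage or dominant-coded genotypes; dosages are dominant-coded.
    traits
        Trait table; quantitative traits are rank-Z normalized before the
        eigentrait decomposition unless ``rank_z_quantitative`` is False.
    candidates
        Marker IDs to test pairwise (default: all markers).
    use_sex
        Include the 0/1 sex covariate as a pseudo-marker in the pair pool
        and as an additive covariate in every model it is not a member of.
    n_perm_values
        Minimum size of the pooled permutation null.
    seed
        Drives the permutation stream.

    Returns a :class:`CapeResult`; ``result.network`` holds the directed
    edges significant at BH q < ``q_threshold``.
    """
    if genotypes.coding == DOSAGE:
        genotypes = dominant_code(genotypes)
    if candidates is None:
        candidates = list(genotypes.marker_ids)
    else:
        candidates = [m for m in candidates]

    values = traits.values.copy()
    if rank_z_quantitative:
        for t in traits.quantitative_traits():
            values[t] = rank_z(values[t].to_numpy())
    decomposition = decompose_traits(values)
    ets, cumvar = select_eigentraits(decomposition, n_eigentraits)

    covariates = traits.covariates[["sex"]] if (
        use_sex and "sex" in traits.covariates.columns) else None
    enumeration = cape.enumerate_pairs(candidates, genotypes,
                                       covariates=covariates, ld_max=ld_max)
    scan = cape.PreparedPairScan(enumeration)
    beta, cov, ok = scan.fit(ets)
    res = cape.influence_batch(beta, cov, ok)

    single = cape.singlescan(enumeration.frame, ets)

    null = significance.permutation_null(scan, ets, n_values=n_perm_values,
                                         seed=seed)

    pair_ids = enumeration.pair_ids
    rows = []
    trait_effects = {}
    for p_idx, (a, b) in enumerate(pair_ids):
        for d, (src, tgt) in enumerate(((a, b), (b, a))):
            rows.append({
                "source": src, "target": tgt,
                "m": res["m"][p_idx, d], "se": res["se"][p_idx, d],
                "stat": res["stat"][p_idx, d],
                "delta": res["delta"][p_idx, d],
            })
        if ok[p_idx]:
            effects = back_rotate(beta[p_idx, :, 3], decomposition)
            trait_effects[(a, b)] = effects.to_dict()
            trait_effects[(b, a)] = effects.to_dict()
    edges = pd.DataFrame(rows)
    finite = np.isfinite(edges["stat"].to_numpy())
    pvals = np.full(len(edges), np.nan)
    if finite.any():
        pvals[finite] = significance.empirical_p(
            edges.loc[finite, "stat"].to_numpy(), null)
    edges["p"] = pvals
    qvals = np.full(len(edges), np.nan)
    if finite.any():
        qvals[finite] = significance.fdr_adjust(pvals[finite])
    edges["q"] = qvals

    network = significance.build_network(
        edges, q_threshold=q_threshold, marker_meta=genotypes.marker_meta,
        trait_effects=trait_effects)

    counts = {
        "n_individuals": genotypes.n_individuals,
        "n_candidates": len(candidates),
        "n_covariates": 0 if covariates is None else covariates.shape[1],
        "n_pairs_possible": enumeration.n_possible,
        "n_pairs_excluded_ld": enumeration.n_excluded_ld,
        "n_pairs_tested": scan.n_pairs,
        "n_pairs_estimable": int(ok.sum()),
        "n_null_values": len(null),
        "n_permutations": null.n_permutations,
        "top_et_cumulative_variance_pct": cumvar,
        "n_edges_significant": network.number_of_edges(),
        "q_threshold": q_threshold,
        "seed": seed,
    }
    return CapeResult(decomposition=decomposition, enumeration=enumeration,
                      edges=edges, null=null, network=network,
                      singlescan=single, counts=counts)
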