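"""Iterative selection of epistatic, pleiotropic candidate markers.

Genome-wide interaction scans produce far more markers than a pairwise
influence analysis can afford, so the marker set is reduced to the K
markers most likely to participate in interactions affecting more than
one trait:

Stage 1 ("multi-trait-pair"): every pair that interacts significantly for
more than one trait contributes both of its members.

Stage 2 ("t-trait-SNP", t descending from the number of traits to 2):
individual markers whose significant interactions — with any partners —
span exactly t distinct traits are added.  A partner that supports such a
marker but is itself single-trait is *not* added on that basis (if marker
1 interacts with marker 2 for one trait and with marker 3 for another,
marker 1 is kept while markers 2 and 3 are discarded).

Within a stage markers are ranked by their best supporting p-value
(ascending), ties broken lexicographically by marker ID; selection stops
once K markers are collected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGE_PAIR = "multi-trait-pair"


@dataclass
class CandidateSet:
    """Ordered candidate markers with per-marker selection provenance."""

    markers: list
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: long-format supporting records (marker, partner, trait, p)
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)


def significant_pairs(scans: dict, alpha: float = 1e-6) -> dict:
    """Per-trait sets of significantly interacting pairs.

    ``scans`` maps trait name to a pair-scan result frame (columns
    ``marker_i, marker_j, p, estimable``).  Returns trait ->  DataFrame of
    the rows with estimable p < alpha (possibly empty).
    """
    out = {}
    for trait, df in scans.items():
        keep = df[df["estimable"] & (df["p"] < alpha)]
        out[trait] = keep[["marker_i", "marker_j", "p"]].reset_index(drop=True)
    return out


def select_candidates(sig_pairs: dict, k: int) -> CandidateSet:
    """Reduce per-trait significant pairs to at most ``k`` candidate markers.

    ``sig_pairs`` is the output of :func:`significant_pairs`.  Selection is
    deterministic: stage-1 pairs are ranked by their best p across traits,
    stage-2 markers by best supporting p then marker ID, and the result is
    invariant to the input ordering of pairs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    records = []
    for trait, df in sig_pairs.items():
        for row in df.itertuples(index=False):
            a, b = sorted((str(row.marker_i), str(row.marker_j)))
            records.append((a, b, trait, float(row.p)))
    rec = pd.DataFrame(records, columns=["marker_a", "marker_b", "trait", "p"])

    long_rows = []
    for row in rec.itertuples(index=False):
        long_rows.append((row.marker_a, row.marker_b, row.trait, row.p))
        long_rows.append((row.marker_b, row.marker_a, row.trait, row.p))
    long = pd.DataFrame(long_rows, columns=["marker", "partner", "trait", "p"])

    selected: list = []
    prov_rows = []

    def add(marker: str, stage: str, best_p: float, n_traits: int) -> bool:
        if marker in set(selected):
            return len(selected) < k
        selected.append(marker)
        prov_rows.append({"marker": marker, "stage": stage,
                          "best_p": best_p, "n_traits": n_traits})
        return len(selected) < k

    room = True
    if len(rec):
        # Stage 1: pairs significant for more than one trait
        grouped = rec.groupby(["marker_a", "marker_b"]).agg(
            n_traits=("trait", "nunique"), best_p=("p", "min"))
        multi = grouped[grouped["n_traits"] > 1].sort_values(
            ["best_p", "marker_a", "marker_b"])
        for (a, b), row in multi.iterrows():
            if not room:
                break
            room = add(a, STAGE_PAIR, float(row["best_p"]), int(row["n_traits"]))
            if room:
                room = add(b, STAGE_PAIR, float(row["best_p"]), int(row["n_traits"]))

        # Stage 2: single markers whose interactions span t traits, t descending
        per_marker = long.groupby("marker").agg(
            n_traits=("trait", "nunique"), best_p=("p", "min"))
        n_traits_total = max(len(sig_pairs), 2)
        for t in range(n_traits_total, 1, -1):
            if not room:
                break
            tier = (per_marker[per_marker["n_traits"] == t]
                    .reset_index()
                    .sort_values(["best_p", "marker"]))
            for row in tier.itertuples(index=False):
                if not room:
                    break
                room = add(row.marker, f"{t}-trait-SNP", float(row.best_p),
                           int(row.n_traits))

    if len(selected) < k:
        warnings.warn(
            f"only {len(selected)} markers qualify as epistatic and "
            f"pleiotropic (requested {k})", stacklevel=2)
    provenance = pd.DataFrame(prov_rows,
                              columns=["marker", "stage", "best_p", "n_traits"])
    support = long[long["marker"].isin(selected)].reset_index(drop=True)
    return CandidateSet(markers=selected, provenance=provenance, records=support)
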