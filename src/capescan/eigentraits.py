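"""Eigentrait decomposition of a multi-trait table.

Traits that share underlying biology are combined by singular value
decomposition of the column-standardized trait matrix,

    Y_std = U * diag(S) * V',

whose orthogonal left factors define composite "eigentraits" (ETs) that
concentrate shared trait variance.  Mapping on a leading subset of ETs
and rotating effect estimates back through V recovers per-trait effects
for all traits simultaneously.

Conventions fixed here:

* every trait column — binary traits included — is mean-centered and
  scaled to unit sample SD before the SVD;
* the sign ambiguity of each singular pair is resolved by flipping so the
  largest-magnitude trait loading in each V column is positive;
* regressions use the variance-weighted scores U * diag(S), so that
  back-rotation is simply V @ effects and equals the direct trait-space
  regression coefficients when all ETs are selected.  The delta/m
  influence parameters downstream are invariant to any per-ET rescaling,
  so this choice only affects back-rotation bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TraitTable


@dataclass
class EigentraitDecomposition:
    """SVD factors of the standardized trait matrix plus bookkeeping."""

    u: np.ndarray                # individuals x r, orthonormal columns
    s: np.ndarray                # singular values, descending
    v: np.ndarray                # traits x r loadings, orthonormal columns
    trait_names: list
    individual_ids: pd.Index
    center: np.ndarray
    scale: np.ndarray

    @property
    def n_eigentraits(self) -> int:
        return len(self.s)

    @property
    def variance_explained(self) -> np.ndarray:
        """Percent of standardized trait variance captured by each ET."""
        s2 = self.s ** 2
        return 100.0 * s2 / s2.sum()

    def standardized_traits(self) -> np.ndarray:
        return self.u @ np.diag(self.s) @ self.v.T

    def scores(self, n: int | None = None) -> np.ndarray:
        """Variance-weighted ET scores U * diag(S) for the leading ``n`` ETs."""
        n = self.n_eigentraits if n is None else n
        return self.u[:, :n] * self.s[None, :n]


def decompose_traits(traits: TraitTable | pd.DataFrame) -> EigentraitDecomposition:
    """Standardize the trait columns and decompose them by SVD.

    Requires complete cases (rows with any missing trait are dropped) and
    at least two traits; a constant trait column is rejected because it
    cannot be scaled to unit variance.
    """
    values = traits.values if isinstance(traits, TraitTable) else pd.DataFrame(traits)
    values = values.dropna(axis=0, how="any")
    if values.shape[1] < 2:
        raise ValueError("eigentrait decomposition needs at least 2 traits")
    if values.shape[0] < values.shape[1]:
        raise ValueError("need at least as many complete cases as traits")
    Y = values.to_numpy(dtype=float)
    center = Y.mean(axis=0)
    scale = Y.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = values.columns[np.flatnonzero(scale == 0)[0]]
        raise ValueError(f"trait {bad!r} is constant and cannot be standardized")
    Y_std = (Y - center) / scale
    u, s, vt = np.linalg.svd(Y_std, full_matrices=False)
    v = vt.T
    # deterministic orientation: largest-|loading| entry of each V column > 0
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
            u[:, j] = -u[:, j]
    return EigentraitDecomposition(
        u=u, s=s, v=v, trait_names=list(values.columns),
        individual_ids=values.index, center=center, scale=scale)


def select_eigentraits(decomposition: EigentraitDecomposition, n_ets: int
                       ) -> tuple[np.ndarray, float]:
    """Leading ``n_ets`` ET score columns and their cumulative variance (%)."""
    r = decomposition.n_eigentraits
    if not 1 <= n_ets <= r:
        raise ValueError(f"n_ets must lie in [1, {r}]")
    cumvar = float(decomposition.variance_explained[:n_ets].sum())
    return decomposition.scores(n_ets), cumvar


def back_rotate(effects, decomposition: EigentraitDecomposition) -> pd.Series:
    """Rotate per-ET effect estimates back to trait space.

    ``effects`` is indexed by the leading selected ETs; the trait-space
    effect for trait k is sum_j effects[j] * V[k, j].  Linear in its
    input; with all ETs selected this is the exact inverse of projecting
    trait-space coefficients onto the ET basis.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.ndim != 1 or not 1 <= len(effects) <= decomposition.n_eigentraits:
        raise ValueError("effects must be a vector over the leading selected ETs")
    rotated = decomposition.v[:, :len(effects)] @ effects
    return pd.Series(rotated, index=decomposition.trait_names)


def save_decomposition(decomposition: EigentraitDecomposition,
                       directory: str | Path) -> Path:
    """Persist loadings, singular values and the variance table (TSV + JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(decomposition.v, index=decomposition.trait_names,
                 columns=[f"ET{j+1}" for j in range(decomposition.n_eigentraits)]
                 ).to_csv(directory / "loadings.tsv", sep="\t")
    pd.DataFrame(decomposition.u, index=decomposition.individual_ids,
                 columns=[f"ET{j+1}" for j in range(decomposition.n_eigentraits)]
                 ).to_csv(directory / "scores.tsv", sep="\t")
    meta = {
        "singular_values": decomposition.s.tolist(),
        "variance_explained_pct": decomposition.variance_explained.tolist(),
        "trait_names": list(decomposition.trait_names),
        "center": decomposition.center.tolist(),
        "scale": decomposition.scale.tolist(),
    }
    (directory / "eigentraits.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_decomposition(directory: str | Path) -> EigentraitDecomposition:
    directory = Path(directory)
    meta = json.loads((directory / "eigentraits.json").read_text())
    v = pd.read_csv(directory / "loadings.tsv", sep="\t", index_col=0)
    u = pd.read_csv(directory / "scores.tsv", sep="\t", index_col=0)
    return EigentraitDecomposition(
        u=u.to_numpy(dtype=float), s=np.asarray(meta["singular_values"]),
        v=v.to_numpy(dtype=float), trait_names=meta["trait_names"],
        individual_ids=u.index, center=np.asarray(meta["center"]),
        scale=np.asarray(meta["scale"]))
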