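"""Directional influence inference from pairwise regressions on eigentraits.

For each marker pair the full interaction model is fitted per eigentrait,

    ET_j = b0 + b1*x1 + b2*x2 + b12*x1*x2 + (covariates) + e,

and the coefficients across the two analyzed ETs are recast into the
combined-pleiotropy-and-epistasis parameters.  Writing the 2x2 main-effect
matrix M with rows indexed by ET and columns by marker,

    [delta1, delta2]' = M^-1 [b12_ET1, b12_ET2]',

the deltas measure how much the presence of one marker modulates the
phenotypic effects of the other.  They are translated into directional
influence coefficients through the coupled system

    delta1 = m12 * (1 + delta2),   delta2 = m21 * (1 + delta1),

solved in closed form as m12 = delta1/(1+delta2), m21 = delta2/(1+delta1).
Standard errors of m12/m21 are obtained by propagating the per-ET OLS
coefficient covariances through the composite map beta -> delta -> m with
a second-order multivariate Taylor expansion (gradient term plus the
half-trace curvature correction); the two ET regressions are treated as
independent blocks, justified by ET orthogonality.

Pairs of markers in linkage disequilibrium (dominant-genotype Pearson
|r| above a cutoff, 0.5 by default) are excluded at enumeration time.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .data import DOMINANT, GenotypeMatrix

#: relative tolerance for declaring the main-effect matrix singular
SINGULAR_RTOL = 1e-10
#: finite-difference step scale for the Taylor expansion
_FD_REL = 1e-4


# ---------------------------------------------------------------------------
# pair enumeration

@dataclass
class PairEnumeration:
    """All unordered pairs over candidates + covariate pseudo-markers."""

    frame: pd.DataFrame          # individuals x (candidates + covariates)
    pairs: np.ndarray            # (P, 2) column indices into frame
    covariate_columns: list      # names treated as covariate pseudo-markers
    n_possible: int
    n_excluded_ld: int

    @property
    def pair_ids(self) -> list:
        cols = self.frame.columns
        return [(cols[i], cols[j]) for i, j in self.pairs]


def enumerate_pairs(candidates, genotypes: GenotypeMatrix,
                    covariates: pd.DataFrame | None = None,
                    ld_max: float = 0.5) -> PairEnumeration:
    """Enumerate testable pairs, excluding those in linkage disequilibrium.

    Parameters
    ----------
    candidates
        Candidate marker IDs (a ``CandidateSet`` or any iterable).
    genotypes
        Dominant-coded genotype matrix containing the candidates.
    covariates
        Optional binary covariate columns (e.g. sex) entering the pair
        pool as pseudo-markers.
    ld_max
        Pairs whose dominant-genotype Pearson ``|r|`` exceeds this cutoff
        are dropped.

    The number of possible pairs before exclusion is C(K + c, 2) for K
    candidates and c covariates.
    """
    if genotypes.coding != DOMINANT:
        raise ValueError("enumerate_pairs expects dominant-coded genotypes")
    ids = [m for m in candidates]
    frame = genotypes.to_frame()[ids].astype(float)
    cov_cols: list = []
    if covariates is not None:
        covariates = pd.DataFrame(covariates)
        for c in covariates.columns:
            if not covariates[c].dropna().isin([0, 1]).all():
                raise ValueError(f"covariate {c!r} must be binary 0/1")
            frame[c] = covariates[c].to_numpy(dtype=float)
            cov_cols.append(c)
    X = frame.to_numpy()
    m = X.shape[1]
    n_possible = comb(m, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False) if m > 1 else np.ones((m, m))
    r = np.nan_to_num(r, nan=0.0)  # constant columns: no LD evidence
    iu, ju = np.triu_indices(m, k=1)
    keep = np.abs(r[iu, ju]) <= ld_max
    pairs = np.column_stack([iu[keep], ju[keep]])
    return PairEnumeration(frame=frame, pairs=pairs,
                           covariate_columns=cov_cols,
                           n_possible=n_possible,
                           n_excluded_ld=int((~keep).sum()))


# ---------------------------------------------------------------------------
# regressions

@dataclass
class PairScanFit:
    """Per-ET interaction-model coefficients for one marker pair.

    ``beta`` has one row per ET holding (b0, b1, b2, b12); ``cov`` holds
    the matching 4x4 OLS coefficient covariance per ET.  Index 1 is the
    main effect of ``marker1``, index 2 of ``marker2``, index 3 the
    interaction.
    """

    marker1: str
    marker2: str
    beta: np.ndarray             # (n_et, 4)
    cov: np.ndarray              # (n_et, 4, 4)
    n: int
    estimable: bool


@dataclass
class DeltaPair:
    delta1: float
    delta2: float
    cov: np.ndarray              # 2x2 first-order covariance
    estimable: bool


@dataclass
class InfluenceCoefficients:
    m12: float
    m21: float
    se12: float = np.nan
    se21: float = np.nan

    @property
    def stat12(self) -> float:
        return self.m12 / self.se12

    @property
    def stat21(self) -> float:
        return self.m21 / self.se21


def _design_groups(pairs: np.ndarray, cov_idx: list) -> list:
    """Partition pairs by which covariate columns are members of the pair."""
    cov_set = set(cov_idx)
    keyed: dict = {}
    for row, (i, j) in enumerate(pairs):
        key = tuple(sorted(cov_set & {int(i), int(j)}))
        keyed.setdefault(key, []).append(row)
    return [(key, np.asarray(rows)) for key, rows in keyed.items()]


class PreparedPairScan:
    """Batched OLS of responses on every enumerated pair's design.

    The designs, their Gram inverses and the estimability masks depend
    only on the genotypes, so they are computed once; :meth:`fit` then
    refits arbitrary response matrices (observed or permuted eigentraits)
    cheaply.  Used both for the observed scan and inside the permutation
    null.
    """

    def __init__(self, enumeration: PairEnumeration):
        X = enumeration.frame.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("pair scan requires complete genotype data")
        self.n = X.shape[0]
        self.pairs = enumeration.pairs
        cov_idx = [enumeration.frame.columns.get_loc(c)
                   for c in enumeration.covariate_columns]
        self._groups = []
        for key, rows in _design_groups(self.pairs, cov_idx):
            extra = [c for c in cov_idx if c not in key]
            p1 = self.pairs[rows, 0]
            p2 = self.pairs[rows, 1]
            k = 4 + len(extra)
            D = np.empty((len(rows), self.n, k))
            D[:, :, 0] = 1.0
            D[:, :, 1] = X[:, p1].T
            D[:, :, 2] = X[:, p2].T
            D[:, :, 3] = (X[:, p1] * X[:, p2]).T
            for a, c in enumerate(extra):
                D[:, :, 4 + a] = X[None, :, c]
            XtX = np.einsum("pnk,pnl->pkl", D, D)
            # estimable: df > 0 and all four two-locus cells populated and
            # a numerically nonsingular Gram matrix
            x1, x2 = X[:, p1].T, X[:, p2].T
            cells = np.stack([
                ((1 - x1) * (1 - x2)).sum(1), ((1 - x1) * x2).sum(1),
                (x1 * (1 - x2)).sum(1), (x1 * x2).sum(1)])
            ok = (cells > 0).all(axis=0) & (self.n - k >= 1)
            eig = np.linalg.eigvalsh(XtX)
            ok &= eig[:, 0] > 1e-9 * np.maximum(eig[:, -1], 1.0)
            XtX_safe = np.where(ok[:, None, None], XtX,
                                np.eye(k)[None, :, :])
            self._groups.append({
                "rows": rows, "D": D, "k": k,
                "XtX_inv": np.linalg.inv(XtX_safe), "ok": ok,
            })

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def fit(self, responses: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """OLS of each response column on each pair design.

        Returns ``beta`` (pairs, responses, 4), ``cov`` (pairs, responses,
        4, 4) — both restricted to the (intercept, main1, main2,
        interaction) terms — and the per-pair estimability mask.
        """
        Y = np.asarray(responses, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != self.n:
            raise ValueError("response rows must match individual count")
        q = Y.shape[1]
        P = self.n_pairs
        beta = np.full((P, q, 4), np.nan)
        cov = np.full((P, q, 4, 4), np.nan)
        estimable = np.zeros(P, dtype=bool)
        for g in self._groups:
            D, XtX_inv, rows, k = g["D"], g["XtX_inv"], g["rows"], g["k"]
            XtY = np.einsum("pnk,nq->pkq", D, Y)
            B = XtX_inv @ XtY                       # (p, k, q)
            resid = Y[None, :, :] - np.einsum("pnk,pkq->pnq", D, B)
            sse = np.einsum("pnq,pnq->pq", resid, resid)
            sigma2 = sse / (self.n - k)
            C = XtX_inv[:, None, :, :] * sigma2[:, :, None, None]  # (p,q,k,k)
            beta[rows] = np.transpose(B, (0, 2, 1))[:, :, :4]
            cov[rows] = C[:, :, :4, :4]
            estimable[rows] = g["ok"]
        return beta, cov, estimable


def pairscan(x1, x2, responses, covariates=None,
             markers: tuple = ("marker1", "marker2")) -> PairScanFit:
    """Fit the pairwise interaction model for one pair of binary markers.

    ``responses`` is the (n x n_et) eigentrait score matrix; additional
    additive covariate columns may be supplied (the caller drops a
    covariate from this list when it is itself a member of the pair).
    """
    frame = pd.DataFrame({markers[0]: np.asarray(x1, dtype=float),
                          markers[1]: np.asarray(x2, dtype=float)})
    cov_cols = []
    if covariates is not None:
        covariates = pd.DataFrame(covariates)
        for c in covariates.columns:
            frame[c] = covariates[c].to_numpy(dtype=float)
            cov_cols.append(c)
    enum = PairEnumeration(frame=frame, pairs=np.array([[0, 1]]),
                           covariate_columns=cov_cols,
                           n_possible=1, n_excluded_ld=0)
    beta, cov, ok = PreparedPairScan(enum).fit(responses)
    return PairScanFit(marker1=markers[0], marker2=markers[1],
                       beta=beta[0], cov=cov[0], n=frame.shape[0],
                       estimable=bool(ok[0]))


def singlescan(genotypes, responses, covariates=None) -> pd.DataFrame:
    """Single-marker OLS of each response on each marker (plus covariates).

    A covariate column listed among the markers (e.g. sex as a
    pseudo-marker) is not entered twice.  Returns a tidy frame with one
    row per (marker, response).
    """
    X = genotypes.to_frame() if isinstance(genotypes, GenotypeMatrix) \
        else pd.DataFrame(genotypes)
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    resp_names = [f"ET{j+1}" for j in range(Y.shape[1])]
    covariates = pd.DataFrame(covariates) if covariates is not None else None
    rows = []
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        cols = [np.ones_like(x), x]
        if covariates is not None:
            cols += [covariates[c].to_numpy(dtype=float)
                     for c in covariates.columns if c != name]
        D = np.column_stack(cols)
        k = D.shape[1]
        ok = (np.ptp(x) > 0 and len(x) - k >= 1
              and np.linalg.matrix_rank(D) == k)
        if not ok:
            for rn in resp_names:
                rows.append({"marker": name, "response": rn, "beta": np.nan,
                             "se": np.nan, "t": np.nan, "p": np.nan,
                             "estimable": False})
            continue
        XtX_inv = np.linalg.inv(D.T @ D)
        B = XtX_inv @ (D.T @ Y)
        resid = Y - D @ B
        sigma2 = (resid ** 2).sum(axis=0) / (len(x) - k)
        se = np.sqrt(XtX_inv[1, 1] * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = B[1] / se
        p = 2.0 * stats.t.sf(np.abs(t), len(x) - k)
        for j, rn in enumerate(resp_names):
            rows.append({"marker": name, "response": rn,
                         "beta": float(B[1, j]), "se": float(se[j]),
                         "t": float(t[j]),
                         "p": float(np.clip(p[j], np.finfo(float).tiny, 1.0)),
                         "estimable": bool(np.isfinite(t[j]))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delta / m reparametrization (vectorized over leading dimensions)

def _theta_from_fit(beta: np.ndarray) -> np.ndarray:
    """(…, 2 ETs, 4 coefs) -> (…, 6) parameter vector
    (b1_ET1, b2_ET1, b12_ET1, b1_ET2, b2_ET2, b12_ET2)."""
    return np.concatenate([beta[..., 0, 1:4], beta[..., 1, 1:4]], axis=-1)


def _sigma_from_fit(cov: np.ndarray) -> np.ndarray:
    """Block-diagonal 6x6 covariance (cross-ET blocks zero)."""
    out = np.zeros(cov.shape[:-3] + (6, 6))
    out[..., :3, :3] = cov[..., 0, 1:4, 1:4]
    out[..., 3:, 3:] = cov[..., 1, 1:4, 1:4]
    return out


def _deltas_from_theta(theta: np.ndarray) -> np.ndarray:
    """Solve M [d1 d2]' = [b12_ET1 b12_ET2]' with M rows = ETs, cols = markers.

    Singular systems (|det| below SINGULAR_RTOL x ||M||_F^2) yield NaN.
    """
    b1_1, b2_1, b12_1 = theta[..., 0], theta[..., 1], theta[..., 2]
    b1_2, b2_2, b12_2 = theta[..., 3], theta[..., 4], theta[..., 5]
    det = b1_1 * b2_2 - b2_1 * b1_2
    scale = b1_1 ** 2 + b2_1 ** 2 + b1_2 ** 2 + b2_2 ** 2
    bad = np.abs(det) <= SINGULAR_RTOL * np.maximum(scale, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = (b2_2 * b12_1 - b2_1 * b12_2) / det
        d2 = (b1_1 * b12_2 - b1_2 * b12_1) / det
    out = np.stack([d1, d2], axis=-1)
    out[bad] = np.nan
    return out


def _m_from_deltas(deltas: np.ndarray) -> np.ndarray:
    """m12 = d1/(1+d2), m21 = d2/(1+d1); near-zero denominators yield NaN."""
    d1, d2 = deltas[..., 0], deltas[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m12 = np.where(np.abs(1 + d2) > SINGULAR_RTOL, d1 / (1 + d2), np.nan)
        m21 = np.where(np.abs(1 + d1) > SINGULAR_RTOL, d2 / (1 + d1), np.nan)
    return np.stack([m12, m21], axis=-1)


def _m_from_theta(theta: np.ndarray) -> np.ndarray:
    return _m_from_deltas(_deltas_from_theta(theta))


def _fd_steps(theta: np.ndarray) -> np.ndarray:
    return _FD_REL * np.maximum(np.abs(theta), 0.1)


def _gradient_hessian(func, theta: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient and Hessian of a (…,6)->(…,2) map.

    All stencil points are evaluated in one vectorized call.  Returns
    gradient (…, 2, 6) and Hessian (…, 2, 6, 6).
    """
    h = _fd_steps(theta)
    points = [theta]
    for k in range(6):
        for sgn in (+1, -1):
            t = theta.copy()
            t[..., k] += sgn * h[..., k]
            points.append(t)
    off = list(combinations(range(6), 2))
    for k, l in off:
        for sk, sl in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            t = theta.copy()
            t[..., k] += sk * h[..., k]
            t[..., l] += sl * h[..., l]
            points.append(t)
    vals = func(np.stack(points, axis=0))        # (S, ..., 2)
    f0 = vals[0]
    plus = vals[1:13:2]
    minus = vals[2:13:2]
    grad = np.stack([(plus[k] - minus[k]) / (2 * h[..., k, None])
                     for k in range(6)], axis=-1)            # (..., 2, 6)
    hess = np.zeros(theta.shape[:-1] + (2, 6, 6))
    for k in range(6):
        hess[..., k, k] = (plus[k] + minus[k] - 2 * f0) / (h[..., k, None] ** 2)
    idx = 13
    for (k, l) in off:
        fpp, fpm, fmp, fmm = vals[idx], vals[idx + 1], vals[idx + 2], vals[idx + 3]
        idx += 4
        mixed = (fpp - fpm - fmp + fmm) / (4 * h[..., k, None] * h[..., l, None])
        hess[..., k, l] = mixed
        hess[..., l, k] = mixed
    return grad, hess


def influence_batch(beta: np.ndarray, cov: np.ndarray,
                    estimable: np.ndarray) -> dict:
    """Delta/m reparametrization with Taylor SEs for a batch of pair fits.

    Parameters are the outputs of :meth:`PreparedPairScan.fit` restricted
    to the two analyzed ETs.  Returns arrays ``delta`` (P, 2),
    ``delta_cov`` (P, 2, 2), ``m`` (P, 2), ``se`` (P, 2) and ``stat``
    (P, 2) with NaN wherever a pair is not estimable or singular.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[-2] != 2:
        raise ValueError("influence inference requires exactly 2 eigentraits")
    theta = _theta_from_fit(beta)
    sigma = _sigma_from_fit(np.asarray(cov, dtype=float))
    mask = np.asarray(estimable, dtype=bool) & np.isfinite(theta).all(axis=-1)
    theta_safe = np.where(mask[..., None], theta, 1.0)

    deltas = _deltas_from_theta(theta_safe)
    m = _m_from_deltas(deltas)

    grad_d, _ = _gradient_hessian(_deltas_from_theta, theta_safe)
    delta_cov = np.einsum("...ik,...kl,...jl->...ij", grad_d, sigma, grad_d)

    grad_m, hess_m = _gradient_hessian(_m_from_theta, theta_safe)
    var_lin = np.einsum("...ik,...kl,...il->...i", grad_m, sigma, grad_m)
    hs = np.einsum("...ikl,...lm->...ikm", hess_m, sigma)
    var_quad = 0.5 * np.einsum("...ikm,...imk->...i", hs, hs)
    var = var_lin + var_quad
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = m / se

    for arr in (deltas, m, se, stat):
        arr[~mask] = np.nan
    delta_cov[~mask] = np.nan
    return {"delta": deltas, "delta_cov": delta_cov, "m": m, "se": se,
            "stat": stat}


# ---------------------------------------------------------------------------
# scalar convenience wrappers (single pair)

def solve_deltas(fit: PairScanFit) -> DeltaPair:
    """Delta parameters for one pair fit over the two analyzed ETs."""
    if not fit.estimable:
        return DeltaPair(np.nan, np.nan, np.full((2, 2), np.nan), False)
    _check_psd(fit.cov)
    res = influence_batch(fit.beta[None], fit.cov[None],
                          np.array([fit.estimable]))
    d = res["delta"][0]
    ok = bool(np.isfinite(d).all())
    return DeltaPair(float(d[0]), float(d[1]), res["delta_cov"][0], ok)


def compute_m(deltas: DeltaPair) -> InfluenceCoefficients:
    """Directional influence coefficients from the delta parameters."""
    if not deltas.estimable:
        return InfluenceCoefficients(np.nan, np.nan)
    m = _m_from_deltas(np.array([deltas.delta1, deltas.delta2]))
    return InfluenceCoefficients(float(m[0]), float(m[1]))


def _check_psd(cov: np.ndarray) -> None:
    c = np.asarray(cov, dtype=float)
    for block in c.reshape(-1, c.shape[-2], c.shape[-1]):
        eig = np.linalg.eigvalsh((block + block.T) / 2)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("coefficient covariance is not positive semidefinite")


def propagate_errors(fit: PairScanFit, deltas: DeltaPair
                     ) -> tuple[float, float]:
    """Second-order Taylor standard errors of (m12, m21) for one pair."""
    if not (fit.estimable and deltas.estimable):
        return (np.nan, np.nan)
    _check_psd(fit.cov)
    res = influence_batch(fit.beta[None], fit.cov[None],
                          np.array([True]))
    return float(res["se"][0, 0]), float(res["se"][0, 1])
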