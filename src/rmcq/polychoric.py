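"""Two-step polychoric correlation estimation for ordinal item matrices.

The latent-variable model: each ordinal item is a discretized standard normal,
cut at item-specific thresholds.  Estimation is the classic two-step scheme:

1. thresholds from the marginal cumulative proportions through the inverse
   normal CDF;
2. for every item pair, the correlation of the underlying bivariate normal is
   found by maximizing the contingency-table multinomial likelihood with the
   thresholds held fixed.

Step 2 uses Fisher scoring with analytic derivatives (d/dr of the rectangle
probability is the bivariate normal density at the cell corners), run
vectorized across all pairs simultaneously, which makes a full 36-item matrix
cheap enough to recompute inside resampling loops.

Empty contingency cells receive a 0.5 continuity correction before the
likelihood is evaluated; near-boundary estimates are clipped to +/-0.999 and
flagged; a non-positive-semidefinite matrix is eigenvalue-smoothed and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from ._bvn import bvn_cdf, bvn_pdf

#: thresholds are clamped to +/- this value instead of +/- infinity;
#: Phi(7.5) is 1 to double precision, so no probability mass is lost.
_TAU_CLAMP = 7.5
_R_CLIP = 0.999


@dataclass
class PolychoricResult:
    """Polychoric correlation matrix with estimation metadata.

    Attributes
    ----------
    corr : (p, p) correlation matrix, symmetric with unit diagonal.
    thresholds : list of per-item threshold vectors (length c_i - 1).
    unit_avar : (p, p) per-observation asymptotic variance of each pairwise
        estimate (inverse Fisher information); Var(r_hat) ~ unit_avar / n.
    clipped : (p, p) boolean mask of pairs clipped at the +/-0.999 boundary.
    smoothed : True when eigenvalue smoothing was applied to restore PSD.
    n : number of observations.
    """

    corr: np.ndarray
    thresholds: list[np.ndarray]
    unit_avar: np.ndarray
    clipped: np.ndarray
    smoothed: bool = False
    n: int = 0


def ordinal_thresholds(codes: np.ndarray, n_categories: int) -> np.ndarray:
    """Thresholds of a single item from its marginal category proportions.

    Returns ``n_categories - 1`` values; categories never observed give
    coincident (clamped) thresholds.
    """
    counts = np.bincount(codes.astype(int), minlength=n_categories)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return np.clip(ndtri(np.clip(cum, 1e-12, 1 - 1e-12)), -_TAU_CLAMP, _TAU_CLAMP)


def contingency_tables(codes: np.ndarray, n_categories: np.ndarray):
    """All pairwise contingency tables of an integer-coded (n, p) matrix.

    Returns ``(pairs, tables)`` where ``pairs`` is the list of (i, j) index
    pairs (i < j) and ``tables`` is an (n_pairs, C, C) array padded to the
    largest category count.
    """
    n, p = codes.shape
    C = int(np.max(n_categories))
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    tables = np.zeros((len(pairs), C, C))
    X = codes.astype(np.int64)
    for idx, (i, j) in enumerate(pairs):
        flat = X[:, i] * C + X[:, j]
        tables[idx] = np.bincount(flat, minlength=C * C).reshape(C, C)
    return pairs, tables


def _normal_scores(codes: np.ndarray, taus: list[np.ndarray]) -> np.ndarray:
    """Map category codes to conditional latent means (for starting values)."""
    n, p = codes.shape
    out = np.empty((n, p))
    for i in range(p):
        tau = np.concatenate(([-np.inf], taus[i], [np.inf]))
        lo, hi = tau[:-1], tau[1:]
        pj = np.maximum(ndtr(hi) - ndtr(lo), 1e-12)
        phi_lo = np.where(np.isfinite(lo), np.exp(-0.5 * lo**2), 0.0) / np.sqrt(2 * np.pi)
        phi_hi = np.where(np.isfinite(hi), np.exp(-0.5 * hi**2), 0.0) / np.sqrt(2 * np.pi)
        out[:, i] = ((phi_lo - phi_hi) / pj)[codes[:, i].astype(int)]
    return out


def smooth_to_psd(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= 0:
        return R
    w = np.maximum(w, floor)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


def polychoric_matrix(
    codes: np.ndarray,
    n_categories: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PolychoricResult:
    """Estimate the full polychoric correlation matrix of an ordinal matrix.

    Parameters
    ----------
    codes : (n, p) integer matrix, item ``i`` coded ``0 .. n_categories[i]-1``,
        no missing cells.
    n_categories : (p,) declared category counts.

    Raises
    ------
    ValueError
        If any item has fewer than two observed categories (its thresholds,
        and hence every correlation involving it, are undefined).
    """
    codes = np.asarray(codes)
    n, p = codes.shape
    n_categories = np.asarray(n_categories, dtype=int)

    for i in range(p):
        if len(np.unique(codes[:, i])) < 2:
            raise ValueError(
                f"item at column {i} has a single observed category; "
                "polychoric correlation is undefined"
            )

    taus = [ordinal_thresholds(codes[:, i], n_categories[i]) for i in range(p)]
    pairs, tables = contingency_tables(codes, n_categories)
    npairs = len(pairs)
    C = tables.shape[1]

    # 0.5 continuity correction in empty cells of the valid sub-table
    valid = np.zeros_like(tables, dtype=bool)
    for idx, (i, j) in enumerate(pairs):
        valid[idx, : n_categories[i], : n_categories[j]] = True
    tables = np.where(valid & (tables == 0), 0.5, tables)
    ntot = tables.sum(axis=(1, 2))

    # padded corner grids: row 0 / col 0 at -clamp, unused rows at +clamp
    a = np.full((npairs, C + 1), _TAU_CLAMP)
    b = np.full((npairs, C + 1), _TAU_CLAMP)
    for idx, (i, j) in enumerate(pairs):
        a[idx, 0], b[idx, 0] = -_TAU_CLAMP, -_TAU_CLAMP
        a[idx, 1 : n_categories[i]] = taus[i]
        b[idx, 1 : n_categories[j]] = taus[j]

    # starting values: Pearson correlation of the normal scores
    z = _normal_scores(codes, taus)
    zc = z - z.mean(axis=0)
    sd = np.sqrt((zc**2).mean(axis=0))
    sd[sd == 0] = 1.0
    r0 = (zc.T @ zc) / n / np.outer(sd, sd)
    r = np.array([np.clip(r0[i, j], -0.9, 0.9) for i, j in pairs])

    info = np.full(npairs, np.nan)
    active = np.ones(npairs, dtype=bool)
    for _ in range(max_iter):
        ia = np.where(active)[0]
        if ia.size == 0:
            break
        aa, bb, rr = a[ia], b[ia], r[ia]
        F = bvn_cdf(aa[:, :, None], bb[:, None, :], rr[:, None, None])
        P = F[:, 1:, 1:] - F[:, :-1, 1:] - F[:, 1:, :-1] + F[:, :-1, :-1]
        P = np.maximum(P, 1e-12)
        f2 = bvn_pdf(aa[:, :, None], bb[:, None, :], rr[:, None, None])
        dP = f2[:, 1:, 1:] - f2[:, :-1, 1:] - f2[:, 1:, :-1] + f2[:, :-1, :-1]
        ratio = dP / P
        g = (tables[ia] * ratio).sum(axis=(1, 2))
        fish = ntot[ia] * (dP * ratio).sum(axis=(1, 2))
        info[ia] = (dP * ratio).sum(axis=(1, 2))
        step = g / np.maximum(fish, 1e-10)
        step = np.clip(step, -0.5, 0.5)
        r_new = np.clip(rr + step, -_R_CLIP, _R_CLIP)
        moved = np.abs(r_new - rr)
        r[ia] = r_new
        done = (moved < tol) | (np.abs(r_new) >= _R_CLIP)
        active[ia[done]] = False

    R = np.eye(p)
    avar = np.zeros((p, p))
    clip_mask = np.zeros((p, p), dtype=bool)
    for idx, (i, j) in enumerate(pairs):
        R[i, j] = R[j, i] = r[idx]
        avar[i, j] = avar[j, i] = 1.0 / max(info[idx], 1e-12)
        if abs(r[idx]) >= _R_CLIP:
            clip_mask[i, j] = clip_mask[j, i] = True

    smoothed = bool(np.linalg.eigvalsh(R).min() < 0)
    if smoothed:
        R = smooth_to_psd(R)
    return PolychoricResult(
        corr=R, thresholds=taus, unit_avar=avar,
        clipped=clip_mask, smoothed=smoothed, n=n,
    )


def polychoric_pair(x: np.ndarray, y: np.ndarray, cx: int, cy: int) -> float:
    """Polychoric correlation of a single item pair (convenience wrapper)."""
    codes = np.column_stack([x, y])
    res = polychoric_matrix(codes, np.array([cx, cy]))
    return float(res.corr[0, 1])
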