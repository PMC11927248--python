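"""Sampling adequacy for factor analysis: polychoric matrix, Bartlett, KMO.

Both gate statistics are computed on the polychoric correlation matrix by
default (the natural choice when the factor analysis itself is polychoric);
a Pearson matrix can be passed instead since both tests only consume a
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .polychoric import PolychoricResult, polychoric_matrix, smooth_to_psd
from .preprocess import CleanMatrix
from .schema import QuestionnaireSchema


@dataclass
class AdequacyReport:
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    kmo_overall: float
    kmo_per_item: np.ndarray

    def to_dict(self) -> dict:
        return {
            "bartlett_chi2": float(self.bartlett_chi2),
            "bartlett_df": int(self.bartlett_df),
            "bartlett_p": float(self.bartlett_p),
            "kmo_overall": float(self.kmo_overall),
            "kmo_per_item": [float(x) for x in self.kmo_per_item],
        }


def estimate_polychoric(clean: CleanMatrix, schema: QuestionnaireSchema) -> PolychoricResult:
    """Polychoric correlation matrix of the cleaned (complete) item matrix."""
    return polychoric_matrix(clean.fa_values, clean.n_categories(schema))


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: H0 is R = I.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2.  A singular R is
    eigenvalue-smoothed first so the log-determinant stays finite.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("sample size must exceed the number of items")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        sign, logdet = np.linalg.slogdet(smooth_to_psd(R))
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(chi2_dist.sf(chi2, df))
    return float(chi2), df, pval


def kmo_msa(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy, overall and per item.

    Anti-image partial correlations come from the inverse correlation matrix:
    a_ij = -s_ij / sqrt(s_ii s_jj) with S = R^{-1};
    KMO = sum r^2_off / (sum r^2_off + sum a^2_off).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    r2 = (R**2)[off]
    if not np.any(r2 > 0):
        raise ValueError("no common variance: all off-diagonal correlations are zero")
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        S = np.linalg.inv(smooth_to_psd(R))
    d = np.sqrt(np.diag(S))
    A = -S / np.outer(d, d)
    a2 = (A**2)
    np.fill_diagonal(a2, 0.0)
    r2m = R**2
    np.fill_diagonal(r2m, 0.0)
    overall = r2m.sum() / (r2m.sum() + a2.sum())
    per_item = r2m.sum(axis=1) / (r2m.sum(axis=1) + a2.sum(axis=1))
    return float(overall), per_item


def adequacy_report(R: np.ndarray, n: int) -> AdequacyReport:
    chi2, df, pval = bartlett_sphericity(R, n)
    overall, per_item = kmo_msa(R)
    return AdequacyReport(
        bartlett_chi2=chi2, bartlett_df=df, bartlett_p=pval,
        kmo_overall=overall, kmo_per_item=per_item,
    )
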