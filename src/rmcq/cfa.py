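"""Confirmatory factor analysis by diagonally weighted least squares.

The ordinal CFA is limited-information and two-stage: thresholds and the
polychoric correlation matrix are estimated first and treated as fixed, then
the factor model (one loading per item, all factor pairs free to correlate,
unit-variance factors, unit-diagonal implied correlation matrix) is fitted by
minimizing

    F(theta) = sum_{i<j} w_ij (r_ij - sigma_ij(theta))^2,

where the weights are the inverse per-observation asymptotic variances of the
pairwise polychoric estimates (the diagonal of the full weight matrix).  The
test statistic is the plain chi2 = (n - 1) * F_min without robust mean/
variance corrections; the CFI/TLI baseline is the independence model (zero
correlations, same thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .polychoric import polychoric_matrix
from .preprocess import CleanMatrix
from .schema import QuestionnaireSchema


@dataclass
class CFAModelSpec:
    """Factor -> item lists with all inter-factor correlations free."""

    factors: list[str]
    items_per_factor: dict[str, list[str]]

    @property
    def item_ids(self) -> list[str]:
        out = []
        for f in self.factors:
            out.extend(self.items_per_factor[f])
        return out

    @property
    def n_free(self) -> int:
        k = len(self.factors)
        return len(self.item_ids) + k * (k - 1) // 2

    def validate(self) -> None:
        seen = set()
        for f in self.factors:
            items = self.items_per_factor.get(f, [])
            if len(items) < 2:
                raise ValueError(f"factor {f!r} has fewer than two items")
            for i in items:
                if i in seen:
                    raise ValueError(f"item {i!r} appears under two factors")
                seen.add(i)


@dataclass
class CFAFit:
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    converged: bool
    n: int
    loadings: dict[str, float] = field(default_factory=dict)
    factor_corr: np.ndarray | None = None
    heywood: bool = False

    def to_dict(self) -> dict:
        return {
            "chi2": float(self.chi2),
            "df": int(self.df),
            "baseline_chi2": float(self.baseline_chi2),
            "baseline_df": int(self.baseline_df),
            "cfi": float(self.cfi),
            "tli": float(self.tli),
            "rmsea": float(self.rmsea),
            "srmr": float(self.srmr),
            "converged": bool(self.converged),
            "heywood": bool(self.heywood),
            "n": int(self.n),
            "loadings": {k: float(v) for k, v in self.loadings.items()},
            "factor_corr": None
            if self.factor_corr is None
            else [[float(x) for x in row] for row in self.factor_corr],
        }


def build_model_from_solution(assignment: dict[str, str]) -> CFAModelSpec:
    """Turn an item -> factor assignment into a CFA model specification."""
    if not assignment:
        raise ValueError("empty assignment")
    factors: list[str] = []
    items: dict[str, list[str]] = {}
    for item, factor in assignment.items():
        if factor not in items:
            factors.append(factor)
            items[factor] = []
        items[factor].append(item)
    spec = CFAModelSpec(factors=factors, items_per_factor=items)
    spec.validate()
    return spec


def build_model_from_specs(specs) -> CFAModelSpec:
    """CFA model from FactorSpec objects (e.g. the bundled reference solution)."""
    assignment = {}
    for s in specs:
        for iid, _ in s.loadings:
            assignment[iid] = s.factor_name
    return build_model_from_solution(assignment)


def _implied(lam: np.ndarray, phi: np.ndarray, loading_factor: np.ndarray) -> np.ndarray:
    Lam = np.zeros((lam.size, phi.shape[0]))
    Lam[np.arange(lam.size), loading_factor] = lam
    S = Lam @ phi @ Lam.T
    np.fill_diagonal(S, 1.0)
    return S


def fit_dwls(
    clean: CleanMatrix,
    model: CFAModelSpec,
    schema: QuestionnaireSchema,
    max_iter: int = 500,
) -> CFAFit:
    """Fit the confirmatory model on the polychoric correlations by DWLS."""
    model.validate()
    missing = [i for i in model.item_ids if i not in clean.item_ids]
    if missing:
        raise ValueError(f"model items absent from data: {missing}")
    cols = [clean.item_ids.index(i) for i in model.item_ids]
    codes = clean.fa_values[:, cols]
    ncat = clean.n_categories(schema)[cols]
    poly = polychoric_matrix(codes, ncat)
    return fit_dwls_matrix(
        poly.corr, poly.unit_avar, clean.n, model, max_iter=max_iter
    )


def fit_dwls_matrix(
    R: np.ndarray,
    unit_avar: np.ndarray,
    n: int,
    model: CFAModelSpec,
    max_iter: int = 500,
) -> CFAFit:
    """DWLS fit given a correlation matrix and unit asymptotic variances.

    ``unit_avar`` is the per-observation asymptotic variance of each pairwise
    correlation estimate: Var(r_ij) ~ unit_avar_ij / n.
    """
    items = model.item_ids
    p = len(items)
    k = len(model.factors)
    loading_factor = np.empty(p, dtype=int)
    for j, f in enumerate(model.factors):
        for iid in model.items_per_factor[f]:
            loading_factor[items.index(iid)] = j

    iu = np.triu_indices(p, 1)
    w = 1.0 / np.maximum(unit_avar[iu], 1e-10)
    r_obs = R[iu]
    pk = np.triu_indices(k, 1)

    def unpack(theta):
        lam = theta[:p]
        phi = np.eye(k)
        phi[pk] = theta[p:]
        phi = phi + np.triu(phi, 1).T
        return lam, phi

    def objective(theta):
        lam, phi = unpack(theta)
        S = _implied(lam, phi, loading_factor)
        resid = r_obs - S[iu]
        F = float(np.sum(w * resid**2))
        # gradient: dF/dSigma then chain to loadings / factor correlations
        M = np.zeros((p, p))
        M[iu] = -2.0 * w * resid
        M = M + M.T
        Lam = np.zeros((p, k))
        Lam[np.arange(p), loading_factor] = lam
        dLam = M @ Lam @ phi  # (p, k); only the loaded entry of each row is free
        g_lam = dLam[np.arange(p), loading_factor]
        dPhi = Lam.T @ M @ Lam
        g_phi = dPhi[pk]
        return F, np.concatenate([g_lam, g_phi])

    theta0 = np.concatenate([np.full(p, 0.7), np.full(k * (k - 1) // 2, 0.3)])
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-2.0, 2.0)] * p + [(-0.99, 0.99)] * (k * (k - 1) // 2),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    lam, phi = unpack(res.x)
    S = _implied(lam, phi, loading_factor)
    F_min = float(np.sum(w * (r_obs - S[iu]) ** 2))
    F_base = float(np.sum(w * r_obs**2))
    chi2 = (n - 1) * F_min
    chi2_b = (n - 1) * F_base
    df = p * (p - 1) // 2 - model.n_free
    df_b = p * (p - 1) // 2
    heywood = bool(np.any(np.abs(lam) > 1.0))

    fit = CFAFit(
        chi2=chi2,
        df=df,
        baseline_chi2=chi2_b,
        baseline_df=df_b,
        cfi=np.nan,
        tli=np.nan,
        rmsea=np.nan,
        srmr=_srmr(R, S),
        converged=bool(res.success),
        n=n,
        loadings={iid: float(lam[i]) for i, iid in enumerate(items)},
        factor_corr=phi,
        heywood=heywood,
    )
    fit.cfi, fit.tli, fit.rmsea, _ = compute_fit_indices(fit)
    return fit


def _srmr(R: np.ndarray, S: np.ndarray) -> float:
    """Root mean squared residual over the lower triangle plus diagonal of
    the standardized (correlation-metric) solution."""
    p = R.shape[0]
    il = np.tril_indices(p, 0)
    resid = (R - S)[il]
    return float(np.sqrt(np.mean(resid**2)))


def compute_fit_indices(fit: CFAFit) -> tuple[float, float, float, float]:
    """CFI, TLI, RMSEA and SRMR from the fitted and baseline chi2.

    CFI  = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)
    TLI  = ((chi2_b/df_b) - (chi2/df)) / ((chi2_b/df_b) - 1), capped to [0,1]
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))
    """
    if fit.df <= 0:
        raise ValueError("RMSEA undefined for a saturated model (df = 0)")
    d = max(fit.chi2 - fit.df, 0.0)
    db = max(fit.baseline_chi2 - fit.baseline_df, 0.0)
    denom = max(db, d)
    cfi = 1.0 if denom == 0 else 1.0 - d / denom
    ratio_b = fit.baseline_chi2 / fit.baseline_df
    ratio_m = fit.chi2 / fit.df
    tli = 1.0 if ratio_b <= 1.0 else (ratio_b - ratio_m) / (ratio_b - 1.0)
    tli = float(np.clip(tli, 0.0, 1.0))
    rmsea = float(np.sqrt(d / (fit.df * (fit.n - 1))))
    return float(cfi), tli, rmsea, fit.srmr


def jackknife_unit_avar(codes: np.ndarray, n_categories: np.ndarray, n_blocks: int = 20):
    """Delete-a-block jackknife estimate of the per-observation asymptotic
    variances of the polychoric correlations (fallback for small samples
    where the information-based variances may be optimistic)."""
    n = codes.shape[0]
    full = polychoric_matrix(codes, n_categories).corr
    blocks = np.array_split(np.arange(n), n_blocks)
    reps = []
    for b in blocks:
        mask = np.ones(n, dtype=bool)
        mask[b] = False
        reps.append(polychoric_matrix(codes[mask], n_categories).corr)
    reps = np.array(reps)
    m = reps.mean(axis=0)
    var = (n_blocks - 1) / n_blocks * np.sum((reps - m) ** 2, axis=0)
    return var * n, full
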