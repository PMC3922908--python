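"""Maximum-likelihood estimation of the second-order HBM factor model.

The model for the 22 observed items y is

    y = Lambda F + eps,            Cov(eps) = Theta (diagonal)
    F = gamma HB + B F + zeta,     Var(HB) = 1, Cov(zeta) = Psi (diagonal)

with simple-structure Lambda (one nonzero loading per row) and an acyclic
structural matrix B among the first-order factors (BAR -> CTA by default).
The implied covariance is

    Sigma(theta) = Lambda Phi Lambda' + Theta,
    Phi = (I - B)^-1 (gamma gamma' + Psi) (I - B)^-T.

Identification fixes Var(HB) = 1 and one marker loading per first-order
factor to 1; all gamma are free.  Estimation minimizes the normal-theory
discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with analytic gradients, quasi-Newton iterations, and multiple jittered
starts.  Variances are optimized on the log scale, which keeps them
positive; solutions adjacent to that boundary are flagged as Heywood
cases.  The standardized solution, per-item total effects of the
second-order factor (the CFA score weights), the model chi-square
(n - 1) * F_ML, and the usual fit-index battery (RMSEA with 90% CI, GFI,
AGFI, NFI, CFI, IFI) are derived from the minimizer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import DEFAULT_SPEC, ITEM_COLUMNS, HBMModelSpec


class NotPositiveDefiniteError(ValueError):
    """Raised when a covariance matrix required to be PD is not."""


@dataclass(frozen=True)
class FitIndices:
    """Scalar goodness-of-fit summaries for a covariance-structure model."""

    rmsea: float
    rmsea_ci_lower: float
    rmsea_ci_upper: float
    gfi: float
    agfi: float
    nfi: float
    cfi: float
    ifi: float
    chi_square_null: float
    df_null: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CFAFit:
    """Estimated second-order CFA solution.

    Raw parameters are in the marker-identified metric; ``*_std`` fields
    hold the fully standardized solution (all latent and observed variances
    1).  ``total_effects`` is the 22-vector of standardized total effects
    of the second-order factor on each item — the CFA score weights.
    """

    spec: HBMModelSpec
    loadings: np.ndarray          # (p,) loading of each item on its factor
    gamma: np.ndarray             # (m,) second-order coefficients
    beta: np.ndarray              # one per structural path
    psi: np.ndarray               # (m,) first-order disturbance variances
    theta: np.ndarray             # (p,) item residual variances
    loadings_std: np.ndarray
    gamma_std: np.ndarray
    beta_std: np.ndarray
    chi_square: float
    df: int
    n_used: int
    fml: float
    sample_cov: np.ndarray
    fit_indices: FitIndices
    total_effects: np.ndarray
    converged: bool
    n_iterations: int
    final_gradient_norm: float
    heywood: bool

    @property
    def n_free_parameters(self) -> int:
        p, m = self.spec.n_items, self.spec.n_factors
        return (p - m) + m + len(self.spec.structural_paths) + m + p

    def implied_covariance(self) -> np.ndarray:
        return model_implied_covariance(
            self.loadings, self.gamma, self.beta, self.psi, self.theta, self.spec
        )

    def to_dict(self) -> dict:
        d = {
            "loadings": self.loadings.tolist(),
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "psi": self.psi.tolist(),
            "theta": self.theta.tolist(),
            "loadings_std": self.loadings_std.tolist(),
            "gamma_std": self.gamma_std.tolist(),
            "beta_std": self.beta_std.tolist(),
            "chi_square": self.chi_square,
            "df": self.df,
            "n_used": self.n_used,
            "fml": self.fml,
            "fit_indices": self.fit_indices.to_dict(),
            "total_effects": self.total_effects.tolist(),
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "final_gradient_norm": self.final_gradient_norm,
            "heywood": self.heywood,
            "factors": list(self.spec.factors),
            "structural_paths": [list(pq) for pq in self.spec.structural_paths],
        }
        return d


# -- covariance algebra ----------------------------------------------------


def _lambda_matrix(loadings: np.ndarray, spec: HBMModelSpec) -> np.ndarray:
    lam = np.zeros((spec.n_items, spec.n_factors))
    lam[np.arange(spec.n_items), spec.item_factor_indices] = loadings
    return lam


def _factor_cov(
    gamma: np.ndarray, beta: np.ndarray, psi: np.ndarray, spec: HBMModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Phi = A (gamma gamma' + Psi) A' with A = (I - B)^-1; returns (Phi, A)."""
    B = spec.structural_matrix(np.asarray(beta, dtype=float))
    eye = np.eye(spec.n_factors)
    try:
        A = np.linalg.inv(eye - B)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - acyclic B is invertible
        raise ValueError("I - B is singular") from exc
    phi = A @ (np.outer(gamma, gamma) + np.diag(psi)) @ A.T
    return phi, A


def model_implied_covariance(
    loadings: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    psi: np.ndarray,
    theta: np.ndarray,
    spec: HBMModelSpec = DEFAULT_SPEC,
) -> np.ndarray:
    """Model-implied item covariance Sigma(theta) for the second-order CFA."""
    loadings = np.asarray(loadings, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    psi = np.asarray(psi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if loadings.shape != (spec.n_items,) or theta.shape != (spec.n_items,):
        raise ValueError("loadings/theta must have one entry per item")
    if gamma.shape != (spec.n_factors,) or psi.shape != (spec.n_factors,):
        raise ValueError("gamma/psi must have one entry per factor")
    lam = _lambda_matrix(loadings, spec)
    phi, _ = _factor_cov(gamma, beta, psi, spec)
    sigma = lam @ phi @ lam.T + np.diag(theta)
    return (sigma + sigma.T) / 2.0


def _logdet_pd(mat: np.ndarray, name: str) -> tuple[float, np.ndarray]:
    """(log-determinant, Cholesky factor) of a PD matrix, or raise."""
    try:
        chol = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(f"{name} is not positive definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol)))), chol


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy F_ML(S, Sigma).

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p; nonnegative, zero iff
    S = Sigma.
    """
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = S.shape[0]
    logdet_s, _ = _logdet_pd(S, "sample covariance")
    logdet_sig, chol = _logdet_pd(sigma, "model covariance")
    # tr(S Sigma^-1) via triangular solves against the Cholesky factor
    half = np.linalg.solve(chol, S)
    inv_part = np.linalg.solve(chol.T, half)
    return float(logdet_sig + np.trace(inv_part) - logdet_s - p)


# -- parameter vector packing ----------------------------------------------


def _pack(loadings, gamma, beta, psi, theta, spec) -> np.ndarray:
    free = spec.free_loading_items
    return np.concatenate(
        [
            np.asarray(loadings, dtype=float)[free],
            np.asarray(gamma, dtype=float),
            np.asarray(beta, dtype=float),
            np.log(np.asarray(psi, dtype=float)),
            np.log(np.asarray(theta, dtype=float)),
        ]
    )


def _unpack(x: np.ndarray, spec: HBMModelSpec):
    p, m, q = spec.n_items, spec.n_factors, len(spec.structural_paths)
    free = spec.free_loading_items
    loadings = np.ones(p)
    loadings[free] = x[: len(free)]
    o = len(free)
    gamma = x[o : o + m]
    beta = x[o + m : o + m + q]
    psi = np.exp(x[o + m + q : o + m + q + m])
    theta = np.exp(x[o + m + q + m :])
    return loadings, gamma, beta, psi, theta


def _objective_and_grad(x: np.ndarray, S: np.ndarray, spec: HBMModelSpec, logdet_s: float):
    loadings, gamma, beta, psi, theta = _unpack(x, spec)
    lam = _lambda_matrix(loadings, spec)
    phi, A = _factor_cov(gamma, beta, psi, spec)
    sigma = lam @ phi @ lam.T + np.diag(theta)
    sigma = (sigma + sigma.T) / 2.0
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(x)
    logdet_sig = 2.0 * float(np.sum(np.log(np.diag(chol))))
    inv_sigma = np.linalg.inv(sigma)
    f = logdet_sig + float(np.sum(inv_sigma * S)) - logdet_s - S.shape[0]

    # dF = tr(G dSigma), G = Sigma^-1 - Sigma^-1 S Sigma^-1
    G = inv_sigma - inv_sigma @ S @ inv_sigma
    GL = G @ lam                      # (p, m)
    H = lam.T @ GL                    # (m, m)
    idx = spec.item_factor_indices

    grad_lam_all = 2.0 * (GL @ phi)[np.arange(spec.n_items), idx]
    AHA = A.T @ H @ A
    grad_gamma = 2.0 * AHA @ gamma
    grad_psi = np.diag(AHA) * psi     # log-scale chain rule
    grad_theta = np.diag(G) * theta
    M = np.outer(gamma, gamma) + np.diag(psi)
    X = A @ M @ A.T @ H @ A           # for structural coefficients
    grad_beta = np.array(
        [
            2.0 * X[spec.factor_index(src), spec.factor_index(dst)]
            for src, dst in spec.structural_paths
        ]
    )
    free = spec.free_loading_items
    grad = np.concatenate(
        [grad_lam_all[free], grad_gamma, grad_beta, grad_psi, grad_theta]
    )
    return f, grad


# -- fitting ---------------------------------------------------------------


def listwise_complete(data: pd.DataFrame, spec: HBMModelSpec = DEFAULT_SPEC) -> pd.DataFrame:
    """Rows with all item columns observed (order preserved)."""
    items = list(ITEM_COLUMNS[: spec.n_items])
    missing = [c for c in items if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks item columns: {missing}")
    return data.dropna(subset=items)


def _start_values(S: np.ndarray, spec: HBMModelSpec, rng: np.random.Generator, jitter: float):
    p, m = spec.n_items, spec.n_factors
    sd = np.sqrt(np.diag(S))
    loadings = np.ones(p) * sd / sd[[spec.markers[f] for f in spec.item_factor_map]]
    gamma = np.full(m, 0.4) * sd[[spec.markers[f] for f in spec.factors]]
    beta = np.zeros(len(spec.structural_paths))
    psi = 0.3 * sd[[spec.markers[f] for f in spec.factors]] ** 2
    theta = 0.5 * np.diag(S).copy()
    x = _pack(loadings, gamma, beta, psi, theta, spec)
    if jitter > 0:
        x = x + rng.normal(0.0, jitter, size=x.shape)
    return x


def fit(
    data_or_cov,
    n: int | None = None,
    spec: HBMModelSpec = DEFAULT_SPEC,
    n_starts: int = 5,
    gtol: float = 1e-6,
    seed: int = 0,
    compute_indices: bool = True,
) -> CFAFit:
    """Fit the second-order CFA by maximum likelihood.

    Parameters
    ----------
    data_or_cov
        Either an item-response table (metadata + item columns; listwise
        deletion is applied) or a (p, p) sample covariance, in which case
        ``n`` must give the sample size behind it.
    n_starts
        Number of jittered starting points; the best minimum is kept.
    gtol
        Gradient-norm threshold declaring convergence.
    """
    if isinstance(data_or_cov, pd.DataFrame):
        complete = listwise_complete(data_or_cov, spec)
        items = list(ITEM_COLUMNS[: spec.n_items])
        arr = complete[items].to_numpy(dtype=float)
        if arr.shape[0] < spec.n_items + 1:
            raise ValueError("too few complete rows to fit the model")
        S = np.cov(arr, rowvar=False, ddof=1)
        n_used = arr.shape[0]
    else:
        S = np.asarray(data_or_cov, dtype=float)
        if n is None:
            raise ValueError("n is required when fitting a covariance matrix")
        n_used = int(n)
    logdet_s, _ = _logdet_pd(S, "sample covariance")  # fail fast on non-PD input

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, n_starts)):
        x0 = _start_values(S, spec, rng, jitter=0.0 if trial == 0 else 0.05)
        res = optimize.minimize(
            _objective_and_grad,
            x0,
            args=(S, spec, logdet_s),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10, "maxcor": 30},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    loadings, gamma, beta, psi, theta = _unpack(best.x, spec)
    _, grad = _objective_and_grad(best.x, S, spec, logdet_s)
    grad_norm = float(np.linalg.norm(grad, ord=np.inf))
    fml = float(best.fun)
    p = spec.n_items
    n_free = (p - spec.n_factors) + spec.n_factors + len(spec.structural_paths) + spec.n_factors + p
    df = p * (p + 1) // 2 - n_free
    chi_square = (n_used - 1) * fml

    loadings_std, gamma_std, beta_std = _standardized_solution(
        loadings, gamma, beta, psi, theta, spec
    )
    heywood = bool(np.min(psi) < 1e-6 or np.min(theta) < 1e-6
                   or np.max(np.abs(loadings_std)) > 1.0 + 1e-8
                   or np.max(np.abs(gamma_std)) > 1.0 + 1e-8)

    sigma = model_implied_covariance(loadings, gamma, beta, psi, theta, spec)
    if compute_indices and df > 0:
        chi0, df0 = null_model(S, n_used)
        indices = fit_indices(chi_square, df, n_used, chi0, df0, S, sigma)
    else:
        indices = None

    result = CFAFit(
        spec=spec,
        loadings=loadings,
        gamma=gamma,
        beta=beta,
        psi=psi,
        theta=theta,
        loadings_std=loadings_std,
        gamma_std=gamma_std,
        beta_std=beta_std,
        chi_square=chi_square,
        df=df,
        n_used=n_used,
        fml=fml,
        sample_cov=S,
        fit_indices=indices,
        total_effects=np.zeros(p),
        converged=bool(grad_norm < gtol),
        n_iterations=int(best.nit),
        final_gradient_norm=grad_norm,
        heywood=heywood,
    )
    result.total_effects = total_effects(result)
    return result


def _standardized_solution(loadings, gamma, beta, psi, theta, spec):
    phi, A = _factor_cov(gamma, beta, psi, spec)
    sd_f = np.sqrt(np.diag(phi))
    if np.any(sd_f == 0.0):
        raise ValueError("zero implied factor variance; cannot standardize")
    sigma = model_implied_covariance(loadings, gamma, beta, psi, theta, spec)
    sd_y = np.sqrt(np.diag(sigma))
    if np.any(sd_y == 0.0):
        raise ValueError("zero implied item variance; cannot standardize")
    idx = spec.item_factor_indices
    loadings_std = loadings * sd_f[idx] / sd_y
    gamma_std = gamma / sd_f  # Var(HB) = 1
    beta_std = np.array(
        [
            b * sd_f[spec.factor_index(src)] / sd_f[spec.factor_index(dst)]
            for b, (src, dst) in zip(np.asarray(beta, dtype=float), spec.structural_paths)
        ]
    )
    return loadings_std, gamma_std, beta_std


def standardize(fit_result: CFAFit) -> CFAFit:
    """Recompute the standardized solution from the raw parameters.

    Idempotent: standardized fields are a pure function of the raw
    solution.
    """
    loadings_std, gamma_std, beta_std = _standardized_solution(
        fit_result.loadings,
        fit_result.gamma,
        fit_result.beta,
        fit_result.psi,
        fit_result.theta,
        fit_result.spec,
    )
    out = dataclasses.replace(
        fit_result,
        loadings_std=loadings_std,
        gamma_std=gamma_std,
        beta_std=beta_std,
    )
    out.total_effects = total_effects(out)
    return out


def total_effects(fit_result: CFAFit) -> np.ndarray:
    """Standardized total effect of the second-order factor on each item.

    The factor-level total effect is (I - B*)^-1 gamma*, which adds the
    structurally mediated routes (BAR -> CTA by default) to the direct
    second-order coefficients; item-level effects multiply by the
    standardized loading.  These are the CFA score weights W.
    """
    spec = fit_result.spec
    B_std = spec.structural_matrix(fit_result.beta_std)
    te_factor = np.linalg.solve(np.eye(spec.n_factors) - B_std, fit_result.gamma_std)
    return fit_result.loadings_std * te_factor[spec.item_factor_indices]


# -- baseline model and fit indices ----------------------------------------


def null_model(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-baseline chi-square and df.

    Sigma_0 = diag(S), so F_ML reduces to ln|diag S| - ln|S| and
    df_null = p (p - 1) / 2.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    chi0 = (n - 1) * ml_discrepancy(S, np.diag(np.diag(S)))
    return float(chi0), p * (p - 1) // 2


def _rmsea_ci(chi_square: float, df: int, n: int, level: float = 0.90):
    """90% RMSEA interval by root-finding the noncentrality of chi2(df)."""
    lo_q, hi_q = (1.0 + level) / 2.0, (1.0 - level) / 2.0  # 0.95, 0.05

    def bound(target: float) -> float:
        f = lambda nc: stats.ncx2.cdf(chi_square, df, nc) - target
        if f(0.0) < 0.0:  # even nc = 0 puts chi2 below the target quantile
            return 0.0
        hi = max(chi_square, df) + 1.0
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > 1e10:  # pragma: no cover
                return np.nan
        nc = optimize.brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12)
        return float(np.sqrt(nc / (df * (n - 1))))

    return bound(lo_q), bound(hi_q)


def fit_indices(
    chi_square: float,
    df: int,
    n: int,
    chi_square_null: float,
    df_null: int,
    S: np.ndarray,
    sigma: np.ndarray,
) -> FitIndices:
    """RMSEA (with 90% CI), GFI, AGFI, NFI, CFI and IFI.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))); its interval inverts
    the noncentral chi-square CDF.  GFI/AGFI follow the ML definitions on
    (S, Sigma); NFI/CFI/IFI compare against the independence baseline.
    """
    if df <= 0:
        raise ValueError("df must be positive for fit indices")
    if n <= 1:
        raise ValueError("n must exceed 1")
    p = S.shape[0]
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    ci_lo, ci_hi = _rmsea_ci(chi_square, df, n)

    inv_sigma = np.linalg.inv(sigma)
    ratio = inv_sigma @ S
    resid = ratio - np.eye(p)
    gfi = float(1.0 - np.trace(resid @ resid) / np.trace(ratio @ ratio))
    agfi = float(1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi))

    if chi_square_null <= 0:
        raise ValueError("null-model chi-square must be positive for comparative indices")
    nfi = float((chi_square_null - chi_square) / chi_square_null)
    denom = max(chi_square_null - df_null, chi_square - df, 0.0)
    cfi = 1.0 if denom == 0.0 else float(1.0 - max(chi_square - df, 0.0) / denom)
    ifi = float((chi_square_null - chi_square) / (chi_square_null - df))

    return FitIndices(
        rmsea=rmsea,
        rmsea_ci_lower=ci_lo,
        rmsea_ci_upper=ci_hi,
        gfi=gfi,
        agfi=agfi,
        nfi=nfi,
        cfi=cfi,
        ifi=ifi,
        chi_square_null=float(chi_square_null),
        df_null=int(df_null),
    )
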