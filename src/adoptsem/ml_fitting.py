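"""Multi-group normal-theory maximum-likelihood fitting of the path model.

Each family structure contributes a sample covariance matrix over its
observed variables.  The fit function is the standard covariance ML
discrepancy, weighted by the group sample size n (not n-1), so the total
objective is on the -2 log-likelihood-difference (chi-square) scale and
equals the noncentrality parameter when fitted to population matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .path_model import (
    PARAM_NAMES,
    VARIANCE_PARAMS,
    CovarianceBlock,
    ModelParams,
    _sigma_observed,
    structure_roster,
)
from .path_model import _ROSTER, _ADO_FOUNDERS, _BIO_FOUNDERS

__all__ = [
    "ModelSpec",
    "GroupData",
    "FitResult",
    "FULL_FREE",
    "ml_fit_function",
    "fit_model",
    "wald_tests",
    "lrt",
]

#: Default free-parameter set for the full model (``r`` is fixed by design:
#: when relatedness structures are present it is set from the known
#: relationship, never estimated).
FULL_FREE = (
    "gamma_m",
    "beta_m",
    "beta_p",
    "beta_o",
    "rho",
    "phi",
    "eps1_sq",
    "eps2_sq",
)

_VAR_LOWER = 1e-8


@dataclass
class ModelSpec:
    """Which parameters are free, which are fixed (and to what), optional
    start values, and box bounds for the optimizer."""

    free_params: tuple[str, ...]
    fixed_params: dict[str, float] = field(default_factory=dict)
    start_values: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.free_params = tuple(self.free_params)
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        covered = set(self.free_params) | set(self.fixed_params)
        missing = set(PARAM_NAMES) - covered
        if missing:
            raise ValueError(
                f"every parameter must be free or fixed; missing: {sorted(missing)}"
            )
        unknown = covered - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        for name in self.free_params:
            if name not in self.bounds:
                if name in VARIANCE_PARAMS:
                    self.bounds[name] = (_VAR_LOWER, np.inf)
                else:
                    self.bounds[name] = (-np.inf, np.inf)

    @classmethod
    def full(cls, fixed: Mapping[str, float] | None = None, **kwargs) -> "ModelSpec":
        """Full model: all effect/variance/covariance parameters free, ``r``
        (and anything in ``fixed``) held constant."""
        fixed = dict(fixed or {})
        fixed.setdefault("r", 0.0)
        free = tuple(n for n in PARAM_NAMES if n not in fixed)
        return cls(free_params=free, fixed_params=fixed, **kwargs)

    def reduced(self, constraint: Mapping[str, float] | Sequence[str]) -> "ModelSpec":
        """Spec with additional parameters fixed (to 0 unless given)."""
        if not isinstance(constraint, Mapping):
            constraint = {name: 0.0 for name in constraint}
        bad = [n for n in constraint if n not in self.free_params]
        if bad:
            raise ValueError(f"constraint parameters not free in this spec: {bad}")
        fixed = dict(self.fixed_params)
        fixed.update({k: float(v) for k, v in constraint.items()})
        free = tuple(n for n in self.free_params if n not in constraint)
        return ModelSpec(
            free_params=free,
            fixed_params=fixed,
            start_values=dict(self.start_values),
            bounds={k: v for k, v in self.bounds.items() if k in free},
        )


@dataclass
class GroupData:
    """Sample covariance matrix for one family structure."""

    structure: str
    cov: CovarianceBlock

    def __post_init__(self) -> None:
        roster = structure_roster(self.structure)
        if tuple(self.cov.labels) != roster.observed_vars:
            raise ValueError(
                f"{self.structure}: covariance labels {self.cov.labels} do not "
                f"match the roster {roster.observed_vars}"
            )
        if self.cov.n is None:
            raise ValueError(f"{self.structure}: sample size n is required")
        p = len(self.cov.labels)
        if self.cov.n < p + 1:
            raise ValueError(
                f"{self.structure}: n={self.cov.n} is below the minimum p+1={p + 1}"
            )

    def to_dict(self) -> dict:
        d = self.cov.to_dict()
        d["structure"] = self.structure
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupData":
        return cls(d["structure"], CovarianceBlock.from_dict(d))


@dataclass
class FitResult:
    """Result of a multi-group ML fit."""

    estimates: dict[str, float]
    standard_errors: dict[str, float] | None
    minus2ll_fit: float
    df_model: int
    converged: bool
    n_restarts_used: int
    group_fits: dict[str, float]
    free_params: tuple[str, ...]
    fixed_params: dict[str, float]
    n_total: int
    message: str = ""
    gradient_norm: float = float("nan")

    @property
    def params(self) -> ModelParams:
        full = dict(self.fixed_params)
        full.update(self.estimates)
        return ModelParams.from_dict(full)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "minus2ll_fit": self.minus2ll_fit,
            "df_model": self.df_model,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "group_fits": self.group_fits,
            "free_params": list(self.free_params),
            "fixed_params": self.fixed_params,
            "n_total": self.n_total,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# Fit function
# ---------------------------------------------------------------------------

def _logdet_pd(a: np.ndarray) -> float:
    """log|A| via Cholesky; raises ValueError if A is not positive definite."""
    try:
        L = np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        raise ValueError("matrix is not positive definite") from None
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def ml_fit_function(
    model_cov: CovarianceBlock | np.ndarray,
    sample_cov: CovarianceBlock | np.ndarray,
    n: int,
) -> float:
    """Normal-theory ML discrepancy n * [ln|Sigma| + tr(S Sigma^-1) - ln|S| - p].

    Zero iff the model-implied matrix equals the sample matrix; linear in n.
    """
    if isinstance(model_cov, CovarianceBlock) and isinstance(sample_cov, CovarianceBlock):
        if model_cov.labels != sample_cov.labels:
            raise ValueError("model and sample covariance labels differ")
    sigma = model_cov.matrix if isinstance(model_cov, CovarianceBlock) else np.asarray(model_cov)
    s = sample_cov.matrix if isinstance(sample_cov, CovarianceBlock) else np.asarray(sample_cov)
    p = sigma.shape[0]
    try:
        logdet_s = _logdet_pd(s)
    except ValueError:
        raise ValueError("sample covariance is not positive definite") from None
    logdet_sigma = _logdet_pd(sigma)  # propagates: rejected step
    tr = float(np.trace(np.linalg.solve(sigma, s)))
    return float(n) * (logdet_sigma + tr - logdet_s - p)


class _GroupModel:
    """Linear-loading representation of one structure's implied covariance.

    Every observed variable is linear in m = k+2 independent-source blocks:
    the k founder genotypes (covariance SF), the segregation deviation
    (variance phi/2) and the phenotype residual.  So Sigma = Lam D Lam^T
    with tiny matrices, and every parameter derivative is closed-form:
    effects move only the Y row of Lam; phi/rho/r/eps move only D.
    """

    def __init__(self, code: str):
        observed, adopted, pair = _ROSTER[code]
        founders = _ADO_FOUNDERS if adopted else _BIO_FOUNDERS
        self.code = code
        self.adopted = adopted
        self.observed = observed
        self.k = k = len(founders)
        self.m = m = k + 2
        self.p = len(observed)
        self.w = np.zeros(k)
        self.w[0] = self.w[1] = 0.5
        self.founder_index = {f: i for i, f in enumerate(founders)}
        # which founder each effect path loads on (Y row of Lam)
        if adopted:
            self.effect_founder = {"gamma_m": 0, "beta_m": 2, "beta_p": 3}
        else:
            self.effect_founder = {"gamma_m": 0, "beta_m": 0, "beta_p": 1}
        self.eps_name = "eps2_sq" if adopted else "eps1_sq"
        # constant dD/dtheta blocks
        dphi = np.zeros((m, m))
        dphi[np.arange(k), np.arange(k)] = 1.0
        dphi[k, k] = 0.5
        self.dD_phi = dphi
        drho = np.zeros((m, m))
        drho[0, 1] = drho[1, 0] = 1.0
        if adopted:
            drho[2, 3] = drho[3, 2] = 1.0
        self.dD_rho = drho
        if pair is not None:
            i, j = self.founder_index[pair[0]], self.founder_index[pair[1]]
            dr = np.zeros((m, m))
            dr[i, j] = dr[j, i] = 1.0
            self.dD_r = dr
        else:
            self.dD_r = None
        deps = np.zeros((m, m))
        deps[m - 1, m - 1] = 1.0
        self.dD_eps = deps

    def loadings(self, pt: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
        k, m = self.k, self.m
        D = np.zeros((m, m))
        D[np.arange(k), np.arange(k)] = pt["phi"]
        D[0, 1] = D[1, 0] = pt["rho"]
        if self.adopted:
            D[2, 3] = D[3, 2] = pt["rho"]
        if self.dD_r is not None:
            D += pt["r"] * self.dD_r
        D[k, k] = pt["phi"] / 2.0
        D[m - 1, m - 1] = pt[self.eps_name]

        lam = np.zeros((self.p, m))
        bo = pt["beta_o"]
        c = np.zeros(k)
        if self.adopted:
            c[0] = pt["gamma_m"]
            c[2] = pt["beta_m"]
            c[3] = pt["beta_p"]
        else:
            c[0] = pt["gamma_m"] + pt["beta_m"]
            c[1] = pt["beta_p"]
        for row, var in enumerate(self.observed):
            if var == "Zo":
                lam[row, :k] = self.w
                lam[row, k] = 1.0
            elif var == "Y":
                lam[row, :k] = c + bo * self.w
                lam[row, k] = bo
                lam[row, m - 1] = 1.0
            else:
                lam[row, self.founder_index[var]] = 1.0
        return lam, D

    def sigma(self, pt: Mapping[str, float]) -> np.ndarray:
        lam, D = self.loadings(pt)
        return lam @ D @ lam.T

    def sigma_and_dsigma(
        self, pt: Mapping[str, float], free: Sequence[str]
    ) -> tuple[np.ndarray, list[np.ndarray | None]]:
        lam, D = self.loadings(pt)
        DLt = D @ lam.T
        sigma = lam @ DLt
        y_row = self.observed.index("Y")
        zero = None
        derivs: list[np.ndarray | None] = []
        for name in free:
            if name in self.effect_founder:
                dlam_y = np.zeros(self.m)
                dlam_y[self.effect_founder[name]] = 1.0
                mrow = dlam_y @ DLt  # only the Y row of dLam is nonzero
                d = np.zeros_like(sigma)
                d[y_row, :] += mrow
                d[:, y_row] += mrow
                derivs.append(d)
            elif name == "beta_o":
                dlam_y = np.zeros(self.m)
                dlam_y[: self.k] = self.w
                dlam_y[self.k] = 1.0
                mrow = dlam_y @ DLt
                d = np.zeros_like(sigma)
                d[y_row, :] += mrow
                d[:, y_row] += mrow
                derivs.append(d)
            elif name == "phi":
                derivs.append(lam @ self.dD_phi @ lam.T)
            elif name == "rho":
                derivs.append(lam @ self.dD_rho @ lam.T)
            elif name == "r":
                derivs.append(None if self.dD_r is None else lam @ self.dD_r @ lam.T)
            elif name == self.eps_name:
                derivs.append(lam @ self.dD_eps @ lam.T)
            else:  # the other family type's residual: no effect here
                derivs.append(zero)
        return sigma, derivs


class _Objective:
    """Total n-weighted ML discrepancy over groups, with analytic gradient."""

    def __init__(self, groups: Sequence[GroupData], spec: ModelSpec):
        self.free = spec.free_params
        self.fixed = dict(spec.fixed_params)
        self.groups = []
        for g in groups:
            s = g.cov.matrix
            logdet_s = _logdet_pd(s)  # validates PD at input
            self.groups.append(
                (g.structure, _GroupModel(g.structure), s, float(g.cov.n), logdet_s, s.shape[0])
            )

    def point(self, x: np.ndarray) -> dict[str, float]:
        d = dict(self.fixed)
        d.update(zip(self.free, x))
        return d

    def value(self, x: np.ndarray) -> float:
        pt = self.point(x)
        total = 0.0
        for code, model, s, n, logdet_s, p in self.groups:
            sigma = model.sigma(pt)
            try:
                logdet_sigma = _logdet_pd(sigma)
            except ValueError:
                eig = np.linalg.eigvalsh(sigma)
                return 1e10 * (1.0 + float(np.sum(np.maximum(-eig, 0.0))))
            tr = float(np.trace(np.linalg.solve(sigma, s)))
            total += n * (logdet_sigma + tr - logdet_s - p)
        return total

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        pt = self.point(x)
        k = len(self.free)
        total = 0.0
        grad = np.zeros(k)
        for code, model, s, n, logdet_s, p in self.groups:
            sigma, derivs = model.sigma_and_dsigma(pt, self.free)
            try:
                L = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                eig = np.linalg.eigvalsh(sigma)
                val = 1e10 * (1.0 + float(np.sum(np.maximum(-eig, 0.0))))
                return val, np.zeros(k)
            logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(L))))
            sigma_inv = np.linalg.inv(sigma)
            total += n * (logdet_sigma + float(np.sum(sigma_inv * s)) - logdet_s - p)
            # dF/dtheta = n * tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma]
            a = sigma_inv - sigma_inv @ s @ sigma_inv
            for j, dsig in enumerate(derivs):
                if dsig is not None:
                    grad[j] += n * float(np.sum(a * dsig))
        return total, grad

    def grad(self, x: np.ndarray) -> np.ndarray:
        return self.value_and_grad(x)[1]

    def hessian(self, x: np.ndarray) -> np.ndarray:
        k = len(self.free)
        H = np.zeros((k, k))
        for j in range(k):
            h = 1e-5 * max(1.0, abs(x[j]))
            hi = x.copy()
            lo = x.copy()
            hi[j] += h
            lo[j] -= h
            H[:, j] = (self.grad(hi) - self.grad(lo)) / (2 * h)
        return 0.5 * (H + H.T)


def _default_starts(groups: Sequence[GroupData], spec: ModelSpec) -> dict[str, float]:
    """Moment-based start values: effects 0.05, phi from observed genotype
    variances, rho from spousal covariances in trios, residuals from pooled
    phenotype variance."""
    geno_vars: list[float] = []
    y_vars: list[float] = []
    rho_obs: list[float] = []
    for g in groups:
        labels = list(g.cov.labels)
        for i, lab in enumerate(labels):
            if lab == "Y":
                y_vars.append(g.cov.matrix[i, i])
            elif lab != "Zo":
                geno_vars.append(g.cov.matrix[i, i])
            else:
                geno_vars.append(g.cov.matrix[i, i])
        if "Zm" in labels and "Zp" in labels:
            rho_obs.append(g.cov.matrix[labels.index("Zm"), labels.index("Zp")])
    phi0 = float(np.mean(geno_vars)) if geno_vars else 1.0
    y0 = float(np.mean(y_vars)) if y_vars else 1.0
    start = {
        "gamma_m": 0.05,
        "beta_m": 0.05,
        "beta_p": 0.05,
        "beta_o": 0.05,
        "rho": float(np.mean(rho_obs)) if rho_obs else 0.0,
        "phi": max(phi0, 1e-3),
        "eps1_sq": max(0.5 * y0, 1e-3),
        "eps2_sq": max(0.5 * y0, 1e-3),
        "r": 0.0,
    }
    start.update(spec.start_values)
    return start


def fit_model(
    groups: Sequence[GroupData],
    spec: ModelSpec,
    *,
    start: Mapping[str, float] | None = None,
    seed: int = 0,
    max_restarts: int = 5,
    compute_se: bool = True,
    polish: bool = True,
) -> FitResult:
    """Fit the multi-group model by minimizing the summed n-weighted ML
    discrepancy over the free parameters.

    Standard errors come from the observed information of the objective:
    Cov(theta_hat) = 2 H^-1 with H the Hessian in the -2lnL metric.  Up to
    ``max_restarts`` jittered restarts (seeded) are attempted when the
    optimizer fails to converge; a Newton polish tightens the solution.
    """
    if not groups:
        raise ValueError("at least one group is required")
    obj = _Objective(groups, spec)
    k = len(spec.free_params)
    start_full = _default_starts(groups, spec)
    if start:
        start_full.update({k_: float(v) for k_, v in start.items()})
    x0 = np.array([start_full[name] for name in spec.free_params])
    lb = np.array([spec.bounds[name][0] for name in spec.free_params])
    ub = np.array([spec.bounds[name][1] for name in spec.free_params])
    x0 = np.clip(x0, lb, ub)

    n_total = int(sum(g.cov.n for g in groups))
    n_moments = sum(
        len(g.cov.labels) * (len(g.cov.labels) + 1) // 2 for g in groups
    )

    if k == 0:
        # degenerate spec: everything fixed, just evaluate
        val = obj.value(np.empty(0))
        return FitResult(
            estimates={},
            standard_errors={} if compute_se else None,
            minus2ll_fit=float(val),
            df_model=n_moments,
            converged=True,
            n_restarts_used=0,
            group_fits=_group_fits(obj, np.empty(0)),
            free_params=(),
            fixed_params=dict(spec.fixed_params),
            n_total=n_total,
            message="no free parameters",
        )

    rng = np.random.default_rng(seed)
    best = None
    n_restarts_used = 0
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            xs = x0
        else:
            n_restarts_used = attempt
            jitter = 1.0 + 0.2 * rng.standard_normal(k)
            xs = np.clip(x0 * jitter + 0.02 * rng.standard_normal(k), lb, ub)
        res = optimize.minimize(
            obj.value_and_grad,
            xs,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        gnorm = float(np.max(np.abs(obj.grad(best.x))))
        scale = 1.0 + abs(best.fun)
        if best.success or gnorm < 1e-5 * scale * max(1.0, n_total / 100.0):
            break

    x = best.x.copy()
    fval = float(best.fun)
    hess = None
    if polish:
        x, fval, hess = _newton_polish(obj, x, fval, lb, ub)

    gnorm = float(np.max(np.abs(obj.grad(x))))
    # gradient scale: the objective is O(n_total), so converged means the
    # relative gradient is tiny
    converged = bool(best.success) or gnorm <= 1e-4 * (1.0 + abs(fval) + n_total * 1e-3)
    at_bound = [
        name
        for name, xi, lo, hi in zip(spec.free_params, x, lb, ub)
        if xi - lo < 1e-7 or hi - xi < 1e-7
    ]
    message = best.message if isinstance(best.message, str) else str(best.message)
    if at_bound:
        message += f" | parameters at bounds: {at_bound}"

    ses: dict[str, float] | None = None
    if compute_se and converged:
        if hess is None:
            hess = obj.hessian(x)
        ses = _standard_errors(hess, spec.free_params)

    estimates = {name: float(v) for name, v in zip(spec.free_params, x)}
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        minus2ll_fit=max(fval, 0.0) if fval > -1e-6 else fval,
        df_model=n_moments - k,
        converged=converged,
        n_restarts_used=n_restarts_used,
        group_fits=_group_fits(obj, x),
        free_params=spec.free_params,
        fixed_params=dict(spec.fixed_params),
        n_total=n_total,
        message=message,
        gradient_norm=gnorm,
    )


def _group_fits(obj: _Objective, x: np.ndarray) -> dict[str, float]:
    pt = obj.point(x)
    out = {}
    for code, model, s, n, logdet_s, p in obj.groups:
        sigma = model.sigma(pt)
        try:
            val = n * (_logdet_pd(sigma) + float(np.trace(np.linalg.solve(sigma, s))) - logdet_s - p)
        except ValueError:
            val = float("inf")
        # groups may repeat a structure label (e.g. two G5 strata)
        key = code
        i = 2
        while key in out:
            key = f"{code}#{i}"
            i += 1
        out[key] = float(val)
    return out


def _newton_polish(
    obj: _Objective,
    x: np.ndarray,
    fval: float,
    lb: np.ndarray,
    ub: np.ndarray,
    max_iter: int = 4,
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """A few safeguarded Newton steps to tighten the optimum."""
    hess = None
    for _ in range(max_iter):
        g = obj.grad(x)
        if np.max(np.abs(g)) < 1e-12 * (1.0 + abs(fval)):
            break
        hess = obj.hessian(x)
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            break
        x_new = np.clip(x - step, lb, ub)
        f_new = obj.value(x_new)
        if not np.isfinite(f_new) or f_new > fval + 1e-10 * (1.0 + abs(fval)):
            break
        x, fval = x_new, float(f_new)
        hess = None  # stale after the move
    return x, fval, hess


def _standard_errors(hess: np.ndarray, names: tuple[str, ...]) -> dict[str, float] | None:
    """SEs from Cov = 2 H^-1; None if the observed information is not PD."""
    try:
        np.linalg.cholesky(hess)
    except np.linalg.LinAlgError:
        return None
    cov = 2.0 * np.linalg.inv(hess)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        return None
    return {name: float(math.sqrt(v)) for name, v in zip(names, diag)}


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def wald_tests(fit: FitResult) -> dict[str, dict[str, float | None]]:
    """Per-parameter Wald z statistics and two-sided normal p-values."""
    if not fit.converged:
        raise ValueError("fit did not converge; Wald tests unavailable")
    if fit.standard_errors is None:
        raise ValueError("standard errors unavailable (information not PD)")
    out: dict[str, dict[str, float | None]] = {}
    for name, est in fit.estimates.items():
        se = fit.standard_errors.get(name)
        if se is None or se == 0:
            out[name] = {"estimate": est, "se": se, "z": None, "p": None}
            continue
        z = est / se
        out[name] = {
            "estimate": est,
            "se": se,
            "z": float(z),
            "p": float(2.0 * stats.norm.sf(abs(z))),
        }
    return out


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of the reduced against the full model.

    Returns (chi2, df, p) with chi2 the difference in the -2lnL-metric fit
    values and df the difference in free-parameter counts.
    """
    if not set(reduced.free_params) <= set(full.free_params):
        raise ValueError("reduced model's free set must nest within the full model's")
    df = len(full.free_params) - len(reduced.free_params)
    chi2 = reduced.minus2ll_fit - full.minus2ll_fit
    if chi2 < -1e-6 * (1.0 + abs(full.minus2ll_fit)):
        raise ValueError(
            f"negative LRT chi-square ({chi2:.3g}); refit with fresh starts"
        )
    chi2 = max(chi2, 0.0)
    if df == 0:
        return chi2, 0, 1.0
    return float(chi2), df, float(stats.chi2.sf(chi2, df))
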