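"""Asymptotic power for detecting prenatal/postnatal maternal genetic effects.

The noncentrality parameter of the full-vs-reduced model comparison is
obtained by fitting the reduced model (parameters of interest constrained to
zero) to exact population covariance matrices generated under the true
parameters; the full model fits those matrices perfectly, so the reduced
model's minimized n-weighted discrepancy is the NCP.  Power is the upper
tail of the corresponding noncentral chi-square beyond the central
(1 - alpha) quantile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .ml_fitting import FULL_FREE, GroupData, ModelSpec, fit_model
from .path_model import (
    PARAM_NAMES,
    STRUCTURE_CODES,
    ModelParams,
    check_identification,
    expected_covariance,
    normalize_residual_variances,
)

__all__ = [
    "PowerResult",
    "IdentificationError",
    "validate_sizes",
    "asymptotic_ncp",
    "power_from_ncp",
    "asymptotic_power",
    "power_grid",
    "effect_for_power",
]


class IdentificationError(ValueError):
    """Raised when a power quantity is requested for an unidentified model."""


@dataclass
class PowerResult:
    """Noncentrality parameter, degrees of freedom, alpha and power of a
    constraint test."""

    ncp: float
    df: int
    alpha: float
    power: float


def validate_sizes(sizes: Mapping[str, int]) -> dict[str, int]:
    out = {}
    for code, n in sizes.items():
        if code not in STRUCTURE_CODES:
            raise ValueError(
                f"unknown family structure {code!r}; valid codes are "
                f"{', '.join(STRUCTURE_CODES)}"
            )
        n = int(n)
        if n < 0:
            raise ValueError(f"negative sample size for {code}")
        if n > 0:
            out[code] = n
    if not out:
        raise ValueError("at least one group must have a positive sample size")
    return out


def population_groups(params: ModelParams, sizes: Mapping[str, int]) -> list[GroupData]:
    """Exact population covariance blocks, one per structure with n > 0."""
    sizes = validate_sizes(sizes)
    groups = []
    for code in sorted(sizes, key=STRUCTURE_CODES.index):
        block = expected_covariance(params, code)
        block.n = sizes[code]
        groups.append(GroupData(code, block))
    return groups


def _guard_identification(codes: Sequence[str], free: Sequence[str]) -> None:
    report = check_identification(codes, free)
    if not report.identified:
        raise IdentificationError(
            f"model with free parameters {tuple(free)} is not identified from "
            f"structures {tuple(codes)} (rank {report.rank} < {report.n_free}); "
            f"null directions: {report.null_space}"
        )


def asymptotic_ncp(
    true_params: ModelParams,
    sizes: Mapping[str, int],
    constraint: Sequence[str],
    *,
    seed: int = 0,
) -> float:
    """Noncentrality parameter for testing ``constraint`` parameters = 0.

    Builds population covariance blocks at ``true_params`` for every
    structure with n > 0, fits the reduced model (constraint applied, all
    other parameters except ``r`` free) and returns its minimized total fit
    value.  Refuses with :class:`IdentificationError` when the full model is
    not identified from the supplied structures.
    """
    constraint = tuple(constraint)
    if not constraint:
        raise ValueError("constraint must name at least one parameter")
    full_spec = ModelSpec.full(fixed={"r": true_params.r})
    bad = [c for c in constraint if c not in full_spec.free_params]
    if bad:
        raise ValueError(f"constraint parameters not free in the full model: {bad}")
    groups = population_groups(true_params, sizes)
    codes = [g.structure for g in groups]
    _guard_identification(codes, full_spec.free_params)

    reduced_spec = full_spec.reduced(constraint)
    start = {k: v for k, v in true_params.as_dict().items() if k in reduced_spec.free_params}
    fit = fit_model(groups, reduced_spec, start=start, seed=seed, compute_se=False)
    if not fit.converged:
        raise RuntimeError(
            f"reduced-model fit did not converge: {fit.message} "
            f"(gradient norm {fit.gradient_norm:.3g})"
        )
    return max(float(fit.minus2ll_fit), 0.0)


def power_from_ncp(ncp: float, df: int, alpha: float) -> float:
    """P[ chi2(df, ncp) > chi2_{1-alpha}(df) ]."""
    if ncp < 0:
        raise ValueError("noncentrality parameter must be nonnegative")
    if df < 1:
        raise ValueError("df must be a positive integer")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    if ncp == 0:
        return float(stats.chi2.sf(crit, df))
    return float(stats.ncx2.sf(crit, df, ncp))


def asymptotic_power(
    true_params: ModelParams,
    sizes: Mapping[str, int],
    constraint: Sequence[str],
    alpha: float = 0.05,
    *,
    seed: int = 0,
) -> PowerResult:
    """Asymptotic power of the LRT of ``constraint`` = 0 at level ``alpha``."""
    constraint = tuple(constraint)
    ncp = asymptotic_ncp(true_params, sizes, constraint, seed=seed)
    df = len(constraint)
    return PowerResult(ncp=ncp, df=df, alpha=alpha, power=power_from_ncp(ncp, df, alpha))


def power_grid(
    base_params: ModelParams,
    sizes: Mapping[str, int],
    vary: Mapping[str, Sequence[float]],
    constraint: Sequence[str],
    alpha: float = 0.05,
    *,
    unit_variance: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep parameters and/or group sizes and tabulate NCP and power.

    ``vary`` maps either parameter names (e.g. ``gamma_m``) or structure
    codes (e.g. ``G7``, varying that group's n) to lists of values; the grid
    is the Cartesian product.  When ``unit_variance`` is set the residual
    variances are renormalized at every grid point so the total phenotypic
    variance is 1 in both family types.  Rows that fail to fit carry the
    error message and NaN power; the sweep continues.
    """
    keys = list(vary)
    for key in keys:
        if key not in PARAM_NAMES and key not in STRUCTURE_CODES:
            raise ValueError(f"cannot vary {key!r}: not a parameter or structure code")
    rows = []
    for values in itertools.product(*(vary[k] for k in keys)):
        setting = dict(zip(keys, values))
        params = base_params.replace(
            **{k: v for k, v in setting.items() if k in PARAM_NAMES}
        )
        cur_sizes = dict(sizes)
        cur_sizes.update({k: int(v) for k, v in setting.items() if k in STRUCTURE_CODES})
        row: dict[str, object] = dict(setting)
        try:
            if unit_variance:
                params = normalize_residual_variances(params)
            res = asymptotic_power(params, cur_sizes, constraint, alpha, seed=seed)
            row.update(ncp=res.ncp, df=res.df, power=res.power, error=None)
        except Exception as exc:  # keep sweeping, record the failure
            row.update(ncp=float("nan"), df=len(tuple(constraint)),
                       power=float("nan"), error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def effect_for_power(
    target_power: float,
    which: str,
    sizes: Mapping[str, int],
    alpha: float = 0.05,
    *,
    base_params: ModelParams | None = None,
    bracket: tuple[float, float] = (0.0, 0.9),
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Effect size at which the test of ``which`` = 0 reaches ``target_power``.

    Bisects on the path coefficient magnitude; returns ``(effect,
    variance_explained)`` where variance explained is effect^2 * phi (the
    squared-path convention with unit genotype variance).  Residual variances
    are renormalized at each trial effect so total phenotypic variance is 1.
    """
    if which not in ("gamma_m", "beta_m", "beta_p", "beta_o"):
        raise ValueError(f"cannot search on {which!r}")
    if base_params is None:
        base_params = ModelParams()
    if not 0 < target_power < 1:
        raise ValueError("target power must be in (0, 1)")

    def power_at(effect: float) -> float:
        params = normalize_residual_variances(base_params.replace(**{which: effect}))
        return asymptotic_power(params, sizes, (which,), alpha, seed=seed).power

    lo, hi = bracket
    if target_power <= alpha + tol:
        return 0.0, 0.0
    p_hi = power_at(hi)
    if p_hi < target_power:
        raise ValueError(
            f"target power {target_power} unattainable within bracket {bracket}: "
            f"power at {hi} is {p_hi:.4f}"
        )
    effect = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = power_at(mid)
        if abs(p_mid - target_power) < tol:
            effect = mid
            break
        if p_mid < target_power:
            lo = mid
        else:
            hi = mid
        effect = 0.5 * (lo + hi)
    return float(effect), float(effect**2 * base_params.phi)
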