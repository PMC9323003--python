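"""Simulation studies: type I error, empirical power, and bias when adopted
singletons were in fact raised by biological relatives.

Each replicate simulates family data, reduces it to per-group sample
covariances, fits the full and reduced models and records likelihood-ratio
(and optionally Wald) rejection decisions.  ``pseudo_true_fit`` is the
deterministic, simulation-free twin: it fits the (possibly misspecified)
analysis model to the exact population covariance matrices of the generating
mixture, yielding the limiting values of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .family_simulator import (
    RELATEDNESS_FACTORS,
    sample_covariance,
    simulate_dataset,
    simulate_misspecified_adoptees,
)
from .ml_fitting import FitResult, GroupData, ModelSpec, fit_model, lrt, wald_tests
from .path_model import CovarianceBlock, ModelParams, expected_covariance
from .power_analysis import asymptotic_power, population_groups, validate_sizes

__all__ = [
    "StudyResult",
    "type1_error_study",
    "empirical_power_study",
    "misspec_bias_study",
    "pseudo_true_fit",
    "binomial_ci",
]


@dataclass
class StudyResult:
    """Per-condition summary table of a replicated simulation study."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)
    flagged: bool = False  # set when > 5% of replicates failed to converge


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson (exact) binomial confidence interval."""
    if n == 0:
        return 0.0, 1.0
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def _fit_replicate(
    groups: list[GroupData],
    constraint: Sequence[str],
    r_fixed: float,
    seed: int,
    wald: bool,
) -> dict:
    """Full fit, one reduced fit per constrained set, LRT p-value."""
    full_spec = ModelSpec.full(fixed={"r": r_fixed})
    full = fit_model(groups, full_spec, seed=seed, compute_se=wald, polish=False)
    out = {"full": full, "p": {}, "wald_p": {}, "converged": full.converged}
    warm = dict(full.estimates)
    for name in constraint:
        red = fit_model(
            groups,
            full_spec.reduced([name]),
            start={k: v for k, v in warm.items() if k != name},
            seed=seed,
            compute_se=False,
            polish=False,
        )
        out["converged"] = out["converged"] and red.converged
        try:
            _, _, p = lrt(full, red)
        except ValueError:
            out["converged"] = False
            p = float("nan")
        out["p"][name] = p
    if wald and full.converged and full.standard_errors is not None:
        wt = wald_tests(full)
        for name in constraint:
            out["wald_p"][name] = wt[name]["p"]
    return out


def _summarize(
    records: list[dict],
    constraint: Sequence[str],
    alpha: float,
    condition: Mapping,
) -> dict:
    """One summary row: means/SDs of estimates, LRT/Wald rejection rates."""
    ok = [r for r in records if r["converged"]]
    n_fail = len(records) - len(ok)
    row: dict[str, object] = dict(condition)
    row["reps_requested"] = len(records)
    row["reps_used"] = len(ok)
    row["n_convergence_failures"] = n_fail
    if ok:
        names = ok[0]["full"].free_params
        est = np.array([[r["full"].estimates[n] for n in names] for r in ok])
        for j, name in enumerate(names):
            row[f"mean_{name}"] = float(est[:, j].mean())
            row[f"sd_{name}"] = float(est[:, j].std(ddof=1)) if len(ok) > 1 else float("nan")
    for name in constraint:
        ps = np.array([r["p"][name] for r in ok])
        k = int(np.sum(ps < alpha))
        rate = k / len(ok) if ok else float("nan")
        lo, hi = binomial_ci(k, len(ok))
        row[f"reject_rate_{name}"] = rate
        row[f"reject_ci_low_{name}"] = lo
        row[f"reject_ci_high_{name}"] = hi
        wps = [r["wald_p"].get(name) for r in ok if r["wald_p"].get(name) is not None]
        if wps:
            row[f"wald_reject_rate_{name}"] = float(np.mean(np.array(wps) < alpha))
    return row


def _run_replicates(
    true_params: ModelParams,
    sizes: Mapping[str, int],
    constraint: Sequence[str],
    reps: int,
    seed: int,
    wald: bool,
    make_groups: Callable | None = None,
) -> list[dict]:
    sizes = validate_sizes(sizes)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(reps)
    records = []
    for i, child in enumerate(children):
        if make_groups is None:
            sim = simulate_dataset(true_params, sizes, seed=child)
            groups = [GroupData(g.label, sample_covariance(g)) for g in sim]
            r_fixed = 0.0
        else:
            groups, r_fixed = make_groups(child)
        try:
            rec = _fit_replicate(groups, constraint, r_fixed, seed=i, wald=wald)
        except (ValueError, RuntimeError) as exc:
            rec = {"full": None, "p": {c: float("nan") for c in constraint},
                   "wald_p": {}, "converged": False, "error": str(exc)}
        records.append(rec)
    return records


def type1_error_study(
    true_params: ModelParams,
    sizes: Mapping[str, int],
    constraint: Sequence[str] = ("gamma_m",),
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    wald: bool = True,
) -> StudyResult:
    """Empirical rejection rate of the LRT when the tested effect is truly 0.

    The tested parameters must be zero in ``true_params``; the rejection rate
    should fall inside the binomial band around ``alpha``.
    """
    for name in constraint:
        if getattr(true_params, name) != 0.0:
            raise ValueError(f"type I error study requires true {name} = 0")
    records = _run_replicates(true_params, sizes, constraint, reps, seed, wald)
    row = _summarize(records, constraint, alpha,
                     {"study": "type1", "alpha": alpha, "seed": seed})
    table = pd.DataFrame([row])
    n_fail = int(row["n_convergence_failures"])
    return StudyResult(
        table=table,
        meta={"true_params": true_params.as_dict(), "sizes": dict(sizes),
              "constraint": tuple(constraint)},
        flagged=n_fail > 0.05 * reps,
    )


def empirical_power_study(
    true_params: ModelParams,
    sizes: Mapping[str, int],
    constraint: Sequence[str] = ("gamma_m",),
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    wald: bool = False,
) -> StudyResult:
    """Empirical power side-by-side with the asymptotic calculation.

    The concordance flag marks whether the empirical rate falls within the
    binomial 95% band of the asymptotic power at the replicate count used.
    """
    records = _run_replicates(true_params, sizes, constraint, reps, seed, wald)
    asym = asymptotic_power(true_params, sizes, constraint, alpha)
    row = _summarize(records, constraint, alpha,
                     {"study": "power", "alpha": alpha, "seed": seed})
    reps_used = int(row["reps_used"])
    half = 1.96 * np.sqrt(asym.power * (1 - asym.power) / max(reps_used, 1))
    row["asymptotic_power"] = asym.power
    row["asymptotic_ncp"] = asym.ncp
    emp = row[f"reject_rate_{constraint[0]}"]
    row["concordant"] = bool(abs(emp - asym.power) <= half)
    table = pd.DataFrame([row])
    n_fail = int(row["n_convergence_failures"])
    return StudyResult(
        table=table,
        meta={"true_params": true_params.as_dict(), "sizes": dict(sizes),
              "constraint": tuple(constraint)},
        flagged=n_fail > 0.05 * reps,
    )


def misspec_bias_study(
    true_params: ModelParams,
    sizes: Mapping[str, int],
    scenario: str,
    relationship: str,
    fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
    reps: int = 200,
    seed: int = 0,
    model_r: bool = False,
    alpha: float = 0.05,
    constraint: Sequence[str] = ("gamma_m", "beta_m"),
    wald: bool = False,
) -> StudyResult:
    """Bias and rejection rates when a fraction of adopted singletons were
    raised by a biological relative (scenario G8-G11).

    With ``model_r=False`` all adoptees are analyzed as plain G5 — the
    misspecified analysis.  With ``model_r=True`` the related adoptees are
    analyzed as their true structure with the relatedness path fixed at its
    known value — the corrected analysis.
    """
    sizes = validate_sizes(sizes)
    if "G5" not in sizes:
        raise ValueError("the misspecification study needs a G5 group size")
    n5 = sizes["G5"]
    other_sizes = {c: n for c, n in sizes.items() if c != "G5"}
    r_value = RELATEDNESS_FACTORS[relationship] * true_params.phi

    rows = []
    for idx, fraction in enumerate(fractions):
        # one deterministic seed stream per fraction
        sub = np.random.SeedSequence(entropy=(seed, idx))

        def make_groups(child):
            c_other, c_adopt = child.spawn(2)
            sim = simulate_dataset(true_params, other_sizes, seed=c_other)
            groups = [GroupData(g.label, sample_covariance(g)) for g in sim]
            adopt = simulate_misspecified_adoptees(
                true_params, n5, fraction, scenario, relationship, seed=c_adopt
            )
            if not model_r:
                groups.append(GroupData("G5", sample_covariance(adopt)))
                return groups, 0.0
            rel = adopt.data["related"].to_numpy()
            plain = adopt.data.loc[~rel, ["Zo", "Y"]]
            related = adopt.data.loc[rel, ["Zo", "Y"]]
            if len(plain) > 0:
                groups.append(GroupData("G5", sample_covariance(plain, as_analyzed=False)))
            if len(related) > 0:
                block = sample_covariance(related, as_analyzed=False)
                groups.append(GroupData(scenario, block))
            return groups, r_value

        records = _run_replicates(
            true_params, sizes, constraint, reps, sub, wald, make_groups=make_groups,
        )
        row = _summarize(
            records, constraint, alpha,
            {"study": "misspec", "scenario": scenario, "relationship": relationship,
             "fraction_related": fraction, "model_r": model_r, "alpha": alpha},
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    flagged = bool((table["n_convergence_failures"] > 0.05 * reps).any())
    return StudyResult(
        table=table,
        meta={"true_params": true_params.as_dict(), "sizes": dict(sizes),
              "scenario": scenario, "relationship": relationship,
              "model_r": model_r, "reps": reps, "seed": seed,
              "r_value": r_value},
        flagged=flagged,
    )


def pseudo_true_fit(
    true_params: ModelParams,
    sizes: Mapping[str, int],
    scenario: str | None = None,
    relationship: str = "sibling",
    fraction: float = 0.0,
    model_r: bool = False,
    seed: int = 0,
) -> tuple[FitResult, float]:
    """Limiting (pseudo-true) estimates of the analysis model fitted to the
    exact population covariance matrices of the generating process.

    The generating process places ``fraction`` of the G5 adoptees under
    ``scenario`` (G8-G11, relatedness path at its sibling/cousin value) and
    the rest under plain G5.  With ``model_r=False`` the analysis pools them
    as a single G5 group (the misspecified analysis); with ``model_r=True``
    the two strata are analyzed separately with ``r`` fixed at truth.

    Returns the fit and its minimized misfit (the NCP-style discrepancy; zero
    whenever the analysis model can reproduce the generating covariances).
    """
    sizes = validate_sizes(sizes)
    if scenario is None or fraction == 0.0:
        groups = population_groups(true_params.replace(r=0.0), sizes)
        r_fixed = 0.0
    else:
        if scenario not in ("G8", "G9", "G10", "G11"):
            raise ValueError("scenario must be one of G8, G9, G10, G11")
        if "G5" not in sizes:
            raise ValueError("the mixture scenario needs a G5 group size")
        r_value = RELATEDNESS_FACTORS[relationship] * true_params.phi
        n5 = sizes["G5"]
        groups = population_groups(
            true_params.replace(r=0.0), {c: n for c, n in sizes.items() if c != "G5"}
        )
        sigma_plain = expected_covariance(true_params.replace(r=0.0), "G5").matrix
        sigma_rel = expected_covariance(true_params.replace(r=r_value), scenario).matrix
        if model_r:
            n_rel = int(round(fraction * n5))
            n_plain = n5 - n_rel
            if n_plain > 0:
                groups.append(
                    GroupData("G5", CovarianceBlock(("Zo", "Y"), sigma_plain, n_plain))
                )
            if n_rel > 0:
                groups.append(
                    GroupData(scenario, CovarianceBlock(("Zo", "Y"), sigma_rel, n_rel))
                )
            r_fixed = r_value
        else:
            mix = (1.0 - fraction) * sigma_plain + fraction * sigma_rel
            groups.append(GroupData("G5", CovarianceBlock(("Zo", "Y"), mix, n5)))
            r_fixed = 0.0

    spec = ModelSpec.full(fixed={"r": r_fixed})
    start = {k: v for k, v in true_params.as_dict().items() if k in spec.free_params}
    fit = fit_model(groups, spec, start=start, seed=seed, compute_se=False)
    if not fit.converged:
        raise RuntimeError(f"pseudo-true fit did not converge: {fit.message}")
    return fit, float(fit.minus2ll_fit)
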