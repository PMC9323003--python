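"""Synthetic family-level genotype-score and phenotype data.

Founder genotype scores are drawn jointly multivariate normal (mean 0,
covariance from the structure's exogenous founder matrix), offspring
genotypes follow the Mendelian rule Zo = 0.5*Zm + 0.5*Zp + N(0, phi/2), and
phenotypes follow the structure's linear model.  Genotype scores are
continuous (polygenic-score scale); no discrete alleles are simulated.

Reproducibility: a master seed is expanded into per-group seeds with
``numpy.random.SeedSequence(master).spawn(...)`` in sorted structure-code
order, so every table is reproducible row by row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .path_model import (
    STRUCTURE_CODES,
    CovarianceBlock,
    FamilyStructure,
    ModelParams,
    exogenous_covariance,
    structure_roster,
)

__all__ = [
    "SimulatedGroup",
    "simulate_families",
    "simulate_dataset",
    "simulate_misspecified_adoptees",
    "sample_covariance",
    "RELATEDNESS_FACTORS",
]

#: Relatedness of the adoptive to the biological parent, as a multiple of phi.
RELATEDNESS_FACTORS = {"sibling": 0.5, "cousin": 0.125}

_SeedLike = "int | np.random.SeedSequence | None"


@dataclass
class SimulatedGroup:
    """Simulated families for one structure.

    ``data`` holds every generated variable (founders, Zo, Y and, for
    misclassified adoptee mixtures, a boolean ``related`` column); columns
    not observed under ``label``'s roster are latent and excluded from the
    as-analyzed view.
    """

    label: str
    data: pd.DataFrame
    params: ModelParams
    seed: object
    meta: dict = field(default_factory=dict)

    @property
    def structure(self) -> FamilyStructure:
        return structure_roster(self.label)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def latent_columns(self) -> tuple[str, ...]:
        observed = set(self.structure.observed_vars)
        return tuple(c for c in self.data.columns if c not in observed)

    def as_analyzed(self) -> pd.DataFrame:
        """Only the columns an analyst observes under this group's label."""
        return self.data[list(self.structure.observed_vars)]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_families(
    params: ModelParams,
    structure: FamilyStructure | str,
    n: int,
    seed=None,
) -> SimulatedGroup:
    """Simulate ``n`` families from one structure; deterministic given seed."""
    if isinstance(structure, str):
        structure = structure_roster(structure)
    if n < 1:
        raise ValueError("n must be at least 1")
    founders = structure.founders
    sf = exogenous_covariance(params, structure).matrix
    try:
        chol = np.linalg.cholesky(sf)
    except np.linalg.LinAlgError:
        raise ValueError(
            "founder genotype covariance is not positive definite "
            f"(phi={params.phi}, rho={params.rho}, r={params.r})"
        ) from None
    rng = _rng(seed)
    z = rng.standard_normal((n, len(founders))) @ chol.T
    seg = rng.standard_normal(n) * np.sqrt(params.phi / 2.0)
    zo = 0.5 * (z[:, 0] + z[:, 1]) + seg

    if structure.adopted:
        coef = np.array([params.gamma_m, 0.0, params.beta_m, params.beta_p])
        eps = params.eps2_sq
    else:
        coef = np.array([params.gamma_m + params.beta_m, params.beta_p])
        eps = params.eps1_sq
    y = z @ coef + params.beta_o * zo + rng.standard_normal(n) * np.sqrt(eps)

    data = pd.DataFrame(z, columns=list(founders))
    data["Zo"] = zo
    data["Y"] = y
    return SimulatedGroup(structure.code, data, params, seed)


def simulate_dataset(
    params: ModelParams,
    sizes: Mapping[str, int],
    seed=None,
) -> list[SimulatedGroup]:
    """One independent :class:`SimulatedGroup` per structure with n > 0.

    Per-group seeds are children of ``SeedSequence(seed)`` in sorted
    structure-code order and are recorded on each group.
    """
    codes = sorted(
        (c for c, n in sizes.items() if int(n) > 0), key=STRUCTURE_CODES.index
    )
    if not codes:
        raise ValueError("at least one group must have a positive sample size")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(len(codes))
    groups = []
    for code, child in zip(codes, children):
        g = simulate_families(params, code, int(sizes[code]), seed=child)
        g.seed = {"master": master.entropy, "spawn_key": child.spawn_key}
        groups.append(g)
    return groups


def simulate_misspecified_adoptees(
    params: ModelParams,
    n: int,
    fraction_related: float,
    scenario: str,
    relationship: str,
    seed=None,
) -> SimulatedGroup:
    """Adopted singletons of which a fraction were raised by a biological
    relative, all labelled G5 so the analyst cannot tell them apart.

    ``round(fraction_related * n)`` families are generated under ``scenario``
    (one of G8-G11) with the relatedness path fixed at r = 0.5*phi (sibling)
    or 0.125*phi (cousin); the remainder are plain G5 families.  The boolean
    ``related`` column records the truth but is latent in the as-analyzed
    view.
    """
    if scenario not in ("G8", "G9", "G10", "G11"):
        raise ValueError("scenario must be one of G8, G9, G10, G11")
    if relationship not in RELATEDNESS_FACTORS:
        raise ValueError(f"relationship must be one of {sorted(RELATEDNESS_FACTORS)}")
    if not 0.0 <= fraction_related <= 1.0:
        raise ValueError("fraction_related must lie in [0, 1]")
    r_value = RELATEDNESS_FACTORS[relationship] * params.phi
    n_rel = int(round(fraction_related * n))
    n_plain = n - n_rel

    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_plain, child_rel = master.spawn(2)
    parts = []
    if n_plain > 0:
        g = simulate_families(params.replace(r=0.0), "G5", n_plain, seed=child_plain)
        d = g.data.copy()
        d["related"] = False
        parts.append(d)
    if n_rel > 0:
        g = simulate_families(params.replace(r=r_value), scenario, n_rel, seed=child_rel)
        d = g.data.copy()
        d["related"] = True
        parts.append(d)
    data = pd.concat(parts, ignore_index=True)
    return SimulatedGroup(
        "G5",
        data,
        params,
        {"master": master.entropy},
        meta={
            "scenario": scenario,
            "relationship": relationship,
            "fraction_related": float(fraction_related),
            "r_value": float(r_value),
            "n_related": n_rel,
        },
    )


def sample_covariance(
    group: SimulatedGroup | pd.DataFrame,
    as_analyzed: bool = True,
    label: str | None = None,
) -> CovarianceBlock:
    """ML (divide-by-n) covariance of a simulated group's columns.

    With ``as_analyzed`` only the observed columns of the group's label are
    used; otherwise every generated variable column is included.
    """
    if isinstance(group, SimulatedGroup):
        if as_analyzed:
            df = group.as_analyzed()
        else:
            cols = [c for c in group.data.columns if c != "related"]
            df = group.data[cols]
    else:
        df = group if label is None else group[list(structure_roster(label).observed_vars)]
    n, p = df.shape
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} rows, got {n}")
    x = df.to_numpy(dtype=float)
    if np.any(np.ptp(x, axis=0) == 0.0):
        const = [c for c, r in zip(df.columns, np.ptp(x, axis=0)) if r == 0.0]
        raise ValueError(f"degenerate (constant) columns: {const}")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / n
    return CovarianceBlock(tuple(df.columns), cov, n)
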