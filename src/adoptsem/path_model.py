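"""Structural model relating parental and offspring genotype scores to an
offspring phenotype in biological and adoptive families.

The model partitions the maternal genetic effect on a continuous offspring
phenotype into a prenatal path (``gamma_m``, carried by the biological
mother's genotype) and a postnatal path (``beta_m``, carried by the rearing
mother's genotype).  Fathers act postnatally only (``beta_p``) and the
offspring's own genotype acts directly (``beta_o``).  Genotypes are
continuous polygenic scores, centered, with parental-generation variance
``phi``; spouses' scores may covary (``rho``, one round of assortment) and,
in the misspecification structures G8-G11, an adoptive parent's score may
covary with a biological parent's score (``r``).

Eleven family structures are supported:

=====  ============================================  =========
code   observed variables                            offspring
=====  ============================================  =========
G1     Zm, Zp, Zo, Y                                 biological
G2     Zm, Zo, Y                                     biological
G3     Zp, Zo, Y                                     biological
G4     Zo, Y                                         biological
G5     Zo, Y                                         adopted
G6     Zm_a, Zo, Y                                   adopted
G7     Zm_b, Zo, Y                                   adopted
G8-11  Zo, Y  (adoptive parent related to a
       biological parent through the ``r`` path)     adopted
=====  ============================================  =========

All modelling is covariance-only: phenotypes are assumed pre-residualized,
so means are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "VARIANCE_PARAMS",
    "STRUCTURE_CODES",
    "ModelParams",
    "FamilyStructure",
    "CovarianceBlock",
    "IdentificationReport",
    "structure_roster",
    "exogenous_covariance",
    "expected_covariance",
    "check_identification",
    "normalize_residual_variances",
]

#: Canonical parameter ordering used throughout the package.
PARAM_NAMES = (
    "gamma_m",
    "beta_m",
    "beta_p",
    "beta_o",
    "rho",
    "phi",
    "eps1_sq",
    "eps2_sq",
    "r",
)

#: Parameters constrained to be (non-)negative during fitting.
VARIANCE_PARAMS = ("phi", "eps1_sq", "eps2_sq")

_BIO_FOUNDERS = ("Zm", "Zp")
_ADO_FOUNDERS = ("Zm_b", "Zp_b", "Zm_a", "Zp_a")

# code -> (observed vars, adopted flag, relatedness pair)
_ROSTER = {
    "G1": (("Zm", "Zp", "Zo", "Y"), False, None),
    "G2": (("Zm", "Zo", "Y"), False, None),
    "G3": (("Zp", "Zo", "Y"), False, None),
    "G4": (("Zo", "Y"), False, None),
    "G5": (("Zo", "Y"), True, None),
    "G6": (("Zm_a", "Zo", "Y"), True, None),
    "G7": (("Zm_b", "Zo", "Y"), True, None),
    "G8": (("Zo", "Y"), True, ("Zm_a", "Zm_b")),
    "G9": (("Zo", "Y"), True, ("Zm_a", "Zp_b")),
    "G10": (("Zo", "Y"), True, ("Zp_a", "Zp_b")),
    "G11": (("Zo", "Y"), True, ("Zp_a", "Zm_b")),
}

STRUCTURE_CODES = tuple(_ROSTER)


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector of the path model.

    Parameters
    ----------
    gamma_m
        Prenatal maternal genetic effect per unit of genotype score.
    beta_m
        Postnatal maternal genetic effect.
    beta_p
        Postnatal paternal genetic effect.
    beta_o
        Direct offspring genetic effect.
    rho
        Covariance between spouses' genotype scores (assumed equal in
        biological and adoptive couples).
    phi
        Variance of a parental-generation genotype score (> 0).
    eps1_sq
        Residual phenotype variance, offspring raised by biological parents.
    eps2_sq
        Residual phenotype variance, adopted offspring.
    r
        Covariance between the designated adoptive and biological parent's
        genotypes; only used by structures G8-G11.
    """

    gamma_m: float = 0.0
    beta_m: float = 0.0
    beta_p: float = 0.0
    beta_o: float = 0.0
    rho: float = 0.0
    phi: float = 1.0
    eps1_sq: float = 1.0
    eps2_sq: float = 1.0
    r: float = 0.0

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if self.eps1_sq < 0 or self.eps2_sq < 0:
            raise ValueError("residual variances must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def replace(self, **kwargs: float) -> "ModelParams":
        return _dc_replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParams":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class FamilyStructure:
    """One of the eleven family-structure layouts G1-G11."""

    code: str
    observed_vars: tuple[str, ...]
    latent_vars: tuple[str, ...]
    adopted: bool
    relatedness_pair: tuple[str, str] | None = None

    @property
    def founders(self) -> tuple[str, ...]:
        return _ADO_FOUNDERS if self.adopted else _BIO_FOUNDERS


@dataclass
class CovarianceBlock:
    """A labelled symmetric covariance matrix, expected or sampled."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    n: int | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.labels)
        if self.matrix.shape != (p, p):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {p} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        if self.n is not None:
            self.n = int(self.n)
            if self.n <= 0:
                raise ValueError("sample size must be positive")

    def submatrix(self, labels: Sequence[str]) -> "CovarianceBlock":
        idx = [self.labels.index(l) for l in labels]
        return CovarianceBlock(tuple(labels), self.matrix[np.ix_(idx, idx)], self.n)

    def to_dict(self) -> dict:
        d = {"labels": list(self.labels), "cov": self.matrix.tolist()}
        if self.n is not None:
            d["n"] = self.n
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovarianceBlock":
        return cls(tuple(d["labels"]), np.asarray(d["cov"], float), d.get("n"))


def structure_roster(code: str) -> FamilyStructure:
    """Return the fixed variable roster of family structure ``code``."""
    try:
        observed, adopted, pair = _ROSTER[code]
    except KeyError:
        raise ValueError(
            f"unknown family structure {code!r}; valid codes are "
            f"{', '.join(STRUCTURE_CODES)}"
        ) from None
    founders = _ADO_FOUNDERS if adopted else _BIO_FOUNDERS
    latent = tuple(v for v in founders if v not in observed)
    return FamilyStructure(code, observed, latent, adopted, pair)


# ---------------------------------------------------------------------------
# Model-implied covariance
# ---------------------------------------------------------------------------

def _founder_cov(p: Mapping[str, float], code: str) -> np.ndarray:
    """Covariance of a structure's founder genotypes.

    Each founder has variance ``phi``; each couple covaries ``rho``; the
    designated adoptive-biological pair (G8-G11) covaries ``r``.  Standard
    path-tracing: no chained double-headed arrows, so all other pairs are 0.
    """
    _, adopted, pair = _ROSTER[code]
    founders = _ADO_FOUNDERS if adopted else _BIO_FOUNDERS
    k = len(founders)
    S = np.zeros((k, k))
    np.fill_diagonal(S, p["phi"])
    S[0, 1] = S[1, 0] = p["rho"]  # biological couple
    if adopted:
        S[2, 3] = S[3, 2] = p["rho"]  # adoptive couple
    if pair is not None:
        i, j = founders.index(pair[0]), founders.index(pair[1])
        S[i, j] = S[j, i] = p["r"]
    return S


def _implied_full(p: Mapping[str, float], code: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Covariance of all generated variables (founders, Zo, Y) of a structure.

    Offspring genotype: Zo = 0.5*(biological mother) + 0.5*(biological
    father) + segregation noise with variance phi/2.  Phenotype:
    Y = (gamma_m+beta_m)*Zm + beta_p*Zp + beta_o*Zo + e1 for non-adopted;
    Y = gamma_m*Zm_b + beta_m*Zm_a + beta_p*Zp_a + beta_o*Zo + e2 adopted.
    """
    _, adopted, _ = _ROSTER[code]
    founders = _ADO_FOUNDERS if adopted else _BIO_FOUNDERS
    k = len(founders)
    SF = _founder_cov(p, code)
    w = np.zeros(k)
    w[0] = w[1] = 0.5  # biological parents are always founders 0, 1
    c = np.zeros(k)
    if adopted:
        c[0] = p["gamma_m"]   # Zm_b, prenatal only
        c[2] = p["beta_m"]    # Zm_a, postnatal
        c[3] = p["beta_p"]    # Zp_a, postnatal
        eps = p["eps2_sq"]
    else:
        c[0] = p["gamma_m"] + p["beta_m"]  # Zm, prenatal + postnatal
        c[1] = p["beta_p"]                 # Zp
        eps = p["eps1_sq"]
    bo = p["beta_o"]

    SFw = SF @ w
    SFc = SF @ c
    var_zo = w @ SFw + p["phi"] / 2.0
    cov_f_zo = SFw
    cov_zo_y = SFw @ c + bo * var_zo
    cov_f_y = SFc + bo * SFw
    var_y = c @ SFc + bo * bo * var_zo + 2.0 * bo * (w @ SFc) + eps

    m = k + 2
    full = np.zeros((m, m))
    full[:k, :k] = SF
    full[:k, k] = full[k, :k] = cov_f_zo
    full[:k, k + 1] = full[k + 1, :k] = cov_f_y
    full[k, k] = var_zo
    full[k, k + 1] = full[k + 1, k] = cov_zo_y
    full[k + 1, k + 1] = var_y
    return founders + ("Zo", "Y"), full


def _sigma_observed(p: Mapping[str, float], code: str) -> np.ndarray:
    """Model-implied covariance over the observed variables only (fast path)."""
    labels, full = _implied_full(p, code)
    observed = _ROSTER[code][0]
    idx = [labels.index(v) for v in observed]
    return full[np.ix_(idx, idx)]


def exogenous_covariance(
    params: ModelParams, structure: FamilyStructure | str
) -> CovarianceBlock:
    """Covariance matrix of a structure's founder genotypes."""
    if isinstance(structure, str):
        structure = structure_roster(structure)
    return CovarianceBlock(
        structure.founders, _founder_cov(params.as_dict(), structure.code)
    )


def expected_covariance(
    params: ModelParams, structure: FamilyStructure | str
) -> CovarianceBlock:
    """Model-implied covariance of a structure's observed variables.

    Latent founder genotypes are marginalized out of the linear structural
    system, so the returned block is directly comparable to a sample
    covariance of the observed columns.
    """
    if isinstance(structure, str):
        structure = structure_roster(structure)
    return CovarianceBlock(
        structure.observed_vars, _sigma_observed(params.as_dict(), structure.code)
    )


def normalize_residual_variances(
    params: ModelParams, total_variance: float = 1.0
) -> ModelParams:
    """Set the residual variances so total phenotypic variance equals
    ``total_variance`` in both biological (G4) and adopted (G5, with r=0)
    families.

    Raises if the genetic paths alone already explain more than
    ``total_variance``.
    """
    p0 = params.replace(eps1_sq=0.0, eps2_sq=0.0)
    gen_bio = expected_covariance(p0, "G4").matrix[1, 1]
    gen_ado = expected_covariance(p0.replace(r=0.0), "G5").matrix[1, 1]
    e1 = total_variance - gen_bio
    e2 = total_variance - gen_ado
    if e1 < 0 or e2 < 0:
        raise ValueError(
            "genetic paths explain more than the requested total phenotypic "
            f"variance (biological: {gen_bio:.4f}, adopted: {gen_ado:.4f})"
        )
    return params.replace(eps1_sq=e1, eps2_sq=e2)


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------

@dataclass
class IdentificationReport:
    """Numerical local-identification report.

    ``identified`` holds iff the Jacobian of all stacked model-implied
    covariance entries with respect to the free parameters has full column
    rank at the probe point.  ``null_space`` lists unit directions in
    parameter space along which the moments are locally flat.
    """

    identified: bool
    rank: int
    n_free: int
    free_params: tuple[str, ...]
    structures: tuple[str, ...]
    singular_values: np.ndarray
    null_space: list[dict[str, float]] = field(default_factory=list)


_PROBE_POINT = {
    "gamma_m": 0.12,
    "beta_m": 0.09,
    "beta_p": 0.15,
    "beta_o": 0.07,
    "rho": 0.05,
    "phi": 1.0,
    "eps1_sq": 0.8,
    "eps2_sq": 1.1,
    "r": 0.3,
}


def moment_jacobian(
    structures: Sequence[str],
    free_params: Sequence[str],
    point: Mapping[str, float],
    step: float = 1e-6,
) -> np.ndarray:
    """Jacobian of stacked unique expected-covariance entries w.r.t.
    ``free_params``, by central differences at ``point``."""
    codes = list(structures)
    rows = []
    for code in codes:
        pdim = len(_ROSTER[code][0])
        rows.append(np.triu_indices(pdim))

    def moments(pt: Mapping[str, float]) -> np.ndarray:
        out = []
        for code, (iu, ju) in zip(codes, rows):
            out.append(_sigma_observed(pt, code)[iu, ju])
        return np.concatenate(out)

    base = dict(point)
    cols = []
    for name in free_params:
        h = step * max(1.0, abs(base[name]))
        hi = dict(base)
        lo = dict(base)
        hi[name] = base[name] + h
        lo[name] = base[name] - h
        cols.append((moments(hi) - moments(lo)) / (2.0 * h))
    return np.column_stack(cols)


def check_identification(
    structures_present: Iterable[str],
    free_params: Iterable[str],
    probe: Mapping[str, float] | None = None,
) -> IdentificationReport:
    """Check local identification of ``free_params`` given the observed
    family structures, via the numerical rank of the moment Jacobian at a
    generic interior parameter point."""
    codes = sorted(set(structures_present), key=STRUCTURE_CODES.index)
    if not codes:
        raise ValueError("structure set must be nonempty")
    for code in codes:
        if code not in _ROSTER:
            raise ValueError(
                f"unknown family structure {code!r}; valid codes are "
                f"{', '.join(STRUCTURE_CODES)}"
            )
    free = tuple(free_params)
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    if not free:
        raise ValueError("free parameter set must be nonempty")
    point = dict(_PROBE_POINT)
    if probe:
        point.update(probe)

    J = moment_jacobian(codes, free, point)
    u, s, vt = np.linalg.svd(J, full_matrices=False)
    tol = max(J.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    # generous relative cutoff: directions with < 1e-7 relative sensitivity
    # are treated as unidentified
    tol = max(tol, 1e-7 * (s[0] if s.size else 1.0))
    rank = int(np.sum(s > tol))
    null = []
    for i in range(rank, len(free)):
        vec = vt[i]
        null.append({name: float(v) for name, v in zip(free, vec)})
    return IdentificationReport(
        identified=(rank == len(free)),
        rank=rank,
        n_free=len(free),
        free_params=free,
        structures=tuple(codes),
        singular_values=s,
        null_space=null,
    )
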