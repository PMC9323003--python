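"""Structure rosters, implied covariances and identification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adoptsem import (
    CovarianceBlock,
    ModelParams,
    check_identification,
    exogenous_covariance,
    expected_covariance,
    normalize_residual_variances,
    structure_roster,
)
from adoptsem.ml_fitting import FULL_FREE

ALL_EFFECTS_01 = ModelParams(
    gamma_m=0.1, beta_m=0.1, beta_p=0.1, beta_o=0.1, rho=0.1, phi=1.0,
    eps1_sq=1.0, eps2_sq=1.0,
)


@pytest.mark.parametrize(
    "code,observed,adopted",
    [
        ("G1", ("Zm", "Zp", "Zo", "Y"), False),
        ("G2", ("Zm", "Zo", "Y"), False),
        ("G3", ("Zp", "Zo", "Y"), False),
        ("G4", ("Zo", "Y"), False),
        ("G5", ("Zo", "Y"), True),
        ("G6", ("Zm_a", "Zo", "Y"), True),
        ("G7", ("Zm_b", "Zo", "Y"), True),
        ("G8", ("Zo", "Y"), True),
        ("G9", ("Zo", "Y"), True),
        ("G10", ("Zo", "Y"), True),
        ("G11", ("Zo", "Y"), True),
    ],
)
def test_structure_rosters(code, observed, adopted):
    s = structure_roster(code)
    assert s.observed_vars == observed
    assert s.adopted is adopted
    # latent founders + observed founders partition the founder set
    assert set(s.latent_vars) | (set(s.observed_vars) & set(s.founders)) == set(s.founders)


@pytest.mark.parametrize(
    "code,pair",
    [("G8", ("Zm_a", "Zm_b")), ("G9", ("Zm_a", "Zp_b")),
     ("G10", ("Zp_a", "Zp_b")), ("G11", ("Zp_a", "Zm_b"))],
)
def test_relatedness_pairs(code, pair):
    assert structure_roster(code).relatedness_pair == pair


def test_unknown_structure_code():
    with pytest.raises(ValueError, match="G1"):
        structure_roster("G12")


def test_exogenous_covariance_couples_and_relatedness():
    p = ModelParams(rho=0.1, phi=1.0)
    g1 = exogenous_covariance(p, "G1")
    assert g1.labels == ("Zm", "Zp")
    assert np.allclose(g1.matrix, [[1, 0.1], [0.1, 1]])

    g5 = exogenous_covariance(ModelParams(rho=0.0, phi=1.0), "G5")
    assert np.allclose(g5.matrix, np.eye(4))

    g8 = exogenous_covariance(p.replace(r=0.5), "G8")
    lab = g8.labels
    m = g8.matrix
    assert m[lab.index("Zm_a"), lab.index("Zm_b")] == 0.5
    assert m[lab.index("Zm_a"), lab.index("Zp_b")] == 0.0
    assert m[lab.index("Zm_b"), lab.index("Zp_b")] == 0.1  # biological couple
    assert m[lab.index("Zm_a"), lab.index("Zp_a")] == 0.1  # adoptive couple


def test_expected_covariance_closed_forms():
    """Path-tracing values cross-checked by Monte Carlo at build time."""
    g1 = expected_covariance(ALL_EFFECTS_01, "G1")
    lab = g1.labels
    assert g1.matrix[lab.index("Zm"), lab.index("Y")] == pytest.approx(0.265)
    assert g1.matrix[lab.index("Zo"), lab.index("Y")] == pytest.approx(0.27)

    g5 = expected_covariance(ALL_EFFECTS_01, "G5")
    assert g5.matrix[0, 1] == pytest.approx(0.16)

    g8 = expected_covariance(ALL_EFFECTS_01.replace(r=0.5), "G8")
    assert g8.matrix[0, 1] == pytest.approx(0.185)


def test_offspring_variance_inflated_by_assortment():
    m = expected_covariance(ModelParams(rho=0.2), "G4").matrix
    assert m[0, 0] == pytest.approx(1.1)  # phi + rho/2


@pytest.mark.parametrize("code", ["G1", "G4", "G5", "G7", "G8"])
def test_null_model_covariance(code):
    p = ModelParams(eps1_sq=0.7, eps2_sq=1.3, rho=0.1, r=0.2)
    block = expected_covariance(p, code)
    lab = block.labels
    adopted = structure_roster(code).adopted
    assert block.matrix[lab.index("Zo"), lab.index("Y")] == 0.0
    assert block.matrix[lab.index("Y"), lab.index("Y")] == (1.3 if adopted else 0.7)


def test_adopted_singleton_free_of_postnatal_paths():
    """G5 Cov(Zo, Y) carries prenatal but not postnatal information."""
    base = expected_covariance(ALL_EFFECTS_01, "G5").matrix[0, 1]
    for kw in ({"beta_m": 0.4}, {"beta_p": -0.25}, {"beta_m": 0.0, "beta_p": 0.0}):
        perturbed = expected_covariance(ALL_EFFECTS_01.replace(**kw), "G5")
        assert perturbed.matrix[0, 1] == pytest.approx(base, abs=1e-14)


def test_scenario_pairs_share_genotype_phenotype_covariance():
    p = ALL_EFFECTS_01.replace(r=0.5)
    c = {c_: expected_covariance(p, c_).matrix for c_ in ("G8", "G9", "G10", "G11")}
    assert c["G8"][0, 1] == pytest.approx(c["G9"][0, 1], abs=1e-14)
    assert c["G10"][0, 1] == pytest.approx(c["G11"][0, 1], abs=1e-14)
    # the unmodelled paths are r/2*beta_m and r/2*beta_p on top of the G5 value
    g5 = expected_covariance(p.replace(r=0.0), "G5").matrix[0, 1]
    assert c["G8"][0, 1] - g5 == pytest.approx(0.5 / 2 * 0.1)
    assert c["G10"][0, 1] - g5 == pytest.approx(0.5 / 2 * 0.1)


@pytest.mark.parametrize("code", ["G1", "G2", "G3", "G6", "G7"])
def test_no_assortment_gives_diagonal_genotype_block(code):
    p = ModelParams(gamma_m=0.2, beta_m=0.1, beta_p=0.1, beta_o=0.1, rho=0.0, r=0.0, phi=1.3)
    block = expected_covariance(p, code)
    lab = block.labels
    geno = [i for i, l in enumerate(lab) if l != "Y"]
    sub = block.matrix[np.ix_(geno, geno)]
    off = sub - np.diag(np.diag(sub))
    labels = [lab[i] for i in geno]
    # parent-offspring transmission still links biological parents to Zo
    for a in range(len(geno)):
        for b in range(len(geno)):
            if a == b:
                continue
            pairset = {labels[a], labels[b]}
            if "Zo" in pairset and pairset & {"Zm", "Zp", "Zm_b"}:
                assert off[a, b] == pytest.approx(1.3 / 2)
            else:
                assert off[a, b] == 0.0
    assert sub[labels.index("Zo"), labels.index("Zo")] == pytest.approx(1.3)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    gamma=st.floats(-0.4, 0.4), bm=st.floats(-0.4, 0.4), bp=st.floats(-0.4, 0.4),
    bo=st.floats(-0.4, 0.4), rho=st.floats(-0.15, 0.15), phi=st.floats(0.6, 1.6),
    code=st.sampled_from(["G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8", "G9", "G10", "G11"]),
)
def test_expected_covariance_symmetric_psd(gamma, bm, bp, bo, rho, phi, code):
    p = ModelParams(gamma_m=gamma, beta_m=bm, beta_p=bp, beta_o=bo,
                    rho=rho, phi=phi, eps1_sq=0.8, eps2_sq=1.1, r=0.2 * phi)
    m = expected_covariance(p, code).matrix
    assert np.allclose(m, m.T)
    assert np.min(np.linalg.eigvalsh(m)) > -1e-10


def test_identification_requires_adoptees_for_partition():
    rep = check_identification({"G1", "G2", "G3", "G4"}, FULL_FREE)
    assert not rep.identified
    # one flat direction mixes the prenatal and postnatal maternal paths
    assert any(
        abs(d["gamma_m"]) > 0.1 and abs(d["beta_m"]) > 0.1 for d in rep.null_space
    )


def test_identification_with_trios_and_adopted_singletons():
    assert check_identification({"G1", "G5"}, FULL_FREE).identified


def test_identification_singletons_alone():
    rep = check_identification({"G4"}, ("beta_o", "phi", "eps1_sq"))
    assert rep.identified and rep.rank == 3


def test_identification_empty_structures_rejected():
    with pytest.raises(ValueError):
        check_identification(set(), FULL_FREE)


def test_normalize_residual_variances_unit_total():
    p = normalize_residual_variances(
        ModelParams(gamma_m=0.1, beta_m=0.1, beta_p=0.1, beta_o=0.1)
    )
    assert expected_covariance(p, "G4").matrix[1, 1] == pytest.approx(1.0)
    assert expected_covariance(p, "G5").matrix[1, 1] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        normalize_residual_variances(ModelParams(gamma_m=1.2))


def test_covariance_block_validation():
    with pytest.raises(ValueError):
        CovarianceBlock(("a", "b"), np.array([[1.0, 0.5], [0.4, 1.0]]))
    with pytest.raises(ValueError):
        CovarianceBlock(("a",), np.eye(2))
    b = CovarianceBlock(("a", "b"), np.eye(2), n=10)
    assert b.submatrix(["b"]).matrix[0, 0] == 1.0
    assert CovarianceBlock.from_dict(b.to_dict()).n == 10
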