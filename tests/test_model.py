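"""Design matrices, variance partition, MME solver and DGV prediction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from haploblup import (
    ModelVariant,
    build_design_matrix,
    partition_variance,
    predict_dgv,
    solve_model,
)
from haploblup.phasing import BlockPhase, PhasedData, SelectedHaplotype
from haploblup.synthetic import SimulationConfig, simulate_population, true_dosage_matrix
from haploblup.types import HaplotypeAllele, LDBlock


def test_variant_numbering_round_trips():
    for n in (1, 2, 3, 4):
        assert ModelVariant.from_number(n).variant_number == n
    assert ModelVariant.from_number(1).z_kind == "probability"
    assert ModelVariant.from_number(4) == ModelVariant("indicator", "size_weighted")
    with pytest.raises(ValueError):
        ModelVariant.from_number(5)
    with pytest.raises(ValueError):
        ModelVariant("probability", "nope")


def _phased_two_alleles(posteriors):
    block = LDBlock("b0", "1", (0, 1))
    alleles = [
        HaplotypeAllele("b0", "00", 0.5),
        HaplotypeAllele("b0", "11", 0.5),
    ]
    phase = BlockPhase(block_id="b0", alleles=alleles, posteriors=posteriors)
    return PhasedData(
        blocks=[block],
        phases={"b0": phase},
        animal_ids=[f"a{i}" for i in range(len(posteriors))],
    )


def _selected(index, string):
    return SelectedHaplotype("b0", index, string, 0.5, 0.5, 2)


def test_design_matrix_certain_and_posterior_cases():
    # animal0: homozygous j/j, animal1: heterozygous j/k,
    # animal2: posterior 0.6 on (j,k) and 0.4 on (k,k)
    posteriors = [
        [(0, 0, 1.0)],
        [(0, 1, 1.0)],
        [(0, 1, 0.6), (1, 1, 0.4)],
    ]
    phased = _phased_two_alleles(posteriors)
    sel = [_selected(0, "00")]
    z_prob = build_design_matrix(phased, sel, "probability")
    assert z_prob.to_numpy().ravel() == pytest.approx([1.0, 0.5, 0.3])
    z_ind = build_design_matrix(phased, sel, "indicator")
    assert z_ind.to_numpy().ravel() == pytest.approx([1.0, 1.0, 1.0])
    z_dos = build_design_matrix(phased, sel, "probability", dosage_mode="dosage")
    assert z_dos.to_numpy().ravel() == pytest.approx([2.0, 1.0, 0.6])


def test_indicator_uses_modal_diplotype():
    phased = _phased_two_alleles([[(0, 1, 0.4), (1, 1, 0.6)]])
    z = build_design_matrix(phased, [_selected(0, "00")], "indicator")
    assert z.to_numpy().ravel() == pytest.approx([0.0])


def test_partition_equal_matches_table_arithmetic():
    sel = [_selected(0, "00")] * 4
    v = partition_variance(sel, 213_490.0, "equal")
    assert v == pytest.approx([53_372.5] * 4)


def test_partition_size_weighted_examples():
    def sized(sizes):
        return [
            SelectedHaplotype("b", i, "0", 0.5, 0.5, s) for i, s in enumerate(sizes)
        ]

    assert partition_variance(sized([2, 2]), 10.0, "size_weighted") == pytest.approx(
        [5.0, 5.0]
    )
    assert partition_variance(sized([6, 2]), 8.0, "size_weighted") == pytest.approx(
        [6.0, 2.0]
    )
    with pytest.raises(ValueError):
        partition_variance([], 1.0, "equal")


@given(
    sizes=st.lists(st.integers(2, 20), min_size=1, max_size=30),
    var_g=st.floats(1e-6, 1e7),
    scheme=st.sampled_from(["equal", "size_weighted"]),
)
def test_partition_conserves_genetic_variance(sizes, var_g, scheme):
    sel = [SelectedHaplotype("b", i, "0", 0.5, 0.5, s) for i, s in enumerate(sizes)]
    v = partition_variance(sel, var_g, scheme)
    assert np.all(v > 0)
    assert v.sum() == pytest.approx(var_g, rel=1e-12)


def _random_instance(rng, n=None, h=None):
    n = n or int(rng.integers(5, 31))
    h = h or int(rng.integers(1, 11))
    z = rng.integers(0, 3, size=(n, h)).astype(float) / 2.0
    y = rng.normal(size=n)
    variances = rng.uniform(0.1, 2.0, size=h)
    sigma_e = rng.uniform(0.5, 2.0)
    return y, z, variances, sigma_e


def _dense_mme_solution(y, z, variances, sigma_e, weights=None):
    """Independent oracle: explicit inverse of the full MME matrix."""
    n, h = z.shape
    w = np.ones(n) if weights is None else weights
    x = np.hstack([np.ones((n, 1)), z])
    rinv = np.diag(w / sigma_e)
    a = x.T @ rinv @ x
    a[1:, 1:] += np.diag(1.0 / variances)
    return np.linalg.inv(a) @ (x.T @ rinv @ y)


def test_solver_matches_dense_inversion_on_random_instances(rng):
    for _ in range(200):
        y, z, variances, sigma_e = _random_instance(rng)
        fit = solve_model(y, z, variances, sigma_e)
        expected = _dense_mme_solution(y, z, variances, sigma_e)
        got = np.concatenate([[fit.mu_hat], fit.effects])
        assert np.allclose(got, expected, rtol=1e-8, atol=1e-10)


def test_solver_matches_generalized_ridge_closed_form(rng):
    """h_hat = (Z'MZ + D)^-1 Z'My with M absorbing the mean, on small cases."""
    for _ in range(30):
        y, z, variances, sigma_e = _random_instance(rng)
        n = len(y)
        m = np.eye(n) - np.ones((n, n)) / n
        d = np.diag(sigma_e / variances)
        h_ridge = np.linalg.solve(z.T @ m @ z + d, z.T @ m @ y)
        fit = solve_model(y, z, variances, sigma_e)
        assert np.allclose(fit.effects, h_ridge, rtol=1e-8, atol=1e-10)


def test_weighted_solver_matches_oracle(rng):
    y, z, variances, sigma_e = _random_instance(rng, n=20, h=4)
    w = rng.uniform(0.2, 5.0, size=20)
    fit = solve_model(y, z, variances, sigma_e, weights=w)
    expected = _dense_mme_solution(y, z, variances, sigma_e, weights=w)
    assert np.allclose(np.concatenate([[fit.mu_hat], fit.effects]), expected, rtol=1e-8)


def test_infinite_variance_limit_recovers_ols():
    import statsmodels.api as sm

    rng = np.random.default_rng(21)
    z = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    fit = solve_model(y, z, np.full(3, 1e8), 1.0)
    ols = sm.OLS(y, sm.add_constant(z)).fit()
    assert np.allclose(
        np.concatenate([[fit.mu_hat], fit.effects]), ols.params, atol=1e-6
    )


def test_zero_variance_limit_shrinks_to_mean():
    rng = np.random.default_rng(22)
    z = rng.normal(size=(40, 3))
    y = rng.normal(size=40) + 5.0
    fit = solve_model(y, z, np.full(3, 1e-8), 1.0)
    assert np.allclose(fit.effects, 0.0, atol=1e-6)
    assert fit.mu_hat == pytest.approx(y.mean(), abs=1e-6)


def test_shrinkage_monotone_in_haplotype_variance():
    rng = np.random.default_rng(23)
    z = rng.normal(size=(30, 4))
    y = rng.normal(size=30)
    prev = None
    for v in (10.0, 1.0, 0.1, 0.01, 0.001):
        fit = solve_model(y, z, np.full(4, v), 1.0)
        mags = np.abs(fit.effects)
        if prev is not None:
            assert np.all(mags <= prev + 1e-12)
        prev = mags


def test_singular_system_returns_minimum_norm_with_warning():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    z = np.zeros((4, 2))
    z[:, 0] = [1, 0, 1, 0]
    # unbounded variances zero the ridge diagonal -> zero column is singular
    with pytest.warns(RuntimeWarning, match="h1"):
        fit = solve_model(y, z, np.array([np.inf, np.inf]), 1.0)
    assert np.all(np.isfinite(fit.effects))


def test_dgv_is_z_times_effects(rng):
    from haploblup.model import HaplotypeModelFit

    z = rng.normal(size=(4, 3))
    effects = rng.normal(size=3)
    fit = HaplotypeModelFit(
        mu_hat=2.0,
        effects=effects,
        haplotype_variances=np.ones(3),
        error_variance=1.0,
        residuals=np.zeros(4),
        columns=["h0", "h1", "h2"],
    )
    # summation-loop oracle
    expected = [sum(z[i, j] * effects[j] for j in range(3)) for i in range(4)]
    assert predict_dgv(z, fit) == pytest.approx(expected)
    assert predict_dgv(np.zeros((2, 3)), fit) == pytest.approx([0.0, 0.0])
    one_hot = np.eye(3)
    assert predict_dgv(one_hot, fit) == pytest.approx(effects)
    with pytest.raises(ValueError):
        predict_dgv(np.ones((2, 4)), fit)


def test_effect_recovery_improves_with_training_size():
    """corr(h_hat, h_true) at n=1000 beats n=100 in a majority of replicates."""
    wins = 0
    n_rep = 10
    for rep in range(n_rep):
        corr = {}
        for n in (100, 1000):
            cfg = SimulationConfig(
                n_animals=n,
                n_blocks=15,
                alleles_per_block=3,
                block_size_range=(2, 4),
                heritability=0.3,
                genetic_variance=1.0,
                missing_rate=0.0,
                seed=1000 + rep,
            )
            pop = simulate_population(cfg)
            dosage, effects = true_dosage_matrix(pop)
            rng = np.random.default_rng(2000 + rep)
            y = pop.tbv + rng.normal(0, 0.5, size=n)
            variances = np.full(len(effects), 1.0 / len(effects))
            fit = solve_model(y, dosage / 2.0, variances, 0.25)
            corr[n] = np.corrcoef(fit.effects, effects)[0, 1]
        assert corr[1000] > 0
        wins += corr[1000] > corr[100]
    assert wins >= 6
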