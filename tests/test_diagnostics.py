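"""Sensitivity analysis and sum of ranking differences."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import crocinopt as co
from crocinopt.ann import EnsembleModel, new_model


def _random_ensemble(seed, n_members=2, n_hidden=3):
    rng = np.random.default_rng(seed)
    X_cal = np.vstack([np.zeros(25), np.ones(25)])
    members = []
    for _ in range(n_members):
        model = new_model(n_hidden, "tanh", X_cal, np.array([0.0, 2.0]))
        model.set_weights(rng.normal(scale=0.5,
                                     size=n_hidden * 27 + 1))
        members.append(model)
    return EnsembleModel(members=members)


def test_zero_output_weights_give_zero_derivatives():
    X_cal = np.vstack([np.zeros(25), np.ones(25)])
    model = new_model(4, "tanh", X_cal, np.array([0.0, 1.0]))
    model.W_h[:] = np.random.default_rng(0).normal(size=model.W_h.shape)
    derivs = co.partial_derivatives(EnsembleModel(members=[model]),
                                    np.random.default_rng(1).random((5, 25)))
    np.testing.assert_allclose(derivs, 0.0, atol=1e-15)


def test_analytic_derivatives_match_central_differences():
    ensemble = _random_ensemble(seed=11)
    rng = np.random.default_rng(2)
    X = rng.random((4, 25))
    derivs = co.partial_derivatives(ensemble, X)

    h = 1e-6
    m = ensemble.members[0]
    scale = m.x_max - m.x_min  # dz/dx per column
    for row in range(X.shape[0]):
        for col in range(3):
            Xp, Xm = X.copy(), X.copy()
            # step in natural units equivalent to h in scaled units
            Xp[row, col] += h * scale[col]
            Xm[row, col] -= h * scale[col]
            fd = (co.predict(ensemble, Xp)[row]
                  - co.predict(ensemble, Xm)[row]) / (2 * h)
            assert derivs[row, col] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def test_importances_normalize_and_rank_dominant_factor():
    derivs = np.array([[2.0, 0.0, 0.0], [-2.0, 0.0, 0.0]])
    report = co.factor_importance(derivs)
    assert report.importance == {"phi": 1.0, "t_g": 0.0, "T": 0.0}

    symmetric = np.array([[1.0, -1.0, 0.5], [-1.0, 1.0, 0.5]])
    report = co.factor_importance(symmetric)
    assert report.importance["phi"] == pytest.approx(report.importance["t_g"])
    assert sum(report.importance.values()) == pytest.approx(1.0)


def test_all_zero_derivatives_rejected():
    with pytest.raises(ValueError, match="importances undefined"):
        co.factor_importance(np.zeros((4, 3)))


def test_temperature_dominant_fixture_recovered(design):
    """Scaling the simulator's T coefficients up makes T rank first."""
    from dataclasses import replace

    config = co.SimulationConfig(seed=0).noise_free()
    params = [
        replace(p, slope_T=2.5 * p.slope_T) for p in co.sample_analyte_params(config)
    ]
    chroms = co.simulate_campaign(params, design, config)
    calibration, _ = co.assemble(chroms)
    split = co.split_dataset(calibration)
    X, y = co.samples_to_arrays(calibration)
    tr, vl = list(split.training), list(split.validation)
    ensemble = co.train_ensemble(
        8, "tanh", X[tr], y[tr], X[vl], y[vl],
        co.TrainConfig(restarts=3, seed=0),
    )
    report = co.factor_importance(co.partial_derivatives(ensemble, X))
    assert report.importance["T"] == max(report.importance.values())


# --- SRD ---


def test_reference_column_scores_zero():
    rng = np.random.default_rng(0)
    matrix = rng.random((21, 5))
    result = co.srd(matrix, reference=2, n_draws=1000, seed=0)
    assert result.srd[2] == 0.0
    assert np.all(result.srd >= 0)
    assert np.all((0 <= result.srd_normalized) & (result.srd_normalized <= 100))


def test_reversed_ranking_attains_maximum():
    matrix = np.column_stack([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
    result = co.srd(matrix, reference=0, n_draws=100, seed=0)
    assert result.srd[1] == 4 == co.max_srd(3)
    assert result.srd_normalized[1] == pytest.approx(100.0)


@given(seed=st.integers(0, 1000))
def test_srd_invariant_to_object_permutation(seed):
    rng = np.random.default_rng(seed)
    matrix = rng.random((8, 4))
    perm = rng.permutation(8)
    a = co.srd(matrix, reference=0, n_draws=10, seed=0).srd
    b = co.srd(matrix[perm], reference=0, n_draws=10, seed=0).srd
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize("n", range(2, 9))
def test_max_srd_formula_against_brute_force(n):
    reference = np.arange(1, n + 1)
    brute = max(
        sum(abs(p - r) for p, r in zip(perm, reference))
        for perm in itertools.permutations(reference)
    )
    assert co.max_srd(n) == brute


def test_srd_needs_two_objects():
    with pytest.raises(ValueError, match="at least 2 objects"):
        co.srd(np.array([[1.0, 2.0]]), reference=0)


def test_crrn_two_objects_exhaustive():
    null = co.crrn(2, n_draws=100_000, seed=0)
    # SRD of a random 2-ranking is 0 or 2, each with probability 1/2
    freq0 = np.mean(null["draws"] == 0)
    sd = math.sqrt(0.25 / 100_000)
    assert abs(freq0 - 0.5) < 3 * sd
    assert set(np.unique(null["draws"])) == {0.0, 2.0}


def test_crrn_three_objects_matches_exhaustive_distribution():
    exact = {}
    for perm in itertools.permutations((1, 2, 3)):
        srd_val = sum(abs(p - r) for p, r in zip(perm, (1, 2, 3)))
        exact[srd_val] = exact.get(srd_val, 0) + 1 / 6
    null = co.crrn(3, n_draws=100_000, seed=1)
    values, counts = np.unique(null["draws"], return_counts=True)
    mc = dict(zip(values, counts / len(null["draws"])))
    assert set(mc) == set(exact)
    for v, p in exact.items():
        assert mc[v] == pytest.approx(p, abs=0.01)


def test_crrn_is_deterministic_given_seed():
    a = co.crrn(10, n_draws=2000, seed=5)
    b = co.crrn(10, n_draws=2000, seed=5)
    assert (a["lower"], a["upper"]) == (b["lower"], b["upper"])


def test_sensitivity_stable_across_master_seeds(nf_campaign):
    """Importances vary little between two independent ensembles."""
    split = nf_campaign["split"]
    X, y = nf_campaign["X_cal"], nf_campaign["y_cal"]
    tr, vl = list(split.training), list(split.validation)
    importances = []
    for seed in (101, 202):
        ensemble = co.train_ensemble(
            8, "tanh", X[tr], y[tr], X[vl], y[vl],
            co.TrainConfig(restarts=3, seed=seed),
        )
        report = co.factor_importance(co.partial_derivatives(ensemble, X))
        importances.append(report.importance)
    for key in ("phi", "t_g", "T"):
        assert abs(importances[0][key] - importances[1][key]) <= 0.05
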