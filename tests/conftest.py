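"""Shared fixtures: the seed-0 synthetic campaign and a trained ensemble."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crocinopt as co

settings.register_profile(
    "det", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def factors():
    return co.default_factors()


@pytest.fixture(scope="session")
def design(factors):
    return co.campaign_design(factors)


@pytest.fixture(scope="session")
def nf_campaign(factors, design):
    """Noise-free seed-0 campaign with its encoded dataset and split."""
    config = co.SimulationConfig(seed=0).noise_free()
    params = co.sample_analyte_params(config)
    chroms = co.simulate_campaign(params, design, config)
    calibration, external = co.assemble(chroms)
    split = co.split_dataset(calibration, n_train=486)
    X_cal, y_cal = co.samples_to_arrays(calibration)
    X_ext, y_ext = co.samples_to_arrays(external)
    return {
        "config": config,
        "params": params,
        "chromatograms": chroms,
        "calibration": calibration,
        "external": external,
        "split": split,
        "X_cal": X_cal, "y_cal": y_cal,
        "X_ext": X_ext, "y_ext": y_ext,
    }


@pytest.fixture(scope="session")
def recovery_ensemble(nf_campaign):
    """10-restart 25-8-1 tanh ensemble fitted to the noise-free campaign."""
    split = nf_campaign["split"]
    X, y = nf_campaign["X_cal"], nf_campaign["y_cal"]
    tr, vl = list(split.training), list(split.validation)
    config = co.TrainConfig(restarts=10, seed=0)
    return co.train_ensemble(8, "tanh", X[tr], y[tr], X[vl], y[vl], config)


@pytest.fixture(scope="session")
def oracle_grids(nf_campaign, factors):
    """Noise-free R_G oracle on the default surface grid at t_g 8/10/12."""
    from crocinopt.doe import DesignPoint, code_levels

    params = nf_campaign["params"]
    T_axis = np.arange(25.0, 35.001, 0.25)
    phi_axis = np.arange(0.6, 1.0001, 0.01)
    grids = {}
    for t_g in (8.0, 10.0, 12.0):
        grid = np.zeros((len(T_axis), len(phi_axis)))
        for a, T in enumerate(T_axis):
            for b, phi in enumerate(phi_axis):
                point = DesignPoint(
                    id="oracle", T=float(T), t_g=t_g, phi=float(phi),
                    coded=code_levels((T, t_g, phi), factors),
                    role="calibration",
                )
                grid[a, b] = co.true_global_resolution(
                    params, point, co.DEFAULT_RETAINED_PAIRS
                )
        grids[t_g] = grid
    return {"T_axis": T_axis, "phi_axis": phi_axis, "grids": grids}
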