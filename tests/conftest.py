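"""Shared fixtures and oracle helpers for the test suite.

The heavier checks (local-vs-global energy oracle, kernel acceptance
statistics, parameter-recovery batteries) are implemented once here and
invoked at small size from the module tests and at full size from the
acceptance tests.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from emergrow import cpm_core, experiment_runner, growth_fitting
from emergrow._kernels import mcs_sweep


def make_square_cell_state(
    shape=(16, 16), top=5, left=5, size=6, cell_type=cpm_core.LIVE
):
    state = cpm_core.LatticeState(shape)
    rr, cc = np.meshgrid(
        np.arange(top, top + size), np.arange(left, left + size), indexing="ij"
    )
    state.add_cell(np.column_stack([rr.ravel(), cc.ravel()]), cell_type)
    return state


def make_random_state(rng, shape=(16, 16), n_cells=3, n_warmup_mcs=3):
    """A few random rectangular cells, roughened by a short Monte Carlo warmup."""
    state = cpm_core.LatticeState(shape)
    placed, tries = 0, 0
    while placed < n_cells and tries < 200:
        tries += 1
        h = int(rng.integers(2, 6))
        w = int(rng.integers(2, 6))
        r = int(rng.integers(0, shape[0] - h))
        c = int(rng.integers(0, shape[1] - w))
        if np.all(state.labels[r : r + h, c : c + w] == cpm_core.MEDIUM):
            rr, cc = np.meshgrid(np.arange(r, r + h), np.arange(c, c + w), indexing="ij")
            state.add_cell(np.column_stack([rr.ravel(), cc.ravel()]))
            placed += 1
    params = cpm_core.CPMParams(target_volume_sites=9)
    for _ in range(n_warmup_mcs):
        cpm_core.monte_carlo_step(state, params, rng)
    return state


@pytest.fixture
def default_params():
    return cpm_core.CPMParams()


# ---------------------------------------------------------------------------
# shared oracle checks


def explicit_integrate(state, oxy_params, t_total, n_steps):
    """Forward-Euler integration of the oxygen field over t_total seconds."""
    from emergrow import oxygen_pde

    field = oxygen_pde.OxygenField.uniform(state.labels.shape, oxy_params)
    sources = oxygen_pde.source_raster(state, oxy_params)
    mask = state.labels != cpm_core.MEDIUM
    dt = t_total / n_steps
    for _ in range(n_steps):
        field = oxygen_pde.explicit_substep(field, sources, dt, oxy_params, mask)
    return field


def max_delta_energy_error(seed: int, n_attempts: int, shape=(16, 16)) -> float:
    """Worst |local dH - global energy difference| over random copy attempts."""
    rng = np.random.default_rng(seed)
    params = cpm_core.CPMParams(target_volume_sites=9)
    worst = 0.0
    done = 0
    while done < n_attempts:
        state = make_random_state(rng, shape=shape)
        e_before = cpm_core.total_effective_energy(state, params)
        for _ in range(50):
            if done >= n_attempts:
                break
            r = int(rng.integers(0, shape[0]))
            c = int(rng.integers(0, shape[1]))
            dr, dc = cpm_core.VON_NEUMANN_OFFSETS[int(rng.integers(0, 4))]
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < shape[0] and 0 <= c2 < shape[1]):
                continue
            dh = cpm_core.delta_energy_for_copy(state, (r, c), (r2, c2), params)
            # apply the copy without registry pruning: an agent emptied by a
            # copy keeps its volume penalty until end-of-MCS cleanup, which is
            # the convention the local dH uses
            trial = state.copy()
            sid, tid = int(trial.labels[r, c]), int(trial.labels[r2, c2])
            trial.labels[r2, c2] = sid
            trial.volumes_by_id[tid] -= 1
            trial.volumes_by_id[sid] += 1
            e_after = cpm_core.total_effective_energy(trial, params)
            worst = max(worst, abs((e_after - e_before) - dh))
            done += 1
    return worst


def kernel_acceptance_frequency(seed: int, n_draws: int):
    """Empirical acceptance rate of one fixed uphill copy attempt.

    The same attempt is replayed through the compiled sweep kernel on a
    pristine state (reverting on acceptance), so the statistic exercises the
    kernel's dH computation and its Metropolis draw, not just the closed-form
    probability.
    """
    params = cpm_core.CPMParams()
    state = make_square_cell_state()
    # medium site left of the cell copying into the cell's edge site
    src = (7, 4)
    tgt = (7, 5)
    dh = cpm_core.delta_energy_for_copy(state, src, tgt, params)
    assert dh > 0
    p_expected = cpm_core.acceptance_probability(dh, params.motility_hstar)

    h, w = state.labels.shape
    src_flat = np.array([src[0] * w + src[1]], dtype=np.int64)
    nbr = np.array([3], dtype=np.int64)  # (0, +1): rightwards
    u = np.empty(1, dtype=np.float64)
    rng = np.random.default_rng(seed)
    lam = params.lambda_by_type()
    vt = params.vtarget_by_type()
    jm = params.contact_matrix()
    cell_id = int(state.labels[tgt])
    accepted = 0
    for ui in rng.random(n_draws):
        u[0] = ui
        mcs_sweep(
            state.labels, state.types_by_id, state.volumes_by_id,
            lam, vt, jm, src_flat, nbr, u, params.motility_hstar,
        )
        if state.labels[tgt] == cpm_core.MEDIUM:
            accepted += 1
            state.labels[tgt] = cell_id
            state.volumes_by_id[cell_id] += 1
            state.volumes_by_id[cpm_core.MEDIUM] -= 1
    return accepted / n_draws, p_expected


def shape_recovery_errors(
    s_values=(2.0 / 3.0, 1.0, 1.4, 2.0), n_curves_per_s=13, noise_sd=0.01, seed=7
):
    """|fitted S - true S| over noisy synthetic curves, for the recovery check."""
    errors = []
    k = 0
    for s_true in s_values:
        for _ in range(n_curves_per_s):
            k += 1
            curve = experiment_runner.generate_fixture_curve(
                A=0.12, W0=0.005, G=2.7, S=s_true, noise_sd=noise_sd, seed=seed + k
            )
            curve = growth_fitting.adjusted_time_origin(curve)
            fit = growth_fitting.fit_growth_model(curve, "urichards")
            errors.append(abs(fit.S - s_true))
    return np.array(errors)


# ---------------------------------------------------------------------------
# shared simulation fixtures (session-scoped: each runs once per suite)


@pytest.fixture(scope="session")
def scaled_demo_run():
    """The reduced-scale Control run (64x64, 15 kMCS, seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return experiment_runner.run_experiment(experiment_runner.scaled_demo_config(seed=0))


@pytest.fixture(scope="session")
def converged_demo_run():
    """The reduced-scale Control run continued to its plateau (45 kMCS)."""
    config = dataclasses.replace(experiment_runner.scaled_demo_config(seed=0), total_kmcs=45)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return experiment_runner.run_experiment(config)
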