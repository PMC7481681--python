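"""Oxygen source mapping, explicit integration and steady-state relaxation."""

import dataclasses

import numpy as np
import pytest

from emergrow import cpm_core, oxygen_pde
from conftest import explicit_integrate, make_random_state, make_square_cell_state


@pytest.fixture
def params():
    return oxygen_pde.OxygenParams()


class TestSourceRaster:
    def test_no_live_cells_all_zero(self, params):
        state = cpm_core.LatticeState((8, 8))
        assert np.all(oxygen_pde.source_raster(state, params) == 0.0)

    def test_single_cell_unit_conversion(self, params):
        # 0.5 fmol/s over 36 sites of volume alpha^3; 1 fmol/um^3 = 1 mol/L
        state = make_square_cell_state()
        raster = oxygen_pde.source_raster(state, params)
        per_site = -(0.5 / 36.0) / (2.96**3) * 1000.0  # mM/s
        cell = state.labels != 0
        assert raster[cell] == pytest.approx(per_site, rel=1e-12)
        assert np.all(raster[~cell] == 0.0)

    def test_two_cells_double_the_total_sink(self, params):
        one = make_square_cell_state((24, 24), top=3, left=3)
        two = make_square_cell_state((24, 24), top=3, left=3)
        rr, cc = np.meshgrid(np.arange(14, 20), np.arange(14, 20), indexing="ij")
        two.add_cell(np.column_stack([rr.ravel(), cc.ravel()]))
        total_one = oxygen_pde.source_raster(one, params).sum()
        total_two = oxygen_pde.source_raster(two, params).sum()
        assert total_two == pytest.approx(2 * total_one, rel=1e-12)

    def test_dead_cells_do_not_respire(self, params):
        state = make_square_cell_state(cell_type=cpm_core.DEAD)
        assert np.all(oxygen_pde.source_raster(state, params) == 0.0)


class TestExplicitSubstep:
    def test_uniform_field_zero_sources_unchanged(self, params):
        state = make_square_cell_state()
        field = oxygen_pde.OxygenField.uniform((16, 16), params)
        out = oxygen_pde.explicit_substep(
            field, np.zeros((16, 16)), params.stability_dt_s, params, state.labels != 0
        )
        assert np.array_equal(out.conc_mM, field.conc_mM)

    def test_sink_site_concentration_decreases(self, params):
        state = make_square_cell_state()
        field = oxygen_pde.OxygenField.uniform((16, 16), params)
        sources = oxygen_pde.source_raster(state, params)
        out = oxygen_pde.explicit_substep(
            field, sources, params.stability_dt_s, params, state.labels != 0
        )
        assert out.conc_mM[7, 7] < field.conc_mM[7, 7]

    def test_unstable_dt_rejected(self, params):
        field = oxygen_pde.OxygenField.uniform((8, 8), params)
        with pytest.raises(ValueError):
            oxygen_pde.explicit_substep(
                field, np.zeros((8, 8)), 2 * params.stability_dt_s, params,
                np.zeros((8, 8), dtype=bool),
            )

    def test_step_halving_convergence(self):
        # halving dt over the same physical interval changes the field by
        # less than 1e-6 mM in max-norm (mild-sink fixture: the forward-Euler
        # error is dominated by the switch-on transient and scales with the
        # source magnitude)
        params = oxygen_pde.OxygenParams(uptake_fmol_per_cell_s=0.05)
        state = make_square_cell_state()
        t_total = 50 * params.stability_dt_s
        coarse = explicit_integrate(state, params, t_total, 50)
        fine = explicit_integrate(state, params, t_total, 100)
        assert np.abs(coarse.conc_mM - fine.conc_mM).max() <= 1e-6


class TestRelaxOverMcs:
    def test_no_cells_gives_clamped_uniform_field(self, params):
        state = cpm_core.LatticeState((12, 12))
        field = oxygen_pde.OxygenField(np.full((12, 12), 0.05))
        out = oxygen_pde.relax_over_mcs(field, state, params)
        assert np.all(out.conc_mM == params.env_concentration_mM)

    def test_clamp_and_maximum_principle(self, params):
        rng = np.random.default_rng(2)
        for _ in range(5):
            state = make_random_state(rng)
            field = oxygen_pde.OxygenField.uniform((16, 16), params)
            out = oxygen_pde.relax_over_mcs(field, state, params)
            medium = state.labels == 0
            assert np.all(out.conc_mM[medium] == params.env_concentration_mM)
            assert np.all(out.conc_mM >= 0.0)
            assert np.all(out.conc_mM <= params.env_concentration_mM)

    def test_modes_agree_on_single_cell(self, params):
        # quasi-steady solve vs 50 MCS of explicit integration (5 s physical)
        state = make_square_cell_state((32, 32), top=13, left=13)
        start = oxygen_pde.OxygenField.uniform((32, 32), params)
        steady = oxygen_pde.relax_over_mcs(start, state, params)
        explicit_params = dataclasses.replace(params, mode="explicit_substep")
        field = start
        for _ in range(50):
            field = oxygen_pde.relax_over_mcs(field, state, explicit_params)
        assert np.abs(steady.conc_mM - field.conc_mM).max() <= 1e-4

    def test_extra_sink_never_raises_concentration(self, params):
        one = make_square_cell_state((24, 24), top=3, left=3)
        two = make_square_cell_state((24, 24), top=3, left=3)
        rr, cc = np.meshgrid(np.arange(14, 20), np.arange(14, 20), indexing="ij")
        two.add_cell(np.column_stack([rr.ravel(), cc.ravel()]))
        start = oxygen_pde.OxygenField.uniform((24, 24), params)
        f_one = oxygen_pde.relax_over_mcs(start, one, params)
        f_two = oxygen_pde.relax_over_mcs(start, two, params)
        # the second cell's sites are medium (clamped) in the one-cell state
        cells_one = one.labels != 0
        assert np.all(f_two.conc_mM[cells_one] <= f_one.conc_mM[cells_one] + 1e-9)

    def test_nonconvergence_raises(self, params):
        state = make_square_cell_state()
        field = oxygen_pde.OxygenField.uniform((16, 16), params)
        broken = dataclasses.replace(params, max_iterations=1)
        with pytest.raises(oxygen_pde.NonConvergenceError):
            oxygen_pde.relax_over_mcs(field, state, broken)


class TestMeanConcentration:
    def test_uniform_field(self, params):
        field = oxygen_pde.OxygenField.uniform((8, 8), params)
        assert oxygen_pde.mean_concentration(field, [[2, 2], [3, 3]]) == 0.2

    def test_two_site_average(self):
        conc = np.zeros((4, 4))
        conc[0, 0], conc[1, 1] = 0.1, 0.3
        field = oxygen_pde.OxygenField(conc)
        assert oxygen_pde.mean_concentration(field, [[0, 0], [1, 1]]) == pytest.approx(0.2)

    def test_ramped_field_matches_direct_sum(self, params):
        state = make_square_cell_state()
        conc = np.tile(np.linspace(0.0, 0.2, 16), (16, 1))
        field = oxygen_pde.OxygenField(conc)
        sites = state.sites_of(state.cell_ids()[0])
        expected = sum(conc[r, c] for r, c in sites) / len(sites)
        assert oxygen_pde.mean_concentration(field, sites) == pytest.approx(
            expected, rel=1e-12
        )

    def test_empty_site_set_raises(self, params):
        field = oxygen_pde.OxygenField.uniform((4, 4), params)
        with pytest.raises(ValueError):
            oxygen_pde.mean_concentration(field, np.empty((0, 2)))
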