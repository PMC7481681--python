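"""Gaussian response parametrisation, sampling, division and death."""

import math
import warnings

import numpy as np
import pytest

from emergrow import cpm_core, oxygen_pde, phenotype
from conftest import make_square_cell_state


def independent_profile(multiplier, width, cutoff=1e-6):
    """Closed-form oracle for the derived response parameters."""
    q = math.exp(math.log(multiplier) / 10_000.0) - 1.0
    sigma = width / math.sqrt(math.log(q) - math.log(cutoff))
    return q, sigma


class TestBuildProfile:
    def test_control_death_peak_probability(self):
        built = phenotype.build_profile(phenotype.ResponseSpec(0.0, 50.0, 6.0))
        q, sigma = independent_profile(6.0, 50.0)
        assert built.peak_prob_q == pytest.approx(q, rel=1e-12)
        assert built.gaussian_sigma_uM == pytest.approx(sigma, rel=1e-12)
        # 6x population per 10 kMCS corresponds to roughly 1.8e-4 per MCS
        assert built.peak_prob_q == pytest.approx(1.79192e-4, rel=1e-5)

    @pytest.mark.parametrize("name", sorted(phenotype.PROFILE_PRESETS))
    def test_cutoff_probability_round_trip(self, name):
        # at |c - target| = width every response drops to once per million MCS
        profile = phenotype.get_preset(name)
        for built in (profile.proliferation, profile.death):
            spec = built.spec
            for c in (spec.target_uM - spec.width_uM, spec.target_uM + spec.width_uM):
                assert phenotype.response_probability(c, built) == pytest.approx(
                    spec.cutoff_prob, rel=1e-12
                )
            assert phenotype.response_probability(
                spec.target_uM, built
            ) == pytest.approx(built.peak_prob_q, rel=1e-12)

    def test_half_width_probability(self):
        built = phenotype.build_profile(phenotype.ResponseSpec(0.0, 50.0, 6.0))
        q, sigma = independent_profile(6.0, 50.0)
        expected = q * math.exp(-((25.0 / sigma) ** 2))
        assert phenotype.response_probability(25.0, built) == pytest.approx(
            expected, rel=1e-12
        )

    def test_population_ratio_after_10k_mcs(self):
        # multiplier 4 vs 6 implies a 4/6 population ratio at the target
        q4 = phenotype.get_preset("Decrease 1").proliferation.peak_prob_q
        q6 = phenotype.get_preset("Control").proliferation.peak_prob_q
        ratio = (1 + q4) ** 10_000 / (1 + q6) ** 10_000
        assert ratio == pytest.approx(4.0 / 6.0, rel=1e-9)

    def test_peak_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            phenotype.build_profile(
                phenotype.ResponseSpec(0.0, 50.0, multiplier=1.0000001)
            )

    @pytest.mark.parametrize("n", [4.0, 6.0])
    def test_exponential_growth_multiplier(self, n):
        # a birth-only population at the target multiplies by n over 10 kMCS
        built = phenotype.build_profile(phenotype.ResponseSpec(200.0, 100.0, n))
        rng = np.random.default_rng(int(n))
        reps, n0 = 20, 400
        counts = np.full(reps, n0, dtype=np.int64)
        for _ in range(10_000):
            counts += rng.binomial(counts, built.peak_prob_q)
        ratios = counts / n0
        sem = ratios.std(ddof=1) / math.sqrt(reps)
        assert abs(ratios.mean() - n) <= 3 * sem


class TestSampleResponses:
    def make_scene(self, conc_mM):
        state = make_square_cell_state()
        params = oxygen_pde.OxygenParams()
        field = oxygen_pde.OxygenField(np.full((16, 16), conc_mM))
        return state, field, params

    def test_far_from_both_targets_no_events(self):
        state, field, _ = self.make_scene(1.0)  # 1000 uM: both responses ~ 0
        profile = phenotype.get_preset("Control")
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert phenotype.sample_responses(state, field, profile, rng) == []

    def test_event_frequency_at_target(self):
        # a cell held at the proliferation target divides at the peak rate
        state, field, _ = self.make_scene(0.2)  # 200 uM
        profile = phenotype.get_preset("Control")
        rng = np.random.default_rng(1)
        n = 100_000
        hits = 0
        for _ in range(n):
            events = phenotype.sample_responses(state, field, profile, rng)
            hits += sum(ev.kind == "proliferate" for ev in events)
        p = profile.proliferation.peak_prob_q
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) <= 3 * se

    def test_dying_cell_emits_no_proliferation(self):
        state, field, _ = self.make_scene(0.2)
        # certain death and certain division: death must win and exclude division
        certain = phenotype.BuiltResponse(
            phenotype.ResponseSpec(200.0, 100.0, 6.0), 1.0, 43.9
        )
        profile = phenotype.PhenotypeProfile("certain", certain, certain)
        events = phenotype.sample_responses(
            state, field, profile, np.random.default_rng(0)
        )
        assert [ev.kind for ev in events] == ["die"]

    def test_dead_cells_never_sampled(self):
        state, field, params = self.make_scene(0.2)
        phenotype.kill_cell(state, state.cell_ids()[0], cpm_core.CPMParams())
        profile = phenotype.get_preset("Control")
        for _ in range(100):
            assert (
                phenotype.sample_responses(state, field, profile, np.random.default_rng(0))
                == []
            )


class TestDivideCell:
    def test_2x6_rectangle_splits_into_equal_halves(self, default_params):
        state = cpm_core.LatticeState((12, 12))
        rr, cc = np.meshgrid(np.arange(2, 4), np.arange(2, 8), indexing="ij")
        cid = state.add_cell(np.column_stack([rr.ravel(), cc.ravel()]))
        nid = phenotype.divide_cell(state, cid, default_params)
        assert nid == cid + 1
        # cut perpendicular to the long axis: two 2x3 daughters
        assert state.volumes_by_id[cid] == 6
        assert state.volumes_by_id[nid] == 6
        assert set(state.sites_of(nid)[:, 1]) == {5, 6, 7}

    def test_square_tie_break_gives_even_halves(self, default_params):
        state = make_square_cell_state()
        cid = state.cell_ids()[0]
        nid = phenotype.divide_cell(state, cid, default_params)
        assert state.volumes_by_id[cid] == 18
        assert state.volumes_by_id[nid] == 18
        state.validate()

    def test_division_conserves_sites_on_random_shapes(self, default_params):
        rng = np.random.default_rng(9)
        for _ in range(20):
            state = cpm_core.LatticeState((20, 20))
            h = int(rng.integers(2, 7))
            w = int(rng.integers(2, 7))
            rr, cc = np.meshgrid(np.arange(3, 3 + h), np.arange(3, 3 + w), indexing="ij")
            cid = state.add_cell(np.column_stack([rr.ravel(), cc.ravel()]))
            cpm_core.monte_carlo_step(state, default_params, rng)
            before = int(state.volumes_by_id[cid])
            nid = phenotype.divide_cell(state, cid, default_params)
            if nid is None:
                assert before < phenotype.MIN_DIVISION_SITES or before <= 1
                continue
            assert (
                int(state.volumes_by_id[cid]) + int(state.volumes_by_id[nid]) == before
            )
            assert nid == state.next_id - 1
            state.validate()

    def test_below_minimum_size_skipped(self, default_params):
        state = cpm_core.LatticeState((8, 8))
        cid = state.add_cell([[2, 2], [2, 3], [3, 2]])
        assert phenotype.divide_cell(state, cid, default_params) is None


class TestKillCell:
    def test_kill_marks_dead_and_stops_respiration(self, default_params):
        state = make_square_cell_state()
        cid = state.cell_ids()[0]
        phenotype.kill_cell(state, cid, default_params)
        assert state.types_by_id[cid] == cpm_core.DEAD
        assert np.all(oxygen_pde.source_raster(state, oxygen_pde.OxygenParams()) == 0.0)

    def test_double_kill_warns(self, default_params):
        state = make_square_cell_state()
        cid = state.cell_ids()[0]
        phenotype.kill_cell(state, cid, default_params)
        with pytest.warns(UserWarning):
            phenotype.kill_cell(state, cid, default_params)

    def test_dead_cell_removed_within_5_kmcs(self, default_params):
        # the zero volume constraint lets adhesion erase a dead cell; this
        # holds in at least 95% of seeded runs for an isolated 36-site cell
        removed = 0
        for seed in range(20):
            state = make_square_cell_state()
            cid = state.cell_ids()[0]
            phenotype.kill_cell(state, cid, default_params)
            rng = np.random.default_rng(seed)
            for _ in range(5000):
                cpm_core.monte_carlo_step(state, default_params, rng)
                if cid not in state._active:
                    removed += 1
                    break
        assert removed >= 19
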