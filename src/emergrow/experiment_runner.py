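"""Experiment configuration, the per-MCS scheduler, and output writing.

A run couples the three model layers in a fixed per-MCS order: one Monte
Carlo sweep of copy attempts (cell motility), one oxygen relaxation, then
one round of stochastic response sampling with death and division applied
immediately. Aggregate area, live-cell count, eccentricity and the two
probability areas are sampled on a fixed interval (1 kMCS in the full
study); at the end of a run the growth curve is re-zeroed at the 15-cell
adjusted origin and fitted to the unified-Richards model and its three
classical submodels.

The full study domain is a 600 um square (203 sites of 2.96 um) seeded with
five 6x6 cells in a plus-shaped central cluster. All randomness in a run
flows through one seeded generator, so (config, seed) reproduces outputs
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import aggregate_analysis, cpm_core, growth_fitting, oxygen_pde, phenotype

#: Run lengths (kMCS) long enough for each profile's aggregate to converge.
DEFAULT_DURATION_KMCS = {
    "Control": 100,
    "Decrease 1": 150,
    "Decrease 2": 250,
    "Shift 1": 150,
    "Shift 2": 150,
    "Shrink 1": 150,
    "Shrink 2": 150,
    "Increase 1": 100,
    "Increase 2": 100,
    "Expand 1": 100,
    "Expand 2": 100,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    profile_name: str = "Control"
    lattice_side_sites: int = 203
    n_initial_cells: int = 5
    total_kmcs: Optional[int] = None  # None -> profile default duration
    sample_interval_mcs: int = 1000
    seed: int = 0
    oxygen_mode: str = "quasi_steady"
    output_dir: Optional[str] = None
    light: bool = False  # curves/series only, no lattice snapshots
    origin_cell_threshold: int = 15

    def resolved_total_kmcs(self) -> int:
        if self.total_kmcs is not None:
            if self.total_kmcs < 1:
                raise ConfigError("total_kmcs must be >= 1")
            return self.total_kmcs
        return DEFAULT_DURATION_KMCS.get(self.profile_name, 100)


def load_profile_set(name: str) -> phenotype.PhenotypeProfile:
    """Named phenotype preset (Control and its ten single-parameter variations)."""
    return phenotype.get_preset(name)


#: Initial 6x6 block offsets (units of one block) forming a plus-shaped
#: cluster, then corners; the first n_initial_cells entries are used.
_BLOCK_OFFSETS = [
    (0, 0),
    (-1, 0),
    (1, 0),
    (0, -1),
    (0, 1),
    (-1, -1),
    (-1, 1),
    (1, -1),
    (1, 1),
]


def initialize_state(
    config: RunConfig,
    cpm_params: Optional[cpm_core.CPMParams] = None,
    oxygen_params: Optional[oxygen_pde.OxygenParams] = None,
) -> tuple[cpm_core.LatticeState, oxygen_pde.OxygenField]:
    """Seed the lattice with square cells around the centre and a uniform field."""
    cpm_params = cpm_params or cpm_core.CPMParams()
    oxygen_params = oxygen_params or oxygen_pde.OxygenParams(
        site_length_um=cpm_params.site_length_um, mode=config.oxygen_mode
    )
    if config.n_initial_cells < 1:
        raise ConfigError("n_initial_cells must be >= 1")
    if config.n_initial_cells > len(_BLOCK_OFFSETS):
        raise ConfigError(
            f"at most {len(_BLOCK_OFFSETS)} initial cells are supported"
        )
    side = config.lattice_side_sites
    block = int(round(np.sqrt(cpm_params.target_volume_sites)))
    if block * block != cpm_params.target_volume_sites:
        raise ConfigError("target volume must be a perfect square for seeding")
    state = cpm_core.LatticeState((side, side))
    centre = side // 2
    for br, bc in _BLOCK_OFFSETS[: config.n_initial_cells]:
        r0 = centre + br * block - block // 2
        c0 = centre + bc * block - block // 2
        if r0 < 0 or c0 < 0 or r0 + block > side or c0 + block > side:
            raise ConfigError("initial cells do not fit inside the lattice")
        rr, cc = np.meshgrid(
            np.arange(r0, r0 + block), np.arange(c0, c0 + block), indexing="ij"
        )
        state.add_cell(np.column_stack([rr.ravel(), cc.ravel()]))
    field = oxygen_pde.OxygenField.uniform((side, side), oxygen_params)
    return state, field


@dataclass
class RunResult:
    config: RunConfig
    curve: growth_fitting.GrowthCurve
    fits: Optional[Dict[str, growth_fitting.URichardsFit]]
    eccentricity: aggregate_analysis.EccentricitySeries
    probability_areas: pd.DataFrame
    manifest: dict
    state: cpm_core.LatticeState
    field: oxygen_pde.OxygenField


def run_experiment(
    config: RunConfig,
    cpm_params: Optional[cpm_core.CPMParams] = None,
    oxygen_params: Optional[oxygen_pde.OxygenParams] = None,
) -> RunResult:
    """Simulate one aggregate-growth experiment and analyse its outputs."""
    cpm_params = cpm_params or cpm_core.CPMParams()
    oxygen_params = oxygen_params or oxygen_pde.OxygenParams(
        site_length_um=cpm_params.site_length_um, mode=config.oxygen_mode
    )
    profile = load_profile_set(config.profile_name)
    rng = np.random.default_rng(config.seed)
    state, field = initialize_state(config, cpm_params, oxygen_params)
    field = oxygen_pde.relax_over_mcs(field, state, oxygen_params)

    total_mcs = config.resolved_total_kmcs() * 1000
    interval = config.sample_interval_mcs
    alpha = cpm_params.site_length_um

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        if not config.light:
            (outdir / "snapshots").mkdir(exist_ok=True)

    curve_rows: List[tuple[int, float, int]] = []
    ecc_rows: List[tuple[int, float]] = []
    parea_rows: List[tuple[int, float, float]] = []
    n_divisions = 0
    n_deaths = 0
    n_skipped_divisions = 0

    def record(k: int) -> None:
        mask, area = aggregate_analysis.aggregate_mask(state, alpha)
        n_live = len(state.cell_ids(cpm_core.LIVE))
        curve_rows.append((k, area, n_live))
        parea_rows.append(
            (
                k,
                aggregate_analysis.probability_area(
                    field, mask, profile.proliferation, alpha
                ),
                aggregate_analysis.probability_area(field, mask, profile.death, alpha),
            )
        )
        if k >= 1000:  # shape sampling starts at 1 kMCS
            try:
                fit = aggregate_analysis.ellipse_eccentricity(mask, alpha)
                ecc_rows.append((k, fit.eccentricity))
            except aggregate_analysis.DegenerateMaskError:
                warnings.warn(f"degenerate aggregate at MCS {k}; sample skipped")
        if outdir is not None and not config.light:
            np.savez_compressed(
                outdir / "snapshots" / f"mcs_{k:07d}.npz",
                labels=state.labels.astype(np.int32),
                conc_mM=field.conc_mM,
                agent_ids=np.array(state.cell_ids(), dtype=np.int64),
                agent_types=np.array(
                    [state.types_by_id[i] for i in state.cell_ids()], dtype=np.int8
                ),
                agent_volumes=np.array(
                    [state.volumes_by_id[i] for i in state.cell_ids()], dtype=np.int64
                ),
            )

    record(0)
    for k in range(1, total_mcs + 1):
        cpm_core.monte_carlo_step(state, cpm_params, rng)
        field = oxygen_pde.relax_over_mcs(field, state, oxygen_params)
        events = phenotype.sample_responses(state, field, profile, rng)
        for ev in events:
            if ev.kind == "die":
                phenotype.kill_cell(state, ev.cell_id, cpm_params)
                n_deaths += 1
            else:
                if phenotype.divide_cell(state, ev.cell_id, cpm_params) is None:
                    n_skipped_divisions += 1
                else:
                    n_divisions += 1
        if k % interval == 0:
            record(k)

    curve = growth_fitting.GrowthCurve(
        *(np.array(col) for col in zip(*curve_rows))
    )
    fits: Optional[Dict[str, growth_fitting.URichardsFit]] = None
    fit_warning = None
    try:
        curve = growth_fitting.adjusted_time_origin(
            curve, config.origin_cell_threshold
        )
        fits = growth_fitting.compare_classical_fits(curve)
    except (ValueError, growth_fitting.FitError) as exc:
        fit_warning = str(exc)
        warnings.warn(f"growth-model fitting skipped: {exc}")

    ecc_arr = (
        np.array(ecc_rows, dtype=np.float64)
        if ecc_rows
        else np.empty((0, 2))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ecc = aggregate_analysis.eccentricity_summary(
            ecc_arr[:, 0].astype(np.int64), ecc_arr[:, 1]
        )
    pareas = pd.DataFrame(
        parea_rows, columns=["mcs", "proliferation_um2", "death_um2"]
    )

    manifest = {
        "config": dataclasses.asdict(config),
        "site_length_um": alpha,
        "beta_s_per_mcs": oxygen_params.beta_s_per_mcs,
        "total_mcs": total_mcs,
        "n_divisions": n_divisions,
        "n_deaths": n_deaths,
        "n_skipped_divisions": n_skipped_divisions,
        "origin_mcs": curve.origin_mcs,
        "fit_warning": fit_warning,
        "final_live_cells": len(state.cell_ids(cpm_core.LIVE)),
        "final_area_mm2": float(curve.area_mm2[-1]),
    }

    result = RunResult(config, curve, fits, ecc, pareas, manifest, state, field)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: RunResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.curve.to_csv(outdir / "growth_curve.csv")
    pd.DataFrame(
        {"mcs": result.eccentricity.mcs, "eccentricity": result.eccentricity.eccentricity}
    ).to_csv(outdir / "eccentricity.csv", index=False)
    result.probability_areas.to_csv(outdir / "probability_area.csv", index=False)
    if result.fits is not None:
        with open(outdir / "fits.json", "w") as fh:
            json.dump({tag: f.to_dict() for tag, f in result.fits.items()}, fh, indent=2)
    summary = dict(result.manifest)
    summary["eccentricity_window_mean"] = result.eccentricity.window_mean
    summary["eccentricity_window_std"] = result.eccentricity.window_std
    summary["eccentricity_histogram"] = result.eccentricity.histogram.tolist()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def scaled_demo_config(seed: int = 0, output_dir: Optional[str] = None) -> RunConfig:
    """Reduced-scale Control run used for fast end-to-end demonstrations.

    64x64 lattice (one third of the study domain side), five initial cells,
    15 kMCS, quasi-steady oxygen, sampling every 500 MCS so the 15-cell
    adjusted origin still leaves a well-populated fit window at the reduced
    duration.
    """
    return RunConfig(
        profile_name="Control",
        lattice_side_sites=64,
        n_initial_cells=5,
        total_kmcs=15,
        sample_interval_mcs=500,
        seed=seed,
        oxygen_mode="quasi_steady",
        output_dir=output_dir,
        light=True,
    )


def generate_fixture_curve(
    A: float,
    W0: float,
    G: float,
    S: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    span_kmcs: int = 100,
    interval_kmcs: int = 1,
    origin_kmcs: int = 0,
    threshold: int = 15,
) -> growth_fitting.GrowthCurve:
    """Synthetic growth curve sampled from the unified-Richards model.

    ``G`` is in (100 kMCS)^-1. Multiplicative Gaussian noise of relative
    standard deviation ``noise_sd`` is applied; synthetic cell counts cross
    ``threshold`` at ``origin_kmcs`` so the adjusted-origin machinery works
    on the fixture exactly as on simulated curves.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0, span_kmcs + 1, interval_kmcs, dtype=np.float64)
    areas = np.asarray(
        growth_fitting.urichards_value((t - origin_kmcs) / 100.0, A, W0, G, S),
        dtype=np.float64,
    )
    if noise_sd > 0:
        areas = areas * (1.0 + noise_sd * rng.standard_normal(areas.shape))
        areas = np.maximum(areas, 1e-12)
    counts = np.where(t >= origin_kmcs, threshold, max(threshold - 10, 1))
    return growth_fitting.GrowthCurve(
        (t * 1000).astype(np.int64), areas, counts.astype(np.int64)
    )
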