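"""Oxygen reaction--diffusion field coupled to the cell lattice.

Oxygen obeys dc/dt = D lap(c) + s on the physical domain, where the source
field s maps per-cell respiration onto a concentration rate: each live cell
consumes a fixed molar rate (default 0.5 fmol/s) spread evenly over its
current sites, dead cells do not respire, and every medium site is held at
the environmental concentration (default 0.2 mM) as a prescribed boundary
condition. Physical time relates to Monte Carlo steps through beta (s/MCS),
chosen so diffusion is much faster than cell motility; because of that
separation the default solver relaxes the field to the steady state of the
balance each MCS (``quasi_steady``), while a forward-Euler explicit
integrator over the beta-second window is retained for verification
(``explicit_substep``).

Unit note: per-site sink rates need a voxel volume to convert fmol/s into
mM/s; each site is treated as a voxel of volume alpha^3 (the site length is
the only available depth scale), and 1 fmol/um^3 = 1 mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import cpm_core
from ._kernels import steady_state_sor


class NonConvergenceError(RuntimeError):
    """Steady-state relaxation failed to reach tolerance."""


@dataclass(frozen=True)
class OxygenParams:
    diffusivity_um2_s: float = 2500.0
    uptake_fmol_per_cell_s: float = 0.5
    env_concentration_mM: float = 0.2
    beta_s_per_mcs: float = 0.1
    site_length_um: float = 2.96
    mode: str = "quasi_steady"  # or "explicit_substep"
    steady_tol_mM_s: float = 1e-9
    max_iterations: int = 500_000

    def __post_init__(self) -> None:
        if self.diffusivity_um2_s <= 0:
            raise ValueError("diffusivity must be positive")
        if self.env_concentration_mM <= 0:
            raise ValueError("environmental concentration must be positive")
        if self.beta_s_per_mcs <= 0:
            raise ValueError("beta must be positive")
        if self.mode not in ("quasi_steady", "explicit_substep"):
            raise ValueError(f"unknown oxygen mode {self.mode!r}")

    @property
    def site_volume_um3(self) -> float:
        return self.site_length_um**3

    @property
    def stability_dt_s(self) -> float:
        """Explicit forward-Euler stability bound alpha^2 / (4 D)."""
        return self.site_length_um**2 / (4.0 * self.diffusivity_um2_s)

    @property
    def laplacian_rate_per_s(self) -> float:
        """D / alpha^2, the discrete-Laplacian prefactor."""
        return self.diffusivity_um2_s / self.site_length_um**2


@dataclass
class OxygenField:
    """Scalar concentration raster in mM, same shape as the cell lattice."""

    conc_mM: np.ndarray

    @classmethod
    def uniform(cls, shape: tuple[int, int], params: OxygenParams) -> "OxygenField":
        return cls(np.full(shape, params.env_concentration_mM, dtype=np.float64))

    def copy(self) -> "OxygenField":
        return OxygenField(self.conc_mM.copy())


def source_raster(state: cpm_core.LatticeState, params: OxygenParams) -> np.ndarray:
    """Per-site concentration rate (mM/s, negative = sink).

    Each live cell's molar uptake is divided evenly over its current sites;
    dead cells and medium carry zero source (metabolic activity ceases on
    death).
    """
    rate_by_id = np.zeros(state.types_by_id.shape[0], dtype=np.float64)
    fmol_to_mM = 1000.0 / params.site_volume_um3  # fmol/um^3 == mol/L == 1000 mM
    for cid in state.cell_ids(cpm_core.LIVE):
        n = int(state.volumes_by_id[cid])
        if n == 0:
            raise cpm_core.ConsistencyError(f"live cell {cid} has zero sites")
        rate_by_id[cid] = -params.uptake_fmol_per_cell_s / n * fmol_to_mM
    return rate_by_id[state.labels]


def _explicit_step_arrays(
    conc: np.ndarray,
    cell_mask: np.ndarray,
    source: np.ndarray,
    dt: float,
    params: OxygenParams,
) -> np.ndarray:
    p = np.pad(conc, 1, mode="edge")  # zero-flux at the domain edge
    lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * conc
    new = conc + dt * (params.laplacian_rate_per_s * lap + source)
    new = np.clip(new, 0.0, params.env_concentration_mM)
    new[~cell_mask] = params.env_concentration_mM
    return new


def explicit_substep(
    field: OxygenField,
    sources: np.ndarray,
    dt: float,
    params: OxygenParams,
    cell_mask: np.ndarray,
) -> OxygenField:
    """One forward-Euler update of the cell-occupied sites.

    ``cell_mask`` marks non-medium sites (live and dead cells); all other
    sites are re-clamped to the environmental concentration after the update.
    """
    if dt > params.stability_dt_s * (1 + 1e-12):
        raise ValueError(
            f"dt={dt:g}s exceeds the explicit stability bound "
            f"{params.stability_dt_s:g}s"
        )
    return OxygenField(_explicit_step_arrays(field.conc_mM, cell_mask, sources, dt, params))


def relax_over_mcs(
    field: OxygenField,
    state: cpm_core.LatticeState,
    params: OxygenParams,
    sources: Optional[np.ndarray] = None,
) -> OxygenField:
    """Advance the field over one MCS worth of physical time.

    In ``explicit_substep`` mode the field is integrated over beta seconds in
    ceil(beta/dt_max) equal stable substeps. In ``quasi_steady`` mode the
    field is relaxed to the steady state of the reaction--diffusion balance
    (projected residual max-norm below ``steady_tol_mM_s``), warm-started
    from the supplied field.
    """
    if field.conc_mM.shape != state.labels.shape:
        raise ValueError("field and lattice shapes differ")
    if sources is None:
        sources = source_raster(state, params)
    cell_mask = state.labels != cpm_core.MEDIUM

    if params.mode == "explicit_substep":
        n_sub = int(np.ceil(params.beta_s_per_mcs / params.stability_dt_s))
        dt = params.beta_s_per_mcs / n_sub
        conc = field.conc_mM
        for _ in range(n_sub):
            conc = _explicit_step_arrays(conc, cell_mask, sources, dt, params)
        return OxygenField(conc)

    conc = field.conc_mM.copy()
    n = max(conc.shape)
    omega = 2.0 / (1.0 + np.sin(np.pi / n))
    sweeps = steady_state_sor(
        conc,
        cell_mask,
        sources,
        params.env_concentration_mM,
        params.laplacian_rate_per_s,
        omega,
        params.steady_tol_mM_s,
        params.max_iterations,
    )
    if sweeps < 0:
        raise NonConvergenceError(
            f"steady-state relaxation did not reach {params.steady_tol_mM_s:g} mM/s "
            f"within {params.max_iterations} sweeps "
            f"(lattice {conc.shape}, {state.n_non_medium_sites} cell sites)"
        )
    return OxygenField(conc)


def quasi_steady(field, state, params):
    """Relax to steady state regardless of the configured mode."""
    return relax_over_mcs(field, state, replace(params, mode="quasi_steady"))


def mean_concentration(field: OxygenField, cell_sites: np.ndarray) -> float:
    """Arithmetic mean concentration (mM) over a cell's sites."""
    sites = np.atleast_2d(np.asarray(cell_sites, dtype=np.int64))
    if sites.size == 0:
        raise ValueError("cell has no sites")
    return float(field.conc_mM[sites[:, 0], sites[:, 1]].mean())


def mean_concentration_by_cell(
    field: OxygenField, state: cpm_core.LatticeState
) -> np.ndarray:
    """Mean concentration (mM) per agent id, indexed by id (0 = medium)."""
    n_ids = state.types_by_id.shape[0]
    sums = np.bincount(
        state.labels.ravel(), weights=field.conc_mM.ravel(), minlength=n_ids
    )
    counts = np.bincount(state.labels.ravel(), minlength=n_ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return means
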