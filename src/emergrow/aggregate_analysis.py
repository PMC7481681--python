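"""Aggregate morphology and probability-area analysis.

The aggregate is the set of all non-medium sites (live and dead cells). Its
shape is summarised by the eccentricity of the best-fit ellipse obtained
from the second central moments of the site coordinates: if l1 >= l2 are the
eigenvalues of the coordinate covariance, the ellipse semi-axes are
2*sqrt(l1) and 2*sqrt(l2) (exact for a filled ellipse) and

    eccentricity = sqrt(1 - (minor/major)^2) = sqrt(1 - l2/l1).

The probability area of a response j weights each aggregate site's area by
the per-MCS response probability at that site's oxygen concentration,

    A_j = sum_sites q_j exp(-((c - c_j)/sigma_j)^2) * alpha^2   [um^2],

and measures the effective area in which the response is active; the final
aggregate size is expected where the proliferation and death probability
areas balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import cpm_core, oxygen_pde, phenotype

#: Samples in the end-of-run eccentricity window (one per kMCS in the study).
ECC_WINDOW_SAMPLES = 25
HIST_BIN_EDGES = np.linspace(0.0, 1.0, 11)


class DegenerateMaskError(ValueError):
    """Mask has too few or collinear sites for an ellipse fit."""


def aggregate_mask(
    state: cpm_core.LatticeState, site_length_um: float = 2.96
) -> tuple[np.ndarray, float]:
    """Boolean mask of all non-medium sites and the aggregate area in mm^2."""
    mask = state.labels != cpm_core.MEDIUM
    area_mm2 = float(mask.sum()) * (site_length_um * 1e-3) ** 2
    return mask, area_mm2


@dataclass(frozen=True)
class EllipseFit:
    centroid_um: tuple[float, float]
    major_semiaxis_um: float
    minor_semiaxis_um: float
    eccentricity: float


def ellipse_eccentricity(mask: np.ndarray, site_length_um: float = 2.96) -> EllipseFit:
    """Best-fit ellipse of a site mask via second central moments."""
    coords = np.argwhere(mask).astype(np.float64)
    if coords.shape[0] < 3:
        raise DegenerateMaskError("need at least 3 sites for an ellipse fit")
    centroid = coords.mean(axis=0)
    x = coords - centroid
    cov = x.T @ x / coords.shape[0]
    evals = np.linalg.eigvalsh(cov)  # ascending
    if evals[0] <= 0:
        raise DegenerateMaskError("collinear mask: minor axis has zero extent")
    minor = 2.0 * np.sqrt(evals[0]) * site_length_um
    major = 2.0 * np.sqrt(evals[1]) * site_length_um
    ecc = float(np.sqrt(1.0 - (minor / major) ** 2))
    return EllipseFit(
        centroid_um=(centroid[0] * site_length_um, centroid[1] * site_length_um),
        major_semiaxis_um=float(major),
        minor_semiaxis_um=float(minor),
        eccentricity=ecc,
    )


@dataclass(frozen=True)
class EccentricitySeries:
    """Eccentricity samples with their distribution and end-window statistics.

    The histogram uses bin edges 0.0, 0.1, ..., 1.0 (right-open except the
    last bin) normalised to unit mass; the window mean/SD (sample SD,
    ddof=1) covers the final `ECC_WINDOW_SAMPLES` samples and identifies
    consistently eccentric final shapes (high mean, low SD).
    """

    mcs: np.ndarray
    eccentricity: np.ndarray
    histogram: np.ndarray
    window_mean: Optional[float]
    window_std: Optional[float]


def eccentricity_summary(
    mcs: np.ndarray, eccentricity: np.ndarray
) -> EccentricitySeries:
    mcs = np.asarray(mcs, dtype=np.int64)
    ecc = np.asarray(eccentricity, dtype=np.float64)
    if mcs.shape != ecc.shape or mcs.ndim != 1:
        raise ValueError("mcs and eccentricity must be equal-length 1-D")
    hist, _ = np.histogram(ecc, bins=HIST_BIN_EDGES)
    weights = hist / hist.sum() if hist.sum() > 0 else hist.astype(float)
    if ecc.size >= ECC_WINDOW_SAMPLES:
        window = ecc[-ECC_WINDOW_SAMPLES:]
        w_mean = float(window.mean())
        w_std = float(window.std(ddof=1))
    else:
        warnings.warn(
            f"fewer than {ECC_WINDOW_SAMPLES} samples; window statistics unset",
            stacklevel=2,
        )
        w_mean = w_std = None
    return EccentricitySeries(mcs, ecc, weights, w_mean, w_std)


def probability_area(
    field: oxygen_pde.OxygenField,
    mask: np.ndarray,
    response: phenotype.BuiltResponse,
    site_length_um: float = 2.96,
) -> float:
    """Probability-weighted aggregate area of one response, in um^2.

    Uses the per-site concentration (not the per-cell mean) so the integral
    resolves the oxygen gradient inside the aggregate.
    """
    if field.conc_mM.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    c_uM = field.conc_mM[mask] * 1000.0
    p = phenotype.response_probability(c_uM, response)
    return float(np.sum(p) * site_length_um**2)
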