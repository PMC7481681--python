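# Methods

## Model overview

`emergrow` couples three layers on a fixed square lattice, advanced in a
pinned per-MCS order: (i) one Monte Carlo sweep of cellular-Potts copy
attempts, (ii) one oxygen relaxation, (iii) one round of stochastic
phenotype sampling with death and division applied immediately. All
randomness in a run flows through a single seeded NumPy generator in a
documented order (per MCS: source-site draws, neighbour draws, acceptance
uniforms; then one death and one proliferation uniform vector over live
cells in ascending id order), so a `(config, seed)` pair reproduces every
output byte for byte.

## Cellular Potts layer

State is an integer-labelled raster (0 = medium) plus an agent registry
(type and site count per id; ids are never reused). The effective energy is

    H = Σ_cells λ_v (n_sites − v_target)² + Σ_(ordered Moore pairs) (1 − δ) J(τ, τ′)

with the contact sum over *ordered* site pairs (each unordered interface
counted twice), which is how the double sum is written; the local ΔH uses
the matching factor of two. Volume constraints are expressed in lattice
sites (v = 36, λ = 2 for live cells; λ = 0 for medium and dead types).
Copy attempts draw a uniform source site and a uniform von Neumann
neighbour; target sites outside the domain are rejected (fixed,
non-periodic boundary; sites beyond the boundary also contribute no contact
energy), same-agent copies are no-ops, and acceptance follows
`exp(−max(0, ΔH)/H*)` with H* = 10. Agent fragmentation is permitted, as in
the plain model. An agent emptied mid-sweep keeps its volume penalty until
end-of-MCS registry cleanup; this is the convention the local ΔH and the
test oracle share.

Because adhesion acts as a surface tension, a solitary cell equilibrates
near 30 sites rather than the 36-site target; this is ordinary
Potts-model behaviour and the volume-fluctuation test band ([26, 46])
accounts for it.

## Oxygen layer

The field obeys `∂c/∂t = D∇²c + s` with D = 2500 μm²/s (the time unit is
taken as seconds), each live cell a −0.5 fmol/s sink spread evenly over its
current sites, dead cells inert, and every medium site held at 0.2 mM.
Converting molar uptake to a concentration rate needs a voxel volume: each
site is a voxel of α³ (α = 2.96 μm the only available depth scale, kept as
a parameter so the choice is auditable). One consequence of a fixed
per-cell uptake is that the unconstrained steady state can go negative deep
inside large aggregates; the solver therefore treats c ≥ 0 as an obstacle
constraint (projected relaxation), which also enforces the physical range
0 ≤ c ≤ 0.2 mM.

Two solvers share the same discretisation (second-order central
differences, zero-flux at the domain edge — in practice the edge is always
clamped medium):

* `quasi_steady` (default): projected red-black SOR to a residual max-norm
  below 10⁻⁹ mM/s, warm-started from the previous MCS. Justified by the
  time-scale separation β = 0.1 s/MCS: diffusion across the domain is much
  faster than cell motility.
* `explicit_substep`: forward Euler with dt ≤ α²/4D ≈ 8.8·10⁻⁴ s
  (≈ 115 substeps per MCS), retained for verification; the two modes agree
  to ~10⁻¹² mM on single-cell fixtures.

The initial field is uniform at 0.2 mM.

## Phenotype layer

Each response (proliferation, death) is a Gaussian in the cell's *mean*
oxygen concentration with biological parameters: target c_j (μM), width w_j
(μM) and population multiplier n_j per 10 kMCS. The derived per-MCS peak
probability is q = n^(1/10000) − 1, so that a population held at the target
multiplies by exactly n over 10 000 MCS, and the Gaussian width
γ = w/√(ln q − ln p_o) places the cutoff probability p_o = 10⁻⁶/MCS exactly
at offset w. The per-step time-scale factor is folded into q; applying it
separately would break the stated multiplier semantics. The width formula
uses the square root; without it the cutoff construction does not hold and
the expression is dimensionally inconsistent inside the Gaussian.

Death is sampled before proliferation each MCS and excludes it (a cell
cannot do both in one step; the order is pinned for reproducibility).
Division cuts the cell along its minor principal axis (second central
moments of its site coordinates): sites with positive projection on the
major axis become a fresh agent, sites exactly on the cut stay with the
parent, and degenerate (equal-moment) shapes cut perpendicular to the
lattice column direction. Cells under 4 sites skip division (guard against
loss of viability through tiny fragments). Death switches the agent to a
dead type — no respiration, no response sampling, zero volume-constraint
strength — after which adhesion-driven compaction removes it over a few
kMCS; dead types reuse the live contact energies (overridable).

## Growth-law fitting

The unified Richards family is implemented with the rate normalisation
`S^(S/(S−1))`, the unique choice whose S → 1 limit is the Gompertz curve
`A(W0/A)^exp(−eGk)`; |S − 1| < 10⁻⁶ dispatches to the closed Gompertz
branch. Classical submodels are fitted as fixed-shape members (S = 2/3
Bertalanffy, S → 1 Gompertz, S = 2 logistic).

Protocol: the time axis is re-zeroed at the first sample with ≥ 15 cells
(small populations make the early curve highly variable; the threshold
mimics a minimum detectable size), only samples at adjusted time ≥ 0 enter
the plain (unweighted) least-squares objective — W0 is by definition the
size at the adjusted origin — time is normalised to [0, 1] for the solver
and rates are reported per 100 kMCS. Bounded trust-region least squares
runs from three deterministic starts (and, in the four-model comparison,
from each classical optimum, which guarantees the nested-model R²
ordering up to solver tolerance); bounds are A, W0 ∈ (0, 10·max area],
G ∈ (0, 100] (normalised), S ∈ [0.1, 3]. Confidence half-widths are
asymptotic (Jacobian at the optimum, t quantile, n − p degrees of
freedom); goodness of fit is R² = 1 − SSR/SST. At least 8 post-origin
samples are required. Fit reports carry areas both in mm² and in the
10⁻³ mm² scaling usually quoted for sub-millimetre aggregates.

## Shape and probability-area analysis

The aggregate mask is every non-medium site (live + dead; no
connected-component filtering — a single colony is grown). Eccentricity
comes from the eigenvalues l1 ≥ l2 of the site-coordinate covariance:
semi-axes 2√l (exact for a filled ellipse), e = √(1 − l2/l1). Shape is
sampled every curve interval from 1 kMCS; the distribution uses bins of 0.1
(right-open except the last) normalised to unit mass, and the end-of-run
window reports the mean and sample standard deviation (ddof = 1) of the
final 25 samples. The probability area of a response sums the per-site
response probability (per-site concentration, not the cell mean, so the
internal gradient is resolved) times α² over the mask, in μm².

## Study configurations and scaled tiers

Full study: 203×203 sites (600 μm at α = 2.96 μm), five 6×6 cells in a
plus-shaped central cluster, quasi-steady oxygen, sampling every 1 kMCS,
durations per profile (100 kMCS for Control/Increase/Expand, 150 for
Shift/Shrink/Decrease 1, 250 for Decrease 2 — long enough for each
aggregate to converge). A full-scale trial takes hours on one CPU
(`scripts/full_reproduction.py`).

The test suite and the acceptance script use a reduced tier: 64×64 sites,
five initial cells, sampling every 500 MCS (finer than the full study so
the 15-cell origin leaves a usable fit window at short durations). On this
domain hypoxia limits the aggregate radius to ~60 μm; the area curve
plateaus near 0.011 mm² by ~40 kMCS, so the demonstration run uses
45 kMCS. Two known small-scale effects are worth keeping in mind when
interpreting reduced-tier numbers: with only ~25–40 cells the area noise is
~4% (vs ~1% at full scale), which caps attainable R² near 0.97 and makes
the fitted shape parameter unstable; and after ~50 kMCS the small colony
exhibits boom–bust oscillations (hypoxic-core death waves) rather than the
smooth saturation seen at full scale, so the equality of proliferation and
death probability areas at final size is a full-scale diagnostic, not a
reduced-tier one. The plateau property — a near-constant proliferation
probability area while total area keeps growing — already holds at the
reduced scale and is tested there.

## What the synthetic fixtures do and do not show

`generate_fixture_curve` samples the unified Richards model on the study's
time grid with multiplicative Gaussian noise and a configurable 15-cell
crossing time. It validates the fitting layer (parameter recovery,
submodel selection, time-rescaling invariance) under ideal,
correctly-specified noise; it does not emulate the autocorrelated,
state-dependent fluctuations of simulated colonies, so recovery tolerances
met on fixtures do not bound fit uncertainty on simulation output. The
benchmark coefficient table in `emergrow.reference` provides full-scale
trial coefficients for comparison without re-running the multi-hour study.

## Numerical choices and limitations

* SOR relaxation factor ω = 2/(1 + sin(π/N)); convergence is declared on
  the projected residual (|r| where c > 0, max(r, 0) where c = 0).
* Division tie-breaks and the axis-sign convention are pinned for
  determinism; sites exactly on the cut line stay with the parent.
* The histogram, window length (25 samples) and adjusted-origin threshold
  (15 cells) are parameters with the study defaults above.
* 2-D only; no growth inhibitors, no multi-species chemistry, no
  perimeter/shape constraints, no connectedness repair — outside scope by
  design.
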