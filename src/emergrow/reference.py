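"""Benchmark fit coefficients from full-scale reference simulations.

These records hold the unified-Richards coefficients (point estimate and 95%
confidence half-width), the adjusted-time origin, and the per-model
coefficients of determination for full-scale (203x203 lattice, 100-250 kMCS)
reference runs of every phenotype preset: three replicate trials for Control
and Decrease 1, one trial for each remaining variation. They serve as the
long-running reproduction targets for this package and as input to the
report-aggregation helpers; areas are in mm^2, rates in (100 kMCS)^-1.
"""

from __future__ import annotations

from .growth_fitting import summarize_trials

#: Per-trial unified-Richards coefficients:
#: (A_mm2, ci_A, W0_mm2, G_per_100kmcs, ci_G, S, ci_S, origin_mcs)
REFERENCE_URICHARDS_TRIALS = {
    "Control": [
        (0.1222, 0.001195, 0.005093, 2.703, 0.1046, 1.394, 0.1143, 8000),
        (0.1234, 0.001371, 0.005766, 2.630, 0.1075, 1.354, 0.1245, 11000),
        (0.1236, 0.001030, 0.004569, 2.728, 0.09293, 1.430, 0.09631, 7000),
    ],
    "Decrease 1": [
        (0.1195, 0.0009811, 0.004543, 2.095, 0.08017, 1.421, 0.1137, 9000),
        (0.1207, 0.0007499, 0.004578, 2.119, 0.06377, 1.501, 0.09068, 8000),
        (0.1191, 0.0004992, 0.005154, 2.168, 0.04557, 1.591, 0.06837, 9000),
    ],
    "Expand 1": [(0.1111, 0.0007707, 0.004447, 2.913, 0.08141, 1.269, 0.08180, 9000)],
    "Increase 1": [(0.1206, 0.001385, 0.005067, 2.484, 0.1061, 1.422, 0.1238, 7000)],
    "Shrink 1": [(0.1177, 0.0005813, 0.004648, 2.262, 0.05806, 1.523, 0.08008, 6000)],
    "Shift 1": [(0.1154, 0.0008110, 0.004744, 1.713, 0.04079, 1.063, 0.06899, 8000)],
    "Decrease 2": [(0.1116, 0.0005863, 0.005163, 1.107, 0.02593, 1.730, 0.07835, 16000)],
    "Expand 2": [(0.1170, 0.0009594, 0.005425, 2.817, 0.1014, 1.687, 0.1190, 9000)],
    "Increase 2": [(0.1225, 0.001329, 0.004866, 2.562, 0.1018, 1.410, 0.1116, 11000)],
    "Shrink 2": [(0.1174, 0.0009199, 0.004578, 2.065, 0.07872, 1.555, 0.1171, 6000)],
    "Shift 2": [(0.1221, 0.0004837, 0.004630, 2.325, 0.04654, 1.409, 0.06052, 9000)],
}

#: Per-trial coefficients of determination, order
#: (urichards, bertalanffy, gompertz, logistic).
REFERENCE_R_SQUARED = {
    "Control": [
        (0.9947, 0.9830, 0.9915, 0.9896),
        (0.9942, 0.9848, 0.9918, 0.9889),
        (0.9961, 0.9828, 0.9922, 0.9917),
    ],
    "Decrease 1": [
        (0.9915, 0.9782, 0.9876, 0.9868),
        (0.9949, 0.9798, 0.9899, 0.9918),
        (0.9976, 0.9798, 0.9909, 0.9956),
    ],
    "Expand 1": [(0.9969, 0.9883, 0.9953, 0.9891)],
    "Increase 1": [(0.9940, 0.9830, 0.9907, 0.9899)],
    "Shrink 1": [(0.9962, 0.9803, 0.9908, 0.9934)],
    "Shift 1": [(0.9959, 0.9920, 0.9958, 0.9817)],
    "Decrease 2": [(0.9955, 0.9765, 0.9872, 0.9948)],
    "Expand 2": [(0.9961, 0.9766, 0.9879, 0.9950)],
    "Increase 2": [(0.9953, 0.9840, 0.9921, 0.9909)],
    "Shrink 2": [(0.9920, 0.9750, 0.9859, 0.9895)],
    "Shift 2": [(0.9976, 0.9846, 0.9940, 0.9930)],
}


def reference_fit_records(profile_name: str) -> list[dict]:
    """Benchmark trials of one profile as summarize_trials-compatible records."""
    rows = REFERENCE_URICHARDS_TRIALS[profile_name]
    return [
        {
            "A_mm2": a,
            "W0_mm2": w0,
            "G_per_100kmcs": g,
            "S": s,
            "ci_A_mm2": ci_a,
            "ci_G_per_100kmcs": ci_g,
            "ci_S": ci_s,
            "origin_mcs": origin,
        }
        for (a, ci_a, w0, g, ci_g, s, ci_s, origin) in rows
    ]


def reference_trial_means(profile_name: str) -> dict:
    """Mean/SD of the benchmark coefficients for one profile."""
    return summarize_trials(reference_fit_records(profile_name))
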