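"""Published regression configurations of the study system.

Each entry pins a regression reported for *Centris pallida* (slope/exponent,
intercept, R², sample size, and observed head-width span) as a generator
configuration, so synthetic datasets can be drawn at exactly those conditions
and the fitting machinery checked by parameter recovery.  Log-log entries
carry a plausible intercept on the log10 scale (the publication reports only
the exponent and R²; the intercept does not enter slope recovery).
"""
from __future__ import annotations

from typing import Dict

import numpy as np

from .allometry import fit_scaling
from .eyegen import AllometryGenParams, generate_allometry_dataset

#: Printed regressions, keyed by a descriptive name.
PRINTED_REGRESSIONS: Dict[str, AllometryGenParams] = {
    # ommatidia number vs head width (linear)
    "male_ommatidia_number": AllometryGenParams(
        slope=1095.0, intercept=5198.0, r_squared_target=0.56,
        x_range=(4.53, 6.02), n=18,
    ),
    "female_ommatidia_number": AllometryGenParams(
        slope=1247.0, intercept=3651.0, r_squared_target=0.75,
        x_range=(4.85, 5.97), n=8,
    ),
    # eye height vs head width (log-log scaling exponents)
    "small_male_eye_height": AllometryGenParams(
        slope=1.10, intercept=-0.213, r_squared_target=0.90,
        x_range=(4.53, 5.27), n=18, log_log=True,
    ),
    "large_male_eye_height": AllometryGenParams(
        slope=0.61, intercept=0.141, r_squared_target=0.67,
        x_range=(5.34, 6.02), n=12, log_log=True,
    ),
    "female_eye_height": AllometryGenParams(
        slope=0.83, intercept=-0.076, r_squared_target=0.84,
        x_range=(4.85, 5.97), n=13, log_log=True,
    ),
    # local inter-ommatidial angles vs head width in males (linear, degrees/mm)
    "male_dphi_x": AllometryGenParams(
        slope=-0.93, intercept=6.84, r_squared_target=0.52,
        x_range=(4.53, 6.02), n=27,
    ),
    "male_dphi_y": AllometryGenParams(
        slope=-0.58, intercept=4.18, r_squared_target=0.53,
        x_range=(4.53, 6.02), n=27,
    ),
    # relative eye:head height vs head width, small males (linear)
    "small_male_rel_eye_height": AllometryGenParams(
        slope=-0.07, intercept=1.26, r_squared_target=0.39,
        x_range=(4.53, 5.27), n=18,
    ),
}


def recover_mean_slope(
    name: str, n_seeds: int = 500, base_seed: int = 1
) -> tuple[float, float]:
    """Monte-Carlo slope recovery at a printed configuration.

    Draws ``n_seeds`` independent datasets at the named configuration, refits
    each by OLS (log10 axes for log-log entries), and returns the mean
    recovered slope with its Monte-Carlo standard error.
    """
    base = PRINTED_REGRESSIONS[name]
    seeds = np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_seeds)
    slopes = np.empty(n_seeds)
    for i, s in enumerate(seeds):
        params = AllometryGenParams(
            slope=base.slope, intercept=base.intercept,
            r_squared_target=base.r_squared_target, x_range=base.x_range,
            n=base.n, log_log=base.log_log, seed=int(s),
        )
        df = generate_allometry_dataset(params)
        slopes[i] = fit_scaling(df["x"], df["y"], log_log=base.log_log).slope
    return float(slopes.mean()), float(slopes.std(ddof=1) / np.sqrt(n_seeds))
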