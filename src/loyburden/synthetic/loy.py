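"""Array-style LOY measurement simulation.

Emulates what a SNP-array LOY pipeline would emit per man: per-probe log R
ratios summarised into mLRR-Y, a dichotomous PAR-LOY call from a parametric
detector, and the estimated clone cell fraction AF-LOY.  The phase-based
PAR-LOY caller itself is not modelled — only its outputs are.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from ..config import SimulationConfig
from ..loy_scores import compute_mlrr_y, score_measures

_STAGE_LOY = 2


def simulate_loy_inputs(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate mLRR-Y, PAR-LOY, AF-LOY and the composite PAR-LOYq per man.

    For each male: probe LRRs are Gaussian around ``-lrr_slope * clone
    fraction`` and summarised by :func:`loyburden.loy_scores.compute_mlrr_y`;
    the PAR-LOY call fires with sensitivity ``expit((f - midpoint) /
    steepness)`` in the clone fraction f (or a constant sensitivity if
    ``detection_sensitivity`` is set), with a configurable false-positive
    rate in men without a clone; AF-LOY is the clone fraction plus Gaussian
    noise for called men, and 0 (or missing, per ``af_loy_undetected``)
    otherwise.  Females receive missing values throughout.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), _STAGE_LOY])
    n = len(cohort)
    male = cohort["sex"].to_numpy() == "M"
    frac = cohort["clone_fraction"].to_numpy(dtype=float)
    present = cohort["clone_present"].to_numpy() == 1

    mlrr = np.full(n, np.nan)
    par = np.full(n, np.nan)
    af = np.full(n, np.nan)

    probes = rng.standard_normal((n, config.n_probes)) * config.lrr_probe_sd \
        - config.lrr_slope * frac[:, None]
    for i in np.flatnonzero(male):
        mlrr[i] = compute_mlrr_y(probes[i], summariser="median")

    if config.detection_sensitivity is not None:
        sens = np.full(n, float(config.detection_sensitivity))
    else:
        sens = expit((frac - config.detection_midpoint) / config.detection_steepness)
    p_call = np.where(present, sens, config.detection_false_positive_rate)
    call = (rng.random(n) < p_call) & male
    par[male] = call[male].astype(float)

    noise = rng.standard_normal(n) * config.af_loy_noise_sd
    af_called = np.clip(np.where(present, frac, 0.02) + noise, 0.0, 1.0)
    af[male] = np.where(call[male], af_called[male],
                        np.nan if config.af_loy_undetected == "missing" else 0.0)

    measures = pd.DataFrame({
        "iid": cohort["iid"].to_numpy(),
        "mlrr_y": mlrr,
        "par_loy": par,
        "af_loy": af,
    })
    return score_measures(measures)
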