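"""Cohort, latent LOY clone and phenotype simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ..config import SimulationConfig, ConfigurationError


class AlignmentError(ValueError):
    """Raised when carrier indicators do not align with cohort individuals."""


# Stage offsets mixed into the seed so each generation stage has an
# independent, call-order-invariant stream.
_STAGE_COHORT = 1
_STAGE_PHENO = 4


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a cohort with covariates and a latent LOY clone state.

    Individuals receive sex, age (uniform over ``age_range``), ever-smoking
    status, genotyping-chip indicator and independent standard-normal
    principal-component scores.  Carrier status for each configured carrier
    gene is pre-assigned here (columns ``carrier_<gene>``) so the exome
    simulator can plant genotypes consistently.  The latent clone state is
    zero-inflated: presence follows a logistic model in age, smoking and
    LOY-risk carrier status; the clone cell fraction, given presence, is
    Beta distributed.

    Returns a DataFrame indexed 0..n-1 with column ``iid`` holding sample ids.
    """
    config.validate()
    rng = _rng(config, _STAGE_COHORT)
    n = config.n_individuals

    iid = np.array([f"S{i:06d}" for i in range(n)])
    is_male = rng.random(n) < config.prop_male
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n).astype(float)
    smoke = (rng.random(n) < config.smoking_prevalence).astype(int)
    chip = (rng.random(n) < config.chip_fraction).astype(int)
    pcs = rng.standard_normal((n, config.n_pcs))

    cohort = pd.DataFrame({"iid": iid, "sex": np.where(is_male, "M", "F"),
                           "age": age, "ever_smoked": smoke, "chip": chip})
    for k in range(config.n_pcs):
        cohort[f"PC{k + 1}"] = pcs[:, k]

    # planted carriers: distinct individuals per gene, assigned up front
    loy_risk = np.zeros(n)
    for spec in config.carrier_gene_specs:
        idx = rng.choice(n, size=spec.n_carriers, replace=False)
        col = np.zeros(n, dtype=int)
        col[idx] = 1
        cohort[f"carrier_{spec.gene}"] = col
        if spec.loy_risk_log_odds != 0.0:
            loy_risk = loy_risk + spec.loy_risk_log_odds * col

    age_mid = (lo + hi) / 2.0
    eta = (
        logit(config.clone_baseline_prevalence)
        + config.clone_age_log_odds_per_decade * (age - age_mid) / 10.0
        + config.clone_smoking_log_odds * smoke
        + loy_risk
    )
    clone_present = (rng.random(n) < expit(eta)).astype(int)
    a, b = config.clone_fraction_beta
    frac = rng.beta(a, b, size=n)
    cohort["clone_present"] = clone_present
    cohort["clone_fraction"] = np.where(clone_present == 1, frac, 0.0)
    return cohort


def _aligned_carrier(cohort: pd.DataFrame, carrier) -> np.ndarray:
    """Validate and align a carrier indicator with the cohort."""
    n = len(cohort)
    if isinstance(carrier, str):
        col = f"carrier_{carrier}" if f"carrier_{carrier}" in cohort else carrier
        if col not in cohort:
            raise AlignmentError(f"no carrier column for gene {carrier!r} in cohort")
        return cohort[col].to_numpy(dtype=float)
    if isinstance(carrier, pd.Series):
        if carrier.index.equals(pd.Index(cohort["iid"])):
            return carrier.to_numpy(dtype=float)
        if len(carrier) == n:
            return carrier.to_numpy(dtype=float)
        raise AlignmentError("carrier indicator index does not align with cohort ids")
    arr = np.asarray(carrier, dtype=float)
    if arr.shape != (n,):
        raise AlignmentError(
            f"carrier indicator has length {arr.shape}, cohort has {n} individuals"
        )
    return arr


def solve_intercept(eta: np.ndarray, target_prevalence: float) -> float:
    """Intercept b0 such that mean(expit(b0 + eta)) equals the target."""
    lo_b, hi_b = -30.0, 30.0
    f = lambda b0: expit(b0 + eta).mean() - target_prevalence
    return brentq(f, lo_b, hi_b, xtol=1e-12)


def simulate_binary_trait(
    cohort: pd.DataFrame,
    carrier,
    odds_ratio: float,
    baseline_prevalence: float,
    age_log_odds_per_decade: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary trait from a logistic model.

    The intercept is solved so that the expected prevalence among
    non-carriers equals ``baseline_prevalence``; the carrier log-odds is
    ``ln(odds_ratio)``.
    """
    if odds_ratio <= 0:
        raise ConfigurationError("odds_ratio must be positive")
    if rng is None:
        rng = np.random.default_rng()
    c = _aligned_carrier(cohort, carrier)
    age = cohort["age"].to_numpy(dtype=float)
    eta_cov = age_log_odds_per_decade * (age - age.mean()) / 10.0
    b0 = solve_intercept(eta_cov[c == 0], baseline_prevalence)
    eta = b0 + eta_cov + np.log(odds_ratio) * c
    return (rng.random(len(cohort)) < expit(eta)).astype(int)


def simulate_phenotypes(
    cohort: pd.DataFrame,
    carrier,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    effect_quantitative: float | None = None,
    effect_binary: float | None = None,
) -> pd.DataFrame:
    """Simulate a quantitative and a binary phenotype with a carrier effect.

    Quantitative trait: covariate effects plus standard-normal noise,
    standardised to mean 0 / SD 1 among non-carriers, after which the
    carrier effect (``effect_quantitative`` of the matching carrier spec,
    in non-carrier SD units) is added — so the generating effect is exactly
    on the reported scale.  Binary trait: logistic model with the intercept
    solved to give ``binary_trait_baseline_prevalence`` among non-carriers
    and carrier log-odds ``ln(effect_binary)``.
    """
    if rng is None:
        rng = _rng(config, _STAGE_PHENO)
    c = _aligned_carrier(cohort, carrier)

    if isinstance(carrier, str):
        gene = carrier.removeprefix("carrier_")
        spec = next((s for s in config.carrier_gene_specs if s.gene == gene), None)
        eff_q = spec.effect_quantitative if spec else 0.0
        eff_b = spec.effect_binary if spec else 1.0
    else:
        specs = config.carrier_gene_specs
        eff_q = specs[0].effect_quantitative if specs else 0.0
        eff_b = specs[0].effect_binary if specs else 1.0
    if effect_quantitative is not None:
        eff_q = effect_quantitative
    if effect_binary is not None:
        eff_b = effect_binary

    age = cohort["age"].to_numpy(dtype=float)
    male = (cohort["sex"].to_numpy() == "M").astype(float)
    base = (
        config.quant_age_effect * (age - age.mean()) / 10.0
        + config.quant_sex_effect * male
        + rng.standard_normal(len(cohort))
    )
    nc = c == 0
    base = (base - base[nc].mean()) / base[nc].std(ddof=1)
    quant = base + eff_q * c

    binary = simulate_binary_trait(
        cohort, c, eff_b, config.binary_trait_baseline_prevalence,
        config.binary_age_log_odds_per_decade, rng,
    )
    return pd.DataFrame({"iid": cohort["iid"].to_numpy(),
                         "quant_trait": quant, "binary_trait": binary})
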