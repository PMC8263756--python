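"""Robustness analyses for gene-level association signals.

* leave-one-out: drop each qualifying variant in turn and re-test, to show
  no single variant drives the signal;
* subset re-analysis: rebuild the set excluding multi-allelic sites,
  indels, or everything but LOFTEE high-confidence loss-of-function calls;
* confounding check: association of carrier status with each genetic
  principal component (population-structure artefact screen);
* phenome scan: the carrier indicator tested across a panel of traits,
  each with its own family, transformation and covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import (NullTraitResults, GeneSetAssociation, burden_test,
                          fit_null, DEFAULT_COVARIATES)
from .burden import BurdenSet, build_burden_set

logger = logging.getLogger(__name__)

SCHEMES = {
    "none": (),
    "no_multiallelic": ("multi_allelic",),
    "no_indel": ("indel",),
    "loftee_hc_only": ("non_HC_loftee",),
}

# Leave-one-out retention is a qualitative robustness check; retention is
# judged at a nominal level by default (configurable) because at realistic
# carrier counts the discovery threshold itself has limited single-drop power.
LOO_RETENTION_ALPHA = 0.05


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------

def leave_one_out(
    burden_set: BurdenSet,
    null: NullTraitResults,
    weights=None,
    retention_alpha: float = LOO_RETENTION_ALPHA,
    tests=("burden", "skat", "acatv"),
) -> pd.DataFrame:
    """Drop each qualifying variant in turn and re-run the set tests.

    Returns one reference row (``dropped_variant = '<none>'``) plus one row
    per dropped variant with the post-drop carrier count, burden and
    omnibus p-values, the change in -log10 omnibus p relative to the full
    set, and whether the association is retained at ``retention_alpha``.
    """
    if burden_set.n_variants < 2:
        raise ValueError("leave-one-out requires a set with at least 2 variants")
    full = GeneSetAssociation(burden_set, null, weights=weights, tests=tests).fit()
    ref_log10 = -np.log10(full.p_omnibus) if np.isfinite(full.p_omnibus) else np.nan
    rows = [{
        "gene": burden_set.gene, "dropped_variant": "<none>",
        "n_variants": full.n_variants, "n_carriers": full.n_carriers,
        "p_burden": full.p_burden, "p_omnibus": full.p_omnibus,
        "delta_log10_p": 0.0,
        "retained": bool(np.isfinite(full.p_omnibus) and full.p_omnibus < retention_alpha),
        "skipped": False,
    }]
    for key in burden_set.variant_keys:
        sub = burden_set.drop_variant(key)
        if sub.n_carriers == 0:
            rows.append({"gene": burden_set.gene, "dropped_variant": key,
                         "n_variants": sub.n_variants, "n_carriers": 0,
                         "p_burden": np.nan, "p_omnibus": np.nan,
                         "delta_log10_p": np.nan, "retained": False, "skipped": True})
            continue
        res = GeneSetAssociation(sub, null, tests=tests,
                                 weights=_subset_weights(weights, burden_set, key)).fit()
        p_omni = res.p_omnibus
        rows.append({
            "gene": burden_set.gene, "dropped_variant": key,
            "n_variants": sub.n_variants, "n_carriers": sub.n_carriers,
            "p_burden": res.p_burden, "p_omnibus": p_omni,
            "delta_log10_p": (-np.log10(p_omni) - ref_log10)
            if np.isfinite(p_omni) else np.nan,
            "retained": bool(np.isfinite(p_omni) and p_omni < retention_alpha),
            "skipped": False,
        })
    return pd.DataFrame(rows)


def _subset_weights(weights, burden_set: BurdenSet, dropped_key: str):
    if weights is None or isinstance(weights, str):
        return weights
    w = np.asarray(weights, dtype=float)
    mask = np.array([k != dropped_key for k in burden_set.variant_keys])
    return w[mask]


# ---------------------------------------------------------------------------
# subset re-analysis
# ---------------------------------------------------------------------------

def subset_analysis(
    gene: str,
    annotations: pd.DataFrame,
    dosages: pd.DataFrame,
    null: NullTraitResults,
    schemes=("none", "no_multiallelic", "no_indel", "loftee_hc_only"),
    model: str = "loss_of_function",
    variant_flags: pd.DataFrame | None = None,
    weights=None,
    **build_kwargs,
) -> pd.DataFrame:
    """Rebuild and re-test a gene's burden set under exclusion schemes.

    Each scheme maps to :func:`loyburden.burden.build_burden_set`
    exclusions; a scheme that empties the set (or leaves no carriers) is
    flagged skipped with its reason.
    """
    unknown = set(schemes) - set(SCHEMES)
    if unknown:
        raise ValueError(f"unknown exclusion scheme(s): {sorted(unknown)}")
    rows = []
    for scheme in schemes:
        s = build_burden_set(gene, annotations, dosages, model=model,
                             exclusions=SCHEMES[scheme],
                             variant_flags=variant_flags, **build_kwargs)
        if s.n_variants == 0 or s.n_carriers == 0:
            rows.append({"gene": gene, "scheme": scheme, "n_variants": s.n_variants,
                         "n_carriers": s.n_carriers, "beta": np.nan, "se": np.nan,
                         "p_burden": np.nan, "p_omnibus": np.nan,
                         "skipped": True, "reason": "no qualifying variants/carriers"})
            continue
        res = GeneSetAssociation(s, null, weights=weights).fit()
        row = res.to_row()
        rows.append({"gene": gene, "scheme": scheme, "n_variants": s.n_variants,
                     "n_carriers": s.n_carriers, "beta": row["beta"], "se": row["se"],
                     "p_burden": row["p_burden"], "p_omnibus": row["p_omnibus"],
                     "skipped": False, "reason": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confounding check
# ---------------------------------------------------------------------------

def confounding_check(carrier, pcs: pd.DataFrame) -> pd.DataFrame:
    """Logistic regression of carrier status on each principal component
    separately; reports OR and p per PC.  A constant PC column is flagged
    undefined; fewer than 5 carriers adds a low-power note (the check is
    still computed)."""
    c = np.asarray(carrier, dtype=float)
    mask = ~np.isnan(c)
    c = c[mask]
    if len(np.unique(c)) < 2:
        raise ValueError("carrier indicator is degenerate (all 0 or all 1)")
    low_power = (c == 1).sum() < 5
    rows = []
    for col in pcs.columns:
        x = pcs[col].to_numpy(dtype=float)[mask]
        ok = ~np.isnan(x)
        if np.ptp(x[ok]) == 0:
            rows.append({"covariate": col, "odds_ratio": np.nan, "se": np.nan,
                         "p": np.nan, "flag": "constant_column"})
            continue
        X = np.column_stack([np.ones(ok.sum()), x[ok]])
        try:
            res = sm.GLM(c[ok], X, family=sm.families.Binomial()).fit(maxiter=100)
            beta, se = float(res.params[1]), float(res.bse[1])
            p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan
            rows.append({"covariate": col, "odds_ratio": float(np.exp(beta)),
                         "se": se, "p": p,
                         "flag": "low_power" if low_power else ""})
        except Exception as e:
            rows.append({"covariate": col, "odds_ratio": np.nan, "se": np.nan,
                         "p": np.nan, "flag": f"fit_error:{e}"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenome scan
# ---------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """Configuration of one phenome-scan trait."""

    name: str
    family: str = "gaussian"        # "gaussian" | "binomial"
    transform: str = "none"          # "none" | "rint" (rank inverse normal)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    extra_covariates: tuple[str, ...] = ()   # e.g. ("bmi",) for BMI adjustment
    unit: str = ""


def default_phenome_traits() -> list[TraitSpec]:
    """A representative 17-trait metabolic-health panel (illustrative names;
    real analyses supply their own panel and per-trait transformations)."""
    binary = ["t2d"]
    quant = ["random_glucose", "hba1c", "bmi", "fat_mass", "lean_mass",
             "waist_hip_ratio", "sitting_height_ratio", "grip_strength",
             "igf1", "height", "weight", "birthweight", "sbp", "dbp",
             "triglycerides", "hdl_cholesterol"]
    out = [TraitSpec(name="t2d", family="binomial")]
    out += [TraitSpec(name=t, family="gaussian") for t in quant]
    assert len(out) == 17
    return out


def rank_inverse_normal(x: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse-normal transform (NaNs preserved)."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    n = ok.sum()
    ranks = stats.rankdata(x[ok])
    out[ok] = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return out


def phenome_scan(
    carrier,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
    trait_config: list[TraitSpec] | None = None,
) -> pd.DataFrame:
    """Burden-test the carrier indicator across a panel of traits.

    Each configured trait is fitted with its declared family,
    transformation and covariates; effects are reported in native trait
    units (or as odds ratios for binary traits).  Traits with all-missing
    values are skipped with a reason.  One output row per configured
    trait; results do not depend on trait order.
    """
    if trait_config is None:
        trait_config = [TraitSpec(name=c) for c in traits.columns]
    c = np.asarray(carrier, dtype=float)
    rows = []
    for spec in trait_config:
        if spec.name not in traits.columns:
            rows.append(_skip_row(spec, "trait column absent"))
            continue
        y = traits[spec.name].to_numpy(dtype=float)
        if np.all(np.isnan(y)):
            rows.append(_skip_row(spec, "all values missing"))
            continue
        if spec.transform == "rint":
            y = rank_inverse_normal(y)
        elif spec.transform != "none":
            raise ValueError(f"unknown transformation {spec.transform!r}")
        cov_cols = [col for col in (*spec.covariates, *spec.extra_covariates)
                    if col in covariates.columns]
        X = covariates[cov_cols].to_numpy(dtype=float) if cov_cols \
            else np.empty((len(y), 0))
        mask = ~np.isnan(y) & ~np.isnan(c)
        if X.size:
            mask &= ~np.isnan(X).any(axis=1)
        if spec.family == "binomial" and len(np.unique(y[mask])) < 2:
            rows.append(_skip_row(spec, "binary trait is constant"))
            continue
        # drop constant covariate columns on the analysis subset
        Xm = X[mask]
        if Xm.size:
            keep = np.ptp(Xm, axis=0) > 0
            Xm = Xm[:, keep]
        null = fit_null(y[mask], Xm, family=spec.family, trait=spec.name)
        res = burden_test(c[mask], null)
        rows.append({
            "trait": spec.name, "family": spec.family, "transform": spec.transform,
            "n_obs": int(mask.sum()), "n_carriers": res.n_carriers,
            "effect": res.odds_ratio if spec.family == "binomial" else res.beta,
            "beta": res.beta, "se": res.se, "p": res.p_wald, "unit": spec.unit,
            "skipped": False, "reason": ";".join(res.flags),
        })
    return pd.DataFrame(rows)


def _skip_row(spec: TraitSpec, reason: str) -> dict:
    return {"trait": spec.name, "family": spec.family, "transform": spec.transform,
            "n_obs": 0, "n_carriers": 0, "effect": np.nan, "beta": np.nan,
            "se": np.nan, "p": np.nan, "unit": spec.unit,
            "skipped": True, "reason": reason}
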