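"""Mosaic loss-of-Y (LOY) scoring.

Three array-derived LOY measures are handled here:

* ``mLRR-Y`` — the median (or mean) log2 R ratio of probes in the
  male-specific region of chromosome Y; more negative means more Y loss.
* ``PAR-LOY`` — a dichotomous LOY call from pseudo-autosomal-region
  allelic imbalance, with ``AF-LOY`` its estimated LOY cell fraction.
* ``PAR-LOYq`` — the composite quantitative score
  ``PAR-LOY + 3·AF-LOY − 3·mLRR-Y`` cropped to ``[0, 2]``, which up-weights
  men whose clone occupies a larger cell fraction.

The crop weights (3, −3) are fixed constants of the score, not tunable
parameters.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd


class InputError(ValueError):
    pass


def compute_mlrr_y(probe_lrr: Iterable[float], summariser: str = "median") -> float:
    """Summarise per-probe log2 R ratios into a single mLRR-Y value.

    Parameters
    ----------
    probe_lrr : array-like of float
        Log2 R ratios for the male-specific-region probes of one man.
    summariser : {"median", "mean"}
        The summary statistic; median is the default as it is robust to
        single-probe outliers.
    """
    arr = np.asarray(list(probe_lrr) if not isinstance(probe_lrr, np.ndarray) else probe_lrr,
                     dtype=float)
    if arr.size == 0:
        raise InputError("probe_lrr must contain at least one value")
    if not np.all(np.isfinite(arr)):
        raise InputError("probe_lrr values must all be finite")
    if summariser == "median":
        return float(np.median(arr))
    if summariser == "mean":
        return float(np.mean(arr))
    raise InputError(f"unknown summariser {summariser!r}; use 'median' or 'mean'")


def compute_par_loyq(par_loy, af_loy, mlrr_y):
    """Composite quantitative LOY score, cropped to [0, 2].

    ``PAR-LOYq = PAR-LOY + 3·AF-LOY − 3·mLRR-Y``, then cropped.  Accepts
    scalars or aligned arrays; missing inputs (NaN) propagate to missing
    output rather than being zero-filled.
    """
    p = np.asarray(par_loy, dtype=float)
    a = np.asarray(af_loy, dtype=float)
    m = np.asarray(mlrr_y, dtype=float)
    valid = ~(np.isnan(p) | np.isnan(a) | np.isnan(m))
    if np.any(~np.isin(p[valid], (0.0, 1.0))):
        raise InputError("par_loy must be 0 or 1")
    if np.any((a[valid] < 0) | (a[valid] > 1)):
        raise InputError("af_loy must lie in [0, 1]")
    raw = p + 3.0 * a - 3.0 * m
    out = np.clip(raw, 0.0, 2.0)
    out = np.where(valid, out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def score_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Add a ``par_loyq`` column to a table with ``par_loy``, ``af_loy`` and
    ``mlrr_y`` columns (missing rows stay missing)."""
    out = measures.copy()
    out["par_loyq"] = compute_par_loyq(
        measures["par_loy"].to_numpy(dtype=float),
        measures["af_loy"].to_numpy(dtype=float),
        measures["mlrr_y"].to_numpy(dtype=float),
    )
    return out


def _pairwise_t(y: np.ndarray, x: np.ndarray) -> float:
    """t statistic of the slope in a univariable linear regression y ~ x."""
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = y.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    r = float(np.corrcoef(y, x)[0, 1])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt((n - 2) / (1.0 - r * r))


def compare_measures(
    measures: pd.DataFrame,
    covariates: pd.DataFrame,
    dosages: pd.DataFrame | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Compare the association strength of competing LOY measures.

    Each measure column is standardised to unit variance, then associated
    with every covariate column by univariable linear regression (reported
    as the |t| statistic) and, if variant dosages are supplied, with every
    variant (reported as the chi-square, i.e. squared z).  Percent
    improvement of each measure over the ``reference`` measure (default:
    first column) is ``100·(stat − ref_stat)/ref_stat``; across variants the
    median chi-square improvement is additionally reported as a summary row.

    Rows are tidy: columns ``measure, kind, covariate, statistic,
    ref_statistic, pct_improvement``.
    """
    shared = measures.dropna(how="all").index.intersection(covariates.index)
    if len(shared) < 2:
        raise InputError("fewer than 2 shared individuals between measures and covariates")
    meas = measures.loc[shared]
    cov = covariates.loc[shared]
    if reference is None:
        reference = measures.columns[0]
    if reference not in measures.columns:
        raise InputError(f"reference measure {reference!r} not among measure columns")

    std = {}
    for col in meas.columns:
        v = meas[col].to_numpy(dtype=float)
        sd = np.nanstd(v, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise InputError(f"measure {col!r} has zero variance")
        std[col] = v / sd

    rows = []
    stats: dict[tuple[str, str], float] = {}
    for mcol in meas.columns:
        for ccol in cov.columns:
            t = abs(_pairwise_t(std[mcol], cov[ccol].to_numpy(dtype=float)))
            stats[(mcol, ccol)] = t
    dos = None
    if dosages is not None:
        dos = dosages.reindex(shared)
        for mcol in meas.columns:
            for vcol in dos.columns:
                t = _pairwise_t(std[mcol], dos[vcol].to_numpy(dtype=float))
                stats[(mcol, f"variant:{vcol}")] = t * t

    for mcol in meas.columns:
        for ccol in cov.columns:
            ref = stats[(reference, ccol)]
            s = stats[(mcol, ccol)]
            rows.append({"measure": mcol, "kind": "covariate", "covariate": ccol,
                         "statistic": s, "ref_statistic": ref,
                         "pct_improvement": 100.0 * (s - ref) / ref if ref else np.nan})
        if dos is not None:
            imps = []
            for vcol in dos.columns:
                key = f"variant:{vcol}"
                ref = stats[(reference, key)]
                s = stats[(mcol, key)]
                imp = 100.0 * (s - ref) / ref if ref else np.nan
                imps.append(imp)
                rows.append({"measure": mcol, "kind": "variant", "covariate": vcol,
                             "statistic": s, "ref_statistic": ref,
                             "pct_improvement": imp})
            rows.append({"measure": mcol, "kind": "summary",
                         "covariate": "median_chisq_improvement",
                         "statistic": float(np.nanmedian(imps)) if imps else np.nan,
                         "ref_statistic": np.nan,
                         "pct_improvement": float(np.nanmedian(imps)) if imps else np.nan})
    return pd.DataFrame(rows)
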