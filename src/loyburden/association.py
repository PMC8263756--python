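"""Association testing for gene burden sets.

Organised as model/results pairs:

* :class:`NullTraitModel` fits the covariate-only null model (Gaussian
  least squares or binomial IRLS) and exposes the residuals and variance
  weights that all score tests reuse.
* :class:`GeneSetAssociation` tests one gene's burden set against a fitted
  null model, producing a :class:`GeneSetResults` with the burden
  (carrier-indicator) Wald/score test, the SKAT variance-component test,
  ACAT-V, and the Cauchy omnibus combination, plus per-variant score
  statistics.

Population structure is handled by fixed-effects adjustment (principal
components as covariates) rather than a mixed model; on unrelated cohorts
the two coincide in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
import statsmodels.api as sm

from .burden import BurdenSet
from .quadform import mixture_chisq_tail

logger = logging.getLogger(__name__)

EXOME_WIDE_ALPHA = 1.6e-6   # exome-wide significance threshold (strict <)

DEFAULT_COVARIATES = ("age", "chip") + tuple(f"PC{i}" for i in range(1, 11))
SET_TEST_COVARIATES = ("age", "age2", "sex", "chip") + tuple(f"PC{i}" for i in range(1, 11))

_P_FLOOR = 1e-300
_TINY_P = 1e-15


# ---------------------------------------------------------------------------
# Cauchy combination
# ---------------------------------------------------------------------------

def acat(pvalues, weights=None) -> float:
    """Weighted Cauchy combination of p-values.

    ``T = sum_j w_j tan((0.5 - p_j) pi) / sum_j w_j`` and the combined
    p-value is ``0.5 - arctan(T)/pi``.  For p_j below 1e-15 the summand is
    replaced by its tail expansion ``1/(p_j pi)``; p-values of exactly 0
    are clipped to a 1e-300 floor with a warning.  Robust to arbitrary
    dependence between the component p-values.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("at least one p-value required")
    if np.any(np.isnan(p)) or np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    if np.any(p == 0):
        logger.warning("p-value of exactly 0 clipped to %g in Cauchy combination", _P_FLOOR)
        p = np.maximum(p, _P_FLOOR)
    p = np.minimum(p, 1.0 - 1e-16)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != p.shape or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative, not all zero, aligned with p-values")
    terms = np.where(p < _TINY_P, 1.0 / (p * np.pi), np.tan((0.5 - p) * np.pi))
    T = float(np.dot(w, terms) / w.sum())
    if T > 1e15:
        out = 1.0 / (T * np.pi)
    else:
        out = 0.5 - np.arctan(T) / np.pi
    return float(min(max(out, _P_FLOOR), 1.0))


def acat_v(pvalues, weights=None) -> float:
    """ACAT-V: Cauchy combination of per-variant p-values within a set."""
    return acat(pvalues, weights)


def cauchy_omnibus(*component_pvalues) -> float:
    """Equal-weight Cauchy combination of test-level p-values; undefined
    (NaN) components are dropped with a log entry.  All-undefined input
    yields NaN."""
    p = np.asarray(component_pvalues, dtype=float).ravel()
    defined = ~np.isnan(p)
    if defined.sum() < p.size:
        logger.debug("cauchy_omnibus: dropped %d undefined component(s)",
                     int((~defined).sum()))
    if not defined.any():
        return float("nan")
    return acat(p[defined])


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullTraitResults:
    """Fitted covariate-only model: the reusable core of every score test."""

    trait: str
    family: str
    exog_names: list[str]
    params: np.ndarray
    fitted: np.ndarray
    resid: np.ndarray               # response residuals y - mu
    weights: np.ndarray             # variance weights: sigma^2 (gaussian) or mu(1-mu)
    dispersion: float
    endog: np.ndarray
    exog: np.ndarray
    index: pd.Index
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        Xw = self.exog * self.weights[:, None]
        self._XtWX = self.exog.T @ Xw
        self._cho = cho_factor(self._XtWX)
        self._Xw = Xw

    @property
    def nobs(self) -> int:
        return len(self.endog)

    def score_test(self, g: np.ndarray) -> tuple[float, float, float]:
        """Score test of one extra column against the null model.

        Returns ``(U, var_U, p)`` with ``U = g' (y - mu)`` and the variance
        of U projected off the covariate space.  Two-sided normal p-value.
        """
        g = np.asarray(g, dtype=float)
        U = float(g @ self.resid)
        gw = self._Xw.T @ g
        var = float(g @ (self.weights * g) - gw @ cho_solve(self._cho, gw))
        if var <= 0:
            return U, var, float("nan")
        z = U / np.sqrt(var)
        return U, var, float(2.0 * stats.norm.sf(abs(z)))

    def summary(self) -> str:
        lines = [f"Null model: {self.trait} ~ {' + '.join(self.exog_names)}",
                 f"family: {self.family}   n = {self.nobs}   "
                 f"dispersion = {self.dispersion:.4g}"]
        for name, b in zip(self.exog_names, self.params):
            lines.append(f"  {name:<12} {b:+.4f}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


class NullTraitModel:
    """Covariate-only trait model (Gaussian or binomial).

    Parameters
    ----------
    endog : array-like
        Trait values; binary traits must be coded {0, 1}.
    exog : array-like or DataFrame
        Covariate design; an intercept is prepended if absent.
    family : {"gaussian", "binomial"}
    """

    def __init__(self, endog, exog, family: str = "gaussian",
                 trait: str = "trait", exog_names: list[str] | None = None):
        if family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            index = exog.index
            exog = exog.to_numpy(dtype=float)
        else:
            exog = np.asarray(exog, dtype=float)
            index = pd.RangeIndex(len(exog))
        endog = np.asarray(endog, dtype=float)
        if endog.shape[0] != exog.shape[0]:
            raise ValueError("endog and exog are not aligned")
        if np.isnan(endog).any() or np.isnan(exog).any():
            raise ValueError("complete cases required: drop missing rows first")
        if family == "binomial" and not np.all(np.isin(endog, (0.0, 1.0))):
            raise ValueError("binomial endog must be coded {0, 1}")
        if exog.ndim == 1:
            exog = exog[:, None]
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(exog.shape[1])]
        # prepend an intercept unless a constant non-zero column already exists
        has_const = any(np.ptp(exog[:, j]) == 0 and exog[0, j] != 0
                        for j in range(exog.shape[1]))
        if not has_const:
            exog = np.column_stack([np.ones(len(exog)), exog])
            exog_names = ["const"] + list(exog_names)
        self.endog = endog
        self.exog = exog
        self.exog_names = list(exog_names)
        self.family = family
        self.trait = trait
        self.index = index

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str,
                       covariates=DEFAULT_COVARIATES, family: str = "gaussian"):
        """Build from a phenotype/covariate table.

        ``age2`` and ``sex`` pseudo-covariates are derived on the fly
        (age squared; male=1) when requested but absent.
        """
        df = data.copy()
        if "age2" in covariates and "age2" not in df:
            df["age2"] = df["age"].astype(float) ** 2
        if "sex" in covariates and df["sex"].dtype == object:
            df["sex"] = (df["sex"] == "M").astype(float)
        cols = [c for c in covariates if c in df.columns]
        use = df[[trait] + cols].dropna()
        # constant columns (e.g. sex in a males-only cohort) carry no information
        kept = [c for c in cols if np.ptp(use[c].to_numpy(dtype=float)) > 0]
        return cls(use[trait].to_numpy(dtype=float), use[kept].astype(float),
                   family=family, trait=trait)

    def fit(self) -> NullTraitResults:
        y, X = self.endog, self.exog
        flags: list[str] = []
        if self.family == "gaussian":
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ beta
            resid = y - fitted
            dof = max(len(y) - rank, 1)
            sigma2 = float(resid @ resid) / dof
            weights = np.full(len(y), sigma2)
            converged = True
            dispersion = sigma2
        else:
            glm = sm.GLM(y, X, family=sm.families.Binomial())
            try:
                res = glm.fit(maxiter=100)
                converged = bool(res.converged)
            except Exception as e:  # pragma: no cover - statsmodels raises rarely
                raise RuntimeError(f"binomial null model failed: {e}") from e
            beta = res.params
            fitted = res.fittedvalues
            if not converged:
                flags.append("nonconvergence")
            if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
                flags.append("separation_suspected")
            resid = y - fitted
            weights = fitted * (1.0 - fitted)
            dispersion = 1.0
        return NullTraitResults(
            trait=self.trait, family=self.family, exog_names=self.exog_names,
            params=np.asarray(beta, dtype=float), fitted=np.asarray(fitted, dtype=float),
            resid=np.asarray(resid, dtype=float), weights=np.asarray(weights, dtype=float),
            dispersion=dispersion, endog=y, exog=X, index=self.index,
            converged=converged, flags=flags)


def fit_null(trait_values, covariates, family: str = "gaussian",
             trait: str = "trait") -> NullTraitResults:
    """Functional wrapper: build and fit a :class:`NullTraitModel`."""
    return NullTraitModel(trait_values, covariates, family=family, trait=trait).fit()


# ---------------------------------------------------------------------------
# Firth-penalised logistic regression (separation fallback)
# ---------------------------------------------------------------------------

def _firth_logistic(y, X, maxiter=100, tol=1e-8):
    """Jeffreys-prior penalised logistic fit (Firth); returns (beta, se,
    converged).  Finite estimates exist even under complete separation."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        XtW = X.T * w
        I = XtW @ X
        try:
            Iinv = np.linalg.inv(I)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        h = np.einsum("ij,jk,ik->i", X, Iinv, X * w[:, None])
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = Iinv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    w = expit(eta) * (1 - expit(eta))
    I = (X.T * w) @ X
    se = np.sqrt(np.diag(np.linalg.inv(I)))
    return beta, se, True


# ---------------------------------------------------------------------------
# Burden (carrier-indicator) test
# ---------------------------------------------------------------------------

@dataclass
class BurdenTestResult:
    beta: float
    se: float
    p_wald: float
    p_score: float
    n_carriers: int
    n_obs: int
    odds_ratio: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.beta)


def burden_test(carrier, null: NullTraitResults) -> BurdenTestResult:
    """Test the collapsed carrier indicator against the fitted null model.

    The indicator joins the covariate design: Gaussian traits get a Wald
    test from least squares (beta in trait-SD units when the trait is
    standardised); binomial traits get the carrier log-odds and odds ratio
    from logistic regression, with a Firth-penalised fallback when
    separation or non-convergence is detected.  A score-test p-value
    against the unmodified null is always reported alongside.
    Individuals with missing carrier status are dropped (complete case).
    """
    c = np.asarray(carrier, dtype=float)
    mask = ~np.isnan(c)
    flags: list[str] = []
    if mask.all():
        base = null
        c_use = c
    else:
        base = fit_null(null.endog[mask], null.exog[mask, 1:]
                        if null.exog_names[0] == "const" else null.exog[mask],
                        family=null.family, trait=null.trait)
        c_use = c[mask]
        flags.append("carrier_missingness_refit")
    n_car = int((c_use == 1).sum())
    if n_car == 0 or n_car == len(c_use):
        return BurdenTestResult(np.nan, np.nan, np.nan, np.nan, n_car,
                                int(mask.sum()), None, flags + ["degenerate_carrier"])
    _, _, p_score = base.score_test(c_use)

    X = np.column_stack([base.exog, c_use])
    y = base.endog
    if base.family == "gaussian":
        beta_all, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_all
        dof = max(len(y) - rank, 1)
        sigma2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
        beta = float(beta_all[-1])
        p = float(2.0 * stats.t.sf(abs(beta / se), dof)) if se > 0 else np.nan
        return BurdenTestResult(beta, se, p, p_score, n_car, len(y), None, flags)

    # binomial
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # separation warning handled below
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        beta = float(res.params[-1])
        se = float(res.bse[-1])
        ok = bool(res.converged) and np.isfinite(se) and se < 50 and abs(beta) < 15
    except Exception:
        ok = False
    if not ok:
        beta_f, se_f, conv = _firth_logistic(y, X)
        beta, se = float(beta_f[-1]), float(se_f[-1])
        flags = flags + ["firth_fallback"]
        if not conv:
            flags.append("firth_nonconvergence")
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 and np.isfinite(se) else np.nan
    return BurdenTestResult(beta, se, p, p_score, n_car, len(y),
                            float(np.exp(beta)), flags)


# ---------------------------------------------------------------------------
# SKAT
# ---------------------------------------------------------------------------

@dataclass
class SkatResult:
    Q: float
    p: float
    method: str
    n_variants_used: int
    flags: list[str] = field(default_factory=list)


def skat_test(G, null: NullTraitResults, weights=None) -> SkatResult:
    """Variance-component (SKAT) test of a dosage matrix.

    ``Q = sum_j w_j^2 (g_j' r)^2`` with r the null-model response
    residuals; the null distribution is the chi-square mixture whose
    eigenvalues come from the weighted, covariate-projected genotype
    covariance.  Missing dosages are mean-imputed per variant;
    zero-variance columns are dropped.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != null.nobs:
        raise ValueError("G must be (n_obs x m) aligned with the null model")
    G = G.copy()
    flags: list[str] = []
    for j in range(G.shape[1]):
        col = G[:, j]
        nanmask = np.isnan(col)
        if nanmask.any():
            col[nanmask] = np.nanmean(col) if not np.all(nanmask) else 0.0
    keep = G.std(axis=0) > 0
    if not keep.all():
        logger.info("skat_test: dropped %d zero-variance variant column(s)",
                    int((~keep).sum()))
        flags.append("dropped_zero_variance")
    G = G[:, keep]
    m = G.shape[1]
    if m == 0:
        return SkatResult(np.nan, np.nan, "skipped", 0, flags + ["no_usable_variants"])
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float).ravel()[keep]
    scores = G.T @ null.resid
    Q = float(np.sum((w * scores) ** 2))
    if np.all(w == 0):
        return SkatResult(0.0, 1.0, "degenerate", m, flags + ["all_zero_weights"])
    # eigenvalues of W (G' Sigma G) W with Sigma the residual covariance
    WG = null.weights[:, None] * G
    K = G.T @ WG
    B = null._Xw.T @ G
    K -= B.T @ cho_solve(null._cho, B)
    K = (w[:, None] * K) * w[None, :]
    lam = np.linalg.eigvalsh(0.5 * (K + K.T))
    lam = lam[lam > 1e-10 * max(lam.max(), 1e-300)]
    if lam.size == 0:
        return SkatResult(Q, np.nan, "skipped", m, flags + ["degenerate_kernel"])
    p, method = mixture_chisq_tail(lam, Q, full_output=True)
    return SkatResult(Q, p, method, m, flags)


# ---------------------------------------------------------------------------
# Per-variant score tests (feeding ACAT-V)
# ---------------------------------------------------------------------------

def per_variant_score_pvalues(G, null: NullTraitResults) -> np.ndarray:
    """Two-sided score-test p-value per dosage column (NaN if untestable)."""
    G = np.asarray(G, dtype=float)
    out = np.full(G.shape[1], np.nan)
    for j in range(G.shape[1]):
        col = G[:, j].copy()
        nanmask = np.isnan(col)
        if nanmask.all():
            continue
        if nanmask.any():
            col[nanmask] = np.nanmean(G[:, j])
        if np.ptp(col) == 0:
            continue
        _, _, p = null.score_test(col)
        out[j] = p
    return out


# ---------------------------------------------------------------------------
# Gene-set model/results
# ---------------------------------------------------------------------------

@dataclass
class GeneSetResults:
    """All set-level association results for one gene under one model."""

    gene: str
    model: str
    trait: str
    family: str
    n_variants: int
    n_carriers: int
    burden: BurdenTestResult | None
    skat: SkatResult | None
    p_acatv: float
    p_omnibus: float
    variant_keys: list[str]
    variant_pvalues: np.ndarray
    weights: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def p_burden(self) -> float:
        return self.burden.p_wald if self.burden is not None else float("nan")

    @property
    def p_skat(self) -> float:
        return self.skat.p if self.skat is not None else float("nan")

    def significant(self, alpha: float = EXOME_WIDE_ALPHA) -> bool:
        p = self.p_omnibus
        return bool(np.isfinite(p) and p < alpha)

    def to_row(self) -> dict:
        b = self.burden
        return {
            "gene": self.gene, "model": self.model, "trait": self.trait,
            "n_variants": self.n_variants, "n_carriers": self.n_carriers,
            "beta": b.beta if b else np.nan, "se": b.se if b else np.nan,
            "odds_ratio": (b.odds_ratio if b and b.odds_ratio is not None else np.nan),
            "p_burden": self.p_burden,
            "p_burden_score": b.p_score if b else np.nan,
            "Q_skat": self.skat.Q if self.skat else np.nan,
            "p_skat": self.p_skat,
            "skat_method": self.skat.method if self.skat else "",
            "p_acatv": self.p_acatv,
            "p_omnibus": self.p_omnibus,
            "flags": ";".join(self.flags),
        }

    def summary(self) -> str:
        r = self.to_row()
        lines = [
            f"Gene set association: {self.gene} [{self.model}] vs {self.trait} "
            f"({self.family})",
            f"  variants = {self.n_variants}   carriers = {self.n_carriers}",
        ]
        if self.burden is not None and self.burden.defined:
            eff = (f"OR = {r['odds_ratio']:.3f}" if self.family == "binomial"
                   else f"beta = {r['beta']:.3f} SD")
            lines.append(f"  burden : {eff} (SE {r['se']:.3f})  p = {r['p_burden']:.3g}")
        if self.skat is not None and np.isfinite(self.p_skat):
            lines.append(f"  SKAT   : Q = {r['Q_skat']:.2f}  p = {r['p_skat']:.3g} "
                         f"[{r['skat_method']}]")
        if np.isfinite(self.p_acatv):
            lines.append(f"  ACAT-V : p = {r['p_acatv']:.3g}")
        lines.append(f"  omnibus: p = {r['p_omnibus']:.3g}")
        if self.flags:
            lines.append("  flags  : " + ", ".join(self.flags))
        return "\n".join(lines)


class GeneSetAssociation:
    """Association model for one burden set against a fitted null model.

    Parameters
    ----------
    burden_set : BurdenSet
        Qualifying variants, dosages and carrier indicator for one gene.
    null : NullTraitResults
        Fitted covariate-only model, aligned with the burden set's
        individuals (same order).
    weights : None or "cadd" or array-like
        Per-variant weights for SKAT/ACAT-V; "cadd" uses the CADD Phred
        scores, default is unweighted.
    min_set_variants : int
        Sets with fewer qualifying variants are skipped by the
        variance-component tests (the burden test still runs if there is
        at least one carrier).
    """

    def __init__(self, burden_set: BurdenSet, null: NullTraitResults,
                 weights=None, tests=("burden", "skat", "acatv"),
                 min_set_variants: int = 2):
        self.set = burden_set
        self.null = null
        self.tests = tests
        self.min_set_variants = min_set_variants
        if isinstance(weights, str):
            if weights != "cadd":
                raise ValueError("weights must be None, 'cadd' or an array")
            w = np.asarray(burden_set.cadd, dtype=float)
            w = np.where(np.isfinite(w), w, np.nanmean(w) if np.isfinite(np.nanmean(w)) else 1.0)
        elif weights is None:
            w = np.ones(burden_set.n_variants)
        else:
            w = np.asarray(weights, dtype=float)
        self.weights = w

    def fit(self) -> GeneSetResults:
        s = self.set
        null = self.null
        flags: list[str] = []
        G = s.dosages.to_numpy(dtype=float) if s.n_variants else \
            np.empty((null.nobs, 0))
        if s.n_variants and G.shape[0] != null.nobs:
            raise ValueError("burden set and null model are not aligned")

        burden_res = None
        if "burden" in self.tests and s.n_variants >= 1:
            burden_res = burden_test(s.carrier.to_numpy(dtype=float), null)
            flags.extend(burden_res.flags)

        skat_res = None
        p_acatv = float("nan")
        var_p = np.full(s.n_variants, np.nan)
        if s.n_variants >= self.min_set_variants:
            if "skat" in self.tests:
                skat_res = skat_test(G, null, weights=self.weights)
                flags.extend(skat_res.flags)
            if "acatv" in self.tests:
                var_p = per_variant_score_pvalues(G, null)
                ok = ~np.isnan(var_p)
                if ok.any():
                    p_acatv = acat_v(var_p[ok], self.weights[ok])
        elif s.n_variants:
            flags.append("below_min_set_variants")
        else:
            flags.append("empty_set")

        components = [p for p in (
            burden_res.p_wald if burden_res is not None else np.nan,
            skat_res.p if skat_res is not None else np.nan,
            p_acatv,
        )]
        p_omni = cauchy_omnibus(*components)
        return GeneSetResults(
            gene=s.gene, model=s.model, trait=null.trait, family=null.family,
            n_variants=s.n_variants, n_carriers=s.n_carriers,
            burden=burden_res, skat=skat_res, p_acatv=p_acatv,
            p_omnibus=p_omni, variant_keys=list(s.variant_keys),
            variant_pvalues=var_p, weights=self.weights, flags=flags)


# ---------------------------------------------------------------------------
# Exome-wide scan
# ---------------------------------------------------------------------------

def exome_scan(
    sets: list[BurdenSet],
    null: NullTraitResults,
    weights=None,
    alpha: float = EXOME_WIDE_ALPHA,
    min_set_variants: int = 2,
) -> pd.DataFrame:
    """Run all configured tests for every burden set; one row per
    gene-model, ranked by omnibus p (ties broken by gene id).  Sites are
    flagged significant at ``p < alpha`` (strict).  Per-gene failures are
    isolated and logged; the scan continues."""
    rows = []
    for s in sets:
        try:
            res = GeneSetAssociation(s, null, weights=weights,
                                     min_set_variants=min_set_variants).fit()
            row = res.to_row()
            row["significant"] = res.significant(alpha)
            rows.append(row)
        except Exception as e:
            logger.warning("exome_scan: gene %s [%s] failed: %s", s.gene, s.model, e)
            rows.append({"gene": s.gene, "model": s.model, "trait": null.trait,
                         "n_variants": s.n_variants, "n_carriers": s.n_carriers,
                         "flags": f"error:{e}", "significant": False})
    df = pd.DataFrame(rows)
    df["_p"] = df["p_omnibus"].fillna(np.inf) if "p_omnibus" in df else np.inf
    df = df.sort_values(["_p", "gene"], kind="stable").drop(columns="_p")
    return df.reset_index(drop=True)
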