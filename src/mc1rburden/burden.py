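"""Negative-binomial burden regression with multiple imputation.

The association between MC1R R-allele status and per-class somatic SNV
burden is estimated with NB2 regression (log link, variance mu + mu^2 /
theta) adjusted for clinical covariates.  Missing clinical values are
multiply imputed (m = 10) by chained equations — predictive mean matching
for continuous variables, logistic draws for binary, polytomous logistic
draws for categorical — with R-allele presence and the six class counts
included in every univariate imputation model, and any categorical level
carried by fewer than five samples set to missing beforehand.  Estimates
are pooled over imputations with Rubin's rules (Barnard–Rubin
small-sample degrees of freedom) and the per-class R-allele p-values are
Benjamini–Hochberg adjusted across the six substitution classes.

Effect sizes are reported as multiplicative changes in the expected SNV
count, 100*(exp(beta) - 1) percent, and the R-allele effect is also
expressed as an age equivalence: the ratio of the R and per-year-age log
rate ratios, i.e. the number of extra years of age carrying the same
modelled mutational burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectrum import CLASSES6, CONTEXTS96, spectra_to_class6

logger = logging.getLogger(__name__)

DEFAULT_M = 10

CONTINUOUS_VARS = ("age", "breslow")
BINARY_VARS = ("sex", "ulceration")
CATEGORICAL_VARS = ("centre", "sample_type", "body_area", "clark")

DEFAULT_REFERENCE_LEVELS = {
    "centre": "EE",  # University of Sydney, the baseline collection centre
    "sex": "F",
    "sample_type": "metastasis",
    "body_area": "extremities",
    "clark": "IV",
}


class ConvergenceError(RuntimeError):
    """NB maximum-likelihood fit failed to converge (trace attached)."""


class DegenerateDesignError(ValueError):
    """Design matrix is rank deficient or a response is degenerate."""


@dataclass
class ModelSpec:
    response: str = "six_class"  # "six_class", "total", or a single class e.g. "C>T"
    r_predictor: str = "presence"  # "presence" (2 levels) or "count" (3 levels)
    covariates: tuple[str, ...] = ("age", "sex", "centre", "sample_type")
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )


@dataclass
class NBFit:
    coefficients: dict[str, tuple[float, float]]  # term -> (beta, SE)
    theta: float
    loglik: float
    n: int

    def beta(self, term: str) -> float:
        return self.coefficients[term][0]

    def se(self, term: str) -> float:
        return self.coefficients[term][1]


# ---------------------------------------------------------------------------
# multiple imputation by chained equations


def _class_count_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    ctx = [c for c in CONTEXTS96 if c in cohort.columns]
    if len(ctx) == 96:
        return spectra_to_class6(cohort[ctx])
    present = [c for c in CLASSES6 if c in cohort.columns]
    if len(present) == 6:
        return cohort[list(CLASSES6)].copy()
    raise ValueError("cohort carries neither 96-context nor 6-class count columns")


def _encode_predictors(frame: pd.DataFrame, exclude: str) -> np.ndarray:
    cols = [c for c in frame.columns if c != exclude]
    parts = [np.ones((len(frame), 1))]
    for c in cols:
        col = frame[c]
        if pd.api.types.is_numeric_dtype(col) and col.dtype != object:
            parts.append(np.asarray(col, dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            if dummies.shape[1]:
                parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def _pmm_impute(y: pd.Series, X: np.ndarray, miss: np.ndarray, rng, k: int = 5) -> np.ndarray:
    """Predictive mean matching with a Bayesian draw of the regression
    coefficients (van Buuren type-1 matching)."""
    obs = ~miss
    Xo, yo = X[obs], np.asarray(y[obs], dtype=float)
    n_obs, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    betahat = np.linalg.solve(XtX, Xo.T @ yo)
    resid = yo - Xo @ betahat
    dof = max(n_obs - p, 1)
    sigma2 = (resid @ resid) / dof
    sigma2_star = sigma2 * dof / max(rng.chisquare(dof), 1e-8)
    cov = sigma2_star * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(betahat, cov, method="cholesky")
    yhat_obs = Xo @ betahat
    yhat_mis = X[miss] @ beta_star
    out = np.asarray(y, dtype=float).copy()
    kk = min(k, n_obs)
    for i, yh in zip(np.flatnonzero(miss), yhat_mis):
        donors = np.argpartition(np.abs(yhat_obs - yh), kk - 1)[:kk]
        out[i] = yo[donors[int(rng.integers(kk))]]
    return out


def _logistic_impute(y: pd.Series, X: np.ndarray, miss: np.ndarray, rng) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    obs = ~miss
    yo = y[obs].astype(str)
    levels = np.unique(yo)
    out = y.astype(object).to_numpy().copy()
    if len(levels) == 1:
        out[miss] = levels[0]
        return out
    model = LogisticRegression(max_iter=200, C=1.0)
    model.fit(X[obs], yo)
    probs = model.predict_proba(X[miss])
    classes = model.classes_
    cum = probs.cumsum(axis=1)
    u = rng.random(len(cum))
    draws = classes[(u[:, None] < cum).argmax(axis=1)]
    out[miss] = draws
    return out


def impute_missing(
    cohort: pd.DataFrame,
    m: int = DEFAULT_M,
    seed: int = 0,
    covariates: Optional[Sequence[str]] = None,
    n_iter: int = 5,
    min_level_count: int = 5,
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation of clinical covariates.

    Returns ``m`` completed copies of ``cohort``.  Every univariate
    imputation model uses the other clinical covariates, R-allele
    presence, and the (log1p) counts of the six substitution classes as
    predictors.  Complete input yields ``m`` identical copies.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    cohort = cohort.reset_index(drop=True)
    if covariates is None:
        covariates = [c for c in ("age", "sex", "centre", "sample_type",
                                  "body_area", "breslow", "clark", "ulceration")
                      if c in cohort.columns]
    covariates = list(covariates)
    for c in covariates:
        if cohort[c].isna().all():
            raise ValueError(f"covariate {c!r} is fully missing; cannot impute")

    work = cohort[covariates].copy()
    if "breslow" in work.columns:
        work["breslow"] = np.log(work["breslow"].astype(float))  # heavy-tailed, model on log scale

    # rare categorical levels (<5 samples) are set to missing and imputed
    for c in covariates:
        if c in CATEGORICAL_VARS or c in BINARY_VARS:
            vc = work[c].dropna().astype(str).value_counts()
            rare = vc.index[vc < min_level_count]
            if len(rare):
                logger.info("setting rare level(s) %s of %r to missing", list(rare), c)
                work[c] = work[c].where(~work[c].astype(str).isin(rare))

    miss_mask = {c: work[c].isna().to_numpy() for c in covariates}
    any_missing = any(mask.any() for mask in miss_mask.values())

    aux = pd.DataFrame(index=work.index)
    if "r_present" in cohort.columns:
        aux["r_present"] = cohort["r_present"].astype(float)
    counts6 = _class_count_frame(cohort)
    for cls in CLASSES6:
        aux[f"log1p_{cls}"] = np.log1p(counts6[cls].astype(float))

    completed: list[pd.DataFrame] = []
    master = np.random.SeedSequence(seed)
    streams = master.spawn(m)
    for d in range(m):
        rng = np.random.default_rng(streams[d])
        filled = work.copy()
        if any_missing:
            for c in covariates:  # initial fill: random draws from the observed margin
                mask = miss_mask[c]
                if mask.any():
                    donors = filled.loc[~mask, c].to_numpy()
                    filled.loc[mask, c] = rng.choice(donors, size=int(mask.sum()))
            for _ in range(n_iter):
                for c in covariates:
                    mask = miss_mask[c]
                    if not mask.any():
                        continue
                    frame = pd.concat([filled, aux], axis=1)
                    X = _encode_predictors(frame, exclude=c)
                    if c in CONTINUOUS_VARS:
                        filled[c] = _pmm_impute(filled[c].astype(float), X, mask, rng)
                    else:
                        filled[c] = _logistic_impute(filled[c], X, mask, rng)
        out = cohort.copy()
        for c in covariates:
            if c == "breslow":
                out[c] = np.exp(filled[c].astype(float))
            elif c == "ulceration":
                vals = filled[c]
                out[c] = vals.map(lambda v: v in (True, "True", "true", 1, "1"))
            else:
                out[c] = filled[c]
        completed.append(out)
    return completed


# ---------------------------------------------------------------------------
# NB2 fitting


def build_design(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Assemble the regression design matrix (with intercept) for one
    completed dataset.  Categorical covariates are dummy-coded against the
    configured reference levels; Breslow depth enters on the log scale."""
    X = pd.DataFrame(index=cohort.index)
    X["const"] = 1.0
    if spec.r_predictor == "presence":
        X["r_present"] = cohort["r_present"].astype(float)
    elif spec.r_predictor == "count":
        rc = cohort["r_count"].astype(int)
        X["r_count_1"] = (rc == 1).astype(float)
        X["r_count_2"] = (rc == 2).astype(float)
    else:
        raise ValueError(f"unknown r_predictor {spec.r_predictor!r}")
    for c in spec.covariates:
        col = cohort[c]
        if c == "age":
            X["age"] = col.astype(float)
        elif c == "breslow":
            X["log_breslow"] = np.log(col.astype(float))
        elif c == "ulceration":
            X["ulceration"] = col.astype(bool).astype(float)
        else:
            ref = spec.reference_levels.get(c)
            levels = sorted(col.astype(str).unique())
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{c}[{lev}]"
                X[name] = (col.astype(str) == lev).astype(float)
    # drop constant (zero-variance) dummies so the design stays full rank
    keep = ["const"] + [c for c in X.columns[1:] if X[c].std() > 0]
    X = X[keep]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DegenerateDesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    return X


def fit_negbin(counts: np.ndarray, design: pd.DataFrame) -> NBFit:
    """Joint ML fit of the NB2 model over coefficients and dispersion.

    ``theta`` is the NB size parameter (statsmodels estimates
    ``alpha = 1/theta``); standard errors are Wald, from the observed
    information at the optimum.
    """
    import statsmodels.api as sm

    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    X = design.to_numpy(dtype=float)
    try:
        start = sm.Poisson(y, X).fit(disp=0, maxiter=100).params
    except Exception:
        start = np.zeros(X.shape[1])
        start[0] = np.log(max(y.mean(), 0.5))
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    res = None
    trace = []
    for method in ("bfgs", "newton", "nm"):
        try:
            res = model.fit(
                start_params=np.append(start, 0.5),
                method=method,
                maxiter=500,
                disp=0,
            )
        except Exception as exc:  # singular hessian etc.
            trace.append(f"{method}: {exc}")
            res = None
            continue
        if res.mle_retvals.get("converged", True):
            break
        trace.append(f"{method}: not converged")
    if res is None or not res.mle_retvals.get("converged", True):
        raise ConvergenceError("NB fit failed to converge; " + "; ".join(trace))
    names = list(design.columns) + ["alpha"]
    coefs = {n: (float(b), float(s)) for n, b, s in zip(names, res.params, res.bse)}
    alpha = max(coefs.pop("alpha")[0], 1e-8)
    return NBFit(coefficients=coefs, theta=1.0 / alpha, loglik=float(res.llf), n=len(y))


# ---------------------------------------------------------------------------
# pooling, multiplicity, effect summaries


def pool_rubin(fits: Sequence[NBFit], n_params: Optional[int] = None) -> pd.DataFrame:
    """Pool coefficient estimates across imputations with Rubin's rules.

    Total variance = mean within-imputation variance + (1 + 1/m) x
    between-imputation variance; degrees of freedom follow the
    Barnard–Rubin small-sample formula; p-values are two-sided from the t
    reference.
    """
    if len(fits) == 0:
        raise ValueError("pool_rubin requires at least one fit")
    m = len(fits)
    terms = list(fits[0].coefficients)
    for f in fits[1:]:
        if list(f.coefficients) != terms:
            raise ValueError("fits have differing model terms; cannot pool")
    n = fits[0].n
    k = n_params if n_params is not None else len(terms)
    nu_com = max(n - k, 1)
    rows = []
    for t in terms:
        q = np.array([f.beta(t) for f in fits])
        w = np.array([f.se(t) ** 2 for f in fits])
        qbar = q.mean()
        W = w.mean()
        B = q.var(ddof=1) if m > 1 else 0.0
        T = W + (1.0 + 1.0 / m) * B
        if B > 0 and m > 1:
            r = (1.0 + 1.0 / m) * B / W
            df_old = (m - 1) * (1.0 + 1.0 / r) ** 2
            df_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * W / T
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = float(nu_com)
        se = np.sqrt(T)
        stat = qbar / se if se > 0 else np.inf
        p = 2.0 * sps.t.sf(abs(stat), df)
        rows.append((t, qbar, se, np.sqrt(W), np.sqrt(B) if B > 0 else 0.0, df, p))
    return pd.DataFrame(
        rows, columns=["term", "beta", "se", "within_se", "between_se", "df", "p"]
    ).set_index("term")


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effect_summary(beta: float, se: float, df: float, level: float = 0.95) -> dict:
    """Percent change in expected count, with a t-based CI."""
    tq = sps.t.ppf(0.5 + level / 2.0, df)
    return {
        "percent_change": 100.0 * (np.exp(beta) - 1.0),
        "ci_low": 100.0 * (np.exp(beta - tq * se) - 1.0),
        "ci_high": 100.0 * (np.exp(beta + tq * se) - 1.0),
    }


def age_equivalence(beta_r: float, beta_age: float) -> float:
    """Years of aging with the same modelled effect as the R predictor."""
    if beta_age == 0:
        raise ZeroDivisionError("age coefficient is zero; equivalence undefined")
    return beta_r / beta_age


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PooledResult:
    response: str
    pooled: pd.DataFrame  # pool_rubin output
    m: int
    r_terms: tuple[str, ...]
    effects: dict[str, dict]  # term -> percent change summary
    age_equiv_years: Optional[float]
    p_raw: float
    p_adjusted: Optional[float] = None


@dataclass
class BurdenAnalysis:
    results: dict[str, PooledResult]
    spec: ModelSpec
    m: int
    seed: int

    def table(self) -> pd.DataFrame:
        """Effect table shaped like a published multiplicative-change table."""
        rows = []
        for resp, r in self.results.items():
            term = r.r_terms[0]
            eff = r.effects[term]
            rows.append(
                {
                    "class": resp,
                    "term": term,
                    "percent_change": eff["percent_change"],
                    "ci_low": eff["ci_low"],
                    "ci_high": eff["ci_high"],
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "age_equivalence_years": r.age_equiv_years,
                }
            )
        return pd.DataFrame(rows)


def run_burden_analysis(
    cohort: pd.DataFrame,
    spec: Optional[ModelSpec] = None,
    m: int = DEFAULT_M,
    seed: int = 0,
) -> BurdenAnalysis:
    """Impute, fit per class per imputation, pool, adjust, summarize.

    In ``six_class`` mode returns one pooled result per substitution class
    with BH-adjusted R-term p-values across the six classes; in ``total``
    mode a single result with no multiplicity adjustment.
    """
    spec = spec or ModelSpec()
    counts6 = _class_count_frame(cohort)
    completed = impute_missing(cohort, m=m, seed=seed, covariates=list(spec.covariates))

    if spec.response == "six_class":
        responses = {c: counts6[c].to_numpy() for c in CLASSES6}
    elif spec.response == "total":
        responses = {"total": counts6.sum(axis=1).to_numpy()}
    elif spec.response in CLASSES6:
        responses = {spec.response: counts6[spec.response].to_numpy()}
    else:
        raise ValueError(f"unknown response {spec.response!r}")

    fits: dict[str, list[NBFit]] = {r: [] for r in responses}
    for dataset in completed:
        X = build_design(dataset, spec)
        for resp, y in responses.items():
            fits[resp].append(fit_negbin(y, X))

    wanted = ("r_present",) if spec.r_predictor == "presence" else ("r_count_1", "r_count_2")
    results: dict[str, PooledResult] = {}
    for resp in responses:
        pooled = pool_rubin(fits[resp])
        # levels absent from the cohort (e.g. no 2-R samples) drop out of the design
        r_terms = tuple(t for t in wanted if t in pooled.index)
        if not r_terms:
            raise DegenerateDesignError("no R-allele term survived in the design")
        effects = {
            t: effect_summary(pooled.loc[t, "beta"], pooled.loc[t, "se"], pooled.loc[t, "df"])
            for t in pooled.index
        }
        aeq = None
        if "age" in pooled.index:
            beta_age = pooled.loc["age", "beta"]
            if beta_age != 0:
                aeq = age_equivalence(pooled.loc[r_terms[-1], "beta"], beta_age)
        results[resp] = PooledResult(
            response=resp,
            pooled=pooled,
            m=m,
            r_terms=r_terms,
            effects=effects,
            age_equiv_years=aeq,
            p_raw=float(pooled.loc[r_terms[0], "p"]),
        )
    if spec.response == "six_class":
        adj = adjust_bh([results[c].p_raw for c in CLASSES6])
        for c, a in zip(CLASSES6, adj):
            results[c].p_adjusted = float(a)
    return BurdenAnalysis(results=results, spec=spec, m=m, seed=seed)
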