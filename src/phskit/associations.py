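"""Association models linking the polygenic hazard score to imaging and cognition.

Three families:

* cross-sectional linear regressions of regional baseline Centiloid on the
  score, controlling for age, sex, education and APOE e4 carriage (the APOE
  covariate is dropped automatically in carrier-only / non-carrier-only
  subgroups, where it has no variation), with Benjamini-Hochberg FDR across
  the region family;

* longitudinal random-intercept linear mixed models of the form

      outcome = b0 + b1 PHS*Time + b2 Centiloid(frontal)*Time
              + b3 entorhinal-volume*Time + b4 baseline-age*Time
              + b5 Sex*Time + b6 Education*Time + b7 APOE*Time + (1 | participant)

  fitted by maximum likelihood (so likelihood-ratio tests on fixed effects
  are valid), with continuous covariates centred and scaled; plus AIC
  backward selection and +/- 1 SD simple-effect slopes;

* a 33-region atrophy panel of the same mixed model with FDR across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelResult",
    "LongitudinalModelSpec",
    "fdr_adjust",
    "fit_cross_sectional",
    "cross_sectional_panel",
    "likelihood_ratio_test",
    "fit_longitudinal",
    "backward_select_aic",
    "simple_effect_slopes",
    "run_atrophy_panel",
    "LongitudinalInteractionModel",
]

#: default interaction covariates of the longitudinal model, in b1..b7 order
DEFAULT_LMM_TERMS = (
    "phs",
    "cl_frontal",
    "entorhinal_volume",
    "age_baseline",
    "sex",
    "education",
    "apoe",
)

CONTINUOUS_COVARIATES = {"phs", "cl_frontal", "entorhinal_volume", "age_baseline", "education"}


@dataclass
class ModelResult:
    """Fitted-model summary: per-term estimates plus fit metrics."""

    terms: pd.DataFrame          # index term; columns beta, se, ci_low, ci_high, p
    llf: float
    aic: float
    nobs: int
    formula: str
    method: str                  # "ols" | "mixedlm" | "mixedlm->ols"
    converged: bool = True
    n_groups: int | None = None
    _sm_result: object = field(default=None, repr=False, compare=False)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        collinear = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy(dtype=float)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def _encode(df: pd.DataFrame, col: str) -> pd.Series:
    s = df[col]
    if s.dtype == object or str(s.dtype) == "category":
        if col == "sex":
            return (s.astype(str) == "male").astype(float)
        return pd.factorize(s)[0].astype(float)
    return s.astype(float)


def _ols_terms(res) -> pd.DataFrame:
    ci = res.conf_int()
    return pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues,
        }
    )


def fit_cross_sectional(
    data: pd.DataFrame,
    outcome: str,
    predictor: str = "phs",
    covariates: tuple[str, ...] = ("age_baseline", "sex", "education", "apoe"),
    subgroup: str = "all",
) -> ModelResult:
    """OLS regression of a baseline outcome on the score plus covariates.

    ``subgroup`` restricts to APOE e4 carriers or non-carriers (column
    ``apoe`` coded 0/1); within a subgroup the APOE covariate is dropped
    because it has no variation there. Complete cases only.
    """
    if subgroup not in ("all", "e4_carriers", "e4_noncarriers"):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    df = data
    covs = list(covariates)
    if subgroup == "e4_carriers":
        df = df[df["apoe"] == 1]
        covs = [c for c in covs if c != "apoe"]
    elif subgroup == "e4_noncarriers":
        df = df[df["apoe"] == 0]
        covs = [c for c in covs if c != "apoe"]

    cols = [outcome, predictor, *covs]
    df = df[cols + (["participant_id"] if "participant_id" in df.columns else [])].dropna(
        subset=cols
    )
    X = pd.DataFrame({c: _encode(df, c) for c in [predictor, *covs]}, index=df.index)
    X.insert(0, "const", 1.0)
    _check_full_rank(X)
    res = sm.OLS(df[outcome].astype(float), X).fit()
    formula = f"{outcome} ~ {' + '.join([predictor, *covs])}"
    return ModelResult(
        terms=_ols_terms(res),
        llf=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
        formula=formula,
        method="ols",
        _sm_result=res,
    )


def cross_sectional_panel(
    data: pd.DataFrame,
    regions: tuple[str, ...] = ("cl_neocortex", "cl_frontal", "cl_posterior_cingulate"),
    predictor: str = "phs",
    covariates: tuple[str, ...] = ("age_baseline", "sex", "education", "apoe"),
    subgroup: str = "all",
) -> pd.DataFrame:
    """One cross-sectional fit per region, FDR-adjusted across the region family.

    Returns a tidy frame (one row per region) with the predictor's beta, SE,
    CI, raw and BH-adjusted p.
    """
    rows = []
    for region in regions:
        res = fit_cross_sectional(data, region, predictor, covariates, subgroup)
        t = res.term(predictor)
        rows.append(
            {
                "region": region,
                "n": res.nobs,
                "beta": t["beta"],
                "se": t["se"],
                "ci_low": t["ci_low"],
                "ci_high": t["ci_high"],
                "p": t["p"],
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    return out


def _n_free_params(res) -> int:
    if hasattr(res, "fe_params"):  # MixedLM: fixed effects + variance components
        k_re = res.model.k_re
        n_vc = k_re * (k_re + 1) // 2 + getattr(res.model, "k_vc", 0)
        return int(len(res.fe_params) + n_vc + 1)  # + residual variance
    return int(len(res.params) + 1)  # OLS: betas + residual variance


def likelihood_ratio_test(full_fit, reduced_fit) -> tuple[float, int, float]:
    """LRT of nested maximum-likelihood fits: 2*(ll_full - ll_reduced) ~ chi2(df).

    Accepts statsmodels results or :class:`ModelResult`; the reduced model
    must be nested in the full model and fitted to the same rows.
    """
    def unwrap(r):
        return r._sm_result if isinstance(r, ModelResult) else r

    full, reduced = unwrap(full_fit), unwrap(reduced_fit)
    if int(full.nobs) != int(reduced.nobs):
        raise ValueError("models fitted to different numbers of rows")
    df = _n_free_params(full) - _n_free_params(reduced)
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = 2.0 * (float(full.llf) - float(reduced.llf))
    if df == 0:
        return (max(stat, 0.0), 0, 1.0)
    if stat < -1e-6:
        raise ValueError("full model has lower likelihood; models are not nested")
    stat = max(stat, 0.0)
    return (stat, df, float(stats.chi2.sf(stat, df)))


@dataclass(frozen=True)
class LongitudinalModelSpec:
    """The interaction-with-Time random-intercept mixed model.

    ``terms`` are the covariates entering as covariate*Time interactions, in
    the b1..b7 order by default; the model has no Time main effect unless
    ``include_time_main`` is set (an explicitly documented variant).
    """

    outcome: str
    terms: tuple[str, ...] = DEFAULT_LMM_TERMS
    include_time_main: bool = False
    time_col: str = "time"
    group_col: str = "participant_id"
    standardize: bool = True

    def dropping(self, term: str) -> "LongitudinalModelSpec":
        if term not in self.terms:
            raise KeyError(term)
        return replace(self, terms=tuple(t for t in self.terms if t != term))


def _standardize(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    return (s - s.mean()) / sd if sd > 0 else s - s.mean()


def _lmm_design(data: pd.DataFrame, spec: LongitudinalModelSpec):
    cols = [spec.outcome, spec.time_col, spec.group_col, *spec.terms]
    df = data[cols].dropna().copy()
    for c in spec.terms:
        enc = _encode(df, c)
        df[c] = _standardize(enc) if (spec.standardize and c in CONTINUOUS_COVARIATES) else enc
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    if spec.include_time_main:
        X[spec.time_col] = df[spec.time_col].astype(float)
    for c in spec.terms:
        X[f"{c}:time"] = df[c] * df[spec.time_col].astype(float)
    return df, X


def fit_longitudinal(data: pd.DataFrame, spec: LongitudinalModelSpec) -> ModelResult:
    """Fit the interaction-with-Time mixed model by maximum likelihood.

    A singular or non-converging random-intercept fit degenerates to OLS with
    the method flagged as ``"mixedlm->ols"``.
    """
    df, X = _lmm_design(data, spec)
    groups = df[spec.group_col]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 participants")
    formula = (
        f"{spec.outcome} ~ "
        + ("time + " if spec.include_time_main else "")
        + " + ".join(f"{t}:time" for t in spec.terms)
        + f" + (1 | {spec.group_col})"
    )
    y = df[spec.outcome].astype(float)
    res = None
    for method in ("bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups)
                res = model.fit(reml=False, method=method, maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            res = None
            continue
        if res.converged:
            break
    singular = res is not None and res.converged and np.any(np.diag(res.cov_re) < 1e-10)

    if singular and res is not None and res.converged:
        # variance component on the boundary: keep the fit but note it
        warnings.warn("random-intercept variance near zero", stacklevel=2)

    if res is None or not res.converged:
        warnings.warn(
            "mixed model failed to converge; refitting as OLS", stacklevel=2
        )
        ols = sm.OLS(y, X).fit()
        return ModelResult(
            terms=_ols_terms(ols),
            llf=float(ols.llf),
            aic=float(ols.aic),
            nobs=int(ols.nobs),
            formula=formula,
            method="mixedlm->ols",
            converged=False,
            n_groups=int(groups.nunique()),
            _sm_result=ols,
        )

    fe = res.fe_params
    se = res.bse_fe
    z = fe / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    ci_low = fe - 1.959963984540054 * se
    ci_high = fe + 1.959963984540054 * se
    terms = pd.DataFrame(
        {"beta": fe, "se": se, "ci_low": ci_low, "ci_high": ci_high, "p": p}
    )
    k = _n_free_params(res)
    aic = 2.0 * k - 2.0 * float(res.llf)
    return ModelResult(
        terms=terms,
        llf=float(res.llf),
        aic=aic,
        nobs=int(res.nobs),
        formula=formula,
        method="mixedlm",
        converged=bool(res.converged),
        n_groups=int(groups.nunique()),
        _sm_result=res,
    )


def backward_select_aic(
    data: pd.DataFrame, spec: LongitudinalModelSpec
) -> tuple[LongitudinalModelSpec, ModelResult]:
    """AIC backward selection over the interaction terms.

    Iteratively removes the covariate*Time term whose removal lowers AIC the
    most; stops when no removal improves AIC. The intercept and the random
    intercept are never dropped. Deterministic for fixed data.
    """
    current_spec = spec
    current_fit = fit_longitudinal(data, current_spec)
    while len(current_spec.terms) > 0:
        trials = []
        for t in current_spec.terms:
            cand = current_spec.dropping(t)
            fit = fit_longitudinal(data, cand)
            trials.append((fit.aic, t, cand, fit))
        trials.sort(key=lambda x: (x[0], x[1]))
        best_aic, _, best_spec, best_fit = trials[0]
        if best_aic < current_fit.aic:
            current_spec, current_fit = best_spec, best_fit
        else:
            break
    return current_spec, current_fit


def simple_effect_slopes(
    fit: ModelResult, levels: tuple[float, float] = (1.0, -1.0), term: str = "phs:time"
) -> pd.DataFrame:
    """Outcome-change slopes at high / low score levels, with delta-method SEs.

    ``slope(level) = beta_time_main + level * beta_interaction`` on the
    centred/scaled score axis (the Time main-effect slope is 0 in the
    interaction-only model). Returns one row per level plus the difference.
    """
    if term not in fit.terms.index:
        raise KeyError(f"model does not contain the {term} interaction")
    sm_res = fit._sm_result
    names = list(fit.terms.index)
    if hasattr(sm_res, "cov_params"):
        cov_full = np.asarray(sm_res.cov_params())[: len(names), : len(names)]
    else:  # pragma: no cover
        cov_full = np.diag(fit.terms["se"].to_numpy() ** 2)
    i1 = names.index(term)
    has_time = "time" in names
    it = names.index("time") if has_time else None

    b1 = fit.terms.loc[term, "beta"]
    bt = fit.terms.loc["time", "beta"] if has_time else 0.0
    rows = []
    for lev in levels:
        slope = bt + lev * b1
        var = lev**2 * cov_full[i1, i1]
        if has_time:
            var += cov_full[it, it] + 2.0 * lev * cov_full[it, i1]
        rows.append(("high" if lev == max(levels) else "low", lev, slope, np.sqrt(var)))
    diff = (levels[0] - levels[1]) * b1
    diff_se = abs(levels[0] - levels[1]) * np.sqrt(cov_full[i1, i1])
    rows.append(("difference", levels[0] - levels[1], diff, diff_se))
    out = pd.DataFrame(rows, columns=["level", "score_value", "slope", "se"])
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["slope"] / out["se"]))
    return out


def run_atrophy_panel(
    data: pd.DataFrame,
    rois: tuple[str, ...],
    terms: tuple[str, ...] = ("phs", "sex", "education", "apoe"),
    predictor_term: str = "phs:time",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Longitudinal mixed-model fit per region of interest, FDR across the family.

    The per-region model regresses the (pre-adjusted) regional volume on
    score*Time plus sex/education/APOE interactions with Time and a random
    intercept; the score-interaction row of each fit is collected and BH
    adjusted across regions. Missing ROI columns are skipped with a warning.
    """
    present = [r for r in rois if r in data.columns]
    absent = [r for r in rois if r not in data.columns]
    if absent:
        warnings.warn(f"missing ROI columns skipped: {absent}", stacklevel=2)
    rows = []
    for roi in present:
        spec = LongitudinalModelSpec(outcome=roi, terms=terms)
        fit = fit_longitudinal(data, spec)
        t = fit.term(predictor_term)
        rows.append(
            {
                "roi": roi,
                "n": fit.nobs,
                "beta": t["beta"],
                "se": t["se"],
                "ci_low": t["ci_low"],
                "ci_high": t["ci_high"],
                "p": t["p"],
                "method": fit.method,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
        out["significant_fdr"] = out["p_fdr"] < alpha
    return out


class LongitudinalInteractionModel:
    """Estimator-style wrapper over :func:`fit_longitudinal`.

    ``fit`` stores ``result_`` (a :class:`ModelResult`); ``slopes`` exposes
    the +/- 1 SD simple effects of the fitted model.
    """

    def __init__(self, spec: LongitudinalModelSpec):
        self.spec = spec

    def fit(self, data: pd.DataFrame):
        self.result_ = fit_longitudinal(data, self.spec)
        return self

    def slopes(self, levels: tuple[float, float] = (1.0, -1.0)) -> pd.DataFrame:
        return simple_effect_slopes(self.result_, levels)

    def get_params(self, deep=True):
        return {"spec": self.spec}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
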