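"""Age-of-onset survival analysis of amyloid abnormality.

Survival time is the number of years from birth to (a) the (imputed) age at
which amyloid became abnormal (event), (b) withdrawal from the study
(censored), or (c) the last completed follow-up without an event (censored).
High- and low-score strata (mid excluded) are compared with Cox proportional
hazards (Efron ties, adjusted for baseline age, sex and education) and
Kaplan-Meier curves with a log-rank test.

Because age is the time scale, risk sets are left-truncated at study-entry
age by default to avoid immortal-time bias; the literal untruncated
birth-to-event definition is available via ``left_truncation=False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.base import BaseEstimator

__all__ = [
    "build_survival_table",
    "fit_cox_ph",
    "km_compare",
    "OnsetCoxModel",
]


def build_survival_table(
    participants: pd.DataFrame,
    onset_estimates: pd.DataFrame,
    strata: pd.Series,
    withdrawal_age: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-participant birth-to-event/censoring table for the onset analysis.

    * event: an abnormal scan exists -> time is the imputed onset age, event=1;
    * censored: withdrawal age if the participant withdrew, otherwise the age
      at the last completed follow-up examination, event=0.

    Participants in the mid stratum are excluded (the comparison is high vs
    low). ``participants`` must carry ``participant_id``, ``age_baseline``,
    ``sex``, ``education`` and ``last_visit_age``; ``onset_estimates`` is the
    output of the progression model (``participant_id``, ``onset_age``,
    ``status``).
    """
    df = participants.merge(
        onset_estimates[["participant_id", "onset_age", "status"]],
        on="participant_id",
        how="left",
    )
    df["stratum"] = strata.reindex(df["participant_id"]).to_numpy()
    df = df[df["stratum"].isin(["high", "low"])].copy()

    event = (df["status"] == "event").fillna(False).to_numpy()
    censor_time = df["last_visit_age"].to_numpy(dtype=float)
    if withdrawal_age is not None:
        w = withdrawal_age.reindex(df["participant_id"]).to_numpy(dtype=float)
        censor_time = np.where(np.isfinite(w), w, censor_time)
    time = np.where(event, df["onset_age"].to_numpy(dtype=float), censor_time)

    bad = ~event & np.isfinite(df["onset_age"].to_numpy(dtype=float))
    bad &= df["onset_age"].to_numpy(dtype=float) >= censor_time
    if np.any(bad):
        raise ValueError(
            "censored record(s) with onset age at/after censor age: "
            f"{df.loc[bad, 'participant_id'].tolist()}"
        )
    if np.any(~(time > 0)):
        raise ValueError("non-positive survival times")

    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "time": time,
            "event": event.astype(int),
            "stratum": df["stratum"].to_numpy(),
            "entry_age": df["age_baseline"].to_numpy(dtype=float),
            "age_baseline": df["age_baseline"].to_numpy(dtype=float),
            "sex": (df["sex"].astype(str) == "male").astype(float).to_numpy(),
            "education": df["education"].to_numpy(dtype=float),
        }
    )
    return out


def fit_cox_ph(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age_baseline", "sex", "education"),
    left_truncation: bool = True,
) -> dict:
    """Cox PH hazard ratio of the high vs low stratum, Efron tie handling.

    With ``left_truncation`` (default) individuals enter the risk set at
    their study-entry age. Records whose (imputed) event time precedes study
    entry were ascertained retrospectively, not observed at-risk from entry;
    their entry is set to 0 (birth) so risk sets stay well formed.
    """
    for stratum in ("high", "low"):
        if table.loc[table["stratum"] == stratum, "event"].sum() < 1:
            raise ValueError(f"no events in the {stratum} stratum")
    df = table.copy()
    df["high"] = (df["stratum"] == "high").astype(float)
    cols = ["time", "event", "high", *covariates]
    cph = CoxPHFitter()
    kwargs = {}
    if left_truncation:
        entry_age = df["entry_age"].to_numpy(dtype=float)
        entry = np.where(df["time"].to_numpy() <= entry_age, 0.0, entry_age)
        df["entry"] = entry
        cols.append("entry")
        kwargs["entry_col"] = "entry"
    try:
        cph.fit(df[cols], duration_col="time", event_col="event", **kwargs)
    except ConvergenceError as err:
        raise RuntimeError(
            "Cox model did not converge (possible complete separation); "
            "consider penalization or pooling strata"
        ) from err
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_.loc["high"]
    return {
        "hazard_ratio": hr,
        "hr_ci_low": float(np.exp(ci.iloc[0])),
        "hr_ci_high": float(np.exp(ci.iloc[1])),
        "log_hr": float(cph.params_["high"]),
        "log_hr_se": float(cph.standard_errors_["high"]),
        "p": float(cph.summary.loc["high", "p"]),
        "n": int(len(df)),
        "n_events": int(df["event"].sum()),
        "left_truncation": left_truncation,
        "model": cph,
    }


def _median_with_ci(kmf: KaplanMeierFitter) -> tuple[float, float, float]:
    """Median onset age with CI from the (log-log) confidence band."""
    from lifelines.utils import median_survival_times

    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        return (np.nan, np.nan, np.nan)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return (median, lo, hi)


def km_compare(table: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per stratum, median onset ages and log-rank test.

    Medians are reported only where the survival curve crosses 0.5 (NaN
    otherwise); the log-rank test compares the high and low strata.
    """
    if table["event"].sum() == 0:
        raise ValueError("no events in the survival table; log-rank undefined")
    out: dict = {"strata": {}}
    curves = []
    for stratum, g in table.groupby("stratum", sort=False):
        kmf = KaplanMeierFitter(label=stratum)
        kmf.fit(g["time"], event_observed=g["event"])
        median, lo, hi = _median_with_ci(kmf)
        out["strata"][stratum] = {
            "n": int(len(g)),
            "n_events": int(g["event"].sum()),
            "median_onset_age": median,
            "median_ci_low": lo,
            "median_ci_high": hi,
            "kmf": kmf,
        }
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_
        curve = pd.DataFrame(
            {
                "stratum": stratum,
                "age": sf.index.to_numpy(),
                "survival": sf.iloc[:, 0].to_numpy(),
                "ci_low": ci.iloc[:, 0].to_numpy(),
                "ci_high": ci.iloc[:, 1].to_numpy(),
            }
        )
        curves.append(curve)
    out["curves"] = pd.concat(curves, ignore_index=True)

    hi_g = table[table["stratum"] == "high"]
    lo_g = table[table["stratum"] == "low"]
    if len(hi_g) and len(lo_g):
        lr = logrank_test(
            hi_g["time"], lo_g["time"], event_observed_A=hi_g["event"], event_observed_B=lo_g["event"]
        )
        out["logrank_statistic"] = float(lr.test_statistic)
        out["logrank_p"] = float(lr.p_value)
    return out


class OnsetCoxModel(BaseEstimator):
    """Estimator wrapper for the high-vs-low onset comparison.

    ``fit`` takes a survival table from :func:`build_survival_table`; fitted
    attributes expose the hazard ratio (``hazard_ratio_``, ``hr_ci_``), the
    KM medians (``medians_``) and the log-rank p (``logrank_p_``).
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = ("age_baseline", "sex", "education"),
        left_truncation: bool = True,
    ):
        self.covariates = covariates
        self.left_truncation = left_truncation

    def fit(self, X: pd.DataFrame, y=None):
        cox = fit_cox_ph(X, self.covariates, self.left_truncation)
        km = km_compare(X)
        self.cox_ = cox
        self.km_ = km
        self.hazard_ratio_ = cox["hazard_ratio"]
        self.hr_ci_ = (cox["hr_ci_low"], cox["hr_ci_high"])
        self.medians_ = {
            s: v["median_onset_age"] for s, v in km["strata"].items()
        }
        self.logrank_p_ = km.get("logrank_p", np.nan)
        return self
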