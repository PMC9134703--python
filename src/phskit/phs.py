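"""Polygenic hazard score derivation and scoring.

The score is built in three steps: (1) filter GWAS summary statistics to
candidate variants below a p-value threshold; (2) forward stepwise Cox
proportional-hazards selection of variants associated with amyloid age of
onset, with the two APOE variants forced into the model before any step;
(3) per-individual scoring as the weighted allele-dosage sum using the final
joint Cox coefficients, so the score reproduces the joint model's linear
predictor. Individuals are stratified into high / mid / low score groups at
the cohort mean plus/minus one standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SnpPanel",
    "filter_candidate_snps",
    "forward_stepwise_cox",
    "compute_phs",
    "stratify_phs",
    "align_dosages",
    "PolygenicHazardScorer",
    "PhsStratifier",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SnpPanel:
    """Selected variants with effect alleles and per-allele log-hazard weights."""

    table: pd.DataFrame  # index snp_id; columns: effect_allele, weight, forced

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.table["weight"].to_numpy(dtype=float))):
            raise ValueError("panel weights must be finite")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]

    def to_tsv(self, path) -> None:
        self.table.reset_index().rename(columns={"index": "snp_id"}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "SnpPanel":
        t = pd.read_csv(path, sep="\t").set_index("snp_id")
        return cls(t[["effect_allele", "weight", "forced"]])


def filter_candidate_snps(summary_stats: pd.DataFrame, p_threshold: float = 1e-5) -> list[str]:
    """Variant ids with association p strictly below the threshold, in input order.

    ``summary_stats`` needs columns ``snp_id`` and ``p``; p-values must parse
    as numbers in (0, 1].
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    if summary_stats.empty:
        return []
    p = pd.to_numeric(summary_stats["p"], errors="coerce")
    bad = summary_stats.loc[p.isna() | (p <= 0) | (p > 1), "snp_id"]
    if len(bad):
        raise ValueError(f"malformed p-value for variant(s): {list(bad)}")
    return list(summary_stats.loc[p.to_numpy() < p_threshold, "snp_id"])


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(
        df[["time", "event", *covariates]],
        duration_col="time",
        event_col="event",
    )
    return cph


def forward_stepwise_cox(
    candidates: list[str],
    dosages: pd.DataFrame,
    survival: pd.DataFrame,
    forced_covariates: tuple[str, ...] = ("APOE_e4", "APOE_e2"),
    alpha_entry: float = 0.05,
    max_snps: int = 31,
    summary_stats: pd.DataFrame | None = None,
) -> SnpPanel:
    """Forward stepwise Cox selection of score variants.

    Starts from the forced-covariate (APOE) Cox model; at each step adds the
    candidate giving the largest partial-likelihood improvement, provided its
    one-degree likelihood-ratio p-value is below ``alpha_entry``; stops when
    no candidate qualifies or ``max_snps`` have entered. Weights are the
    coefficients of the final joint refit. Ties in improvement are broken by
    smaller summary-statistics p, then lexicographic id.

    ``survival`` must carry columns ``time`` and ``event`` indexed like
    ``dosages``; at least one event is required.
    """
    if survival["event"].sum() < 1:
        raise ValueError("survival table must contain at least one event")
    missing = [c for c in forced_covariates if c not in dosages.columns]
    if missing:
        raise ValueError(f"forced covariates absent from dosages: {missing}")

    df = pd.concat(
        [survival[["time", "event"]], dosages], axis=1, join="inner"
    ).astype(float)

    summary_p = {}
    if summary_stats is not None:
        summary_p = dict(zip(summary_stats["snp_id"], pd.to_numeric(summary_stats["p"])))

    try:
        current = _fit_cox(df, list(forced_covariates))
    except ConvergenceError as err:
        raise RuntimeError(
            "forced-covariate Cox model failed to converge (possible separation)"
        ) from err

    selected: list[str] = []
    remaining = [c for c in candidates if c in dosages.columns]
    dropped = [c for c in candidates if c not in dosages.columns]
    if dropped:
        warnings.warn(f"candidates absent from dosage matrix skipped: {dropped}", stacklevel=2)

    while remaining and len(selected) < max_snps:
        base_ll = current.log_likelihood_
        trials = []
        for cand in remaining:
            if df[cand].nunique() < 2:
                continue
            try:
                fit = _fit_cox(df, list(forced_covariates) + selected + [cand])
            except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                warnings.warn(f"Cox fit failed for candidate {cand}; skipped", stacklevel=2)
                continue
            lr = 2.0 * (fit.log_likelihood_ - base_ll)
            trials.append((lr, cand, fit))
        if not trials:
            break
        # best improvement; break ties by summary p then id
        trials.sort(key=lambda t: (-t[0], summary_p.get(t[1], 1.0), t[1]))
        lr, best, fit = trials[0]
        p = stats.chi2.sf(max(lr, 0.0), df=1)
        if p >= alpha_entry:
            break
        selected.append(best)
        remaining.remove(best)
        current = fit

    order = list(forced_covariates) + selected
    coefs = current.params_
    table = pd.DataFrame(
        {
            "effect_allele": ["."] * len(order),
            "weight": [coefs[c] for c in order],
            "forced": [c in forced_covariates for c in order],
        },
        index=pd.Index(order, name="snp_id"),
    )
    return SnpPanel(table)


def align_dosages(
    dosages: pd.DataFrame,
    counted_alleles: pd.Series,
    panel: SnpPanel,
) -> pd.DataFrame:
    """Flip dosages (2 - d) where the file's counted allele is not the panel's
    effect allele; palindromic (A/T, C/G) mismatches are strand-ambiguous and
    raise an error rather than being silently flipped."""
    out = dosages.copy()
    for snp in panel.snp_ids:
        eff = panel.table.loc[snp, "effect_allele"]
        if eff in (".", None) or snp not in counted_alleles.index:
            continue
        counted = counted_alleles.loc[snp]
        if counted == eff:
            continue
        if _COMPLEMENT.get(counted) == eff:
            raise ValueError(
                f"palindromic/strand-ambiguous allele mismatch for {snp}: "
                f"counted {counted}, effect {eff}"
            )
        out[snp] = 2.0 - out[snp]
    return out


def compute_phs(dosages: pd.DataFrame, panel: SnpPanel) -> pd.Series:
    """Per-individual score: sum over panel variants of weight x dosage.

    Missing variants or missing dosage values raise; no silent imputation.
    """
    missing = [s for s in panel.snp_ids if s not in dosages.columns]
    if missing:
        raise KeyError(f"panel variants absent from dosage matrix: {missing}")
    sub = dosages[panel.snp_ids]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing dosage values in variants: {bad}")
    scores = sub.to_numpy(dtype=float) @ panel.weights.to_numpy(dtype=float)
    return pd.Series(scores, index=dosages.index, name="phs")


def stratify_phs(
    scores: pd.Series | np.ndarray,
    thresholds: tuple[float, float] | None = None,
) -> pd.Series:
    """Assign low / mid / high strata at mean +/- 1 SD (or explicit thresholds).

    ``thresholds`` is (high, low): high stratum is score > high, low stratum
    is score < low, everything else mid.
    """
    s = pd.Series(scores)
    if thresholds is None:
        if s.nunique() < 2:
            raise ValueError("cannot compute mean +/- SD thresholds: fewer than 2 distinct scores")
        sd = s.std(ddof=1)
        if sd == 0:
            raise ValueError("zero standard deviation; supply explicit thresholds")
        hi, lo = s.mean() + sd, s.mean() - sd
    else:
        hi, lo = thresholds
        if lo > hi:
            raise ValueError("low threshold exceeds high threshold")
    out = pd.Series(
        np.where(s > hi, "high", np.where(s < lo, "low", "mid")),
        index=s.index,
        name="stratum",
    )
    return out


class PolygenicHazardScorer(BaseEstimator, TransformerMixin):
    """Derive and apply a polygenic hazard score.

    Parameters
    ----------
    summary_stats : DataFrame or None
        GWAS summary statistics (columns ``snp_id``, ``effect_allele``, ``or``
        or ``beta``, ``p``). When given, candidates are variants with
        ``p < p_threshold``; when None, every non-forced dosage column is a
        candidate.
    p_threshold : float
        Candidate inclusion threshold on the GWAS p-value (strict ``<``).
    forced : tuple of str
        Variants entered into the Cox model before any stepwise step
        (the two APOE variants by default).
    alpha_entry : float
        Likelihood-ratio entry p-value for each stepwise step.
    max_snps : int
        Cap on the number of stepwise-selected variants (the forced variants
        do not count against it).
    center_scale : bool
        Optionally standardize scores to the fitting cohort after summation.

    Attributes
    ----------
    panel_ : SnpPanel
        Selected variants with joint Cox weights.
    score_mean_, score_sd_ : float
        Fitting-cohort score moments (used by ``center_scale``).
    """

    def __init__(
        self,
        summary_stats: pd.DataFrame | None = None,
        p_threshold: float = 1e-5,
        forced: tuple[str, ...] = ("APOE_e4", "APOE_e2"),
        alpha_entry: float = 0.05,
        max_snps: int = 31,
        center_scale: bool = False,
    ):
        self.summary_stats = summary_stats
        self.p_threshold = p_threshold
        self.forced = forced
        self.alpha_entry = alpha_entry
        self.max_snps = max_snps
        self.center_scale = center_scale

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """Select the variant panel on dosages ``X`` and survival table ``y``
        (columns ``time`` and ``event``, indexed like ``X``)."""
        if self.summary_stats is not None:
            candidates = [
                c
                for c in filter_candidate_snps(self.summary_stats, self.p_threshold)
                if c not in self.forced
            ]
        else:
            candidates = [c for c in X.columns if c not in self.forced]
        self.panel_ = forward_stepwise_cox(
            candidates,
            X,
            y,
            forced_covariates=self.forced,
            alpha_entry=self.alpha_entry,
            max_snps=self.max_snps,
            summary_stats=self.summary_stats,
        )
        raw = compute_phs(X, self.panel_)
        self.score_mean_ = float(raw.mean())
        self.score_sd_ = float(raw.std(ddof=1))
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        """Score individuals with the fitted panel."""
        raw = compute_phs(X, self.panel_)
        if self.center_scale:
            return (raw - self.score_mean_) / self.score_sd_
        return raw


class PhsStratifier(BaseEstimator, TransformerMixin):
    """Stratify scores into low / mid / high groups.

    With ``thresholds=None`` the cut points are learned as the fitting
    cohort's mean +/- 1 SD; explicit ``(high, low)`` thresholds override.
    """

    def __init__(self, thresholds: tuple[float, float] | None = None):
        self.thresholds = thresholds

    def fit(self, X, y=None):
        s = pd.Series(np.asarray(X).ravel())
        if self.thresholds is not None:
            self.high_, self.low_ = self.thresholds
        else:
            sd = s.std(ddof=1)
            if not sd > 0:
                raise ValueError("zero score standard deviation; supply explicit thresholds")
            self.high_, self.low_ = s.mean() + sd, s.mean() - sd
        return self

    def transform(self, X) -> pd.Series:
        s = pd.Series(X) if isinstance(X, (pd.Series, list)) else pd.Series(np.asarray(X).ravel())
        return stratify_phs(s, thresholds=(self.high_, self.low_))
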