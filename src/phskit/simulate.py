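"""Synthetic cohort generator.

Emulates the statistical structure of a longitudinal ageing cohort with
genotypes, amyloid-PET Centiloid trajectories, regional brain volumes and
cognitive testing: ~780 participants, biallelic SNP dosages under
Hardy-Weinberg equilibrium, amyloid onset ages drawn from a proportional-
hazards model on the true genetic score, sigmoidal Centiloid trajectories
anchored at the 20-CL abnormality threshold at onset, score-dependent atrophy
and cognitive slopes, and 18-month visits with per-visit dropout.

Every downstream stage (scoring, onset imputation, association models,
survival) can therefore be tested against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .hazards import GompertzHazard

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "DK_ROIS",
    "generate_genotypes",
    "generate_onsets",
    "generate_amyloid_trajectories",
    "generate_longitudinal_outcomes",
    "simulate_cohort",
    "summarize_cohort",
]

REGIONS = ("neocortex", "frontal", "posterior_cingulate")

# Region-specific accumulation-rate multipliers; all regions cross the
# threshold at the individual's onset age, posterior cingulate accumulates
# fastest thereafter.
REGION_RATE_SCALE = {"neocortex": 1.0, "frontal": 1.08, "posterior_cingulate": 1.15}

#: 33 cortical regions of interest (Desikan-Killiany-style parcellation).
DK_ROIS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole",
)

#: Raw neuropsychological tests feeding the cognitive composites:
#: (population mean, population SD, direction: +1 higher-is-better).
COGNITIVE_TESTS = {
    "cvlt_recognition": (12.0, 2.5, +1),
    "rcft_recognition": (20.0, 4.0, +1),
    "cowat": (40.0, 11.0, +1),
    "category_switching": (12.0, 3.5, +1),
    "cvlt_recall": (9.0, 3.0, +1),
    "logical_memory_ii": (11.0, 4.0, +1),
    "rcft_recall": (16.0, 6.0, +1),
}

TEST_DOMAIN = {
    "cvlt_recognition": "recognition",
    "rcft_recognition": "recognition",
    "cowat": "executive",
    "category_switching": "executive",
    "cvlt_recall": "episodic",
    "logical_memory_ii": "episodic",
    "rcft_recall": "episodic",
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions the pipeline targets: 780
    participants, 31 risk SNPs plus the two APOE variants, visits every 1.5
    years with dropout giving ~4.8 years of mean follow-up, Centiloid
    measurement noise of 5 CL, and a Gompertz baseline hazard for amyloid
    onset.
    """

    n_participants: int = 780
    n_snps: int = 31
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    true_betas: np.ndarray | None = None          # per-SNP log-hazard effects
    true_beta_sd: float = 0.08                    # used when true_betas is None
    apoe_weights: tuple[float, float] = (1.0, -0.5)   # (e4, e2) log-hazard
    apoe_freqs: tuple[float, float] = (0.15, 0.08)
    baseline_hazard: GompertzHazard = field(default_factory=GompertzHazard)
    horizon_age: float = 110.0                    # onsets beyond => never-converter
    baseline_age_mean: float = 72.0
    baseline_age_sd: float = 6.5
    baseline_age_range: tuple[float, float] = (55.0, 95.0)
    visit_interval: float = 1.5                   # years
    n_visits_mean: int = 4
    dropout_prob_per_visit: float = 0.15
    cl_threshold: float = 20.0
    cl_floor: float = 0.0
    cl_ceiling: float = 100.0
    cl_rate: float = 0.15                         # logistic growth rate, 1/year
    cl_noise_sd: float = 5.0                      # Centiloid units
    volume_base_slope: float = -0.005             # volume-fraction/year
    atrophy_slope_per_phs: float = -0.004         # volume-fraction/year per score unit
    volume_intercept_sd: float = 0.05
    volume_noise_sd: float = 0.02
    cognition_base_slope: float = -0.01           # composite-SD/year
    cognition_slope_per_phs: float = -0.03        # composite-SD/year per score unit
    cognition_intercept_sd: float = 0.5
    cognition_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_snps <= 0:
            raise ValueError("n_participants and n_snps must be positive")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele frequencies must lie in (0, 1)")
        if self.visit_interval <= 0:
            raise ValueError("visit_interval must be positive")
        if self.cl_noise_sd < 0:
            raise ValueError("cl_noise_sd must be nonnegative")
        if not 0.0 <= self.dropout_prob_per_visit < 1.0:
            raise ValueError("dropout_prob_per_visit must lie in [0, 1)")
        if self.cl_ceiling <= self.cl_threshold:
            raise ValueError("Centiloid ceiling must exceed the abnormality threshold")
        if self.true_betas is not None:
            self.true_betas = np.asarray(self.true_betas, dtype=float)
            if self.true_betas.shape != (self.n_snps,):
                raise ValueError("true_betas must have length n_snps")

    @property
    def max_visits(self) -> int:
        return int(np.ceil(1.5 * self.n_visits_mean))


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth."""

    config: SimulationConfig
    dosages: pd.DataFrame            # individuals x variants, values in {0,1,2}
    snp_info: pd.DataFrame           # snp_id, effect_allele, freq, true_beta
    participants: pd.DataFrame       # one row per individual
    amyloid: pd.DataFrame            # long: participant_id, region, age, centiloid
    volumes: pd.DataFrame            # wide: participant_id, age, time, <33 ROIs>
    cognition: pd.DataFrame          # long: participant_id, age, time, test, value
    cdr: pd.DataFrame                # participant_id, age, time, cdr_sb


def _participant_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i:04d}" for i in range(n)], name="participant_id")


def generate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw biallelic dosages under HWE plus the two APOE pseudo-variants.

    Each dosage is Binomial(2, f) with f uniform in ``allele_freq_range``.
    Returns ``(dosages, snp_info)`` where dosages is individuals x variants
    and snp_info records effect allele, frequency and true log-hazard weight.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_participants, config.n_snps
    freqs = rng.uniform(*config.allele_freq_range, size=m)
    betas = (
        config.true_betas
        if config.true_betas is not None
        else rng.normal(0.0, config.true_beta_sd, size=m)
    )
    snp_ids = [f"rs{100000 + 7 * j}" for j in range(m)]
    alleles = rng.choice(list("ACGT"), size=m)

    dosage = rng.binomial(2, freqs, size=(n, m)).astype(float)
    # APOE pseudo-variants: the e4-defining risk allele and e2-defining
    # protective allele, modelled as two independent biallelic variants.
    apoe = rng.binomial(2, config.apoe_freqs, size=(n, 2)).astype(float)

    ids = _participant_ids(n)
    columns = snp_ids + ["APOE_e4", "APOE_e2"]
    dosages = pd.DataFrame(np.hstack([dosage, apoe]), index=ids, columns=columns)
    snp_info = pd.DataFrame(
        {
            "snp_id": columns,
            "effect_allele": list(alleles) + ["C", "T"],
            "freq": list(freqs) + list(config.apoe_freqs),
            "true_beta": list(betas) + list(config.apoe_weights),
            "forced": [False] * m + [True, True],
        }
    ).set_index("snp_id")
    return dosages, snp_info


def generate_onsets(
    true_scores,
    baseline_hazard: GompertzHazard,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw amyloid onset ages under ``h(t) = h0(t) exp(score)``.

    Returns the raw sampled event ages (possibly beyond any follow-up
    horizon); callers decide which count as never-converters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return baseline_hazard.sample_onset(true_scores, rng)


def _visit_schedule(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-participant strictly increasing visit ages with Bernoulli dropout."""
    lo, hi = config.baseline_age_range
    base = np.clip(
        rng.normal(config.baseline_age_mean, config.baseline_age_sd, config.n_participants),
        lo,
        hi,
    )
    schedules = []
    for b in base:
        ages = [b]
        for _ in range(config.max_visits - 1):
            if rng.uniform() < config.dropout_prob_per_visit:
                break
            ages.append(ages[-1] + config.visit_interval)
        schedules.append(np.asarray(ages))
    return schedules


def noiseless_centiloid(age, onset_age, config: SimulationConfig, region: str = "neocortex"):
    """Noiseless logistic Centiloid trajectory anchored at the threshold at onset."""
    lo, hi, thr = config.cl_floor, config.cl_ceiling, config.cl_threshold
    r = config.cl_rate * REGION_RATE_SCALE.get(region, 1.0)
    shift = np.log((hi - lo) / (thr - lo) - 1.0) / r
    return lo + (hi - lo) / (1.0 + np.exp(-r * ((np.asarray(age) - onset_age) - shift)))


def generate_amyloid_trajectories(
    onset_ages,
    visit_ages: Sequence[np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    participant_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Longitudinal Centiloid table over the three reporting regions.

    The noiseless trajectory is a logistic function of (age - onset) equal to
    the abnormality threshold at onset, with floor ~0 and ceiling ~100 CL;
    Gaussian noise with sd ``cl_noise_sd`` is added independently per scan.
    """
    onset_ages = np.asarray(onset_ages, dtype=float)
    if participant_ids is None:
        participant_ids = _participant_ids(len(onset_ages))
    rows = []
    for pid, onset, ages in zip(participant_ids, onset_ages, visit_ages):
        for region in REGIONS:
            clean = noiseless_centiloid(ages, onset, config, region)
            noisy = clean + rng.normal(0.0, config.cl_noise_sd, size=len(ages))
            for a, c in zip(ages, noisy):
                rows.append((pid, region, a, c))
    return pd.DataFrame(rows, columns=["participant_id", "region", "age", "centiloid"])


def generate_longitudinal_outcomes(
    true_scores,
    visit_ages: Sequence[np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    participant_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regional volumes and raw cognitive test scores over the visit schedule.

    Each outcome follows ``intercept + (base_slope + slope_per_phs * score) * time
    + random intercept + noise``, the generative counterpart of the
    random-intercept mixed model fitted downstream.
    """
    true_scores = np.asarray(true_scores, dtype=float)
    if participant_ids is None:
        participant_ids = _participant_ids(len(true_scores))

    vol_rows, cog_rows = [], []
    n_roi = len(DK_ROIS)
    for pid, score, ages in zip(participant_ids, true_scores, visit_ages):
        t = ages - ages[0]
        slope = config.volume_base_slope + config.atrophy_slope_per_phs * score
        u_roi = rng.normal(0.0, config.volume_intercept_sd, size=n_roi)
        for a, ti in zip(ages, t):
            noise = rng.normal(0.0, config.volume_noise_sd, size=n_roi)
            vols = 1.0 + u_roi + slope * ti + noise
            vol_rows.append([pid, a, ti, *vols])

        cog_slope = config.cognition_base_slope + config.cognition_slope_per_phs * score
        u_dom = {d: rng.normal(0.0, config.cognition_intercept_sd) for d in
                 ("recognition", "executive", "episodic")}
        for a, ti in zip(ages, t):
            for test, (mu, sd, direction) in COGNITIVE_TESTS.items():
                z = u_dom[TEST_DOMAIN[test]] + cog_slope * ti
                raw = mu + sd * (direction * z + rng.normal(0.0, config.cognition_noise_sd))
                cog_rows.append((pid, a, ti, test, raw))

    volumes = pd.DataFrame(vol_rows, columns=["participant_id", "age", "time", *DK_ROIS])
    cognition = pd.DataFrame(
        cog_rows, columns=["participant_id", "age", "time", "test", "value"]
    )
    return volumes, cognition


def _assign_diagnosis(baseline_age, onset_age, rng) -> np.ndarray:
    """Stand-in clinical labels from amyloid-relative disease stage.

    Thresholds a latent severity (years since amyloid onset at baseline, plus
    noise); this is artifact plumbing, not a validated clinical model.
    """
    stage = baseline_age - onset_age + rng.normal(0.0, 3.0, size=len(baseline_age))
    labels = np.where(stage >= 24.0, "AD", np.where(stage >= 10.0, "MCI", "CN"))
    return labels


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete cohort; identical config (incl. seed) is bitwise-reproducible."""
    rng = np.random.default_rng(config.seed)
    dosages, snp_info = generate_genotypes(config, rng)
    true_score = dosages.to_numpy() @ snp_info["true_beta"].to_numpy()
    true_score = true_score - true_score.mean()

    onsets = generate_onsets(true_score, config.baseline_hazard, rng)
    schedules = _visit_schedule(config, rng)
    ids = dosages.index

    amyloid = generate_amyloid_trajectories(onsets, schedules, config, rng, ids)
    volumes, cognition = generate_longitudinal_outcomes(true_score, schedules, config, rng, ids)

    base_age = np.array([s[0] for s in schedules])
    diagnosis = _assign_diagnosis(base_age, onsets, rng)
    cdr_rows = []
    for pid, score, onset, ages in zip(ids, true_score, onsets, schedules):
        t = ages - ages[0]
        stage0 = max(0.0, ages[0] - onset)
        base = 0.25 * max(0.0, stage0 - 8.0)
        slope = 0.05 + 0.08 * max(score, 0.0)
        for a, ti in zip(ages, t):
            cdr_rows.append((pid, a, ti, max(0.0, base + slope * ti + rng.normal(0, 0.15))))
    cdr = pd.DataFrame(cdr_rows, columns=["participant_id", "age", "time", "cdr_sb"])

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": rng.choice(["female", "male"], size=len(ids), p=[0.54, 0.46]),
            "age_baseline": base_age,
            "education": np.clip(np.round(rng.normal(13.0, 2.8, len(ids))), 6, 20),
            "apoe_e4_count": dosages["APOE_e4"].astype(int).to_numpy(),
            "diagnosis": diagnosis,
            "true_score": true_score,
            "true_onset_age": np.where(onsets <= config.horizon_age, onsets, np.nan),
            "n_visits": [len(s) for s in schedules],
            "last_visit_age": [s[-1] for s in schedules],
        }
    ).set_index("participant_id")

    return SyntheticCohort(
        config=config,
        dosages=dosages,
        snp_info=snp_info,
        participants=participants.reset_index(),
        amyloid=amyloid,
        volumes=volumes,
        cognition=cognition,
        cdr=cdr,
    )


def _fmt_count_pct(count: int, total: int) -> str:
    pct = 100.0 * count / total if total else float("nan")
    return f"{count} ({pct:.1f}%)"


def _fmt_mean_sd(x: pd.Series) -> str:
    return f"{x.mean():.1f} ({x.std(ddof=1):.1f})"


def summarize_cohort(participants: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics per diagnosis group.

    Counts with within-group percentages (one decimal) for sex and APOE e4
    carriage; mean (SD) for age, education and, if present, the polygenic
    hazard score. Empty diagnosis groups are omitted with a warning.
    """
    order = [d for d in ("CN", "MCI", "AD") if d in set(participants["diagnosis"])]
    missing = [d for d in ("CN", "MCI", "AD") if d not in order]
    if missing:
        warnings.warn(f"empty diagnosis group(s) omitted: {missing}", stacklevel=2)
    out: dict[str, dict[str, str]] = {}
    for dx in order:
        g = participants[participants["diagnosis"] == dx]
        n = len(g)
        col = {
            "N": str(n),
            "Sex: female": _fmt_count_pct(int((g["sex"] == "female").sum()), n),
            "Sex: male": _fmt_count_pct(int((g["sex"] == "male").sum()), n),
            "Age (years)": _fmt_mean_sd(g["age_baseline"]),
            "APOE e4: absent": _fmt_count_pct(int((g["apoe_e4_count"] == 0).sum()), n),
            "APOE e4: present": _fmt_count_pct(int((g["apoe_e4_count"] > 0).sum()), n),
            "Education (years)": _fmt_mean_sd(g["education"]),
        }
        if "phs" in g.columns:
            col["PHS"] = f"{g['phs'].mean():.3g} ({g['phs'].std(ddof=1):.3g})"
        out[f"{dx} (N={n})"] = col
    return pd.DataFrame(out)
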