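"""End-to-end orchestration: simulate/load -> score -> onset -> composites
-> associations -> survival, with per-stage outputs and a JSON run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    LongitudinalModelSpec,
    cross_sectional_panel,
    fit_longitudinal,
    run_atrophy_panel,
    simple_effect_slopes,
)
from .composites import CognitiveCompositeScorer
from .phs import PhsStratifier, PolygenicHazardScorer
from .progression import AmyloidProgressionModel
from .simulate import DK_ROIS, SimulationConfig, simulate_cohort, summarize_cohort
from .survival import OnsetCoxModel, build_survival_table

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

STAGES = ("inputs", "score", "onset", "composites", "associations", "survival")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run.

    Exactly one of ``simulation`` (synthetic branch) or the real input paths
    must be active. Thresholds: Centiloid abnormality at 20 CL, score strata
    at mean +/- 1 SD unless explicit thresholds are given.
    """

    out_dir: str = "phskit_run"
    simulation: SimulationConfig | None = None
    dosage_tsv: str | None = None
    summary_stats_tsv: str | None = None
    amyloid_csv: str | None = None
    participants_csv: str | None = None
    cl_threshold: float = 20.0
    phs_thresholds: tuple[float, float] | None = None  # (high, low), e.g. (1.04, -0.67)
    alpha_entry: float = 0.05
    max_snps: int = 31
    fdr_level: float = 0.05
    subgroups: tuple[str, ...] = ("all",)
    atrophy_rois: tuple[str, ...] = DK_ROIS
    cognitive_outcomes: tuple[str, ...] = ("recognition", "executive", "episodic", "cdr_sb")
    cognition_baseline_diagnoses: tuple[str, ...] = ("CN", "MCI")
    left_truncation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        real = any([self.dosage_tsv, self.amyloid_csv, self.participants_csv])
        if (self.simulation is None) == (not real):
            raise ValueError("exactly one of synthetic simulation or real input paths must be set")
        for v in (self.cl_threshold, self.alpha_entry, self.fdr_level):
            if not np.isfinite(v):
                raise ValueError("all thresholds must be finite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = d["simulation"]
            sim["baseline_hazard"] = dataclasses.asdict(self.simulation.baseline_hazard)
            if sim.get("true_betas") is not None:
                sim["true_betas"] = list(map(float, sim["true_betas"]))
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            from .hazards import GompertzHazard

            bh = sim.pop("baseline_hazard", None)
            if bh is not None:
                sim["baseline_hazard"] = GompertzHazard(**bh)
            raw["simulation"] = SimulationConfig(**sim)
        for key in ("phs_thresholds", "subgroups", "atrophy_rois", "cognitive_outcomes",
                    "cognition_baseline_diagnoses"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _baseline_cl(amyloid: pd.DataFrame) -> pd.DataFrame:
    """First scan per participant and region, widened to cl_<region> columns."""
    first = (
        amyloid.sort_values("age")
        .groupby(["participant_id", "region"], sort=False)
        .first()
        .reset_index()
    )
    wide = first.pivot(index="participant_id", columns="region", values="centiloid")
    return wide.rename(columns={c: f"cl_{c}" for c in wide.columns})


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order, writing each stage's outputs before the next.

    Returns the run report (also written to ``report.json``); failures abort
    with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
        "outputs": {},
        "status": "running",
    }

    def finish_stage(name: str, info: dict, files: dict[str, Path]) -> None:
        report["stages"][name] = info
        for label, path in files.items():
            report["outputs"][str(path.name)] = {"label": label, "sha256": _sha256(path)}

    stage = "inputs"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if config.simulation is not None:
                cohort = simulate_cohort(config.simulation)
            else:
                raise NotImplementedError(
                    "real-data branch: load inputs with phskit.io and assemble a "
                    "SyntheticCohort-shaped bundle"
                )
            participants = cohort.participants.set_index("participant_id")
            n = len(participants)
            summary = summarize_cohort(cohort.participants)
            summary.to_csv(out / "cohort_summary.csv")
            finish_stage(stage, {"n_participants": n, "n_variants": cohort.dosages.shape[1]},
                         {"cohort_summary": out / "cohort_summary.csv"})

        # ---- score ------------------------------------------------------
        stage = "score"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            prog = AmyloidProgressionModel(threshold=config.cl_threshold).fit(cohort.amyloid)
            onsets = prog.predict(cohort.amyloid)
            train = onsets.merge(
                participants[["last_visit_age"]].reset_index(), on="participant_id"
            )
            surv = pd.DataFrame(
                {
                    "time": np.where(
                        train["status"] == "event", train["onset_age"], train["last_visit_age"]
                    ),
                    "event": (train["status"] == "event").astype(int).to_numpy(),
                },
                index=pd.Index(train["participant_id"], name="participant_id"),
            )
            scorer = PolygenicHazardScorer(
                alpha_entry=config.alpha_entry, max_snps=config.max_snps
            ).fit(cohort.dosages, surv)
            phs = scorer.transform(cohort.dosages)
            strata = PhsStratifier(thresholds=config.phs_thresholds).fit(phs).transform(phs)
            scores = pd.DataFrame({"phs": phs, "stratum": strata})
            scores.to_csv(out / "phs.csv")
            scorer.panel_.to_tsv(out / "panel.tsv")
            report["warnings"] += [str(w.message) for w in caught]
            finish_stage(
                stage,
                {
                    "n_scored": int(len(scores)),
                    "n_panel_variants": len(scorer.panel_.snp_ids),
                    "phs_mean": float(phs.mean()),
                    "phs_sd": float(phs.std(ddof=1)),
                    "strata_counts": strata.value_counts().to_dict(),
                },
                {"phs": out / "phs.csv", "panel": out / "panel.tsv"},
            )

        # ---- onset ------------------------------------------------------
        stage = "onset"
        onsets.to_csv(out / "onset_estimates.csv", index=False)
        prog.curve_.to_csv(out / "progression_curve.csv")
        finish_stage(
            stage,
            {
                "n_events": int((onsets["status"] == "event").sum()),
                "n_censored": int((onsets["status"] == "censored").sum()),
            },
            {"onsets": out / "onset_estimates.csv", "curve": out / "progression_curve.csv"},
        )

        # ---- composites -------------------------------------------------
        stage = "composites"
        cog_wide = cohort.cognition.pivot_table(
            index=["participant_id", "age", "time"], columns="test", values="value"
        ).reset_index()
        baseline = cog_wide[cog_wide["time"] == 0].set_index("participant_id")
        cn = participants["diagnosis"].reindex(baseline.index) == "CN"
        comp_scorer = CognitiveCompositeScorer().fit(baseline, cn)
        composites = pd.concat(
            [cog_wide[["participant_id", "age", "time"]],
             comp_scorer.transform(cog_wide)], axis=1
        )
        composites = composites.merge(
            cohort.cdr[["participant_id", "age", "cdr_sb"]], on=["participant_id", "age"],
            how="left",
        )
        composites.to_csv(out / "composites.csv", index=False)
        finish_stage(stage, {"n_rows": int(len(composites))},
                     {"composites": out / "composites.csv"})

        # ---- associations ----------------------------------------------
        stage = "associations"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            base_cl = _baseline_cl(cohort.amyloid)
            covar = pd.DataFrame(
                {
                    "phs": phs,
                    "age_baseline": participants["age_baseline"],
                    "sex": participants["sex"],
                    "education": participants["education"],
                    "apoe": (participants["apoe_e4_count"] > 0).astype(int),
                }
            )
            cs_data = covar.join(base_cl).reset_index()
            cs_results = []
            for sub in config.subgroups:
                res = cross_sectional_panel(cs_data, subgroup=sub)
                res.insert(0, "subgroup", sub)
                cs_results.append(res)
            cs_table = pd.concat(cs_results, ignore_index=True)
            cs_table.to_csv(out / "cross_sectional.csv", index=False)

            ento = (
                cohort.volumes[cohort.volumes["time"] == 0]
                .set_index("participant_id")["entorhinal"]
                .rename("entorhinal_volume")
            )
            lmm_covar = covar.join(ento).join(
                base_cl["cl_frontal"] if "cl_frontal" in base_cl.columns else None
            )
            keep = participants["diagnosis"].isin(config.cognition_baseline_diagnoses)
            long_df = composites.merge(
                lmm_covar[keep.reindex(lmm_covar.index).fillna(False)].reset_index(),
                on="participant_id",
            )
            lmm_rows, slope_rows = [], []
            for outcome in config.cognitive_outcomes:
                spec = LongitudinalModelSpec(outcome=outcome)
                fit = fit_longitudinal(long_df, spec)
                t = fit.term("phs:time")
                lmm_rows.append(
                    {
                        "outcome": outcome,
                        "formula": fit.formula,
                        "n": fit.nobs,
                        "n_participants": fit.n_groups,
                        "method": fit.method,
                        "beta_phs_time": t["beta"],
                        "se": t["se"],
                        "ci_low": t["ci_low"],
                        "ci_high": t["ci_high"],
                        "p": t["p"],
                    }
                )
                sl = simple_effect_slopes(fit)
                sl.insert(0, "outcome", outcome)
                slope_rows.append(sl)
            lmm_table = pd.DataFrame(lmm_rows)
            lmm_table.to_csv(out / "longitudinal_cognition.csv", index=False)
            pd.concat(slope_rows, ignore_index=True).to_csv(
                out / "simple_effect_slopes.csv", index=False
            )

            vol_long = cohort.volumes.merge(
                covar.drop(columns=["age_baseline"]).reset_index(), on="participant_id"
            )
            atrophy = run_atrophy_panel(vol_long, config.atrophy_rois, alpha=config.fdr_level)
            atrophy.to_csv(out / "atrophy_panel.csv", index=False)
            report["warnings"] += [str(w.message) for w in caught]
            finish_stage(
                stage,
                {
                    "cross_sectional_models": int(len(cs_table)),
                    "cognitive_models": int(len(lmm_table)),
                    "atrophy_models": int(len(atrophy)),
                },
                {
                    "cross_sectional": out / "cross_sectional.csv",
                    "longitudinal_cognition": out / "longitudinal_cognition.csv",
                    "slopes": out / "simple_effect_slopes.csv",
                    "atrophy_panel": out / "atrophy_panel.csv",
                },
            )

        # ---- survival ---------------------------------------------------
        stage = "survival"
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = build_survival_table(
                cohort.participants,
                onsets,
                strata.rename_axis("participant_id"),
            )
            table.to_csv(out / "survival_table.csv", index=False)
            model = OnsetCoxModel(left_truncation=config.left_truncation).fit(table)
            model.km_["curves"].to_csv(out / "km_curves.csv", index=False)
            surv_json = {
                "hazard_ratio": model.hazard_ratio_,
                "hr_ci": list(model.hr_ci_),
                "logrank_p": model.logrank_p_,
                "medians": {
                    s: {k: v for k, v in d.items() if k != "kmf"}
                    for s, d in model.km_["strata"].items()
                },
                "left_truncation": config.left_truncation,
            }
            (out / "survival_results.json").write_text(json.dumps(surv_json, indent=2))
            report["warnings"] += [str(w.message) for w in caught]
            finish_stage(
                stage,
                {"n": int(len(table)), "n_events": int(table["event"].sum()),
                 "hazard_ratio": model.hazard_ratio_},
                {
                    "survival_table": out / "survival_table.csv",
                    "km_curves": out / "km_curves.csv",
                    "survival_results": out / "survival_results.json",
                },
            )

        report["status"] = "completed"
    except Exception as err:  # noqa: BLE001 - report then re-raise with stage context
        report["status"] = "aborted"
        report["failed_stage"] = stage
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise PipelineError(stage, err) from err

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
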