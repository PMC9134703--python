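"""Cognitive composite scores.

Composites (recognition memory, executive function, episodic recall) are
built by z-standardising each constituent neuropsychological test against
the baseline mean and SD of the cognitively normal (CN) sample, optionally
flipping sign so higher is always better, then averaging the standardized
scores available at each visit.  CDR sum-of-boxes is a clinical severity sum
and passes through raw, unstandardised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CompositeSpec",
    "NormReference",
    "DEFAULT_COMPOSITES",
    "build_norm_reference",
    "compute_composite",
    "CognitiveCompositeScorer",
]


@dataclass(frozen=True)
class CompositeSpec:
    """A named composite: constituent tests and per-test direction (+1 higher-is-better)."""

    name: str
    tests: tuple[str, ...]
    directions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.tests) == 0:
            raise ValueError("composite needs at least one constituent test")
        dirs = self.directions or tuple([1] * len(self.tests))
        if len(dirs) != len(self.tests) or any(d not in (-1, 1) for d in dirs):
            raise ValueError("directions must be +1/-1, one per test")
        object.__setattr__(self, "directions", dirs)


DEFAULT_COMPOSITES = (
    CompositeSpec("recognition", ("cvlt_recognition", "rcft_recognition")),
    CompositeSpec("executive", ("cowat", "category_switching")),
    CompositeSpec("episodic", ("cvlt_recall", "logical_memory_ii", "rcft_recall")),
)


@dataclass
class NormReference:
    """Per-test baseline mean and SD of the cognitively normal sample."""

    table: pd.DataFrame  # index test; columns mean, sd

    def __post_init__(self) -> None:
        if (self.table["sd"] <= 0).any():
            bad = self.table.index[self.table["sd"] <= 0].tolist()
            raise ValueError(f"non-positive CN baseline SD for test(s): {bad}")


def build_norm_reference(
    baseline: pd.DataFrame, cn_flags: pd.Series, tests: list[str] | None = None
) -> NormReference:
    """Mean/SD per test over CN baseline visits only.

    ``baseline`` holds one row per individual with one column per raw test
    score; ``cn_flags`` is a boolean Series aligned to its index.
    """
    cn = baseline.loc[np.asarray(cn_flags, dtype=bool)]
    tests = tests if tests is not None else list(baseline.columns)
    rows = {}
    for t in tests:
        vals = pd.to_numeric(cn[t], errors="coerce").dropna()
        if len(vals) < 2:
            raise ValueError(f"fewer than 2 non-missing CN baseline scores for test {t!r}")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero CN baseline SD for test {t!r}")
        rows[t] = (vals.mean(), sd)
    return NormReference(pd.DataFrame(rows, index=["mean", "sd"]).T)


def compute_composite(
    scores: pd.DataFrame,
    spec: CompositeSpec,
    reference: NormReference,
    require_complete: bool = False,
) -> pd.Series:
    """Composite value per row of ``scores`` (one row per individual-visit).

    Each constituent is standardized as ``direction * (x - mean) / sd`` with
    the CN-baseline reference, and available z-scores are averaged; rows with
    every constituent missing propagate as missing.  ``require_complete``
    switches to strict mode where any missing constituent yields a missing
    composite.
    """
    missing_ref = [t for t in spec.tests if t not in reference.table.index]
    if missing_ref:
        raise KeyError(f"reference lacks tests: {missing_ref}")
    zs = []
    for t, d in zip(spec.tests, spec.directions):
        mu, sd = reference.table.loc[t, ["mean", "sd"]]
        zs.append(d * (pd.to_numeric(scores[t], errors="coerce") - mu) / sd)
    z = pd.concat(zs, axis=1)
    if require_complete:
        out = z.mean(axis=1)
        out[z.isna().any(axis=1)] = np.nan
    else:
        out = z.mean(axis=1)  # pandas mean skips NaN; all-NaN rows give NaN
    out.name = spec.name
    return out


class CognitiveCompositeScorer(BaseEstimator, TransformerMixin):
    """Fit CN-baseline norms, transform raw test scores into composites.

    ``fit(X, y)`` takes baseline raw scores (one row per individual, one
    column per test) and a boolean CN indicator ``y``; ``transform`` maps any
    wide table of raw test scores (e.g. all visits) to one column per
    composite.
    """

    def __init__(
        self,
        specs: tuple[CompositeSpec, ...] = DEFAULT_COMPOSITES,
        require_complete: bool = False,
    ):
        self.specs = specs
        self.require_complete = require_complete

    def fit(self, X: pd.DataFrame, y):
        tests = sorted({t for s in self.specs for t in s.tests})
        self.reference_ = build_norm_reference(X, pd.Series(y, index=X.index), tests)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                s.name: compute_composite(X, s, self.reference_, self.require_complete)
                for s in self.specs
            },
            index=X.index,
        )
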