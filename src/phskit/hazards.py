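"""Parametric baseline hazards and proportional-hazards utilities.

The polygenic hazard score acts multiplicatively on an age-specific baseline
hazard: ``h(t | s) = h0(t) * exp(s)``.  A Gompertz baseline is used throughout
because late-onset Alzheimer's incidence rises roughly exponentially with age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GompertzHazard:
    """Gompertz baseline hazard ``h0(t) = rate * exp(shape * t)``.

    Parameters
    ----------
    rate : float
        Hazard at age 0, in events per year. Must be positive.
    shape : float
        Exponential growth rate of the hazard, per year. Must be positive.
    """

    rate: float = 8.9e-5
    shape: float = 0.087

    def __post_init__(self) -> None:
        if not (self.rate > 0 and self.shape > 0):
            raise ValueError("Gompertz rate and shape must be positive")

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.rate * np.exp(self.shape * t)

    def cumulative_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.rate / self.shape * (np.exp(self.shape * t) - 1.0)

    def survival(self, t):
        return np.exp(-self.cumulative_hazard(t))

    def cdf(self, t):
        return 1.0 - self.survival(t)

    def inverse_cumulative_hazard(self, h):
        """Solve ``H0(t) = h`` for t (closed form)."""
        h = np.asarray(h, dtype=float)
        return np.log1p(self.shape * h / self.rate) / self.shape

    def sample_onset(self, scores, rng: np.random.Generator):
        """Draw event times under ``h(t|s) = h0(t) exp(s)`` by inverse transform.

        ``S(t|s) = exp(-e^s H0(t))``; setting ``S = U`` gives
        ``t = H0^{-1}(-log U * e^{-s})``.
        """
        scores = np.asarray(scores, dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite score passed to sample_onset")
        u = rng.uniform(size=scores.shape)
        return self.inverse_cumulative_hazard(-np.log(u) * np.exp(-scores))


def hazard_curve(score: float, baseline: GompertzHazard):
    """Age-specific hazard function for an individual with the given score.

    Returns a callable ``h(t) = h0(t) * exp(score)``; the relative hazard
    between two individuals is ``exp(score difference)`` at every age.
    """
    scale = float(np.exp(score))

    def h(t):
        return baseline.hazard(t) * scale

    h.cumulative = lambda t: baseline.cumulative_hazard(t) * scale
    return h
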