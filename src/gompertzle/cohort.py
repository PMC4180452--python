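"""Synthetic survival cohorts with known truth.

Emulates a Health-and-Retirement-Study-like population: persons are
assigned to the 15 Lee-index risk groups (either from the published
point-score distribution or by drawing the 12 risk items from their
published marginal prevalences and scoring them), survival times follow a
per-group Gompertz distribution with a shared shape, and follow-up is cut
by administrative censoring at a fixed horizon (optionally plus uniform
dropout).  Because the generating parameters are known, every estimator in
the package can be tested for recovery without any restricted data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import published
from .life_expectancy import reconstruct_from_quantiles
from .published import GROUP_CAP, ITEM_POINTS, N_GROUPS
from .scoring import age_points

__all__ = ["CohortSpec", "sample_cohort", "hrs_like_spec", "reference_model"]


def reference_model():
    """Shared-shape Gompertz model reconstructed from the published quantile table."""
    return reconstruct_from_quantiles(published.PREDICTED_QUANTILES)


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    Exactly one of ``group_probabilities`` (multinomial membership) or
    ``group_counts`` (exact per-group sizes) describes the score
    distribution.  ``gamma``/``lambdas`` are the true Gompertz parameters;
    they default to the reconstruction of the published quantile table.
    ``horizon`` is the administrative censoring time in years and
    ``dropout`` an optional fraction lost uniformly over (0, horizon).
    """

    n: int
    group_probabilities: tuple | None = None
    group_counts: tuple | None = None
    gamma: float | None = None
    lambdas: tuple | None = None
    horizon: float = 10.0
    dropout: float = 0.0
    mode: str = "score"          # "score" | "factor"
    prevalence: str = "development"  # item prevalences for factor mode
    label: str = ""

    def __post_init__(self) -> None:
        if self.gamma is None or self.lambdas is None:
            ref = reference_model()
            if self.gamma is None:
                self.gamma = ref.shape
            if self.lambdas is None:
                self.lambdas = tuple(ref.rates)
        if self.mode not in ("score", "factor"):
            raise ValueError("mode must be 'score' or 'factor'")
        if self.mode == "score":
            if (self.group_probabilities is None) == (self.group_counts is None):
                raise ValueError(
                    "score mode needs exactly one of group_probabilities or group_counts")
            if self.group_counts is not None:
                if len(self.group_counts) != N_GROUPS:
                    raise ValueError(f"group_counts must have {N_GROUPS} entries")
                if sum(self.group_counts) != self.n:
                    raise ValueError("group_counts must sum to n")
            else:
                p = np.asarray(self.group_probabilities, dtype=float)
                if len(p) != N_GROUPS or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        "group_probabilities must be 15 nonnegative values summing to 1")
        lam = np.asarray(self.lambdas, dtype=float)
        if np.any(lam[np.isfinite(lam)] <= 0):
            raise ValueError("true rates must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _draw_groups_score(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.group_counts is not None:
        g = np.repeat(np.arange(N_GROUPS), spec.group_counts)
        rng.shuffle(g)
        return g
    return rng.choice(N_GROUPS, size=spec.n, p=np.asarray(spec.group_probabilities))


def _draw_groups_factor(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw the 12 items independently from marginal prevalences and score them.

    Independence is an approximation: real risk factors co-occur, so the
    resulting score distribution is narrower than the published one.
    """
    prev = published.ITEM_PREVALENCE[spec.prevalence]
    counts = np.asarray(prev["age_band_counts"], dtype=float)
    band = rng.choice(len(counts), size=spec.n, p=counts / counts.sum())
    band_pts = np.array([age_points(lo) for lo, _, _ in published.AGE_BANDS])
    pts = band_pts[band]
    for item, weight in ITEM_POINTS.items():
        pts = pts + weight * (rng.uniform(size=spec.n) < prev[item])
    return np.minimum(pts, GROUP_CAP).astype(int)


def sample_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate one cohort: columns id, group, time_years, event.

    Survival times are inverse-CDF draws from each group's Gompertz
    distribution ``T = ln(1 - (gamma/lambda) ln U)/gamma``; follow-up is
    censored at the administrative horizon (and at a uniform dropout time
    for the configured fraction).  Output is byte-identical for a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    groups = (_draw_groups_score(spec, rng) if spec.mode == "score"
              else _draw_groups_factor(spec, rng))
    lam = np.asarray(spec.lambdas, dtype=float)[groups]
    if np.any(~np.isfinite(lam)):
        raise ValueError("a sampled group has no true rate in the spec")
    u = rng.uniform(size=spec.n)
    g = spec.gamma
    if abs(g) < 1e-12:
        t = -np.log(u) / lam
    else:
        t = np.log1p(-(g / lam) * np.log(u)) / g
    censor = np.full(spec.n, spec.horizon)
    if spec.dropout > 0:
        drop = rng.uniform(size=spec.n) < spec.dropout
        dtime = rng.uniform(0.0, spec.horizon, size=spec.n)
        censor = np.where(drop, np.minimum(dtime, censor), censor)
    event = t <= censor
    return pd.DataFrame({
        "id": np.arange(spec.n),
        "group": groups.astype(int),
        "time_years": np.where(event, t, censor),
        "event": event,
    })


def hrs_like_spec(cohort: str = "development", **overrides) -> CohortSpec:
    """Built-in spec matching one of the published cohorts.

    ``cohort`` is ``"development"`` (n=11,701), ``"validation"`` (n=8,009)
    or ``"elsa"`` (n=7,042); per-group sizes are the published point-score
    counts, truth defaults to the quantile-table reconstruction, and the
    horizon to the cohort's follow-up limit (10 y for the US cohorts, 8 y
    for the English one).
    """
    if cohort not in published.GROUP_COUNTS:
        raise ValueError(
            f"unknown cohort {cohort!r}; choose from {sorted(published.GROUP_COUNTS)}")
    counts = published.GROUP_COUNTS[cohort]
    spec = CohortSpec(n=sum(counts), group_counts=counts,
                      horizon=published.FOLLOWUP_YEARS[cohort], label=cohort)
    return replace(spec, **overrides) if overrides else spec
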