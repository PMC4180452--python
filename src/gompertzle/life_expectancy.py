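"""Life-expectancy quantiles with confidence and prediction intervals.

A fitted grouped Gompertz model is turned into, per risk group, the time to
25% mortality, the median life expectancy (time to 50% mortality) and the
time to 75% mortality, by inverting the survival function in closed form.
Uncertainty is quantified two ways:

* **95% confidence intervals** — nonparametric bootstrap: resample persons
  with replacement, refit, take percentile intervals of the per-group
  quantiles.  A CI bounds the unknown population quantile.
* **50% prediction intervals** — for each bootstrap replicate, draw
  individual survival times from that replicate's fitted group
  distribution and pool the draws; the central 50% of the pooled draws
  bounds an individual's survival time, mixing sampling uncertainty with
  between-person variability.

The module also reconstructs model parameters from a published quantile
table (shared shape by least squares on the Gompertz quantile-ratio
equation, rates solved exactly from the medians), which is how the
calculator is re-calibrated when only summary tables are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .published import GROUP_LABELS, N_GROUPS
from .gompertz_survival import GompertzFit, PlateauError, fit_mle, quantile

__all__ = [
    "LifeExpectancyEstimate",
    "BootstrapResult",
    "quantile",
    "predict_le",
    "predict_le_table",
    "bootstrap_ci",
    "prediction_interval",
    "reconstruct_from_quantiles",
    "estimate_life_expectancy",
]

QUANTILE_PS = (0.25, 0.50, 0.75)

#: Ratio (e^{g t50} - 1)/(e^{g t25} - 1) implied by any Gompertz model.
_QUANTILE_RATIO_TARGET = float(np.log(0.5) / np.log(0.75))


@dataclass
class LifeExpectancyEstimate:
    """Survival quantiles for one risk group, with intervals when available."""

    group: int
    t25: float
    t50: float
    t75: float
    ci95: dict | None = None       # {"t25": (lo, hi), ...}
    pi50: tuple | None = None      # (lo, hi) years for an individual
    extrapolated: bool = False     # any quantile beyond the validated horizon
    n_boot: int = 0
    seed: int | None = None

    @property
    def group_label(self) -> str:
        return GROUP_LABELS[self.group]


def predict_le(fit: GompertzFit, group: int, horizon: float = 10.0) -> LifeExpectancyEstimate:
    """Point quantiles (t25, median, t75) for one risk group.

    Quantiles beyond ``horizon`` (the follow-up limit the model was
    validated against) are extrapolations of the fitted curve and the
    estimate is flagged accordingly.
    """
    if fit.family != "gompertz":
        raise ValueError("life-expectancy prediction requires a Gompertz fit")
    lam = fit.rate(group)  # raises if group absent
    if lam <= 0:
        raise ValueError(f"group {group} has no events; quantiles undefined")
    t25, t50, t75 = (float(quantile(p, lam, fit.shape)) for p in QUANTILE_PS)
    return LifeExpectancyEstimate(group=group, t25=t25, t50=t50, t75=t75,
                                  extrapolated=t75 > horizon)


def predict_le_table(fit: GompertzFit, horizon: float = 10.0) -> pd.DataFrame:
    """Point quantiles for every group present in the fit."""
    rows = []
    for g in fit.groups:
        est = predict_le(fit, g, horizon=horizon)
        rows.append({"group": g, "label": est.group_label, "t25": est.t25,
                     "t50": est.t50, "t75": est.t75,
                     "extrapolated": est.extrapolated})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Per-replicate quantiles from resampled refits.

    ``quantiles`` has shape (B_ok, n_groups, 3) for (t25, t50, t75);
    ``shapes`` and ``rates`` hold the replicate parameters so prediction
    intervals can re-draw individual times.
    """

    groups: tuple[int, ...]
    quantiles: np.ndarray
    shapes: np.ndarray
    rates: np.ndarray
    n_requested: int
    n_failed: int
    seed: int

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        """Percentile bootstrap interval per group and quantile.

        Replicates in which a group's quantile was undefined (no events in
        the resample) are NaN and excluded group-wise.
        """
        a = (1.0 - level) / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(self.quantiles, 100 * a, axis=0)
            hi = np.nanpercentile(self.quantiles, 100 * (1 - a), axis=0)
        rows = []
        for i, g in enumerate(self.groups):
            rows.append({"group": g,
                         "t25_lo": lo[i, 0], "t25_hi": hi[i, 0],
                         "t50_lo": lo[i, 1], "t50_hi": hi[i, 1],
                         "t75_lo": lo[i, 2], "t75_hi": hi[i, 2]})
        return pd.DataFrame(rows)


def bootstrap_ci(records: pd.DataFrame, B: int = 1000,
                 seed: int = 0) -> BootstrapResult:
    """Resample persons with replacement, refit, collect per-group quantiles.

    Replicates whose refit fails (e.g. a resample with no events in some
    group) are dropped and counted; more than 10% failures triggers a
    warning.  Identical seeds give identical output.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if B < 50:
        warnings.warn(f"B={B} gives very coarse percentile intervals", stacklevel=2)
    rng = np.random.default_rng(seed)
    base = fit_mle(records, family="gompertz")
    groups = base.groups
    n = len(records)
    idx_cols = records[["group", "time_years", "event"]].reset_index(drop=True)

    qs, shapes, rates = [], [], []
    n_failed = 0
    for _ in range(B):
        take = rng.integers(0, n, size=n)
        rep = idx_cols.iloc[take]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_mle(rep, family="gompertz")
        except ValueError:
            n_failed += 1
            continue
        q = np.full((len(groups), len(QUANTILE_PS)), np.nan)
        for i, g in enumerate(groups):
            lam = fit.rates[g]
            if np.isfinite(lam) and lam > 0:
                try:
                    q[i] = [quantile(p, lam, fit.shape) for p in QUANTILE_PS]
                except PlateauError:
                    pass  # leaves NaN: quantile undefined in this resample
        qs.append(q)
        shapes.append(fit.shape)
        rates.append(fit.rates[list(groups)])

    if not qs:
        raise ValueError("every bootstrap replicate failed to fit")
    if n_failed > 0.10 * B:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed and were dropped",
                      stacklevel=2)
    return BootstrapResult(groups=groups, quantiles=np.array(qs),
                           shapes=np.array(shapes), rates=np.array(rates),
                           n_requested=B, n_failed=n_failed, seed=seed)


def prediction_interval(boot: BootstrapResult, level: float = 0.50,
                        n_draws: int = 100, seed: int | None = None) -> pd.DataFrame:
    """Central interval for an individual's survival time, per group.

    For every bootstrap replicate, ``n_draws`` survival times are drawn from
    that replicate's fitted Gompertz distribution (inverse-CDF sampling);
    the interval is the central ``level`` of the pooled draws.  With no
    sampling uncertainty (all replicates identical) this collapses to the
    model's own (t25, t75) band up to Monte-Carlo error.
    """
    if boot.quantiles.shape[0] == 0:
        raise ValueError("no bootstrap replicates available")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(boot.seed + 1 if seed is None else seed)
    B = boot.shapes.shape[0]
    a = (1.0 - level) / 2.0
    rows = []
    for i, g in enumerate(boot.groups):
        u = rng.uniform(size=(B, n_draws))
        lam = boot.rates[:, i][:, None]
        lam = np.where(np.isfinite(lam) & (lam > 0), lam, np.nan)
        gam = boot.shapes[:, None]
        # inverse CDF: T = ln(1 - (gamma/lambda) ln U) / gamma
        with np.errstate(divide="ignore", invalid="ignore"):
            draws = np.where(
                np.abs(gam) < 1e-12,
                -np.log(u) / lam,
                np.log1p(-(gam / lam) * np.log(u)) / gam,
            )
        draws = draws[np.isfinite(draws)]
        if draws.size == 0:  # group inestimable in every replicate
            rows.append({"group": g, "pi_lo": np.nan, "pi_hi": np.nan})
            continue
        lo, hi = np.percentile(draws, [100 * a, 100 * (1 - a)])
        rows.append({"group": g, "pi_lo": lo, "pi_hi": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reconstruction from a published quantile table
# ---------------------------------------------------------------------------

def _as_quantile_frame(table) -> pd.DataFrame:
    if isinstance(table, dict):
        rows = []
        for g, q in table.items():
            q = tuple(q)
            rows.append({"group": int(g), "t25": q[0], "t50": q[1],
                         "t75": q[2] if len(q) > 2 else np.nan})
        table = pd.DataFrame(rows)
    df = table.copy()
    if "t75" not in df.columns:
        df["t75"] = np.nan
    return df[["group", "t25", "t50", "t75"]]


def reconstruct_from_quantiles(table) -> GompertzFit:
    """Recover a shared-shape grouped Gompertz model from published quantiles.

    Any Gompertz distribution satisfies
    ``(e^{g t50} - 1)/(e^{g t25} - 1) = ln(0.5)/ln(0.75)`` for its 25% and
    50% mortality times, so each (t25, t50) pair constrains the shape.  A
    single shared shape is estimated by least squares on these ratio
    residuals over all supplied pairs (groups with short, heavily rounded
    times have flat residuals and therefore little weight); each group's
    rate then follows exactly from its median:
    ``lambda_g = g ln 2 / (e^{g t50_g} - 1)``.

    ``table`` is a DataFrame with columns group, t25, t50 (optional t75,
    unused in estimation) or a mapping group -> (t25, t50[, t75]).
    Quantiles must be positive and increasing within each group.
    """
    df = _as_quantile_frame(table)
    for _, row in df.iterrows():
        seq = [row["t25"], row["t50"]] + ([row["t75"]] if np.isfinite(row["t75"]) else [])
        if any(t <= 0 for t in seq) or any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError(
                f"group {int(row['group'])}: quantiles must be positive and "
                f"strictly increasing, got {tuple(seq)}"
            )
    pairs = df[np.isfinite(df["t25"]) & np.isfinite(df["t50"])]
    if len(pairs) < 1:
        raise ValueError("need at least one group with both t25 and t50")
    t25 = pairs["t25"].to_numpy(float)
    t50 = pairs["t50"].to_numpy(float)

    def obj(g):
        if abs(g) < 1e-12:
            r = t50 / t25
        else:
            r = np.expm1(g * t50) / np.expm1(g * t25)
        return float(np.sum((r - _QUANTILE_RATIO_TARGET) ** 2))

    res = minimize_scalar(obj, bounds=(1e-6, 2.0), method="bounded",
                          options={"xatol": 1e-12})
    gamma = float(res.x)

    rates = np.full(N_GROUPS, np.nan)
    for _, row in df.iterrows():
        g = int(row["group"])
        rates[g] = gamma * np.log(2.0) / np.expm1(gamma * row["t50"])
    present = tuple(int(g) for g in df["group"])
    k = 1 + len(present)
    return GompertzFit("gompertz", gamma, rates, loglik=np.nan, n=0,
                       n_events=0, n_params=k, converged=bool(res.success),
                       message="reconstructed from quantile table",
                       groups=present)


# ---------------------------------------------------------------------------
# High-level pipeline
# ---------------------------------------------------------------------------

def estimate_life_expectancy(records: pd.DataFrame, B: int = 1000, seed: int = 0,
                             horizon: float = 10.0,
                             pi_level: float = 0.50) -> pd.DataFrame:
    """Fit, bootstrap and tabulate life expectancy for every risk group.

    Returns one row per group: point quantiles, 95% percentile-bootstrap
    CIs, the individual-level prediction interval and an extrapolation
    flag.
    """
    fit = fit_mle(records, family="gompertz")
    pts = predict_le_table(fit, horizon=horizon)
    boot = bootstrap_ci(records, B=B, seed=seed)
    ci = boot.ci(0.95)
    pi = prediction_interval(boot, level=pi_level)
    out = pts.merge(ci, on="group").merge(pi, on="group")
    out["n_boot"] = boot.quantiles.shape[0]
    out["seed"] = seed
    return out
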