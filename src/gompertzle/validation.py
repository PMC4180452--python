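"""Model validation: Kaplan-Meier curves, discrimination, calibration.

Predicted group survival curves are compared against the nonparametric
Kaplan-Meier estimate within the follow-up horizon; global discrimination
is summarised by Harrell's c of the point score, and calibration by a
fixed-horizon Hosmer-Lemeshow chi-square over the 15 risk groups with
observed deaths taken from the KM estimate (so censoring is respected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2

from .gompertz_survival import GompertzFit, _extract

__all__ = [
    "KMCurve",
    "HLResult",
    "ValidationReport",
    "kaplan_meier",
    "harrells_c",
    "hosmer_lemeshow",
    "export_curves",
    "validate",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate for one risk group.

    ``times``/``survival`` give the right-continuous step function
    (survival[i] applies on [times[i], times[i+1])); a leading (0, 1) point
    is always present.  Quantile lookups return None when the curve never
    reaches the target within follow-up ("not reached").
    """

    group: int | None
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function lookup S(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.times) - 1)]

    def quantile(self, p: float) -> float | None:
        """First time at which cumulative mortality reaches ``p`` (None if never)."""
        below = self.survival <= 1.0 - p + 1e-12
        if not below.any():
            return None
        return float(self.times[np.argmax(below)])

    @property
    def median(self) -> float | None:
        return self.quantile(0.5)

    def quantile_label(self, p: float, horizon: float) -> str:
        q = self.quantile(p)
        return f">{horizon:g}" if q is None else f"{q:g}"


def _km_one(times: np.ndarray, events: np.ndarray, group=None) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
        s = np.concatenate([[1.0], s])
    ev = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    at_risk = np.nan_to_num(ev, nan=0.0)[: len(grid)]
    if at_risk.size < grid.size:
        at_risk = np.concatenate([[len(times)], at_risk])
    return KMCurve(group=group, times=grid, survival=s, at_risk=at_risk,
                   n=len(times), n_events=int(np.sum(events)))


def kaplan_meier(records: pd.DataFrame, by_group: bool = True):
    """Kaplan-Meier curve(s) from a cohort frame.

    Censored subjects at an event time stay in the risk set for that time
    (the standard product-limit convention).  Returns a dict
    ``group -> KMCurve`` when ``by_group`` (default), else a single pooled
    curve.
    """
    groups, times, events = _extract(records)
    if not by_group:
        return _km_one(times, events)
    out = {}
    for g in np.unique(groups):
        m = groups == g
        out[int(g)] = _km_one(times[m], events[m], group=int(g))
    return out


# ---------------------------------------------------------------------------
# Harrell's c
# ---------------------------------------------------------------------------

def harrells_c(records: pd.DataFrame, scores=None) -> float:
    """Concordance of a risk score with censored survival.

    Usable pairs are those whose ordering the data determine: the shorter
    follow-up time is an observed death and the two times differ.  A pair is
    concordant when the higher-score member dies earlier; score ties count
    half.  By default the risk group column is the score.

    Runs in O(n log n + n * n_scores) by sweeping event times in order and
    keeping per-score counts of subjects still under observation, which is
    exact and fast even for cohorts of 10^4+ persons.
    """
    _, times, events = _extract(records)
    scores = (records["group"].to_numpy(float) if scores is None
              else np.asarray(scores, dtype=float))
    if scores.shape[0] != times.shape[0]:
        raise ValueError("scores must align with records")
    uniq, dense = np.unique(scores, return_inverse=True)
    ns = uniq.size

    order = np.argsort(times, kind="stable")
    s, tt, ev = dense[order], times[order], events[order]
    remaining = np.bincount(s, minlength=ns).astype(float)
    conc = disc = ties = 0.0
    i, n = 0, len(tt)
    while i < n:
        j = i
        while j < n and tt[j] == tt[i]:
            j += 1
        for k in range(i, j):          # tied-time pairs are not usable
            remaining[s[k]] -= 1
        if np.any(ev[i:j]):
            cum = np.cumsum(remaining)  # remaining with score <= x
            total = cum[-1]
            for k in range(i, j):
                if ev[k]:
                    sk = s[k]
                    conc += cum[sk] - remaining[sk]   # lower score outlives death
                    ties += remaining[sk]
                    disc += total - cum[sk]
        i = j
    denom = conc + disc + ties
    if denom == 0:
        raise ValueError("no usable pairs: need two subjects with distinct "
                         "times where the shorter is an event")
    return float((conc + 0.5 * ties) / denom)


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow calibration at a fixed horizon
# ---------------------------------------------------------------------------

@dataclass
class HLResult:
    statistic: float
    df: int
    pvalue: float
    horizon: float
    table: pd.DataFrame = field(repr=False)
    df_convention: str = "internal"


def hosmer_lemeshow(records: pd.DataFrame, fit: GompertzFit, horizon: float,
                    external: bool = False, min_expected: float = 1.0) -> HLResult:
    """Grouped calibration chi-square at a fixed horizon.

    Per risk group g, observed deaths by ``horizon`` are
    ``O_g = n_g (1 - S_KM(h))`` (KM respects censoring) and expected deaths
    are ``E_g = n_g (1 - S_model(h))``.  The statistic is
    ``sum (O-E)^2 / (E (1 - E/n))`` on G-2 degrees of freedom when the
    model was fitted to these data (``external=False``) or G when it is
    being validated on an independent cohort.  Groups with expected deaths
    below ``min_expected`` are merged into the adjacent group.
    """
    grouped = kaplan_meier(records, by_group=True)
    gs = sorted(grouped)
    rows = []
    for g in gs:
        km = grouped[g]
        o = km.n * (1.0 - float(km.survival_at(horizon)))
        e = km.n * (1.0 - float(fit.survival_at(horizon, g)))
        rows.append([g, km.n, o, e])
    # merge sparse groups into their lower neighbour (or upward at the bottom)
    merged = []
    for row in rows:
        if merged and merged[-1][3] < min_expected:
            warnings.warn(
                f"group {merged[-1][0]} has expected deaths < {min_expected}; "
                "merged with next group", stacklevel=2)
            prev = merged.pop()
            row = [prev[0], prev[1] + row[1], prev[2] + row[2], prev[3] + row[3]]
        merged.append(row)
    if len(merged) > 1 and merged[-1][3] < min_expected:
        last = merged.pop()
        warnings.warn(
            f"group {last[0]} has expected deaths < {min_expected}; "
            "merged with previous group", stacklevel=2)
        prev = merged.pop()
        merged.append([prev[0], prev[1] + last[1], prev[2] + last[2],
                       prev[3] + last[3]])

    G = len(merged)
    dof = G if external else G - 2
    if dof <= 0:
        raise ValueError(f"too few groups ({G}) for a {G}-2 df calibration test")
    tab = pd.DataFrame(merged, columns=["group", "n", "observed", "expected"])
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (tab["observed"] - tab["expected"]) ** 2 / (
            tab["expected"] * (1.0 - tab["expected"] / tab["n"]))
    stat = float(contrib.sum())
    p = float(chi2.sf(stat, dof))
    return HLResult(statistic=stat, df=dof, pvalue=p, horizon=horizon,
                    table=tab.assign(contribution=contrib),
                    df_convention="external" if external else "internal")


# ---------------------------------------------------------------------------
# Predicted-vs-observed curve export
# ---------------------------------------------------------------------------

def export_curves(fit: GompertzFit, km_curves: dict, horizon: float) -> pd.DataFrame:
    """Long-format (group, time, predicted, observed) table up to ``horizon``.

    The grid is each group's KM step times (plus 0) truncated at the
    horizon, so observed values are exact step heights.
    """
    rows = []
    for g, km in sorted(km_curves.items()):
        if g not in fit.groups:
            raise ValueError(f"group {g} present in KM curves but not in fit")
        mask = km.times <= horizon
        grid = km.times[mask]
        obs = km.survival[mask]
        pred = np.asarray(fit.survival_at(grid, g), dtype=float)
        for t, pr, ob in zip(grid, pred, obs):
            rows.append({"group": g, "time": float(t), "predicted": float(pr),
                         "observed": float(ob)})
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Bundle of discrimination, calibration and curve comparisons."""

    cohort: str
    harrell_c: float
    hl: dict            # horizon -> HLResult
    curves: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "harrell_c": self.harrell_c,
            "hosmer_lemeshow": {
                str(h): {"statistic": r.statistic, "df": r.df,
                         "pvalue": r.pvalue, "convention": r.df_convention}
                for h, r in self.hl.items()
            },
        }


def validate(records: pd.DataFrame, fit: GompertzFit,
             horizons=(5.0, 8.0, 10.0), external: bool = False,
             cohort: str = "") -> ValidationReport:
    """Full validation pass: Harrell's c, HL at each horizon, curve export."""
    km = kaplan_meier(records, by_group=True)
    c = harrells_c(records)
    hl = {float(h): hosmer_lemeshow(records, fit, float(h), external=external)
          for h in horizons}
    curves = export_curves(fit, km, max(horizons))
    return ValidationReport(cohort=cohort, harrell_c=c, hl=hl, curves=curves)
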