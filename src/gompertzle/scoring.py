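"""Lee-index point scoring.

Converts the 12 risk-factor answers for one person (or a table of persons)
into the Lee point score and the 15-level risk group used by the
life-expectancy model.  Items and weights: age band (0/1/2/3/4/5/7 points
for 50-59 / 60-64 / 65-69 / 70-74 / 75-79 / 80-84 / 85+), male sex (2),
diabetes (1), cancer (2), chronic lung disease (2), heart failure (2),
BMI < 25 (1), current smoking (2), and difficulty with bathing (2),
managing finances (2), walking several blocks (2) and pushing/pulling
heavy objects (1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import pandas as pd

from .published import AGE_BANDS, GROUP_CAP, ITEM_POINTS, MAX_POINTS

__all__ = [
    "RiskFactorProfile",
    "PointScore",
    "age_points",
    "score_profile",
    "score_table",
]


@dataclass(frozen=True)
class RiskFactorProfile:
    """Answers to the 12 Lee-index items for one person.

    ``age_years`` must be at least 50 (the index was developed for
    community-dwelling adults 50 and over); every other field is a plain
    boolean.  BMI may be supplied either as the precomputed indicator
    ``bmi_under_25`` or as a numeric value via :meth:`from_bmi`
    (threshold strictly below 25.0).
    """

    age_years: int
    male: bool = False
    diabetes: bool = False
    cancer: bool = False
    lung_disease: bool = False
    heart_failure: bool = False
    bmi_under_25: bool = False
    current_smoker: bool = False
    difficulty_bathing: bool = False
    difficulty_finances: bool = False
    difficulty_walking_blocks: bool = False
    difficulty_push_pull: bool = False

    def __post_init__(self) -> None:
        if self.age_years is None or self.age_years < 50:
            raise ValueError(
                f"age_years must be >= 50 (got {self.age_years}); the index "
                "is not defined for younger adults"
            )
        for f in fields(self):
            if f.name == "age_years":
                continue
            v = getattr(self, f.name)
            if v is None or not isinstance(v, (bool,)):
                raise ValueError(f"item {f.name!r} must be a boolean, got {v!r}")

    @classmethod
    def from_bmi(cls, age_years: int, bmi: float, **items: bool) -> "RiskFactorProfile":
        """Build a profile from a numeric BMI (kg/m^2); scores 1 point iff bmi < 25.0."""
        return cls(age_years=age_years, bmi_under_25=bool(bmi < 25.0), **items)


@dataclass(frozen=True)
class PointScore:
    """A Lee point total and its risk group (scores of 14+ are pooled)."""

    points: int
    group: int

    def __post_init__(self) -> None:
        if not 0 <= self.points <= MAX_POINTS:
            raise ValueError(f"points out of range [0, {MAX_POINTS}]: {self.points}")
        if self.group != min(self.points, GROUP_CAP):
            raise ValueError("group must equal min(points, 14)")

    @property
    def group_label(self) -> str:
        return "14+" if self.group == GROUP_CAP else str(self.group)


def age_points(age_years: int) -> int:
    """Points for the age band containing ``age_years`` (>= 50)."""
    if age_years < 50:
        raise ValueError(f"age_years must be >= 50, got {age_years}")
    for lo, hi, pts in AGE_BANDS:
        if lo <= age_years <= hi:
            return pts
    raise ValueError(f"age_years out of supported range: {age_years}")


def score_profile(profile: RiskFactorProfile) -> PointScore:
    """Sum the 12 item points and assign the risk group (capped at 14+)."""
    pts = age_points(profile.age_years)
    for item, weight in ITEM_POINTS.items():
        if getattr(profile, item):
            pts += weight
    return PointScore(points=pts, group=min(pts, GROUP_CAP))


_ITEM_COLUMNS = ("age_years",) + tuple(ITEM_POINTS)


def score_table(
    frame: pd.DataFrame,
    column_map: dict[str, str] | None = None,
    missing: str = "error",
) -> pd.DataFrame:
    """Score every row of a risk-factor table.

    Parameters
    ----------
    frame
        One row per person.  Expected columns are ``age_years`` plus the
        eleven item names (see :data:`~gompertzle.published.ITEM_POINTS`);
        a numeric ``bmi`` column may replace ``bmi_under_25``.
    column_map
        Optional mapping from the expected names to the names actually
        present in ``frame``.
    missing
        ``"error"`` (default) rejects missing values; ``"absent"`` treats
        a missing item answer as "no" and warns.  Age itself is always
        required.

    Returns
    -------
    A copy of ``frame`` with ``points`` and ``group`` columns appended.
    """
    if missing not in ("error", "absent"):
        raise ValueError("missing must be 'error' or 'absent'")
    colmap = {c: c for c in _ITEM_COLUMNS}
    colmap.update(column_map or {})

    df = frame.copy()
    bmi_col = (column_map or {}).get("bmi", "bmi")
    if colmap["bmi_under_25"] not in df.columns and bmi_col in df.columns:
        df[colmap["bmi_under_25"]] = df[bmi_col] < 25.0

    for canonical in _ITEM_COLUMNS:
        col = colmap[canonical]
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} (item {canonical!r})")
        n_missing = int(df[col].isna().sum())
        if n_missing and canonical == "age_years":
            raise ValueError(f"{n_missing} rows have missing age")
        if n_missing:
            if missing == "error":
                raise ValueError(
                    f"{n_missing} rows have missing values in {col!r}; pass "
                    "missing='absent' to treat them as item absent"
                )
            warnings.warn(
                f"treating {n_missing} missing values in {col!r} as item absent",
                stacklevel=2,
            )
            df[col] = df[col].map(lambda v: False if pd.isna(v) else bool(v))

    pts = df[colmap["age_years"]].astype(int).map(age_points)
    for item, weight in ITEM_POINTS.items():
        pts = pts + df[colmap[item]].astype(bool).astype(int) * weight
    out = frame.copy()
    out["points"] = pts.astype(int)
    out["group"] = out["points"].clip(upper=GROUP_CAP)
    return out
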