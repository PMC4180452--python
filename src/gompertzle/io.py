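"""Reading and writing the package's delimited file formats.

Cohort files are comma-separated with a header (columns ``id``, ``group``
or ``points``, ``time_years``, ``event``); quantile tables have columns
``group, t25, t50[, t75]``.  Writers prepend ``#``-comment metadata lines
(version, seed, configuration hash) that readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .published import GROUP_CAP

__all__ = ["read_cohort", "write_table", "read_quantile_table",
           "read_fit", "write_fit"]


def _metadata_lines(meta: dict | None) -> str:
    from . import __version__
    meta = dict(meta or {})
    meta.setdefault("version", __version__)
    body = json.dumps({k: v for k, v in meta.items() if k != "confighash"},
                      sort_keys=True, default=str)
    meta.setdefault("confighash", hashlib.sha256(body.encode()).hexdigest()[:12])
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a delimited table with a commented metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_metadata_lines(meta))
        frame.to_csv(fh, index=False)


def read_cohort(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a cohort file into the standard frame (group, time_years, event).

    A ``points`` column is accepted in place of ``group`` and capped at the
    top group.  ``column_map`` maps standard names to the file's names.
    """
    colmap = {k: k for k in ("id", "group", "points", "time_years", "event")}
    colmap.update(column_map or {})
    df = pd.read_csv(path, comment="#")
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    if "group" not in df.columns:
        if "points" not in df.columns:
            raise ValueError(f"{path}: need a 'group' or 'points' column")
        df["group"] = df["points"].astype(int).clip(upper=GROUP_CAP)
    for col in ("time_years", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df["event"] = df["event"].astype(bool)
    if "id" not in df.columns:
        df["id"] = range(len(df))
    return df[["id", "group", "time_years", "event"]]


def read_quantile_table(path) -> pd.DataFrame:
    """Read a published-quantile table (group, t25, t50[, t75])."""
    df = pd.read_csv(path, comment="#")
    need = {"group", "t25", "t50"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: quantile table needs columns {sorted(need)}")
    return df


def write_fit(fit, path, meta: dict | None = None) -> None:
    from .gompertz_survival import GompertzFit  # noqa: F401 (documented return type)
    doc = {"meta": json.loads(_metadata_to_json(meta)), "fit": fit.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=2))


def _metadata_to_json(meta: dict | None) -> str:
    from . import __version__
    meta = dict(meta or {})
    meta.setdefault("version", __version__)
    return json.dumps(meta, sort_keys=True, default=str)


def read_fit(path):
    from .gompertz_survival import GompertzFit
    doc = json.loads(Path(path).read_text())
    return GompertzFit.from_dict(doc["fit"] if "fit" in doc else doc)
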