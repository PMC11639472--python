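"""Packaged datasets and plain-text sample I/O.

Three published healthcare samples ship verbatim as single-column CSV files:

* ``bladder_cancer`` — remission durations (months) of 128 bladder-cancer
  patients;
* ``pakistan_covid_cases`` — daily confirmed COVID-19 cases in Pakistan over
  36 days (March-April 2020);
* ``who_covid_deaths`` — 104 country-level COVID-19 death counts reported to
  the WHO for 26 October 2021.

Two simulation reference tables also ship as CSV: the published Monte-Carlo
mean/RBias/MSE grid (six scenarios x ten sample sizes x four estimators) and
the published per-cell method ranks.  Note: the published rank table is not
fully consistent with the published MSE grid (it contains ties where the MSE
values differ and one row whose ranks sum to 9); both are shipped verbatim.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .distribution import ObservationSet

__all__ = [
    "available_fixtures",
    "load_fixture",
    "load_simulation_table",
    "load_printed_ranks",
    "read_sample",
    "write_report",
]

_FIXTURES = ("bladder_cancer", "pakistan_covid_cases", "who_covid_deaths")


def _data_path(name: str):
    return resources.files("nefr.data").joinpath(name)


def available_fixtures() -> tuple[str, ...]:
    return _FIXTURES


def load_fixture(name: str) -> ObservationSet:
    """Load one of the packaged samples by name, in published order."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}"
        )
    with resources.as_file(_data_path(f"{name}.csv")) as path:
        return read_sample(path, label=name)


def load_simulation_table() -> pd.DataFrame:
    """Published Monte-Carlo summaries, tidy: one row per
    (scenario, n, method, param) with columns mean, rbias, mse."""
    with resources.as_file(_data_path("simulation_tables.csv")) as path:
        return pd.read_csv(path)


def load_printed_ranks() -> pd.DataFrame:
    """Published per-(scenario, n) method ranks with columns mle/lse/wlse/ade."""
    with resources.as_file(_data_path("rank_table.csv")) as path:
        return pd.read_csv(path)


def read_sample(
    path,
    column: Optional[str | int] = None,
    delimiter: Optional[str] = None,
    label: str = "",
) -> ObservationSet:
    """Read a sample of positive durations from a CSV/plain-text file.

    A single header line is auto-detected (first field not parseable as a
    number).  Non-numeric or nonpositive entries raise with the offending
    row index.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter or ","))
    rows = [r for r in rows if r and any(f.strip() for f in r)]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    header = None
    first = rows[0]
    try:
        float(first[0])
    except ValueError:
        header = [f.strip() for f in first]
        rows = rows[1:]
    if isinstance(column, str):
        if header is None or column not in header:
            raise ValueError(f"{path}: column {column!r} not found (header: {header})")
        ci = header.index(column)
    else:
        ci = int(column or 0)
    values = []
    for ri, row in enumerate(rows, start=2 if header else 1):
        field_ = row[ci].strip()
        try:
            v = float(field_)
        except ValueError:
            raise ValueError(f"{path}: non-numeric entry {field_!r} at row {ri}") from None
        if not v > 0:
            raise ValueError(f"{path}: nonpositive duration {v} at row {ri}")
        values.append(v)
    return ObservationSet(np.asarray(values), label or path.stem)


def write_sample(data: ObservationSet, path) -> None:
    """Write a sample as single-column CSV with a `value` header."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["value"])
        for v in data.values:
            w.writerow([repr(float(v))])


def write_report(report, path, format: str = "json", sig: Optional[int] = 6) -> None:
    """Serialize a dataclass report (FitResult, GofReport, ...) to JSON or CSV.

    Keys keep the dataclass field order; numbers are rounded to ``sig``
    significant digits unless ``sig`` is None.
    """
    d = _to_plain_dict(report, sig)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(d.keys())
            w.writerow(d.values())
    else:
        raise ValueError(f"unknown format {format!r}")


def _round_sig(x: float, sig: Optional[int]):
    if sig is None or x == 0 or not np.isfinite(x):
        return x
    return float(f"%.{sig}g" % x)


def _to_plain_dict(obj, sig) -> dict:
    import dataclasses

    if not dataclasses.is_dataclass(obj):
        raise TypeError(f"expected a dataclass report, got {type(obj)}")
    out: dict = {}
    for f in dataclasses.fields(obj):
        if f.name.startswith("_"):
            continue
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            for k2, v2 in _to_plain_dict(v, sig).items():
                out[f"{f.name}_{k2}"] = v2
        elif isinstance(v, (tuple, list, np.ndarray)):
            out[f.name] = [_round_sig(float(x), sig) for x in v]
        elif isinstance(v, (float, np.floating)):
            out[f.name] = _round_sig(float(v), sig)
        else:
            out[f.name] = v
    return out
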