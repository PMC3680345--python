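"""File readers/writers and plain-text model serialization.

Patient and arrival files are delimited text (CSV) with ISO-8601 dates;
internally days are 0-based integers from the series start date.  Fitted
models round-trip through YAML key-value documents so the CLI can reuse
them across invocations.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .arrivals import HarmonicSpec, PARFit
from .data_model import PatientRecord
from .departures import DepartureModel, DepartureModelSet, StratumSpec

__all__ = [
    "ParseError",
    "read_patient_file",
    "write_patient_file",
    "read_arrival_file",
    "write_arrival_file",
    "save_par_fit",
    "load_par_fit",
    "save_departure_models",
    "load_departure_models",
    "write_forecast_file",
]

PATIENT_COLUMNS = [
    "patient_id", "admit_date", "los_days", "censored",
    "bweight", "gestage", "snapdol1", "main1", "snapdol3", "main7",
]


class ParseError(ValueError):
    """Schema violation in an input file; carries offending line numbers."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        preview = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        super().__init__(f"{path}: {preview}{more}")


def _day_of(date_str: str, start: dt.date) -> int:
    return (dt.date.fromisoformat(str(date_str)) - start).days


def read_patient_file(
    path, start_date: Optional[dt.date] = None
) -> tuple[list[PatientRecord], dt.date]:
    """Read patient records, validating the schema row by row.

    Returns the records and the calendar start date mapping day 0.
    Violations (los < 1, scores present though the stay never reaches their
    availability day, bad dates) are collected and raised together with
    their line numbers.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = set(PATIENT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(path, [f"missing columns {sorted(missing_cols)}"])
    if start_date is None:
        start_date = min(
            dt.date.fromisoformat(str(d)) for d in df["admit_date"]
        )
    records: list[PatientRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            admit = _day_of(row["admit_date"], start_date)
            cens = int(row["censored"])
            los_days = int(row["los_days"])
            kwargs = dict(
                patient_id=str(row["patient_id"]),
                admit_day=admit,
                los=None if cens else los_days,
                censored_at=los_days if cens else None,
            )
            for c in ("bweight", "gestage", "snapdol1", "main1", "snapdol3", "main7"):
                v = row[c]
                kwargs[c] = None if pd.isna(v) else float(v)
            records.append(PatientRecord(**kwargs))
        except (ValueError, KeyError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ParseError(path, problems)
    return records, start_date


def write_patient_file(
    records: Sequence[PatientRecord], path, start_date: dt.date
) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "admit_date": (start_date + dt.timedelta(days=r.admit_day)).isoformat(),
                "los_days": r.los if r.los is not None else r.censored_at,
                "censored": int(r.is_censored),
                "bweight": r.bweight,
                "gestage": r.gestage,
                "snapdol1": r.snapdol1,
                "main1": r.main1,
                "snapdol3": r.snapdol3,
                "main7": r.main7,
            }
        )
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)


def read_arrival_file(path) -> tuple[np.ndarray, dt.date]:
    """Daily arrival counts; the file must be gap-free and daily."""
    df = pd.read_csv(path)
    problems = []
    if not {"date", "count"} <= set(df.columns):
        raise ParseError(path, ["columns must be date,count"])
    dates = [dt.date.fromisoformat(str(d)) for d in df["date"]]
    start = dates[0]
    for i, (d, c) in enumerate(zip(dates, df["count"])):
        line = i + 2
        if (d - start).days != i:
            problems.append(f"line {line}: date {d} breaks the daily sequence")
        if not float(c).is_integer() or c < 0:
            problems.append(f"line {line}: count {c} not a nonnegative integer")
    if problems:
        raise ParseError(path, problems)
    return df["count"].to_numpy(int), start


def write_arrival_file(series: Sequence[int], path, start_date: dt.date) -> None:
    dates = [
        (start_date + dt.timedelta(days=i)).isoformat() for i in range(len(series))
    ]
    pd.DataFrame({"date": dates, "count": list(series)}).to_csv(path, index=False)


# --------------------------------------------------------------------- #
# model serialization

def save_par_fit(fit: PARFit, path) -> None:
    doc = {
        "model": "seasonal_par",
        "order": fit.order,
        "intercept": float(fit.intercept),
        "ar_coefs": [float(v) for v in fit.ar_coefs],
        "cos_coefs": [float(v) for v in fit.cos_coefs],
        "sin_coefs": [float(v) for v in fit.sin_coefs],
        "param_cov": fit.param_cov.tolist(),
        "log_lik": float(fit.log_lik),
        "bic": float(fit.bic),
        "n_effective": int(fit.n_effective),
        "harmonic": {
            "n_harmonics": fit.harmonic.n_harmonics,
            "frequencies": [float(f) for f in fit.harmonic.frequencies],
            "series_length": fit.harmonic.series_length,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_par_fit(path) -> PARFit:
    doc = yaml.safe_load(Path(path).read_text())
    harm = doc["harmonic"]
    return PARFit(
        order=doc["order"],
        intercept=doc["intercept"],
        ar_coefs=tuple(doc["ar_coefs"]),
        cos_coefs=tuple(doc["cos_coefs"]),
        sin_coefs=tuple(doc["sin_coefs"]),
        param_cov=np.array(doc["param_cov"], float),
        log_lik=doc["log_lik"],
        bic=doc["bic"],
        harmonic=HarmonicSpec(
            harm["n_harmonics"], tuple(harm["frequencies"]), harm["series_length"]
        ),
        n_effective=doc["n_effective"],
    )


def save_departure_models(model_set: DepartureModelSet, path) -> None:
    blocks = []
    for (k, st), m in sorted(model_set.models.items()):
        blocks.append(
            {
                "horizon": k,
                "stratum": st,
                "covariate_names": list(m.covariate_names),
                "coef": m.coef.tolist(),
                "cov": m.cov.tolist(),
                "x_mean": m.x_mean.tolist(),
                "x_scale": m.x_scale.tolist(),
                "n": m.n,
                "n_events": m.n_events,
                "ridge": m.ridge,
                "fallback": m.fallback,
                "link": m.link,
            }
        )
    doc = {
        "model": "stratified_departure_logistic",
        "max_stratum": model_set.spec.max_stratum,
        "horizons": list(model_set.horizons),
        "cutoff_day": model_set.cutoff_day,
        "blocks": blocks,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_departure_models(path) -> DepartureModelSet:
    doc = yaml.safe_load(Path(path).read_text())
    models = {}
    for b in doc["blocks"]:
        key = (int(b["horizon"]), int(b["stratum"]))
        models[key] = DepartureModel(
            k=key[0],
            stratum=key[1],
            covariate_names=tuple(b["covariate_names"]),
            coef=np.array(b["coef"], float),
            cov=np.array(b["cov"], float),
            x_mean=np.array(b["x_mean"], float),
            x_scale=np.array(b["x_scale"], float),
            n=b["n"],
            n_events=b["n_events"],
            ridge=b["ridge"],
            fallback=b["fallback"],
            link=b["link"],
        )
    return DepartureModelSet(
        models=models,
        spec=StratumSpec(doc["max_stratum"]),
        horizons=tuple(doc["horizons"]),
        cutoff_day=doc["cutoff_day"],
    )


def write_forecast_file(result, path, start_date: Optional[dt.date] = None) -> None:
    """One row per horizon: point, interval, ensemble size, seed."""
    rows = []
    for k in result.horizons:
        rows.append(
            {
                "origin_day": result.origin,
                "origin_date": (
                    (start_date + dt.timedelta(days=int(result.origin))).isoformat()
                    if start_date
                    else ""
                ),
                "horizon": k,
                "point": result.point[k],
                "lo": result.lo[k],
                "hi": result.hi[k],
                "n_realizations": len(result.realizations[k]),
                "seed": result.seed,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
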