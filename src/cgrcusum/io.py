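"""File formats, configuration and fixture registry.

Subject CSV dialect: header ``hospital_id, subject_id, entry_time,
followup_time, event`` followed by any number of covariate columns (detected
by position after ``event``).  Times are float days from the study start,
UTF-8, period decimal separator.  Chart paths and study results are written
as tidy CSV with a fixed column order so that a read of a write round-trips.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .charts import ChartPath
from .model import (
    ExponentialBaseline,
    HospitalData,
    RiskModel,
    StepBaseline,
    SubjectRecord,
    WeibullBaseline,
)

__all__ = [
    "read_subjects",
    "write_subjects",
    "read_model",
    "write_model",
    "read_chart",
    "write_chart",
    "write_results",
    "read_results",
    "RunManifest",
    "fixture_generator",
    "FIXTURES",
]

SUBJECT_COLUMNS = ["hospital_id", "subject_id", "entry_time", "followup_time", "event"]
RESULT_COLUMNS = ["chart", "theta", "arl", "sd", "mrl", "n", "censored"]


def read_subjects(path) -> list[HospitalData]:
    """Read the subject CSV into per-hospital records sorted by entry time."""
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject file {path} is missing columns {missing}")
    cov_cols = list(df.columns[df.columns.get_loc("event") + 1:])
    hospitals = []
    for hid, grp in df.groupby("hospital_id", sort=True):
        subjects = []
        for idx, row in grp.iterrows():
            ev = row["event"]
            if ev not in (0, 1, True, False):
                raise ValueError(f"row {idx}: event must be 0/1, got {ev!r}")
            if row["entry_time"] < 0 or row["followup_time"] <= 0:
                raise ValueError(
                    f"row {idx}: needs entry_time >= 0 and followup_time > 0"
                )
            subjects.append(SubjectRecord(
                id=str(row["subject_id"]),
                entry_time=float(row["entry_time"]),
                followup_time=float(row["followup_time"]),
                event=bool(ev),
                covariates=tuple(float(row[c]) for c in cov_cols),
            ))
        horizon = max(s.exit_time for s in subjects)
        hospitals.append(HospitalData(hospital_id=str(hid), subjects=subjects,
                                      horizon=horizon))
    return hospitals


def write_subjects(path, hospitals: list[HospitalData]) -> None:
    rows = []
    for h in hospitals:
        for s in h.subjects:
            row = {"hospital_id": h.hospital_id, "subject_id": s.id,
                   "entry_time": s.entry_time, "followup_time": s.followup_time,
                   "event": int(s.event)}
            for j, z in enumerate(s.covariates):
                row[f"z{j}"] = z
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Risk-model serialization (YAML)
# ---------------------------------------------------------------------------


def model_to_dict(model: RiskModel) -> dict:
    b = model.baseline
    if isinstance(b, ExponentialBaseline):
        baseline = {"family": "exponential", "rate": float(b.rate)}
    elif isinstance(b, WeibullBaseline):
        baseline = {"family": "weibull", "shape": float(b.shape), "scale": float(b.scale)}
    elif isinstance(b, StepBaseline):
        baseline = {"family": "step", "knots": [float(k) for k in b.knots],
                    "values": [float(v) for v in b.values]}
    else:
        raise TypeError(f"unknown baseline {type(b)}")
    return {"baseline": baseline, "coefficients": [float(c) for c in model.coefficients]}


def model_from_dict(cfg: dict) -> RiskModel:
    b = cfg["baseline"]
    family = b["family"]
    if family == "exponential":
        baseline = ExponentialBaseline(rate=float(b["rate"]))
    elif family == "weibull":
        baseline = WeibullBaseline(shape=float(b["shape"]), scale=float(b["scale"]))
    elif family == "step":
        baseline = StepBaseline(knots=tuple(b["knots"]), values=tuple(b["values"]))
    else:
        raise ValueError(f"unknown baseline family {family!r}")
    return RiskModel(baseline=baseline, coefficients=tuple(cfg.get("coefficients", ())))


def write_model(path, model: RiskModel) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def read_model(path) -> RiskModel:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Chart paths and study results
# ---------------------------------------------------------------------------


def write_chart(path, chart: ChartPath, h: float | None = None) -> None:
    """Tidy chart CSV: time, value, signal (0/1 once the limit is reached)."""
    if np.any(~np.isfinite(chart.values)):
        raise ValueError("chart contains non-finite values")
    signal = np.zeros(chart.times.size, dtype=int)
    if h is not None:
        signal[chart.values >= h] = 1
    elif chart.signal_time is not None:
        signal[chart.times >= chart.signal_time] = 1
    pd.DataFrame({"time": chart.times, "value": chart.values,
                  "signal": signal}).to_csv(path, index=False)


def read_chart(path) -> ChartPath:
    df = pd.read_csv(path)
    sig = df.loc[df["signal"] > 0, "time"]
    return ChartPath(df["time"].to_numpy(), df["value"].to_numpy(),
                     float(sig.iloc[0]) if len(sig) else None)


def write_results(path, table: pd.DataFrame) -> None:
    """Study results CSV with the fixed schema {chart, theta, arl, sd, mrl, n, censored}."""
    df = table.copy()
    if "hazard_ratio" in df.columns and "theta" not in df.columns:
        df["theta"] = np.log(df["hazard_ratio"].astype(float))
        df = df.drop(columns=["hazard_ratio"])
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table is missing columns {missing}")
    df[RESULT_COLUMNS].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to reproduce a stochastic command bit-for-bit."""

    tool: str = "cgrcusum"
    version: str = "0.1.0"
    command: str = ""
    seed: int | None = None
    parameters: dict = field(default_factory=dict)
    config_hash: str | None = None
    timestamp: str = ""

    @staticmethod
    def for_command(command: str, seed: int | None, parameters: dict,
                    config_text: str | None = None) -> "RunManifest":
        cfg_hash = (hashlib.sha256(config_text.encode()).hexdigest()
                    if config_text is not None else None)
        return RunManifest(command=command, seed=seed, parameters=parameters,
                           config_hash=cfg_hash,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Bundled micro-fixtures
# ---------------------------------------------------------------------------


def _single_failure():
    """One subject entering at 0 and failing at day 10 on a rate-0.01 baseline.

    CGI(10) = ln(10) - 9 * 0.1 = 1.402585... (N = 1, Lambda = 0.1).
    """
    model = RiskModel(ExponentialBaseline(rate=0.01))
    hosp = HospitalData("single_failure", [
        SubjectRecord("s1", entry_time=0.0, followup_time=10.0, event=True),
    ], horizon=10.0)
    return {"model": model, "hospitals": [hosp]}


def _two_subject_cgr():
    """Two subjects entering at 0; the censored one drags CGI but not CGR.

    At t* = 50: subject 1 censored with Lambda1 = 0.5, subject 2 fails with
    Lambda2 = 0.1, so the best suffix starts at subject 2 and
    CGR(50) = ln(10) - 0.9 = 1.402585 while CGI(50) ~ 0.11.
    """
    model = RiskModel(ExponentialBaseline(rate=0.01))
    hosp = HospitalData("two_subject_cgr", [
        SubjectRecord("s1", entry_time=0.0, followup_time=50.0, event=False),
        SubjectRecord("s2", entry_time=0.0, followup_time=10.0, event=True,),
    ], horizon=50.0)
    return {"model": model, "hospitals": [hosp]}


def _table1_design():
    """The simulation design of the main run-length comparison study.

    Poisson arrivals psi = 2.28/day (a large center), exponential baseline
    rate 0.002/day (about half the subjects fail within a year), no
    risk adjustment; charts BK(exp(theta1)=1.4, h=6.82),
    BK(exp(theta1)=1.8, h=8.35) and CGR/CGI (h=7.73), all with in-control
    ARL calibrated to about 15 years.
    """
    return {
        "psi": 2.28,
        "model": RiskModel(ExponentialBaseline(rate=0.002)),
        "charts": {
            "bk_14": {"theta1": float(np.log(1.4)), "h": 6.82},
            "bk_18": {"theta1": float(np.log(1.8)), "h": 8.35},
            "cgr": {"h": 7.73},
        },
    }


FIXTURES = {
    "single_failure": _single_failure,
    "two_subject_cgr": _two_subject_cgr,
    "table1_design": _table1_design,
}


def fixture_generator(name: str):
    """Return one of the bundled micro-fixtures used in tests and docs."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
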