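"""Dataset format and serialization.

The on-disk cohort format is a pharmacometric-style long CSV with the exact
header ``ID,TIME,EVID,TYPE,DV``: one row per session event (EVID=1, TYPE
one of coaching/therapy/psychiatry, DV empty) or severity observation
(EVID=0, TYPE ``dsm_l1``, DV in [0,1]).  Within a patient, rows are stably
sorted by TIME with events before observations at equal times — a same-day
session influences only later observations — except that the baseline
observation at time 0 precedes any time-0 session to anchor the record.

Fit results and plan metrics serialize to JSON with all floats rendered at
12 significant digits, so identical inputs and seeds reproduce artifacts
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import (FitResult, IndividualParameters, PatientFit,
                         PopulationParameters)
from .model import (PatientRecord, ServiceType, SessionEvent,
                    SeverityObservation, StructuralParameters,
                    ValidationError)

__all__ = [
    "DATASET_COLUMNS",
    "DatasetError",
    "ReadReport",
    "read_dataset",
    "write_dataset",
    "fit_result_to_dict",
    "fit_result_from_dict",
    "save_fit_result",
    "load_fit_result",
    "dump_json",
    "round_floats",
]

DATASET_COLUMNS = ["ID", "TIME", "EVID", "TYPE", "DV"]
SCHEMA_VERSION = "1.0"

_EVENT_TYPES = {m.value for m in ServiceType}


class DatasetError(ValidationError):
    """Aggregated row-level validation failure."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:20])
        more = "" if len(self.errors) <= 20 else f"\n  ... {len(self.errors) - 20} more"
        super().__init__(f"{len(self.errors)} invalid dataset row(s):\n  {preview}{more}")


@dataclass
class ReadReport:
    """Validation summary produced alongside parsed records."""

    n_rows: int
    n_patients: int
    eligible_ids: list[str]
    ineligible_ids: list[str]


def _row_sort_key(time: float, evid: int) -> tuple:
    # events before observations at equal TIME; the time-0 observation is
    # the documented exception (baseline anchor precedes any day-0 session)
    if evid == 0 and time == 0.0:
        return (time, 0)
    return (time, 1 if evid == 1 else 2)


def read_dataset(path) -> tuple[list[PatientRecord], ReadReport]:
    """Read a cohort CSV, validating every row.

    Returns all patients (ineligible ones retained and flagged in the
    report) or raises :class:`DatasetError` listing every bad row by its
    1-based data row number.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise DatasetError([f"unreadable dataset: {exc}"]) from exc
    if list(df.columns) != DATASET_COLUMNS:
        raise DatasetError(
            [f"header must be exactly {','.join(DATASET_COLUMNS)}, "
             f"got {','.join(map(str, df.columns))}"])
    errors: list[str] = []
    rows = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        pid, time_s, evid_s, typ, dv_s = (row.ID.strip(), row.TIME.strip(),
                                          row.EVID.strip(), row.TYPE.strip(),
                                          row.DV.strip())
        if not pid:
            errors.append(f"row {idx}: empty ID")
            continue
        try:
            time = float(time_s)
        except ValueError:
            errors.append(f"row {idx}: TIME {time_s!r} is not a number")
            continue
        if not np.isfinite(time) or time < 0:
            errors.append(f"row {idx}: TIME must be finite and >= 0, got {time}")
            continue
        if evid_s not in ("0", "1"):
            errors.append(f"row {idx}: EVID must be 0 or 1, got {evid_s!r}")
            continue
        evid = int(evid_s)
        if evid == 1:
            if typ not in _EVENT_TYPES:
                errors.append(f"row {idx}: TYPE for EVID=1 must be one of "
                              f"{sorted(_EVENT_TYPES)}, got {typ!r}")
                continue
            if dv_s:
                errors.append(f"row {idx}: DV must be empty for EVID=1, got {dv_s!r}")
                continue
            rows.append((pid, time, evid, typ, None))
        else:
            if typ != "dsm_l1":
                errors.append(f"row {idx}: TYPE for EVID=0 must be 'dsm_l1', got {typ!r}")
                continue
            if not dv_s:
                errors.append(f"row {idx}: DV is required for EVID=0")
                continue
            try:
                dv = float(dv_s)
            except ValueError:
                errors.append(f"row {idx}: DV {dv_s!r} is not a number")
                continue
            if not (0.0 <= dv <= 1.0):
                errors.append(f"row {idx}: DV must lie in [0,1], got {dv}")
                continue
            rows.append((pid, time, evid, typ, dv))
    if errors:
        raise DatasetError(errors)

    by_id: dict[str, list] = {}
    for r in rows:
        by_id.setdefault(r[0], []).append(r)
    records = []
    for pid in by_id:
        prows = sorted(by_id[pid], key=lambda r: _row_sort_key(r[1], r[2]))
        events = [SessionEvent(t, ServiceType(typ))
                  for _, t, evid, typ, _ in prows if evid == 1]
        obs = [SeverityObservation(t, dv)
               for _, t, evid, _, dv in prows if evid == 0]
        records.append(PatientRecord(pid, sorted(events, key=lambda e: e.time),
                                     sorted(obs, key=lambda o: o.time)))
    report = ReadReport(
        n_rows=len(rows), n_patients=len(records),
        eligible_ids=[r.id for r in records if r.is_inclusion_eligible],
        ineligible_ids=[r.id for r in records if not r.is_inclusion_eligible])
    return records, report


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_dataset(records, path) -> None:
    """Write a cohort to the long CSV format (12-significant-digit floats)."""
    lines = [",".join(DATASET_COLUMNS)]
    for rec in records:
        rows = ([(o.time, 0, "dsm_l1", _fmt(o.severity)) for o in rec.observations]
                + [(e.time, 1, e.service.value, "") for e in rec.events])
        rows.sort(key=lambda r: _row_sort_key(r[0], r[1]))
        for t, evid, typ, dv in rows:
            lines.append(f"{rec.id},{_fmt(t)},{evid},{typ},{dv}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def round_floats(obj, sig: int = 12):
    """Recursively round floats to ``sig`` significant digits for stable JSON."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return round_floats(obj.tolist(), sig)
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def dump_json(obj, path) -> None:
    """Serialize to JSON with deterministic float formatting and key order."""
    with open(path, "w") as fh:
        json.dump(round_floats(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": fit.seed,
        "config": fit.config,
        "population": fit.population.to_dict(),
        "patients": [
            {"id": pf.patient_id,
             "eta": pf.individual.eta.tolist(),
             "realized": pf.individual.realized.to_dict(),
             "obs_times": pf.obs_times.tolist(),
             "observed": pf.observed.tolist(),
             "ipred": pf.ipred.tolist(),
             "ppred": pf.ppred.tolist(),
             "residuals": pf.residuals.tolist(),
             "eligible": pf.eligible}
            for pf in fit.patients],
        "trace": {k: np.asarray(v).tolist() for k, v in fit.trace.items()},
    }


def fit_result_from_dict(d: dict) -> FitResult:
    pop = PopulationParameters.from_dict(d["population"])
    patients = []
    for p in d["patients"]:
        indiv = IndividualParameters(
            eta=np.asarray(p["eta"], dtype=np.float64),
            realized=StructuralParameters.from_dict(p["realized"]))
        patients.append(PatientFit(
            patient_id=p["id"], individual=indiv,
            obs_times=np.asarray(p["obs_times"]),
            observed=np.asarray(p["observed"]),
            ipred=np.asarray(p["ipred"]),
            ppred=np.asarray(p["ppred"]),
            residuals=np.asarray(p["residuals"]),
            eligible=bool(p.get("eligible", True))))
    trace = {k: np.asarray(v) for k, v in d.get("trace", {}).items()}
    return FitResult(population=pop, patients=patients, trace=trace,
                     config=d.get("config", {}), seed=int(d.get("seed", 0)))


def save_fit_result(fit: FitResult, path) -> None:
    dump_json(fit_result_to_dict(fit), path)


def load_fit_result(path) -> FitResult:
    with open(path) as fh:
        return fit_result_from_dict(json.load(fh))
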