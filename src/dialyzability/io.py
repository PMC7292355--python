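"""CSV/JSON round-tripping for session, removal and concentration records."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .metrics import DialysisSession, RemovalMeasurement
from .nca import ConcentrationTimeSeries

SESSION_COLUMNS = [
    "subject_id", "bun_pre_mg_dl", "bun_post_mg_dl", "duration_h",
    "ufv", "bw", "unit_system",
]
REMOVAL_COLUMNS = [
    "drug", "dialysate_conc_mg_ml", "dialysate_volume_ml", "dose_mg", "duration_h",
]


def read_sessions(path: str | Path) -> list[tuple[str, DialysisSession | Exception]]:
    """Parse a session CSV; malformed rows come back as the exception raised.

    Returns (subject_id, session-or-error) per row so callers can report
    bad lines and keep going.
    """
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV missing columns: {sorted(missing)}")
    out: list[tuple[str, DialysisSession | Exception]] = []
    for row in df.itertuples(index=False):
        sid = str(row.subject_id)
        try:
            out.append(
                (sid, DialysisSession(
                    bun_pre=float(row.bun_pre_mg_dl),
                    bun_post=float(row.bun_post_mg_dl),
                    duration=float(row.duration_h),
                    ultrafiltration_volume=float(row.ufv),
                    body_weight_post=float(row.bw),
                    unit_system=str(row.unit_system),
                ))
            )
        except (ValueError, TypeError) as exc:
            out.append((sid, exc))
    return out


def read_removals(path: str | Path) -> list[tuple[str, RemovalMeasurement | Exception]]:
    df = pd.read_csv(path)
    missing = set(REMOVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"removal CSV missing columns: {sorted(missing)}")
    out: list[tuple[str, RemovalMeasurement | Exception]] = []
    for row in df.itertuples(index=False):
        name = str(row.drug)
        try:
            out.append(
                (name, RemovalMeasurement(
                    dialysate_concentration=float(row.dialysate_conc_mg_ml),
                    dialysate_volume=float(row.dialysate_volume_ml),
                    dose=float(row.dose_mg),
                    session_duration=float(row.duration_h),
                ))
            )
        except (ValueError, TypeError) as exc:
            out.append((name, exc))
    return out


def read_concentration_series(
    path: str | Path,
    dose: float,
    infusion_duration: float = 0.0,
    body_weight: float = 1.0,
) -> ConcentrationTimeSeries:
    """Read a `time_h, conc_mg_l` CSV for one subject and drug."""
    df = pd.read_csv(path)
    for col in ("time_h", "conc_mg_l"):
        if col not in df.columns:
            raise ValueError(f"concentration CSV missing column {col!r}")
    return ConcentrationTimeSeries(
        times=df["time_h"].to_numpy(float),
        concentrations=df["conc_mg_l"].to_numpy(float),
        dose=dose,
        infusion_duration=infusion_duration,
        body_weight=body_weight,
    )


def write_records(records: Iterable, path: str | Path, fmt: str | None = None) -> None:
    """Write dataclass records as CSV or JSON (by extension or ``fmt``)."""
    path = Path(path)
    rows = [asdict(r) if not isinstance(r, dict) else r for r in records]
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        path.write_text(json.dumps(rows, indent=2, default=str) + "\n")
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
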