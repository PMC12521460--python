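"""CSV/JSON readers and writers for every pipeline artifact.

Dialect: comma-separated UTF-8 with a header row and '.' decimals.  All
formats round-trip (write then read yields an equal value).  Malformed rows
are reported with their 1-based line number (header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SessionKey, SMEventSet
from .efe import EFEFrameSeries, renormalize_rows
from .hr import HRSeries
from .intervals import Interval
from .questionnaires import QuestionnaireResponse, SCALE_ITEMS
from .report import ConvergenceReport, ObsEvent, ObservationTrack

DEFAULT_KEY = SessionKey(student_id="", session_id="")


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, cols: Sequence[str], path: Path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: non-numeric value {df[c][bad.idxmax()]!r} in column {c}, line {line}")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column {c}, line {line}")
        out[c] = vals
    return out


# ---------------------------------------------------------------------------
# Heart rate

def read_hr_csv(
    path: str | Path, key: SessionKey = DEFAULT_KEY, nominal_rate_hz: float = 1.0
) -> HRSeries:
    """Read time_s,bpm; masks implausible bpm and computes coverage."""
    df = _numeric(_read_csv(path, ["time_s", "bpm"]), ["time_s", "bpm"], Path(path))
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    return HRSeries.from_samples(key, df["time_s"].to_numpy(), df["bpm"].to_numpy(),
                                 nominal_rate_hz=nominal_rate_hz)


def write_hr_csv(series: HRSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.times, "bpm": series.bpm}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Facial-expression features

def read_efe_csv(path: str | Path, key: SessionKey = DEFAULT_KEY, fps: float = 1.0) -> EFEFrameSeries:
    """Read time_s,f1..fd; probability rows are renormalised, all-zero rows masked."""
    df = _read_csv(path, ["time_s"])
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not fcols:
        raise ValueError(f"{path}: no feature columns f1..fd found")
    fcols = sorted(fcols, key=lambda c: int(c[1:]))
    df = _numeric(df, ["time_s"] + fcols, Path(path))
    feats = df[fcols].to_numpy(dtype=float)
    feats, valid = renormalize_rows(feats)
    return EFEFrameSeries(
        key=key, frame_times=df["time_s"].to_numpy(dtype=float),
        features=feats, quality_mask=valid, fps=fps,
    )


def write_efe_csv(series: EFEFrameSeries, path: str | Path) -> None:
    cols = {"time_s": series.frame_times}
    for j in range(series.dim):
        cols[f"f{j + 1}"] = series.features[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Specific-moment event sets

def write_sm_csv(sms: SMEventSet | Sequence[SMEventSet], path: str | Path) -> None:
    sets = [sms] if isinstance(sms, SMEventSet) else list(sms)
    rows = []
    for s in sets:
        src = "|".join(str(t) for t in sorted(s.source_T))
        for a, b in s.intervals:
            rows.append({"start_s": a, "end_s": b, "modality": s.modality, "source_T": src})
    pd.DataFrame(rows, columns=["start_s", "end_s", "modality", "source_T"]).to_csv(path, index=False)


def read_sm_csv(path: str | Path, key: SessionKey = DEFAULT_KEY) -> List[SMEventSet]:
    """One event set per modality found in the file (empty file -> empty list)."""
    df = _read_csv(path, ["start_s", "end_s", "modality"])
    df = _numeric(df, ["start_s", "end_s"], Path(path))
    out = []
    for modality, grp in df.groupby("modality", sort=True):
        src: set = set()
        for v in grp.get("source_T", pd.Series(dtype=str)).dropna():
            src.update(int(x) for x in str(v).split("|") if x)
        intervals = list(zip(grp["start_s"], grp["end_s"]))
        for i, (a, b) in enumerate(intervals):
            if b <= a:
                raise ValueError(f"{path}: interval end <= start at line {int(grp.index[i]) + 2}")
        out.append(SMEventSet(key=key, modality=str(modality), intervals=intervals,
                              source_T=frozenset(src)))
    return out


# ---------------------------------------------------------------------------
# Observation tracks

def read_obs_csv(path: str | Path, key: SessionKey = DEFAULT_KEY) -> ObservationTrack:
    df = _read_csv(path, ["start_s", "end_s", "label", "salient"])
    df = _numeric(df, ["start_s", "end_s"], Path(path))
    events = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        if row["end_s"] <= row["start_s"]:
            raise ValueError(f"{path}: event end <= start at line {line}")
        sal = str(row["salient"]).strip().lower()
        if sal not in {"true", "false", "1", "0"}:
            raise ValueError(f"{path}: salient must be true/false at line {line}")
        events.append(ObsEvent(float(row["start_s"]), float(row["end_s"]),
                               label=str(row["label"]), salient=sal in {"true", "1"}))
    return ObservationTrack(key=key, events=events)


def write_obs_csv(track: ObservationTrack, path: str | Path) -> None:
    rows = [
        {"start_s": e.start_s, "end_s": e.end_s, "label": e.label, "salient": e.salient}
        for e in track.events
    ]
    pd.DataFrame(rows, columns=["start_s", "end_s", "label", "salient"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Questionnaires

def read_questionnaire_csv(path: str | Path, key: SessionKey = DEFAULT_KEY) -> List[QuestionnaireResponse]:
    """Read scale,item_index,value[,reverse] into one response per scale."""
    df = _read_csv(path, ["scale", "item_index", "value"])
    df = _numeric(df, ["item_index", "value"], Path(path))
    out = []
    for scale, grp in df.groupby("scale", sort=True):
        scale = str(scale)
        if scale not in SCALE_ITEMS:
            line = int(grp.index[0]) + 2
            raise ValueError(f"{path}: unknown scale {scale!r} at line {line}")
        grp = grp.sort_values("item_index")
        idx = grp["item_index"].astype(int).tolist()
        if idx != list(range(SCALE_ITEMS[scale])):
            raise ValueError(
                f"{path}: scale {scale} must have items 0..{SCALE_ITEMS[scale] - 1}, got {idx}"
            )
        reverse = None
        if "reverse" in grp.columns and grp["reverse"].notna().any():
            flags = grp["reverse"].astype(str).str.strip().str.lower()
            reverse = frozenset(i for i, f in zip(idx, flags) if f in {"true", "1"})
        out.append(QuestionnaireResponse(key=key, scale=scale,
                                         values=grp["value"].astype(int).tolist(),
                                         reverse_items=reverse))
    return out


def write_questionnaire_csv(responses: Sequence[QuestionnaireResponse], path: str | Path) -> None:
    rows = []
    for r in responses:
        for i, v in enumerate(r.values):
            rows.append({"scale": r.scale, "item_index": i, "value": int(v),
                         "reverse": i in r.reverse_items})
    pd.DataFrame(rows, columns=["scale", "item_index", "value", "reverse"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Coverage and reports

def write_coverage_csv(coverage: Sequence[Interval], path: str | Path) -> None:
    pd.DataFrame(coverage, columns=["start_s", "end_s"]).to_csv(path, index=False)


def read_coverage_csv(path: str | Path) -> List[Interval]:
    df = _numeric(_read_csv(path, ["start_s", "end_s"]), ["start_s", "end_s"], Path(path))
    return [(float(a), float(b)) for a, b in zip(df["start_s"], df["end_s"])]


def write_report_json(report: ConvergenceReport | Dict, path: str | Path) -> None:
    payload = report.as_dict() if isinstance(report, ConvergenceReport) else report
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report_json(path: str | Path) -> Dict:
    return json.loads(Path(path).read_text())
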