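"""Tabular file schemas (CSV, UTF-8, '.' decimal separator).

Three documented tables tie the pipeline stages together; every numeric
column name carries its unit.  Readers are header-keyed (column order is
irrelevant), validate the schema, and report the first offending row for
non-numeric values.  Round-trips are lossless to 15+ significant digits.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .stiffness import StiffnessPanel
from .synthetic import FlowCurveSet, PressureRecord, SubjectTruth

__all__ = [
    "SUBJECT_COLUMNS",
    "FLOW_COLUMNS",
    "PANEL_COLUMNS",
    "write_subjects",
    "read_subjects",
    "write_flow_curves",
    "read_flow_curves",
    "write_panels",
    "read_panels",
]

_FLOAT_FMT = "%.17g"

SUBJECT_COLUMNS = (
    "subject_id", "group",
    "true_pwv_4d_m_per_s", "true_cf_pwv_m_per_s",
    "true_distensibility_1e3_per_mmhg",
    "cf_pwv_m_per_s", "pwv_2d_m_per_s", "pwv_4d_m_per_s",
    "distensibility_1e3_per_mmhg",
    "central_sbp_mmhg", "central_dbp_mmhg", "pulse_pressure_mmhg",
    "heart_rate_bpm", "age_y", "lvmi_g_per_m2", "infarcted_segments_n",
)

FLOW_COLUMNS = ("plane_index", "arc_length_mm", "time_s", "flow_ml_s")

PANEL_COLUMNS = (
    "subject_id", "group",
    "cf_pwv_m_per_s", "pwv_2d_m_per_s", "pwv_4d_m_per_s",
    "distensibility_1e3_per_mmhg",
    "cf_pwv_source", "pwv_2d_source", "pwv_4d_source", "distensibility_source",
)

_STR_COLS = {"subject_id", "group", "cf_pwv_source", "pwv_2d_source",
             "pwv_4d_source", "distensibility_source"}


def _check_schema(df: pd.DataFrame, expected: tuple[str, ...], path) -> pd.DataFrame:
    missing = [c for c in expected if c not in df.columns]
    unexpected = [c for c in df.columns if c not in expected]
    if missing or unexpected:
        raise SchemaError(
            f"{path}: schema mismatch; missing columns {missing}, "
            f"unexpected columns {unexpected}")
    for col in expected:
        if col in _STR_COLS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}")
        df[col] = coerced
    return df[list(expected)]


def subjects_frame(subjects: list[SubjectTruth],
                   panels: list[StiffnessPanel] | None = None) -> pd.DataFrame:
    """One row per subject: ground truth, measured panel (drawn values when
    no estimated panels are given), pressures and covariates."""
    rows = []
    for i, s in enumerate(subjects):
        measured = panels[i].as_dict() if panels is not None else s.drawn
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group,
            "true_pwv_4d_m_per_s": s.true_pwv,
            "true_cf_pwv_m_per_s": s.true_cf_pwv,
            "true_distensibility_1e3_per_mmhg": s.true_distensibility,
            "cf_pwv_m_per_s": measured.get("cf_pwv"),
            "pwv_2d_m_per_s": measured.get("pwv_2d"),
            "pwv_4d_m_per_s": measured.get("pwv_4d"),
            "distensibility_1e3_per_mmhg": measured.get("distensibility"),
            "central_sbp_mmhg": s.pressure.central_sbp,
            "central_dbp_mmhg": s.pressure.central_dbp,
            "pulse_pressure_mmhg": s.pressure.pp,
            "heart_rate_bpm": s.heart_rate,
            "age_y": s.covariates.get("age"),
            "lvmi_g_per_m2": s.covariates.get("lvmi"),
            "infarcted_segments_n": s.covariates.get("infarcted_segments"),
        })
    return pd.DataFrame(rows, columns=list(SUBJECT_COLUMNS))


def write_subjects(subjects, path, panels=None) -> Path:
    path = Path(path)
    subjects_frame(subjects, panels).to_csv(path, index=False,
                                            float_format=_FLOAT_FMT)
    return path


def read_subjects(path) -> pd.DataFrame:
    return _check_schema(pd.read_csv(path, float_precision="round_trip"), SUBJECT_COLUMNS, path)


def write_flow_curves(curves: FlowCurveSet, path) -> Path:
    """Long-format flow table: one row per (plane, time) sample."""
    path = Path(path)
    n_p, n_t = curves.flow.shape
    df = pd.DataFrame({
        "plane_index": np.repeat(np.arange(n_p), n_t),
        "arc_length_mm": np.repeat(curves.plane_arc_lengths, n_t),
        "time_s": np.tile(curves.time_axis, n_p),
        "flow_ml_s": curves.flow.ravel(),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_flow_curves(path) -> FlowCurveSet:
    df = _check_schema(pd.read_csv(path, float_precision="round_trip"), FLOW_COLUMNS, path)
    planes = np.sort(df["plane_index"].unique()).astype(int)
    first = df[df["plane_index"] == planes[0]].sort_values("time_s")
    t = first["time_s"].to_numpy(float)
    arcs = np.empty(planes.size)
    flow = np.empty((planes.size, t.size))
    for k, p in enumerate(planes):
        sub = df[df["plane_index"] == p].sort_values("time_s")
        if len(sub) != t.size:
            raise SchemaError(f"{path}: plane {p} has {len(sub)} samples, "
                              f"expected {t.size}")
        arcs[k] = sub["arc_length_mm"].iloc[0]
        flow[k] = sub["flow_ml_s"].to_numpy(float)
    dt = float(t[1] - t[0])
    return FlowCurveSet(time_axis=t, plane_arc_lengths=arcs, flow=flow,
                        effective_dt=dt)


def panels_frame(subjects, panels) -> pd.DataFrame:
    rows = []
    for s, p in zip(subjects, panels):
        rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "cf_pwv_m_per_s": p.cf_pwv,
            "pwv_2d_m_per_s": p.pwv_2d,
            "pwv_4d_m_per_s": p.pwv_4d,
            "distensibility_1e3_per_mmhg": p.distensibility,
            "cf_pwv_source": p.provenance.get("cf_pwv", "missing"),
            "pwv_2d_source": p.provenance.get("pwv_2d", "missing"),
            "pwv_4d_source": p.provenance.get("pwv_4d", "missing"),
            "distensibility_source": p.provenance.get("distensibility", "missing"),
        })
    return pd.DataFrame(rows, columns=list(PANEL_COLUMNS))


def write_panels(subjects, panels, path) -> Path:
    path = Path(path)
    panels_frame(subjects, panels).to_csv(path, index=False,
                                          float_format=_FLOAT_FMT)
    return path


def read_panels(path) -> pd.DataFrame:
    return _check_schema(pd.read_csv(path, float_precision="round_trip"), PANEL_COLUMNS, path)


def panel_table_for_stats(panel_df: pd.DataFrame) -> pd.DataFrame:
    """Rename unit-suffixed panel columns to the short measure names the
    statistics layer uses."""
    return panel_df.rename(columns={
        "cf_pwv_m_per_s": "cf_pwv",
        "pwv_2d_m_per_s": "pwv_2d",
        "pwv_4d_m_per_s": "pwv_4d",
        "distensibility_1e3_per_mmhg": "distensibility",
        "age_y": "age", "lvmi_g_per_m2": "lvmi",
        "infarcted_segments_n": "infarcted_segments",
    })
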