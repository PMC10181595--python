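"""File formats: OpenSim STO/MOT ASCII tables, TRC marker files, and the
package's CSV trial dialect with a YAML sidecar for units and events.

STO/MOT dialect: free-form ``key=value`` header lines, mandatory ``nRows``
and ``nColumns``, terminated by ``endheader``; then a tab-separated column
name row whose first column is ``time``, then the data rows.  Angles are
written to .mot in degrees with ``inDegrees=yes`` (the OpenSim convention)
but held internally in radians.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gaitwrench.core import GRAVITY, GaitEvent, GaitTrial


# ---------------------------------------------------------------------------
# STO / MOT
# ---------------------------------------------------------------------------

def write_sto(
    path,
    table: pd.DataFrame,
    name: str = "gaitwrench",
    in_degrees: bool | None = None,
    header_meta: dict | None = None,
) -> None:
    """Write a time-series table in the STO/MOT ASCII dialect.

    ``table`` must contain a ``time`` column (written first).  Values are
    formatted with 10 significant digits, which round-trips well beyond the
    8-digit contract of the reader.
    """
    if "time" not in table.columns:
        raise ValueError("table must have a 'time' column")
    cols = ["time"] + [c for c in table.columns if c != "time"]
    lines = [name, "version=1"]
    for k, v in (header_meta or {}).items():
        lines.append(f"{k}={v}")
    if in_degrees is not None:
        lines.append(f"inDegrees={'yes' if in_degrees else 'no'}")
    lines.append(f"nRows={len(table)}")
    lines.append(f"nColumns={len(cols)}")
    lines.append("endheader")
    lines.append("\t".join(cols))
    for _, row in table[cols].iterrows():
        lines.append("\t".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sto(path) -> tuple[pd.DataFrame, dict]:
    """Read an STO/MOT ASCII table.

    Returns ``(table, meta)`` where meta holds the header key=value pairs.
    Raises ValueError (with the offending line number) on malformed
    headers, on nRows/nColumns disagreeing with the body, and on a
    non-monotone time column.
    """
    lines = Path(path).read_text().splitlines()
    meta: dict = {}
    body_start = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped == "endheader":
            body_start = i + 1
            break
        if "=" in stripped:
            k, _, v = stripped.partition("=")
            meta[k.strip()] = v.strip()
        elif i == 0:
            meta["name"] = stripped
        elif stripped:
            raise ValueError(f"{path}: malformed header at line {i + 1}: {line!r}")
    if body_start is None:
        raise ValueError(f"{path}: no 'endheader' line found")
    for key in ("nRows", "nColumns"):
        if key not in meta:
            raise ValueError(f"{path}: header missing {key}")
        try:
            meta[key] = int(meta[key])
        except ValueError as exc:
            raise ValueError(f"{path}: non-integer {key}") from exc
    columns = lines[body_start].split("\t")
    if columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time', got {columns[0]!r} (line {body_start + 1})")
    if len(columns) != meta["nColumns"]:
        raise ValueError(
            f"{path}: header says nColumns={meta['nColumns']} but found {len(columns)} (line {body_start + 1})"
        )
    rows = []
    for i, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != len(columns):
            raise ValueError(f"{path}: row at line {i} has {len(vals)} fields, expected {len(columns)}")
        rows.append([float(v) for v in vals])
    if len(rows) != meta["nRows"]:
        raise ValueError(f"{path}: header says nRows={meta['nRows']} but body has {len(rows)}")
    table = pd.DataFrame(rows, columns=columns)
    t = table["time"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    return table, meta


def read_mot_angles(path) -> pd.DataFrame:
    """Read a .mot kinematics table, converting angle columns to radians
    when the ``inDegrees=yes`` flag is set."""
    table, meta = read_sto(path)
    if str(meta.get("inDegrees", "no")).lower() == "yes":
        for col in table.columns:
            if col != "time":
                table[col] = np.deg2rad(table[col])
    return table


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def read_trc(path) -> tuple[pd.DataFrame, dict]:
    """Read a TRC marker-trajectory file.

    Returns a DataFrame with columns ``time`` and ``<marker>_{x,y,z}``, and
    the header metadata (DataRate, Units, ...).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ValueError(f"{path}: not a TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    meta = dict(zip(keys, vals))
    header = lines[3].split("\t")
    markers = [m for m in header[2:] if m]
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        rows.append([float(v) if v else math.nan for v in line.split("\t")])
    width = 2 + 3 * len(markers)
    data = np.full((len(rows), width), np.nan)
    for i, r in enumerate(rows):
        data[i, : len(r)] = r[:width]
    cols = ["frame", "time"]
    for m in markers:
        cols += [f"{m}_x", f"{m}_y", f"{m}_z"]
    return pd.DataFrame(data, columns=cols).drop(columns="frame"), meta


# ---------------------------------------------------------------------------
# CSV trial dialect + YAML sidecar
# ---------------------------------------------------------------------------

def write_trial_csv(trial: GaitTrial, path) -> None:
    """Write a GaitTrial as CSV plus a YAML sidecar (units, events,
    body weight) at ``<path>.yaml``."""
    from gaitwrench.core import _trial_channels

    path = Path(path)
    table = pd.DataFrame({"time": trial.time, **_trial_channels(trial)})
    table.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "units": {"forces": "BW", "moments": "Nm/kg", "angles": "rad", "positions": "m"},
        "body_weight_N": float(trial.body_weight),
        "events": [{"kind": e.kind, "side": e.side, "time": float(e.time)} for e in trial.events],
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_trial_csv(path, sidecar_path=None) -> GaitTrial:
    """Read a trial written by :func:`write_trial_csv`.

    Forces declared in newtons in the sidecar are converted to BW (and
    moments to Nm/kg) using the declared body weight.
    """
    path = Path(path)
    table = pd.read_csv(path)
    if "time" not in table.columns:
        raise ValueError(f"{path}: 'time' column is mandatory")
    sidecar_path = Path(sidecar_path) if sidecar_path else Path(str(path) + ".yaml")
    sidecar = yaml.safe_load(sidecar_path.read_text()) if sidecar_path.exists() else {}
    bw = float(sidecar.get("body_weight_N", np.nan))
    units = sidecar.get("units", {})

    time = table["time"].to_numpy(dtype=float)
    grf: dict[str, np.ndarray] = {}
    grm: dict[str, np.ndarray] = {}
    cop: dict[str, np.ndarray] = {}
    com_accel = None
    kin_cols = []
    for col in table.columns:
        if col == "time" or col.startswith(("grf_", "grm_", "cop_", "com_accel_")):
            continue
        kin_cols.append(col)
    sides = {"r": "right", "l": "left"}
    for s, side in sides.items():
        fcols = [f"grf_{s}_{ax}" for ax in "xyz"]
        if all(c in table.columns for c in fcols):
            f = table[fcols].to_numpy(dtype=float)
            if units.get("forces", "BW") == "N":
                f = f / bw
            grf[side] = f
        mcols = [f"grm_{s}_{ax}" for ax in "xyz"]
        if all(c in table.columns for c in mcols):
            m = table[mcols].to_numpy(dtype=float)
            if units.get("moments", "Nm/kg") == "Nm":
                m = m / (bw / GRAVITY)
            grm[side] = m
        ccols = [f"cop_{s}_x", f"cop_{s}_ml"]
        if all(c in table.columns for c in ccols):
            cop[side] = table[ccols].to_numpy(dtype=float)
    acols = [f"com_accel_{ax}" for ax in "xyz"]
    if all(c in table.columns for c in acols):
        com_accel = table[acols].to_numpy(dtype=float)

    events = [
        GaitEvent(kind=e["kind"], side=e["side"], time=float(e["time"]))
        for e in sidecar.get("events", [])
    ]
    if units.get("angles") == "deg":
        for col in kin_cols:
            table[col] = np.deg2rad(table[col])
    return GaitTrial(
        time=time,
        kinematics=table[kin_cols],
        grf=grf,
        grm=grm,
        cop=cop or None,
        com_accel=com_accel,
        events=events,
        body_weight=bw,
    )
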