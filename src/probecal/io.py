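"""Readers and writers for the toolkit's tabular formats.

Observation tables are CSV with one row per segmented target: pixel
coordinates, scale factors, the two tracked poses as 16 row-major matrix
entries each, and the digitized truth. View tables drop the phantom pose
and truth columns. Calibration results serialize to JSON with the six
parameters (angles in degrees, translations in mm) plus the row-major 4×4
matrix; metric summaries to CSV rows of (metric, mean, sd, max, min,
n_pooled). Malformed files raise `SchemaError` naming the offending column
or row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationParams, CalibrationResult, Observation
from .geometry import RigidTransform
from .metrics import MetricSummary, View

__all__ = [
    "SchemaError",
    "observations_to_dataframe",
    "observations_from_dataframe",
    "read_observations",
    "write_observations",
    "views_to_dataframe",
    "views_from_dataframe",
    "read_views",
    "write_views",
    "write_calibration",
    "read_calibration",
    "write_metrics",
]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


_PHW = [f"T_ph_w_{i}{j}" for i in range(4) for j in range(4)]
_TWP = [f"T_w_p_{i}{j}" for i in range(4) for j in range(4)]

OBSERVATION_COLUMNS = (
    ["target_id", "x_I_px", "y_I_px", "s_x_mm_per_px", "s_y_mm_per_px"]
    + _PHW + _TWP + ["truth_x_mm", "truth_y_mm", "truth_z_mm"])

VIEW_COLUMNS = (["x_I_px", "y_I_px", "s_x_mm_per_px", "s_y_mm_per_px"]
                + _TWP)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def _transform_from_row(row, cols, what: str, idx) -> RigidTransform:
    try:
        return RigidTransform.from_flat([row[c] for c in cols])
    except ValueError as exc:
        raise SchemaError(f"row {idx}: invalid {what} matrix: {exc}") from exc


def observations_to_dataframe(observations: Sequence[Observation]
                              ) -> pd.DataFrame:
    rows = []
    for obs in observations:
        row = {"target_id": obs.target_id,
               "x_I_px": obs.pixel[0], "y_I_px": obs.pixel[1],
               "s_x_mm_per_px": obs.scale[0], "s_y_mm_per_px": obs.scale[1]}
        row.update(zip(_PHW, obs.world_to_phantom.as_flat()))
        row.update(zip(_TWP, obs.probe_to_world.as_flat()))
        row.update(truth_x_mm=obs.truth_phantom[0],
                   truth_y_mm=obs.truth_phantom[1],
                   truth_z_mm=obs.truth_phantom[2])
        rows.append(row)
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def observations_from_dataframe(df: pd.DataFrame) -> list[Observation]:
    _require_columns(df, OBSERVATION_COLUMNS, "observation")
    out = []
    for idx, row in df.iterrows():
        try:
            obs = Observation(
                target_id=str(row["target_id"]),
                pixel=np.array([row["x_I_px"], row["y_I_px"]]),
                scale=np.array([row["s_x_mm_per_px"], row["s_y_mm_per_px"]]),
                world_to_phantom=_transform_from_row(row, _PHW,
                                                     "world→phantom", idx),
                probe_to_world=_transform_from_row(row, _TWP,
                                                   "probe→world", idx),
                truth_phantom=np.array([row["truth_x_mm"], row["truth_y_mm"],
                                        row["truth_z_mm"]]),
            )
        except SchemaError:
            raise
        except ValueError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
        out.append(obs)
    return out


def read_observations(path) -> list[Observation]:
    return observations_from_dataframe(pd.read_csv(path))


def write_observations(observations: Sequence[Observation], path) -> None:
    observations_to_dataframe(observations).to_csv(path, index=False)


def views_to_dataframe(views: Sequence[View]) -> pd.DataFrame:
    rows = []
    for v in views:
        row = {"x_I_px": v.pixel[0], "y_I_px": v.pixel[1],
               "s_x_mm_per_px": v.scale[0], "s_y_mm_per_px": v.scale[1]}
        row.update(zip(_TWP, v.probe_to_world.as_flat()))
        rows.append(row)
    return pd.DataFrame(rows, columns=VIEW_COLUMNS)


def views_from_dataframe(df: pd.DataFrame) -> list[View]:
    _require_columns(df, VIEW_COLUMNS, "view")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(View(
                pixel=np.array([row["x_I_px"], row["y_I_px"]]),
                scale=np.array([row["s_x_mm_per_px"], row["s_y_mm_per_px"]]),
                probe_to_world=_transform_from_row(row, _TWP,
                                                   "probe→world", idx)))
        except SchemaError:
            raise
        except ValueError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
    return out


def read_views(path) -> list[View]:
    return views_from_dataframe(pd.read_csv(path))


def write_views(views: Sequence[View], path) -> None:
    views_to_dataframe(views).to_csv(path, index=False)


def write_calibration(result: CalibrationResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_calibration(path) -> CalibrationParams:
    """Load the calibration parameters from a result JSON."""
    try:
        d = json.loads(Path(path).read_text())
        return CalibrationParams.from_dict(d)
    except (KeyError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: not a calibration result file: {exc}") from exc


def write_metrics(summaries: dict[str, MetricSummary], path) -> None:
    rows = [{"metric": name, **s.to_dict()} for name, s in summaries.items()]
    pd.DataFrame(rows, columns=["metric", "mean", "sd", "max",
                                "min", "n_pooled"]).to_csv(path, index=False)
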