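"""Plate normalization and file readers/writers.

Plates are long-format tables with a ``well_role`` column.  Viability is
normalized to the vehicle (DMSO) controls; when no-cell minimum controls
are present (MTT-style absorbance) the background is subtracted first:

    viability% = 100 * (signal - min_mean) / (vehicle_mean - min_mean)

Without minimum controls (nuclei-count readouts) viability% is simply
100 * signal / vehicle_mean.  Positive-control wells (staurosporine) are
summarized as plate QC but never enter normalization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WELL_ROLES",
    "normalize_plate",
    "read_plate",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_primary_screen_csv",
    "write_json",
]

WELL_ROLES = ("sample", "vehicle_control", "min_control", "positive_control")


def normalize_plate(plate: pd.DataFrame, signal_col: str = "signal") -> pd.DataFrame:
    """Normalize raw signals to percent viability and inhibition.

    Requires >= 1 vehicle_control row; errors if the minimum-control mean
    is not strictly below the vehicle mean (a failed plate).  Returns a
    copy with ``viability_pct`` and ``inhibition_pct`` columns and QC
    attributes in ``DataFrame.attrs``.
    """
    if "well_role" not in plate.columns:
        raise ValueError("plate table needs a well_role column")
    bad = set(plate["well_role"]) - set(WELL_ROLES)
    if bad:
        raise ValueError(f"unknown well roles: {sorted(bad)}")
    sig = pd.to_numeric(plate[signal_col], errors="raise").to_numpy(float)
    if not np.isfinite(sig).all() or (sig < 0).any():
        raise ValueError("signals must be finite and non-negative")
    roles = plate["well_role"].to_numpy()
    veh = sig[roles == "vehicle_control"]
    if veh.size == 0:
        raise ValueError("no vehicle_control wells on the plate")
    veh_mean = float(veh.mean())
    mins = sig[roles == "min_control"]
    if mins.size:
        min_mean = float(mins.mean())
        if veh_mean <= min_mean:
            raise ValueError(
                f"plate failure: vehicle mean {veh_mean:.4g} <= "
                f"min-control mean {min_mean:.4g}"
            )
        viability = 100.0 * (sig - min_mean) / (veh_mean - min_mean)
    else:
        min_mean = float("nan")
        viability = 100.0 * sig / veh_mean
    out = plate.copy()
    out["viability_pct"] = viability
    out["inhibition_pct"] = 100.0 - viability
    pos = out.loc[out["well_role"] == "positive_control", "inhibition_pct"]
    out.attrs["qc"] = {
        "vehicle_mean": veh_mean,
        "min_mean": min_mean,
        "positive_control_mean_inhibition_pct": float(pos.mean()) if len(pos) else None,
    }
    return out


def read_plate(path) -> pd.DataFrame:
    """Read a long-format plate CSV (compound, dose_uM, replicate, signal,
    well_role)."""
    df = pd.read_csv(path)
    missing = {"signal", "well_role"} - set(df.columns)
    if missing:
        raise ValueError(f"plate file {path} missing columns {sorted(missing)}")
    return df


def read_matrix_csv(path, orientation: str = "inhibition") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an 8x8 matrix CSV whose first row/column carry doses in µM.

    ``orientation`` declares the cell values: "inhibition" or "viability"
    (percent scale either way).  Returns (doses_a, doses_b,
    inhibition_fraction).
    """
    df = pd.read_csv(path, index_col=0)
    doses_a = df.index.to_numpy(float)
    doses_b = df.columns.to_numpy(float)
    vals = df.to_numpy(float)
    if orientation == "viability":
        inh = 1.0 - vals / 100.0
    elif orientation == "inhibition":
        inh = vals / 100.0
    else:
        raise ValueError(f"orientation must be inhibition|viability, got {orientation}")
    return doses_a, doses_b, inh


def write_matrix_csv(path, doses_a, doses_b, matrix) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=np.asarray(doses_a),
                      columns=np.asarray(doses_b))
    df.to_csv(path)


def read_primary_screen_csv(path) -> pd.DataFrame:
    """Read a primary-screen CSV (pair_id, compound_a, compound_b, arm,
    replicate, viability)."""
    df = pd.read_csv(path)
    need = {"pair_id", "compound_a", "compound_b", "arm", "replicate", "viability"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"primary-screen file {path} missing columns {sorted(missing)}")
    bad = set(df["arm"]) - {"A", "B", "AB"}
    if bad:
        raise ValueError(f"unknown arms: {sorted(bad)}")
    return df


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")
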