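"""Trial file I/O.

Trials are plain CSV (comma separator, dot decimal, UTF-8, one header row)
with the columns

    time_s, knee_angle_deg, fx_N, fy_N, fz_N, mx_Nm, my_Nm, mz_Nm,
    app_par_m, app_perp_m, emg_ham, emg_rf

plus a JSON metadata sidecar ``<stem>.meta.json`` holding speed/group
labels, anthropometry, the MVC reference and (for synthetic data) the
ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .limb import Trial

__all__ = ["TRIAL_COLUMNS", "read_trial", "write_trial"]

TRIAL_COLUMNS = ["time_s", "knee_angle_deg", "fx_N", "fy_N", "fz_N",
                 "mx_Nm", "my_Nm", "mz_Nm", "app_par_m", "app_perp_m",
                 "emg_ham", "emg_rf"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json") \
        if path.suffix == ".csv" else path.with_name(path.name + ".meta.json")


def write_trial(trial: Trial, path) -> Path:
    """Write a trial CSV and its metadata sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trial.time,
        "knee_angle_deg": trial.knee_angle_deg,
        "fx_N": trial.force[:, 0], "fy_N": trial.force[:, 1],
        "fz_N": trial.force[:, 2],
        "mx_Nm": trial.moment[:, 0], "my_Nm": trial.moment[:, 1],
        "mz_Nm": trial.moment[:, 2],
        "app_par_m": trial.app_par, "app_perp_m": trial.app_perp,
        "emg_ham": trial.emg.get("ham", np.zeros(len(trial.time))),
        "emg_rf": trial.emg.get("rf", np.zeros(len(trial.time))),
    })
    # default float formatting (shortest exact repr) keeps round trips exact
    df.to_csv(path, index=False)
    meta = dict(trial.meta)
    meta.setdefault("speed_label", trial.speed_label)
    meta.setdefault("group_label", trial.group_label)
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trial(path) -> Trial:
    """Read a trial CSV (+ optional sidecar) back into a :class:`Trial`.

    Raises descriptive errors on missing columns or a non-monotone /
    non-uniform time column (naming the first offending row).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"{path.name}: time not strictly increasing at row {bad[0] + 2} "
            f"(1-based, incl. header)")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return Trial(
        time=t,
        knee_angle_deg=df["knee_angle_deg"].to_numpy(dtype=float),
        force=df[["fx_N", "fy_N", "fz_N"]].to_numpy(dtype=float),
        moment=df[["mx_Nm", "my_Nm", "mz_Nm"]].to_numpy(dtype=float),
        app_par=df["app_par_m"].to_numpy(dtype=float),
        app_perp=df["app_perp_m"].to_numpy(dtype=float),
        emg={"ham": df["emg_ham"].to_numpy(dtype=float),
             "rf": df["emg_rf"].to_numpy(dtype=float)},
        speed_label=meta.get("speed_label", "slow"),
        group_label=meta.get("group_label", "TD"),
        meta=meta)
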