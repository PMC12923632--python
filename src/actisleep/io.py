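"""Plain-file input/output for cohort data.

Epoch series travel as a long table (CSV or parquet) with columns
``participant_id, timestamp, activity_mg, light_lux`` plus optional truth
columns; ground truth is stored as CSV tables plus a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import EpochSeries, GroundTruth

__all__ = [
    "write_epoch_table",
    "read_epoch_table",
    "write_ground_truth",
    "read_ground_truth",
]

_COLMAP = {"activity": "activity_mg", "light": "light_lux"}


def write_epoch_table(series_list: list[EpochSeries], path: str | Path) -> Path:
    """Write a cohort of epoch series as one long CSV or parquet file."""
    path = Path(path)
    frames = []
    for s in series_list:
        df = s.data.rename(columns=_COLMAP).copy()
        df.insert(0, "participant_id", s.participant_id)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    return path


def read_epoch_table(path: str | Path) -> list[EpochSeries]:
    path = Path(path)
    if path.suffix == ".parquet":
        table = pd.read_parquet(path)
    else:
        table = pd.read_csv(path, parse_dates=["timestamp"])
    inv = {v: k for k, v in _COLMAP.items()}
    table = table.rename(columns=inv)
    if "wear" not in table.columns:
        table["wear"] = True
    out = []
    for pid, grp in table.groupby("participant_id", sort=True):
        out.append(EpochSeries(str(pid), grp.drop(columns="participant_id").reset_index(drop=True)))
    return out


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.participants.to_csv(out / "truth_participants.csv", index=False)
    truth.days.to_csv(out / "truth_days.csv", index=False)
    if len(truth.nonwear):
        truth.nonwear.to_csv(out / "truth_nonwear.csv", index=False)
    (out / "truth_header.json").write_text(
        json.dumps({"effects": truth.effects, "slopes": truth.slopes}, indent=2)
    )


def read_ground_truth(out_dir: str | Path) -> GroundTruth:
    out = Path(out_dir)
    header = json.loads((out / "truth_header.json").read_text())
    nw = out / "truth_nonwear.csv"
    return GroundTruth(
        participants=pd.read_csv(out / "truth_participants.csv", parse_dates=["start_noon"]),
        days=pd.read_csv(out / "truth_days.csv"),
        nonwear=pd.read_csv(nw, parse_dates=["start", "end"]) if nw.exists() else pd.DataFrame(),
        effects=[tuple(e) for e in header["effects"]],
        slopes=header["slopes"],
    )
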