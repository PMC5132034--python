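"""File formats: parameter configs (YAML/JSON) and long-format data CSV.

The canonical data interchange is a long-format CSV with header
``subject_id,time,test,score`` (UTF-8, "." decimal, times in years).
Parameter sets are nested-list YAML or JSON mirroring
:meth:`MLMEParams.to_dict`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TrialDesign
from .params import MLMEParams
from .simulate import LongitudinalData

__all__ = [
    "read_params",
    "write_params",
    "read_long_csv",
    "write_long_csv",
    "write_json",
]

REQUIRED_COLUMNS = ("subject_id", "time", "test", "score")


def read_params(path) -> MLMEParams:
    """Read a validated parameter set from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    return MLMEParams.from_dict(d)


def write_params(params: MLMEParams, path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


def read_long_csv(path, design: TrialDesign | None = None) -> LongitudinalData:
    """Read and validate balanced long-format data.

    Checks the header, numeric scores, duplicate cells and balance; if a
    design is given, the observed times must match it within 1e-9.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    if not np.issubdtype(df["score"].dtype, np.number):
        raise ValueError("non-numeric scores in 'score' column")
    if df["score"].isna().any():
        raise ValueError("missing score values")

    dup = df.duplicated(subset=["subject_id", "time", "test"])
    if dup.any():
        first = df.loc[dup, ["subject_id", "time", "test"]].iloc[0]
        raise ValueError(
            f"duplicate (subject, time, test) row: subject {first['subject_id']}, "
            f"time {first['time']}, test {first['test']}"
        )

    times = np.sort(df["time"].unique().astype(float))
    if design is not None:
        if len(times) != design.n_times or not np.allclose(
            times, design.times, atol=1e-9
        ):
            raise ValueError("data measurement times do not match the design")
        times = design.times
    tests = tuple(df["test"].drop_duplicates().tolist())
    subjects = df["subject_id"].drop_duplicates()

    counts = df.groupby(["subject_id", "test"], sort=False)["time"].count()
    if (counts != len(times)).any():
        bad = counts[counts != len(times)].index[0]
        raise ValueError(
            f"incomplete data: subject {bad[0]}, test {bad[1]} does not cover "
            f"all {len(times)} design times"
        )

    return LongitudinalData(
        data=df[list(REQUIRED_COLUMNS)].copy(),
        times=np.asarray(times, dtype=float),
        test_names=tests,
        n_subjects=len(subjects),
    )


def write_long_csv(data: LongitudinalData, path) -> None:
    data.data.to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    """Write a result dictionary as JSON, rounding floats to 12 significant digits."""

    def _round(o):
        if isinstance(o, dict):
            return {k: _round(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_round(v) for v in o]
        if isinstance(o, (float, np.floating)):
            return float(f"{float(o):.12g}")
        if isinstance(o, (int, np.integer)):
            return int(o)
        if isinstance(o, np.ndarray):
            return _round(o.tolist())
        return o

    Path(path).write_text(json.dumps(_round(obj), indent=2) + "\n", encoding="utf-8")
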