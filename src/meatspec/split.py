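"""Calibration/prediction sample-set division schemes.

Two schemes are provided:

* ``concentration_gradient_split`` — rank the samples by one reference
  property, cut the ranking into consecutive blocks of four and draw one
  sample per block (including a final partial block) into the prediction
  set.  Applied independently per property.
* ``carcass_split`` — hold out whole carcasses (all their cuts) as the
  prediction set, by explicit ids or by a per-day count schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SplitAssignment",
    "concentration_gradient_split",
    "carcass_split",
    "split_summary",
    "write_split_csv",
    "read_split_csv",
]

#: Default per-day held-out carcass counts for the carcass scheme.
DEFAULT_CARCASS_SCHEDULE: tuple[int, ...] = (2, 2, 1, 1, 1)

_BLOCK = 4


@dataclass
class SplitAssignment:
    """A calibration/prediction partition of the sample ids."""

    property_name: str
    calibration_ids: list[str]
    prediction_ids: list[str]
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration_ids), set(self.prediction_ids)
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")
        if len(cal) != len(self.calibration_ids) or len(pred) != len(self.prediction_ids):
            raise ValueError("duplicate sample ids within a subset")

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_prediction(self) -> int:
        return len(self.prediction_ids)

    def all_ids(self) -> set[str]:
        return set(self.calibration_ids) | set(self.prediction_ids)


def concentration_gradient_split(
    values: pd.Series, seed: int = 0, property_name: str | None = None
) -> SplitAssignment:
    """One-in-four division along the sorted property gradient.

    ``values`` is indexed by sample id.  Samples are sorted ascending by
    value (ties broken by sample id), partitioned into consecutive blocks
    of four (the final block possibly smaller), and exactly one sample per
    block is drawn uniformly at random into the prediction set.
    """
    if values.isna().any() or not np.all(np.isfinite(values.to_numpy(dtype=float))):
        raise ValueError("property values must be finite")
    n = len(values)
    if n < _BLOCK:
        raise ValueError(f"need at least {_BLOCK} samples, got {n}")
    order = sorted(values.index.astype(str), key=lambda s: (values[s], s))
    rng = np.random.default_rng(seed)
    prediction: list[str] = []
    for start in range(0, n, _BLOCK):
        block = order[start : start + _BLOCK]
        prediction.append(block[int(rng.integers(len(block)))])
    chosen = set(prediction)
    calibration = [s for s in order if s not in chosen]
    return SplitAssignment(
        property_name=property_name or str(values.name or "value"),
        calibration_ids=calibration,
        prediction_ids=prediction,
        method="concentration_gradient",
        seed=seed,
    )


def carcass_split(
    metadata: pd.DataFrame,
    held_out_carcasses: Sequence[str] | None = None,
    schedule: Sequence[int] = DEFAULT_CARCASS_SCHEDULE,
) -> SplitAssignment:
    """Hold out whole carcasses (all cuts) as the prediction set.

    When ``held_out_carcasses`` is not given, the ``schedule`` gives the
    number of carcasses held out per day, matched against the sorted days;
    the lowest carcass ids of each day are taken.
    """
    required = {"carcass_id", "day"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    ids = metadata.index.astype(str)

    if held_out_carcasses is None:
        days = sorted(metadata["day"].unique())
        if len(schedule) > len(days):
            raise ValueError(
                f"schedule covers {len(schedule)} days but metadata has only {len(days)}"
            )
        held: list[str] = []
        for day, count in zip(days, schedule):
            day_carcasses = sorted(metadata.loc[metadata["day"] == day, "carcass_id"].unique())
            if count > len(day_carcasses):
                raise ValueError(
                    f"day {day!r} has {len(day_carcasses)} carcasses; cannot hold out {count}"
                )
            held.extend(day_carcasses[:count])
        held_out_carcasses = held
    else:
        known = set(metadata["carcass_id"].astype(str))
        unknown = [c for c in held_out_carcasses if str(c) not in known]
        if unknown:
            raise ValueError(f"unknown carcass ids: {unknown}")

    held_set = {str(c) for c in held_out_carcasses}
    mask = metadata["carcass_id"].astype(str).isin(held_set)
    prediction = list(ids[mask.to_numpy()])
    calibration = list(ids[~mask.to_numpy()])
    if not prediction:
        raise ValueError("carcass split produced an empty prediction set")
    if not calibration:
        raise ValueError("carcass split produced an empty calibration set")
    return SplitAssignment(
        property_name="all",
        calibration_ids=calibration,
        prediction_ids=prediction,
        method="carcass",
        seed=None,
    )


def split_summary(split: SplitAssignment, references: pd.DataFrame) -> pd.DataFrame:
    """Per-subset descriptive statistics of each reference property.

    Returns one row per (property, subset) with n, min, max, mean, SD
    (n-1 denominator) and CV% = 100 * SD / mean.  SD and CV are reported
    missing for singleton subsets.
    """
    missing = [s for s in split.all_ids() if s not in references.index]
    if missing:
        raise KeyError(f"split references unknown sample ids: {sorted(missing)[:5]}")
    rows = []
    for prop in references.columns:
        for subset, ids in (
            ("calibration", split.calibration_ids),
            ("prediction", split.prediction_ids),
        ):
            vals = references.loc[list(ids), prop].to_numpy(dtype=float)
            n = vals.size
            mean = float(vals.mean()) if n else np.nan
            sd = float(vals.std(ddof=1)) if n > 1 else np.nan
            cv = 100.0 * sd / mean if n > 1 and mean != 0 else np.nan
            rows.append(
                {
                    "property": prop,
                    "subset": subset,
                    "n": n,
                    "min": float(vals.min()) if n else np.nan,
                    "max": float(vals.max()) if n else np.nan,
                    "mean": mean,
                    "sd": sd,
                    "cv_percent": cv,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------


def write_split_csv(split: SplitAssignment, path: str | Path) -> None:
    rows = [
        {"sample_id": s, "property": split.property_name, "subset": subset,
         "method": split.method, "seed": "" if split.seed is None else split.seed}
        for subset, ids in (("calibration", split.calibration_ids),
                            ("prediction", split.prediction_ids))
        for s in ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_split_csv(path: str | Path) -> SplitAssignment:
    frame = pd.read_csv(path, dtype={"sample_id": str})
    seed = frame["seed"].iloc[0]
    return SplitAssignment(
        property_name=str(frame["property"].iloc[0]),
        calibration_ids=list(frame.loc[frame["subset"] == "calibration", "sample_id"]),
        prediction_ids=list(frame.loc[frame["subset"] == "prediction", "sample_id"]),
        method=str(frame["method"].iloc[0]),
        seed=None if pd.isna(seed) or seed == "" else int(seed),
    )
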