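"""Tumor-volume and tumor-growth-inhibition metrics from caliper data.

Volume uses the spheroid approximation V = 0.5 a b^2 (a, b the long and
short tumor diameters in mm). Growth inhibition on a given day is

    TGI% = [1 - (TVi - TV0) / (TVvi - TVv0)] * 100

with TVi/TV0 the treated-arm mean volumes on the readout day and day 0,
and TVvi/TVv0 the vehicle-arm means on the same days. Day 0 is the
first measurement day common to both arms; animals missing either
endpoint are dropped from both means (complete case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["tumor_volume", "tgi", "TGIResult", "time_to_endpoint"]

logger = logging.getLogger(__name__)


def tumor_volume(a: float, b: float) -> float:
    """Spheroid tumor volume 0.5*a*b^2 (mm^3) from caliper diameters."""
    a = float(a)
    b = float(b)
    if b < 0 or a < 0:
        raise ValueError("diameters must be nonnegative")
    if b > a:
        raise ValueError(f"short diameter b={b} exceeds long diameter a={a}")
    return 0.5 * a * b * b


@dataclass(frozen=True)
class TGIResult:
    """Group mean volumes and the growth-inhibition percentage."""

    day: float
    tv_i: float     # treated mean volume on the readout day
    tv_0: float     # treated mean volume on day 0
    tvv_i: float    # vehicle mean volume on the readout day
    tvv_0: float    # vehicle mean volume on day 0
    tgi_percent: float
    n_treated: int
    n_vehicle: int


def _ensure_volume(curves: pd.DataFrame) -> pd.DataFrame:
    df = curves.copy()
    has_vol = "volume" in df.columns
    if has_vol and df["volume"].notna().all():
        return df
    if not {"a_mm", "b_mm"} <= set(df.columns):
        raise ValueError("growth curves need a volume or a_mm/b_mm columns")
    derived = np.array(
        [tumor_volume(a, b) for a, b in zip(df["a_mm"], df["b_mm"])]
    )
    if has_vol:
        df["volume"] = df["volume"].fillna(pd.Series(derived, index=df.index))
    else:
        df["volume"] = derived
    return df


def tgi(curves: pd.DataFrame, day, treated_arm: str = "treated",
        vehicle_arm: str = "vehicle") -> TGIResult:
    """Tumor growth inhibition of the treated arm on ``day``.

    ``curves`` has one row per (animal, day) with ``animal``, ``arm``
    and either ``volume`` or the two diameters. Raises when the readout
    day is missing from either arm or when the vehicle arm shows no net
    volume change (the formula's denominator vanishes).
    """
    df = _ensure_volume(curves)
    for arm in (treated_arm, vehicle_arm):
        if arm not in set(df["arm"]):
            raise ValueError(f"arm '{arm}' absent from growth curves")
    day0_candidates = set(df.loc[df["arm"] == treated_arm, "day"]) & set(
        df.loc[df["arm"] == vehicle_arm, "day"]
    )
    if not day0_candidates:
        raise ValueError("arms share no measurement day to anchor day 0")
    day0 = min(day0_candidates)
    if day not in set(df["day"]):
        raise ValueError(f"day {day} not measured")

    def _arm_means(arm):
        sub = df[df["arm"] == arm]
        v0 = sub[sub["day"] == day0].set_index("animal")["volume"]
        vi = sub[sub["day"] == day].set_index("animal")["volume"]
        animals = sorted(set(v0.index) & set(vi.index))
        dropped = (set(v0.index) | set(vi.index)) - set(animals)
        if dropped:
            logger.info("tgi: dropping incomplete animals in %s arm: %s",
                        arm, sorted(dropped))
        if not animals:
            raise ValueError(f"no animal in arm '{arm}' measured on both days")
        return float(v0.loc[animals].mean()), float(vi.loc[animals].mean()), len(animals)

    tv_0, tv_i, n_t = _arm_means(treated_arm)
    tvv_0, tvv_i, n_v = _arm_means(vehicle_arm)
    denom = tvv_i - tvv_0
    if denom == 0:
        raise ValueError("vehicle arm shows no net growth: TGI undefined")
    value = (1.0 - (tv_i - tv_0) / denom) * 100.0
    return TGIResult(
        day=day, tv_i=tv_i, tv_0=tv_0, tvv_i=tvv_i, tvv_0=tvv_0,
        tgi_percent=float(value), n_treated=n_t, n_vehicle=n_v,
    )


def time_to_endpoint(curves: pd.DataFrame, threshold: float = 2000.0) -> pd.DataFrame:
    """Convert growth curves to a survival table by volume threshold.

    The event time is the first day an animal's volume exceeds
    ``threshold`` mm^3; animals never crossing it are censored at their
    last measurement. Arms become survival groups.
    """
    df = _ensure_volume(curves).sort_values(["animal", "day"])
    rows = []
    for animal, sub in df.groupby("animal", sort=True):
        crossed = sub[sub["volume"] > threshold]
        if len(crossed):
            rows.append(
                {"subject": animal, "time": float(crossed["day"].iloc[0]),
                 "event": 1, "group": sub["arm"].iloc[0]}
            )
        else:
            rows.append(
                {"subject": animal, "time": float(sub["day"].iloc[-1]),
                 "event": 0, "group": sub["arm"].iloc[0]}
            )
    return pd.DataFrame(rows)
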