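"""Xenograft efficacy statistics: time to endpoint, %TGD, log-rank, TGI.

Each animal's tumor-volume series yields a time-to-endpoint (TTE): the day
its tumor reaches the predefined endpoint volume, interpolated log-linearly
between bracketing measurements (exact under exponential growth), or the
final study day with a censoring flag when the endpoint is never reached.
Treatment effect is summarized as percent tumor growth delay (%TGD, the
percent increase in median TTE versus control), compared with the
Mantel-Cox log-rank test, and - at a fixed study day - as tumor growth
inhibition (TGI = 100*(1 - dT/dC) on mean volume changes from baseline)
with a Mann-Whitney test on the day's volumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .biomarkers import rank_sum_test

__all__ = [
    "TTERecord",
    "EfficacyStudy",
    "time_to_endpoint",
    "compute_tte",
    "percent_tgd",
    "logrank_test",
    "tumor_growth_inhibition",
    "km_curve_data",
]


@dataclass(frozen=True)
class TTERecord:
    animal_id: str
    tte: float
    event: bool


@dataclass(frozen=True)
class EfficacyStudy:
    """A study: long-format volume series plus endpoint definitions."""

    volumes: pd.DataFrame  # columns: animal_id, group, day, volume_mm3
    endpoint_volume: float
    final_study_day: float

    def groups(self) -> list[str]:
        return sorted(self.volumes["group"].unique())


def time_to_endpoint(
    days: Sequence[float],
    volumes: Sequence[float],
    endpoint_volume: float,
    final_study_day: float,
    animal_id: str = "",
) -> TTERecord:
    """TTE for one animal.

    Log-linear interpolation between the bracketing measurements:
    ``t1 + (t2 - t1) * ln(E/V1) / ln(V2/V1)``; falls back to linear
    interpolation (with a warning) if a bracketing volume is nonpositive.
    An animal never reaching the endpoint is censored at the final study
    day.
    """
    days = np.asarray(days, dtype=float)
    vols = np.asarray(volumes, dtype=float)
    if days.size == 0:
        raise ValueError("need at least one measurement")
    if np.any(np.diff(days) <= 0):
        raise ValueError("measurement days must be ascending")
    for i, (t, v) in enumerate(zip(days, vols)):
        if v >= endpoint_volume:
            if i == 0:
                return TTERecord(animal_id, float(min(t, final_study_day)), True)
            t1, t2 = days[i - 1], t
            v1, v2 = vols[i - 1], v
            if v1 <= 0 or v2 <= 0:
                warnings.warn("nonpositive volume at crossing; linear interpolation")
                frac = (endpoint_volume - v1) / (v2 - v1)
            else:
                frac = math.log(endpoint_volume / v1) / math.log(v2 / v1)
            tte = t1 + (t2 - t1) * frac
            return TTERecord(animal_id, float(min(tte, final_study_day)), True)
    return TTERecord(animal_id, float(final_study_day), False)


def compute_tte(study: EfficacyStudy) -> pd.DataFrame:
    """Per-animal TTE table (animal_id, group, tte, event)."""
    rows = []
    for (animal, group), sub in study.volumes.groupby(
        ["animal_id", "group"], sort=True
    ):
        sub = sub.sort_values("day")
        rec = time_to_endpoint(
            sub["day"].to_numpy(),
            sub["volume_mm3"].to_numpy(),
            study.endpoint_volume,
            study.final_study_day,
            animal_id=animal,
        )
        rows.append(dict(animal_id=animal, group=group, tte=rec.tte, event=rec.event))
    return pd.DataFrame(rows)


def percent_tgd(
    treated: Sequence[TTERecord], control: Sequence[TTERecord]
) -> tuple[float, bool]:
    """Percent tumor growth delay: 100*(median TTE_t - median TTE_c)/median TTE_c.

    Censored animals contribute their censoring day to the medians (a
    known, conservative limitation); the returned flag is True whenever any
    censored record entered either median.
    """
    if not treated or not control:
        raise ValueError("both arms need at least one TTE record")
    mt = float(np.median([r.tte for r in treated]))
    mc = float(np.median([r.tte for r in control]))
    if mc == 0:
        raise ValueError("control median TTE is zero")
    censored = any(not r.event for r in treated) or any(
        not r.event for r in control
    )
    return 100.0 * (mt - mc) / mc, censored


def logrank_test(
    arm1: Sequence[TTERecord], arm2: Sequence[TTERecord]
) -> tuple[float, float]:
    """Two-group Mantel-Cox log-rank test; returns (chi-square, p)."""
    if not any(r.event for r in list(arm1) + list(arm2)):
        warnings.warn("no events in either arm; log-rank test uninformative")
        return 0.0, 1.0
    res = _ll_logrank(
        [r.tte for r in arm1],
        [r.tte for r in arm2],
        event_observed_A=[r.event for r in arm1],
        event_observed_B=[r.event for r in arm2],
    )
    return float(res.test_statistic), float(res.p_value)


def tumor_growth_inhibition(
    treated_volumes,
    vehicle_volumes,
    treated_baselines,
    vehicle_baselines,
) -> tuple[float | None, float]:
    """Day-fixed TGI% and Mann-Whitney p on the day's volumes.

    ``TGI = 100 * (1 - dT/dC)`` with ``dT``/``dC`` the mean volume changes
    from baseline in the treated and vehicle arms. Undefined (None) when
    the vehicle arm did not grow on average.
    """
    t = np.asarray(treated_volumes, dtype=float)
    v = np.asarray(vehicle_volumes, dtype=float)
    tb = np.asarray(treated_baselines, dtype=float)
    vb = np.asarray(vehicle_baselines, dtype=float)
    d_t = float(np.mean(t - tb))
    d_c = float(np.mean(v - vb))
    p = rank_sum_test(t, v)
    if d_c <= 0:
        warnings.warn("vehicle arm did not grow; TGI undefined")
        return None, p
    return 100.0 * (1.0 - d_t / d_c), p


def km_curve_data(tte_table: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier step-function coordinates per group (plot-ready CSV)."""
    rows = []
    for group, sub in tte_table.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["tte"], event_observed=sub["event"])
        sf = kmf.survival_function_
        for t, s in zip(sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()):
            rows.append(dict(group=group, time=float(t), survival=float(s)))
    return pd.DataFrame(rows)
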