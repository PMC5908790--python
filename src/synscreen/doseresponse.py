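"""Time-zero-anchored dose-response analysis.

Raw viability signals are normalized so that the measurement taken at the
time of dosing (T0) equals 100%. A four-parameter logistic (4PL) curve is
fitted to the normalized responses and three potency metrics are read off
by inverting the fitted curve:

* ``gIC50`` — concentration at the midpoint of the growth window, i.e. the
  response halfway between the untreated (DMSO) level and T0;
* ``gIC100`` — concentration producing complete growth stasis (response
  equals T0, 100%);
* ``dEC50`` — concentration producing 50% net cell death (response equals
  half of T0, 50%).

``Ymin − T0`` is the fitted-curve minimum over the tested concentration
range minus 100: positive values indicate net growth over the assay,
negative values net death. Metrics that are not attained within the tested
range are censored as ``">max"`` (carrying the maximum tested concentration
as a lower bound) and levels outside the curve's asymptotes are censored as
``"unreachable"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GT_MAX",
    "UNREACHABLE",
    "AnchorError",
    "MetricValue",
    "NormalizedCurveData",
    "FourPLCurve",
    "FitResult",
    "GrowthMetrics",
    "normalize_to_t0",
    "fit_4pl",
    "invert_4pl",
    "growth_metrics",
    "aggregate_replicates",
]

#: censor kind: metric not attained at or below the maximum tested concentration
GT_MAX = ">max"
#: censor kind: level lies outside the open interval (bottom, top) of the curve
UNREACHABLE = "unreachable"


class AnchorError(ValueError):
    """Raised when T0 or DMSO anchor wells are missing or nonpositive."""


@dataclass(frozen=True)
class MetricValue:
    """A concentration metric (nM) with explicit censoring state.

    ``value`` is the concentration for uncensored metrics; for ``">max"``
    censoring it carries the maximum tested concentration (the reporting
    convention for right-censored potencies, e.g. "> 29300 nM"); for
    ``"unreachable"`` censoring it is ``None``.
    """

    value: float | None
    censor: str | None = None
    note: str | None = None

    @property
    def is_censored(self) -> bool:
        return self.censor is not None

    def __float__(self) -> float:
        if self.value is None:
            return math.nan
        return float(self.value)


@dataclass(frozen=True)
class NormalizedCurveData:
    """Dose-response data in %T0 units (T0 ≡ 100)."""

    conc: np.ndarray
    response: np.ndarray
    dmso_level: float
    max_tested_conc: float

    def __post_init__(self):
        conc = np.asarray(self.conc, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "response", resp)
        if conc.shape != resp.shape:
            raise ValueError("conc and response lengths differ")
        if conc.size and (np.any(conc <= 0) or np.any(np.diff(conc) <= 0)):
            raise ValueError("concentrations must be strictly positive and ascending")
        if not self.dmso_level > 0:
            raise ValueError("dmso_level must be positive")


@dataclass(frozen=True)
class FourPLCurve:
    """Four-parameter logistic curve in %T0 space.

    ``response(c) = bottom + (top - bottom) / (1 + (c / inflection)**slope)``

    Canonical form has ``top >= bottom``; ``slope > 0`` then means the
    response decreases with dose (the usual shape for a growth inhibitor).
    """

    bottom: float
    top: float
    inflection: float
    slope: float

    def __post_init__(self):
        if not self.inflection > 0:
            raise ValueError("inflection must be positive")
        if not (math.isfinite(self.slope) and self.slope != 0):
            raise ValueError("slope must be finite and nonzero")

    def predict(self, conc):
        c = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (c / self.inflection) ** self.slope
        )

    def canonicalized(self) -> "FourPLCurve":
        if self.bottom > self.top:
            # swapping asymptotes and negating the slope leaves the
            # function unchanged
            return FourPLCurve(self.top, self.bottom, self.inflection, -self.slope)
        return self


@dataclass(frozen=True)
class FitResult:
    curve: FourPLCurve | None
    rss: float
    converged: bool
    degenerate: bool


@dataclass(frozen=True)
class GrowthMetrics:
    """The screen's per-(line, agent) unit of potency."""

    gic50: MetricValue
    gic100: MetricValue
    dec50: MetricValue
    ymin_minus_t0: float
    dmso_level: float
    max_tested_conc: float


def normalize_to_t0(
    treated_conc: Sequence[float],
    treated_signal: Sequence[float],
    t0_signals: Sequence[float],
    dmso_signals: Sequence[float],
) -> NormalizedCurveData:
    """Express raw signals as percent of the mean T0 anchor (T0 = 100%).

    Replicate wells at the same concentration are arithmetically averaged
    after normalization.
    """
    t0 = np.asarray(t0_signals, dtype=float)
    dmso = np.asarray(dmso_signals, dtype=float)
    sig = np.asarray(treated_signal, dtype=float)
    conc = np.asarray(treated_conc, dtype=float)
    if t0.size == 0 or dmso.size == 0:
        raise AnchorError("missing T0 or DMSO anchor wells")
    if np.any(t0 <= 0) or np.any(dmso <= 0) or np.any(sig <= 0):
        raise AnchorError("anchor and treated signals must be positive")
    if conc.shape != sig.shape:
        raise ValueError("treated_conc and treated_signal lengths differ")
    t0_mean = float(t0.mean())
    resp = 100.0 * sig / t0_mean
    dmso_level = float(100.0 * dmso.mean() / t0_mean)
    order = {}
    for c, r in zip(conc, resp):
        order.setdefault(float(c), []).append(float(r))
    cs = np.array(sorted(order))
    rs = np.array([np.mean(order[c]) for c in cs])
    return NormalizedCurveData(cs, rs, dmso_level, float(cs.max()))


def _4pl(logc, bottom, top, log_infl, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logc - log_infl)))


_MAX_RESTARTS = 5


def fit_4pl(data: NormalizedCurveData, max_restarts: int = _MAX_RESTARTS) -> FitResult:
    """Least-squares 4PL fit with quantile initialization.

    Initial values: top = max response, bottom = min response, inflection =
    concentration nearest the mid-response, slope = 1. Up to ``max_restarts``
    jittered restarts are attempted when the optimizer fails. Flat data
    (dynamic range below 1 %T0) yields a degenerate, flagged result rather
    than an exception; downstream metrics are then censored.
    """
    conc = data.conc
    resp = data.response
    if np.unique(conc).size < 4:
        raise ValueError("fit_4pl requires at least 4 distinct concentrations")
    if resp.max() - resp.min() < 1.0:
        level = float(resp.mean())
        curve = FourPLCurve(level, level + 1e-9, float(np.median(conc)), 1.0)
        rss = float(np.sum((resp - level) ** 2))
        return FitResult(curve, rss, converged=False, degenerate=True)

    logc = np.log10(conc)
    mid = 0.5 * (resp.max() + resp.min())
    p0 = np.array(
        [resp.min(), resp.max(), logc[np.argmin(np.abs(resp - mid))], 1.0]
    )
    lo = [resp.min() - 5 * (resp.max() - resp.min()) - 1, -np.inf, logc.min() - 4, 0.01]
    hi = [np.inf, resp.max() + 5 * (resp.max() - resp.min()) + 1, logc.max() + 4, 30.0]
    # keep bounds consistent (bottom free low, top free high); ordering is
    # restored by canonicalization afterwards
    lo[1] = lo[0]
    hi[0] = hi[1]

    rng = np.random.default_rng(161803)
    best = None
    for attempt in range(1 + max_restarts):
        if attempt == 0:
            start = p0
        else:
            start = p0 + rng.normal(0, [5.0, 5.0, 0.5, 0.2], size=4)
            start[3] = max(start[3], 0.05)
        start = np.clip(start, lo, hi)
        try:
            popt, _ = curve_fit(
                _4pl, logc, resp, p0=start, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((resp - _4pl(logc, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if best[1] <= 1e-14 * max(1.0, float(np.sum(resp**2))):
            break

    if best is None:
        return FitResult(None, math.inf, converged=False, degenerate=True)
    popt, rss = best
    curve = FourPLCurve(popt[0], popt[1], 10.0 ** popt[2], popt[3]).canonicalized()
    degenerate = (curve.top - curve.bottom) < 1.0
    return FitResult(curve, rss, converged=True, degenerate=degenerate)


def invert_4pl(
    curve: FourPLCurve, level: float, max_conc: float | None = None
) -> MetricValue:
    """Concentration at which the fitted curve equals ``level`` (%T0).

    Returns a censored value when the level lies outside the open interval
    (bottom, top) (``"unreachable"``), or — when ``max_conc`` is given —
    when the required concentration exceeds the maximum tested
    concentration (``">max"``, carrying ``max_conc`` as the bound).
    """
    c = curve.canonicalized()
    if not (c.bottom < level < c.top):
        return MetricValue(None, UNREACHABLE)
    ratio = (c.top - level) / (level - c.bottom)
    conc = c.inflection * ratio ** (1.0 / c.slope)
    if not (math.isfinite(conc) and conc > 0):
        return MetricValue(None, UNREACHABLE)
    if max_conc is not None and conc > max_conc * (1 + 1e-12):
        return MetricValue(float(max_conc), GT_MAX)
    return MetricValue(float(conc))


def growth_metrics(fit: FitResult, data: NormalizedCurveData) -> GrowthMetrics:
    """Extract gIC50 / gIC100 / dEC50 and net growth from a fitted curve.

    Effect levels: gIC50 at the growth-window midpoint ``(dmso_level+100)/2``,
    gIC100 at 100 (growth stasis), dEC50 at 50 (half of T0). A degenerate
    fit censors all three concentrations and reports the DMSO level as the
    curve minimum.
    """
    dmso = data.dmso_level
    maxc = data.max_tested_conc
    if fit.curve is None or fit.degenerate:
        cens = MetricValue(maxc, GT_MAX, note="degenerate fit")
        return GrowthMetrics(cens, cens, cens, dmso - 100.0, dmso, maxc)
    curve = fit.curve.canonicalized()
    levels = {"gic50": (dmso + 100.0) / 2.0, "gic100": 100.0, "dec50": 50.0}
    vals = {k: invert_4pl(curve, lv, max_conc=maxc) for k, lv in levels.items()}
    # the 4PL is monotone, so its extremes over the tested range sit at the ends
    ends = curve.predict(np.array([data.conc.min(), data.conc.max()]))
    ymin = float(np.min(ends)) - 100.0
    return GrowthMetrics(
        vals["gic50"], vals["gic100"], vals["dec50"], ymin, dmso, maxc
    )


def _aggregate_metric(values: list[MetricValue]) -> MetricValue:
    uncens = [v.value for v in values if not v.is_censored]
    if uncens:
        agg = float(10.0 ** np.mean(np.log10(uncens)))
        note = "partial" if len(uncens) < len(values) else None
        return MetricValue(agg, None, note)
    bounds = [v.value for v in values if v.value is not None]
    if any(v.censor == GT_MAX for v in values):
        return MetricValue(float(max(bounds)) if bounds else None, GT_MAX)
    return MetricValue(None, UNREACHABLE)


def aggregate_replicates(metrics: Sequence[GrowthMetrics]) -> GrowthMetrics:
    """Average growth metrics across biological replicates.

    Concentration metrics are combined by geometric mean over uncensored
    replicates (a metric is censored in the aggregate only when censored in
    every replicate; mixed cases are flagged "partial"); ``ymin − T0`` and
    the anchors are arithmetic means.
    """
    if not metrics:
        raise ValueError("aggregate_replicates requires at least one replicate")
    return GrowthMetrics(
        gic50=_aggregate_metric([m.gic50 for m in metrics]),
        gic100=_aggregate_metric([m.gic100 for m in metrics]),
        dec50=_aggregate_metric([m.dec50 for m in metrics]),
        ymin_minus_t0=float(np.mean([m.ymin_minus_t0 for m in metrics])),
        dmso_level=float(np.mean([m.dmso_level for m in metrics])),
        max_tested_conc=float(np.max([m.max_tested_conc for m in metrics])),
    )
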