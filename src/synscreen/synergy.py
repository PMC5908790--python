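"""Mutually non-exclusive combination-index synergy analysis.

For a fixed-ratio titration of two agents, 4PL curves are fitted to each
single agent and to the mixture. At each effect level attained by the
mixture (the growth-window midpoint, growth stasis, and 50% net death), the
combination index is

``CI = D1/Dx1 + D2/Dx2 + (D1*D2) / (Dx1*Dx2)``

where ``D1``, ``D2`` are the component doses inside the mixture producing
the effect and ``Dx1``, ``Dx2`` the single-agent doses producing the same
effect. The cross term makes the index "mutually non-exclusive": a sham
1:1 self-combination scores exactly 1.25 rather than 1, and an exactly
Loewe-additive mixture scores in (1, 1.25].

Calls use a three-tier rule on the minimum CI across attained levels,
gated by potency fold shifts (single-agent potency / component dose in the
mixture at the same level):

* strongly synergistic — CI < 0.44 and a ≥5-fold shift from each single
  agent at some level;
* synergistic — CI < 0.78 and a ≥3-fold shift from each single agent;
* additive — everything else (including CI in [0.78, 1] and CI < 0.78 with
  a sub-3-fold shift from either agent). No antagonism tier is defined;
  CI > 1 is reported numerically but called additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .doseresponse import (
    FourPLCurve,
    FitResult,
    NormalizedCurveData,
    fit_4pl,
    invert_4pl,
)

__all__ = [
    "FixedRatioDesign",
    "SynergyRule",
    "LevelResult",
    "CombinationResult",
    "combination_index",
    "analyze_combination",
    "classify_synergy",
    "STRONGLY_SYNERGISTIC",
    "SYNERGISTIC",
    "ADDITIVE",
]

STRONGLY_SYNERGISTIC = "strongly_synergistic"
SYNERGISTIC = "synergistic"
ADDITIVE = "additive"

#: classification order from weakest to strongest interaction
CALL_ORDER = (ADDITIVE, SYNERGISTIC, STRONGLY_SYNERGISTIC)

LEVEL_NAMES = ("gic50", "gic100", "dec50")


@dataclass(frozen=True)
class FixedRatioDesign:
    """Fixed-ratio mixture design, e.g. 4 parts agent A : 1 part agent B."""

    agent_a: str
    agent_b: str
    fraction_a: float
    fraction_b: float

    def __post_init__(self):
        if not (self.fraction_a > 0 and self.fraction_b > 0):
            raise ValueError("mixture fractions must be positive")
        if abs(self.fraction_a + self.fraction_b - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")

    @classmethod
    def from_ratio(cls, agent_a: str, agent_b: str, parts_a: float, parts_b: float):
        if parts_a <= 0 or parts_b <= 0:
            raise ValueError("ratio parts must be positive")
        tot = parts_a + parts_b
        return cls(agent_a, agent_b, parts_a / tot, parts_b / tot)

    def swapped(self) -> "FixedRatioDesign":
        return FixedRatioDesign(
            self.agent_b, self.agent_a, self.fraction_b, self.fraction_a
        )


@dataclass(frozen=True)
class SynergyRule:
    """Thresholds and policy flags for the three-tier synergy call.

    ``same_level_for_both`` — when True (default) the fold-shift gate
    requires one common effect level at which BOTH agents shift by the
    threshold; when False each agent may satisfy its shift at a different
    level.  ``summary_level`` — when set to one of the level names, the
    summary CI is taken at that level only instead of the minimum over
    available levels.
    """

    strong_ci: float = 0.44
    synergistic_ci: float = 0.78
    strong_fold: float = 5.0
    synergistic_fold: float = 3.0
    same_level_for_both: bool = True
    summary_level: str | None = None


@dataclass(frozen=True)
class LevelResult:
    level: str
    response_level: float
    d_total: float
    d1: float
    d2: float
    dx1: float | None
    dx2: float | None
    ci: float
    monotherapy_incapable: bool
    fold_shift_a: float | None
    fold_shift_b: float | None


@dataclass(frozen=True)
class CombinationResult:
    design: FixedRatioDesign
    levels: dict[str, LevelResult]
    summary_ci: float | None
    call: str
    reason: str | None = None
    fits: dict[str, FitResult] = field(default_factory=dict)


def combination_index(
    d1: float,
    d2: float,
    dx1: float | None,
    dx2: float | None,
) -> tuple[float, bool]:
    """Three-term non-exclusive combination index.

    ``dx1``/``dx2`` may be ``None`` (or infinite) when the corresponding
    monotherapy cannot attain the effect; that term contributes 0 (the
    ``Dx → ∞`` limit) and the returned flag marks the result
    "monotherapy-incapable".
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("component doses must be nonnegative")
    if d1 == 0 and d2 == 0:
        raise ValueError("at least one component dose must be positive")
    flagged = False
    t1 = t2 = 0.0
    if dx1 is None or not math.isfinite(dx1):
        flagged = True
    else:
        t1 = d1 / dx1
    if dx2 is None or not math.isfinite(dx2):
        flagged = True
    else:
        t2 = d2 / dx2
    cross = t1 * t2
    return t1 + t2 + cross, flagged


def classify_synergy(
    summary_ci: float | None,
    levels: dict[str, LevelResult],
    rule: SynergyRule = SynergyRule(),
) -> str:
    """Apply the three-tier CI + fold-shift classification."""
    if summary_ci is None or not levels:
        return ADDITIVE

    def gate(threshold: float) -> bool:
        avail = levels.values()
        if rule.same_level_for_both:
            return any(
                lv.fold_shift_a is not None
                and lv.fold_shift_b is not None
                and lv.fold_shift_a >= threshold
                and lv.fold_shift_b >= threshold
                for lv in avail
            )
        a_ok = any(
            lv.fold_shift_a is not None and lv.fold_shift_a >= threshold
            for lv in avail
        )
        b_ok = any(
            lv.fold_shift_b is not None and lv.fold_shift_b >= threshold
            for lv in avail
        )
        return a_ok and b_ok

    if summary_ci < rule.strong_ci and gate(rule.strong_fold):
        return STRONGLY_SYNERGISTIC
    if summary_ci < rule.synergistic_ci and gate(rule.synergistic_fold):
        return SYNERGISTIC
    return ADDITIVE


def _dx(curve: FourPLCurve, level: float) -> float | None:
    """Single-agent equi-effective dose; None when outside the asymptotes.

    The fitted curve is inverted without a range cap: an effect the
    monotherapy attains only beyond its tested range is still a finite
    equivalent dose, while asymptote-unreachable effects are censored.
    """
    mv = invert_4pl(curve, level, max_conc=None)
    return mv.value if not mv.is_censored else None


def analyze_combination(
    data_a: NormalizedCurveData,
    data_b: NormalizedCurveData,
    data_mix: NormalizedCurveData,
    design: FixedRatioDesign,
    rule: SynergyRule = SynergyRule(),
) -> CombinationResult:
    """Full fixed-ratio combination analysis for one cell line.

    Fits 4PL curves to both single agents and the mixture (mixture
    concentrations are TOTAL doses), evaluates the non-exclusive CI and the
    per-agent fold shifts at every effect level the mixture attains within
    its tested range, and classifies the interaction.
    """
    fits = {
        "A": fit_4pl(data_a),
        "B": fit_4pl(data_b),
        "mix": fit_4pl(data_mix),
    }
    mix_fit = fits["mix"]
    dmso = data_mix.dmso_level
    targets = {
        "gic50": (dmso + 100.0) / 2.0,
        "gic100": 100.0,
        "dec50": 50.0,
    }
    levels: dict[str, LevelResult] = {}
    if mix_fit.curve is not None and not mix_fit.degenerate:
        for name in LEVEL_NAMES:
            lv = targets[name]
            mv = invert_4pl(mix_fit.curve, lv, max_conc=data_mix.max_tested_conc)
            if mv.is_censored:
                continue
            d_total = mv.value
            d1 = design.fraction_a * d_total
            d2 = design.fraction_b * d_total
            dx1 = _dx(fits["A"].curve, lv) if not fits["A"].degenerate else None
            dx2 = _dx(fits["B"].curve, lv) if not fits["B"].degenerate else None
            ci, flagged = combination_index(d1, d2, dx1, dx2)
            fold_a = dx1 / d1 if dx1 is not None else None
            fold_b = dx2 / d2 if dx2 is not None else None
            levels[name] = LevelResult(
                name, lv, d_total, d1, d2, dx1, dx2, ci, flagged, fold_a, fold_b
            )

    if not levels:
        return CombinationResult(
            design, {}, None, ADDITIVE, reason="no attainable effect level", fits=fits
        )
    if rule.summary_level is not None:
        chosen = levels.get(rule.summary_level)
        summary = chosen.ci if chosen is not None else None
    else:
        summary = min(lv.ci for lv in levels.values())
    call = classify_synergy(summary, levels, rule)
    return CombinationResult(design, levels, summary, call, fits=fits)
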