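"""Synthetic screen generation with known ground truth.

Emulates the statistical structure of a large cell-line proliferation
screen: a panel of a few hundred lines spanning tumor types, 4PL
single-agent dose responses whose potency is shifted multiplicatively in
lines mutant for configured genes, fixed-ratio two-agent titrations built
on an exactly Loewe-additive baseline with a controllable synergy
parameter ``psi`` (1 = additive, <1 = synergistic potency gain), and
exponentially growing xenografts with group-specific growth rates.

All raw signals carry multiplicative lognormal measurement noise with a
configurable coefficient of variation; the same seed and configuration
always reproduce identical tables.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import FourPLCurve, invert_4pl
from scipy.optimize import brentq

__all__ = [
    "ConfigError",
    "PanelConfig",
    "ComboConfig",
    "XenoConfig",
    "synth_single_agent_panel",
    "synth_combination_plates",
    "synth_xenograft",
    "loewe_mixture_response",
]

#: raw-signal scale of the T0 anchor (arbitrary luminescence-like units)
T0_SIGNAL = 1000.0

#: amino-acid hotspots used when annotating planted mutations
_HOTSPOTS = {
    "KRAS": (("G12", 0.7), ("G13", 0.2), ("Q61", 0.1)),
    "NRAS": (("Q61", 0.6), ("G12", 0.4)),
    "HRAS": (("G12", 0.6), ("Q61", 0.4)),
    "BRAF": (("V600", 0.8), ("G469", 0.2)),
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _require(cond: bool, field_name: str, msg: str):
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class PanelConfig:
    """Conditions of the synthetic single-agent screen.

    Defaults emulate the screened panel: ~230 lines across tumor types, a
    lognormal potency distribution centered at 550 nM (the wild-type median
    in the emulated screen) spanning roughly 10 nM to >30 µM, a planted
    3-fold KRAS resistance multiplier, 10-point half-log-ish titrations
    topping at 30 µM, duplicate treated wells, and 10% multiplicative
    measurement noise.
    """

    n_lines: int = 230
    tumor_types: Mapping[str, int] | None = None
    agents: tuple[str, ...] = ("BETi",)
    mutation_freqs: Mapping[str, float] = field(
        default_factory=lambda: {
            "KRAS": 0.20,
            "NRAS": 0.05,
            "HRAS": 0.02,
            "BRAF": 0.09,
            "NF1": 0.08,
            "TP53": 0.45,
            "PIK3CA": 0.12,
            "APC": 0.14,
        }
    )
    effect_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"KRAS": 3.0}
    )
    baseline_gic50_log10_mean: float = math.log10(550.0)
    baseline_gic50_log10_sd: float = 0.7
    noise_cv: float = 0.10
    dose_top_nM: float = 30000.0
    dose_dilution: float = 3.0
    dose_n_points: int = 10
    n_replicates: int = 2
    n_anchor_wells: int = 6
    seed: int = 0

    def validate(self):
        _require(self.n_lines >= 1, "n_lines", "must be >= 1")
        if self.tumor_types is not None:
            _require(
                sum(self.tumor_types.values()) == self.n_lines,
                "tumor_types",
                "per-type counts must sum to n_lines",
            )
        _require(len(self.agents) >= 1, "agents", "need at least one agent")
        for g, f in self.mutation_freqs.items():
            _require(0.0 <= f <= 1.0, "mutation_freqs", f"{g} frequency not in [0,1]")
        for g, m in self.effect_multipliers.items():
            _require(m > 0, "effect_multipliers", f"{g} multiplier must be > 0")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        _require(self.dose_top_nM > 0, "dose_top_nM", "must be > 0")
        _require(self.dose_dilution > 1, "dose_dilution", "must be > 1")
        _require(self.dose_n_points >= 4, "dose_n_points", "must be >= 4 (4PL fit)")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.n_anchor_wells >= 1, "n_anchor_wells", "must be >= 1")

    def dose_grid(self) -> np.ndarray:
        """Ascending concentration grid in nM."""
        k = np.arange(self.dose_n_points)
        return np.sort(self.dose_top_nM / self.dose_dilution**k)


@dataclass(frozen=True)
class ComboConfig:
    """Fixed-ratio combination plate conditions."""

    ratio: tuple[float, float] = (4.0, 1.0)
    psi: float = 1.0
    duration_days: int = 6
    seed: int = 0

    def validate(self):
        _require(
            self.ratio[0] > 0 and self.ratio[1] > 0, "ratio", "parts must be positive"
        )
        _require(self.psi > 0, "psi", "must be > 0")
        _require(self.duration_days in (3, 6), "duration_days", "must be 3 or 6")

    @property
    def fraction_a(self) -> float:
        return self.ratio[0] / (self.ratio[0] + self.ratio[1])

    @property
    def fraction_b(self) -> float:
        return self.ratio[1] / (self.ratio[0] + self.ratio[1])


@dataclass(frozen=True)
class XenoConfig:
    """Xenograft study conditions: exponential growth to a volume endpoint."""

    n_per_group: int = 10
    v0_mm3: tuple[float, float] = (100.0, 200.0)
    growth_rate_per_day: Mapping[str, float] = field(
        default_factory=lambda: {"vehicle": 0.12, "treated": 0.05}
    )
    endpoint_volume_mm3: float = 2000.0
    measurement_interval_days: float = 3.0
    noise_cv: float = 0.10
    max_study_day: float = 60.0
    seed: int = 0

    def validate(self):
        _require(self.n_per_group >= 2, "n_per_group", "must be >= 2")
        _require(
            self.v0_mm3[0] > 0 and self.v0_mm3[1] >= self.v0_mm3[0],
            "v0_mm3",
            "must be a positive (low, high) range",
        )
        _require(
            self.endpoint_volume_mm3 > self.v0_mm3[1],
            "endpoint_volume_mm3",
            "endpoint must exceed the randomization volume range",
        )
        for g, r in self.growth_rate_per_day.items():
            _require(math.isfinite(r), "growth_rate_per_day", f"{g} rate not finite")
        _require(
            self.measurement_interval_days > 0,
            "measurement_interval_days",
            "must be > 0",
        )
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        _require(self.max_study_day > 0, "max_study_day", "must be > 0")


def _noise(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _protein_change(gene: str, rng: np.random.Generator) -> str:
    """A plausible protein-change string; ~10% are frameshift/splice-like."""
    if rng.random() < 0.10:
        pos = int(rng.integers(5, 900))
        return rng.choice([f"X{pos}_splice", f"E{pos}fs"])
    if gene in _HOTSPOTS:
        sites, weights = zip(*_HOTSPOTS[gene])
        site = sites[rng.choice(len(sites), p=np.asarray(weights))]
        ref, pos = site[0], site[1:]
    else:
        # gene-stable pseudo-hotspots so residue-level markers recur
        h = zlib.crc32(gene.encode())
        pos = str(5 + (h % 700) + int(rng.choice([0, 1, 2])))
        ref = _AA[h % len(_AA)]
    alt = _AA[int(rng.integers(len(_AA)))]
    while alt == ref:
        alt = _AA[int(rng.integers(len(_AA)))]
    return f"{ref}{pos}{alt}"


def _sample_panel(config: PanelConfig, rng: np.random.Generator):
    """Draw per-line biology: tumor type, growth window, mutations, curves.

    Returns (lines dataframe, truth dataframe, mutations dataframe).
    The per-agent true gIC50 is drawn from the configured lognormal; the
    4PL inflection is derived from it so the planted multipliers shift the
    inflection — and hence every concentration metric — exactly
    multiplicatively.
    """
    n = config.n_lines
    if config.tumor_types is None:
        types = ["pan-cancer"] * n
    else:
        types = [t for t, k in config.tumor_types.items() for _ in range(k)]
    line_ids = [f"LINE{i:04d}" for i in range(n)]

    top = np.clip(rng.normal(320.0, 50.0, n), 150.0, 500.0)
    kind = rng.choice(3, size=n, p=[0.45, 0.40, 0.15])
    bottom = np.empty(n)
    for i in range(n):
        mid = (top[i] + 100.0) / 2.0
        if kind[i] == 0:  # cytotoxic
            bottom[i] = rng.uniform(0.0, 60.0)
        elif kind[i] == 1:  # cytostatic
            bottom[i] = rng.uniform(60.0, 99.0)
        else:  # partial responder: growth never fully stopped
            bottom[i] = rng.uniform(101.0, min(140.0, mid - 10.0))
    # one Hill slope per line, shared by both agents: with common asymptotes
    # this keeps every Loewe-additive mixture exactly inside the 4PL family
    # (inflection 1/(fA/IA + fB/IB)), so noise-free fits are exact
    slope = rng.uniform(0.8, 1.6, n)

    genes = list(config.mutation_freqs)
    mut_rows = []
    mut_status = {}
    for g in genes:
        calls = rng.random(n) < config.mutation_freqs[g]
        mut_status[g] = calls
        for i in np.nonzero(calls)[0]:
            mut_rows.append(
                {
                    "line_id": line_ids[i],
                    "gene": g,
                    "protein_change": _protein_change(g, rng),
                }
            )
    mutations = pd.DataFrame(mut_rows, columns=["line_id", "gene", "protein_change"])

    truth_rows = []
    for agent_idx, agent in enumerate(config.agents):
        base_gic50 = 10.0 ** rng.normal(
            config.baseline_gic50_log10_mean, config.baseline_gic50_log10_sd, n
        )
        for i in range(n):
            mult = 1.0
            if agent_idx == 0:  # resistance effect targets the primary agent
                for g, m in config.effect_multipliers.items():
                    if mut_status.get(g, np.zeros(n, bool))[i]:
                        mult *= m
            mid = (top[i] + 100.0) / 2.0
            # anchor the sampled gIC50: I = gIC50 * ((mid-bottom)/(top-mid))**(1/s)
            ratio = (mid - bottom[i]) / (top[i] - mid)
            base_infl = base_gic50[i] * ratio ** (1.0 / slope[i])
            truth_rows.append(
                {
                    "line_id": line_ids[i],
                    "tumor_type": types[i],
                    "agent": agent,
                    "bottom": bottom[i],
                    "top": top[i],
                    "baseline_inflection_nM": base_infl,
                    "multiplier": mult,
                    "inflection_nM": base_infl * mult,
                    "slope": slope[i],
                    "true_gic50_nM": base_gic50[i] * mult,
                }
            )
    truth = pd.DataFrame(truth_rows)
    lines = pd.DataFrame({"line_id": line_ids, "tumor_type": types})
    return lines, truth, mutations


def _plate_block(
    rng: np.random.Generator,
    config: PanelConfig,
    line_id: str,
    tumor_type: str,
    agent: str,
    response_fn,
    conc: np.ndarray,
    conc_a: np.ndarray | None = None,
    conc_b: np.ndarray | None = None,
) -> list[dict]:
    """Raw wells for one (line, agent) plate: T0/DMSO anchors + treated grid."""
    rows = []
    top_pct = response_fn(0.0)
    for rep in range(config.n_anchor_wells):
        rows.append(
            dict(
                line_id=line_id,
                tumor_type=tumor_type,
                agent=agent,
                conc_nM=0.0,
                conc_a_nM=np.nan,
                conc_b_nM=np.nan,
                replicate=rep + 1,
                signal=T0_SIGNAL * float(_noise(rng, config.noise_cv)),
                well_role="T0",
            )
        )
    for rep in range(config.n_anchor_wells):
        rows.append(
            dict(
                line_id=line_id,
                tumor_type=tumor_type,
                agent=agent,
                conc_nM=0.0,
                conc_a_nM=np.nan,
                conc_b_nM=np.nan,
                replicate=rep + 1,
                signal=T0_SIGNAL * top_pct / 100.0 * float(_noise(rng, config.noise_cv)),
                well_role="DMSO",
            )
        )
    for j, c in enumerate(conc):
        resp = response_fn(float(c))
        for rep in range(config.n_replicates):
            rows.append(
                dict(
                    line_id=line_id,
                    tumor_type=tumor_type,
                    agent=agent,
                    conc_nM=float(c),
                    conc_a_nM=float(conc_a[j]) if conc_a is not None else np.nan,
                    conc_b_nM=float(conc_b[j]) if conc_b is not None else np.nan,
                    replicate=rep + 1,
                    signal=T0_SIGNAL
                    * resp
                    / 100.0
                    * float(_noise(rng, config.noise_cv)),
                    well_role="treated",
                )
            )
    return rows


def synth_single_agent_panel(config: PanelConfig):
    """Generate the single-agent screen.

    Returns ``(plates, truth, mutations)``: a long-format raw well table
    (with T0 and DMSO anchor wells per plate), the ground-truth 4PL
    parameters per line x agent, and a MAF-like mutation table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lines, truth, mutations = _sample_panel(config, rng)
    grid = config.dose_grid()
    rows = []
    for _, tr in truth.iterrows():
        curve = FourPLCurve(tr.bottom, tr.top, tr.inflection_nM, tr.slope)

        def resp(c, curve=curve):
            return float(curve.predict(c)) if c > 0 else curve.top

        rows.extend(
            _plate_block(
                rng, config, tr.line_id, tr.tumor_type, tr.agent, resp, grid
            )
        )
    plates = pd.DataFrame(rows)
    return plates, truth, mutations


def loewe_mixture_response(
    curve_a: FourPLCurve,
    curve_b: FourPLCurve,
    fraction_a: float,
    fraction_b: float,
    total_dose: float,
    psi: float = 1.0,
) -> float:
    """Response of a fixed-ratio mixture built by Loewe dose equivalence.

    Solves the dose-equivalence identity at effect level ``y``::

        fraction_a * D / DxA(y) + fraction_b * D / DxB(y) = psi

    where ``DxA``/``DxB`` are the single-agent doses producing ``y``
    (infinite when ``y`` is outside that agent's asymptotes, so the term
    vanishes). ``psi`` < 1 inflates the equivalent dose by ``1/psi``
    (synergistic potency gain); ``psi`` = 1 is exactly Loewe-additive. The
    root is found by scalar bracketing to ~1e-12 relative.
    """
    ca = curve_a.canonicalized()
    cb = curve_b.canonicalized()
    if total_dose <= 0:
        return float(min(ca.top, cb.top))
    ceil_y = min(ca.top, cb.top)
    floor_y = min(ca.bottom, cb.bottom)
    span = ceil_y - floor_y
    if span <= 0:
        return float(ceil_y)

    def dx(curve, y):
        mv = invert_4pl(curve, y, max_conc=None)
        return mv.value if not mv.is_censored else None

    def h(y):
        s = 0.0
        for curve, f in ((ca, fraction_a), (cb, fraction_b)):
            d = dx(curve, y)
            if d is not None and d > 0:
                s += f * total_dose / d
        return s - psi

    lo = floor_y + 1e-12 * span
    hi = ceil_y - 1e-12 * span
    if h(hi) <= 0:  # dose too small to move off the top plateau
        return float(ceil_y)
    if h(lo) >= 0:  # dose saturating: response at the floor
        return float(floor_y)
    y = brentq(h, lo, hi, xtol=1e-13 * span, rtol=8.9e-16, maxiter=200)
    return float(y)


def synth_combination_plates(
    config: PanelConfig,
    combo: ComboConfig,
    lines: Sequence[str] | None = None,
):
    """Generate fixed-ratio combination plates: A alone, B alone, A+B.

    ``config.agents`` must name exactly two agents; the same panel seed
    reproduces the same per-line ground-truth curves as the single-agent
    generator. Mixture concentrations are total doses on the panel's dose
    grid, with per-component concentrations recorded. Returns
    ``(plates, truth)``.
    """
    config.validate()
    combo.validate()
    if len(config.agents) != 2:
        raise ConfigError("agents: combination plates need exactly two agents")
    rng = np.random.default_rng(config.seed)
    _, truth, _ = _sample_panel(config, rng)
    if lines is not None:
        truth = truth[truth.line_id.isin(set(lines))]
    grid = config.dose_grid()
    fa, fb = combo.fraction_a, combo.fraction_b
    agent_a, agent_b = config.agents
    mix_label = f"{agent_a}+{agent_b}"
    noise_rng = np.random.default_rng(combo.seed)

    rows = []
    for line_id, sub in truth.groupby("line_id", sort=True):
        by_agent = {tr.agent: tr for tr in sub.itertuples()}
        curves = {
            a: FourPLCurve(t.bottom, t.top, t.inflection_nM, t.slope)
            for a, t in by_agent.items()
        }
        tumor_type = sub.tumor_type.iloc[0]
        for agent in (agent_a, agent_b):
            curve = curves[agent]

            def resp_single(c, curve=curve):
                return float(curve.predict(c)) if c > 0 else curve.top

            rows.extend(
                _plate_block(
                    noise_rng, config, line_id, tumor_type, agent, resp_single, grid
                )
            )

        def resp_mix(c):
            return loewe_mixture_response(
                curves[agent_a], curves[agent_b], fa, fb, c, combo.psi
            )

        rows.extend(
            _plate_block(
                noise_rng,
                config,
                line_id,
                tumor_type,
                mix_label,
                resp_mix,
                grid,
                conc_a=fa * grid,
                conc_b=fb * grid,
            )
        )
    plates = pd.DataFrame(rows)
    plates["duration_days"] = combo.duration_days
    return plates, truth


def synth_xenograft(config: XenoConfig) -> pd.DataFrame:
    """Per-animal tumor-volume series under exponential growth.

    Volumes follow ``V(t) = V0 * exp(rate * t)`` with multiplicative
    measurement noise, measured every ``measurement_interval_days`` from
    randomization (day 0) until the first measurement at or above the
    endpoint volume, or ``max_study_day`` (right-censored).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    aid = 0
    for group in config.growth_rate_per_day:
        rate = config.growth_rate_per_day[group]
        for _ in range(config.n_per_group):
            aid += 1
            v0 = rng.uniform(*config.v0_mm3)
            animal = f"A{aid:03d}"
            day = 0.0
            while day <= config.max_study_day + 1e-9:
                v = v0 * math.exp(rate * day) * float(_noise(rng, config.noise_cv))
                rows.append(
                    dict(
                        animal_id=animal,
                        group=group,
                        day=day,
                        volume_mm3=v,
                    )
                )
                if v >= config.endpoint_volume_mm3:
                    break
                day += config.measurement_interval_days
    return pd.DataFrame(rows)
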