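"""End-to-end analysis stages chaining the core modules.

These functions consume the long-format plate/volume tables (either from
the synthetic generator or from user data in the same layout) and produce
the screen's result tables: per-line growth metrics, biomarker association
tables, combination-synergy calls, and in-vivo efficacy comparisons.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .biomarkers import (
    MutationMatrix,
    resolve_censored_potency,
    screen_all_markers,
)
from .doseresponse import (
    AnchorError,
    GrowthMetrics,
    fit_4pl,
    growth_metrics,
    normalize_to_t0,
)
from .invivo import EfficacyStudy, TTERecord, compute_tte, km_curve_data, logrank_test
from .invivo import percent_tgd, tumor_growth_inhibition
from .synergy import FixedRatioDesign, SynergyRule, analyze_combination

logger = logging.getLogger("synscreen")

__all__ = [
    "normalize_block",
    "fit_panel",
    "run_screen",
    "run_combo",
    "run_invivo",
]


def normalize_block(block: pd.DataFrame):
    """NormalizedCurveData from one (line, agent) block of raw wells."""
    t0 = block.loc[block.well_role == "T0", "signal"].to_numpy()
    dmso = block.loc[block.well_role == "DMSO", "signal"].to_numpy()
    treated = block[block.well_role == "treated"]
    return normalize_to_t0(
        treated["conc_nM"].to_numpy(), treated["signal"].to_numpy(), t0, dmso
    )


def _metric_cols(prefix: str, mv) -> dict:
    return {
        f"{prefix}_nM": mv.value if mv.value is not None else np.nan,
        f"{prefix}_censor": mv.censor or "",
    }


def _metrics_row(m: GrowthMetrics) -> dict:
    row = {}
    row.update(_metric_cols("gic50", m.gic50))
    row.update(_metric_cols("gic100", m.gic100))
    row.update(_metric_cols("dec50", m.dec50))
    row["ymin_minus_t0"] = m.ymin_minus_t0
    row["dmso_level"] = m.dmso_level
    row["max_tested_conc_nM"] = m.max_tested_conc
    return row


def fit_panel(plates: pd.DataFrame) -> pd.DataFrame:
    """Normalize, fit, and extract growth metrics for every (line, agent).

    Plates missing anchor wells are skipped with a warning and counted in
    ``.attrs['n_skipped']``.
    """
    rows = []
    skipped = 0
    for (line_id, agent), block in plates.groupby(["line_id", "agent"], sort=True):
        try:
            data = normalize_block(block)
        except AnchorError as exc:
            warnings.warn(f"{line_id}/{agent}: {exc}; skipped")
            skipped += 1
            continue
        fit = fit_4pl(data)
        m = growth_metrics(fit, data)
        row = dict(
            line_id=line_id,
            tumor_type=block["tumor_type"].iloc[0],
            agent=agent,
            bottom=fit.curve.bottom if fit.curve else np.nan,
            top=fit.curve.top if fit.curve else np.nan,
            inflection_nM=fit.curve.inflection if fit.curve else np.nan,
            slope=fit.curve.slope if fit.curve else np.nan,
            rss=fit.rss,
            converged=fit.converged,
            degenerate=fit.degenerate,
        )
        row.update(_metrics_row(m))
        logger.debug("fit %s/%s rss=%.3g", line_id, agent, fit.rss)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = skipped
    logger.info("fit_panel: %d plates fitted, %d skipped", len(out), skipped)
    return out


def run_screen(
    plates: pd.DataFrame,
    mutations: pd.DataFrame,
    min_mutants: int = 1,
    agent: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-agent screen: growth metrics + biomarker association table."""
    metrics = fit_panel(plates)
    if agent is not None:
        metrics = metrics[metrics.agent == agent]
    metrics = metrics.set_index("line_id")
    matrix = MutationMatrix.from_maf(mutations, list(metrics.index))
    potency = resolve_censored_potency(metrics)["log10_gic50"]
    assoc = screen_all_markers(matrix, potency, min_mutants=min_mutants)
    return metrics.reset_index(), assoc


def _design_from_mix(mix_block: pd.DataFrame, agent_a: str, agent_b: str):
    treated = mix_block[(mix_block.well_role == "treated") & (mix_block.conc_nM > 0)]
    fa = float((treated["conc_a_nM"] / treated["conc_nM"]).iloc[0])
    fb = float((treated["conc_b_nM"] / treated["conc_nM"]).iloc[0])
    return FixedRatioDesign(agent_a, agent_b, fa, fb)


def run_combo(
    plates: pd.DataFrame, rule: SynergyRule = SynergyRule()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combination screen over a plate table holding A, B, and A+B blocks.

    Returns the per-line result table (with every per-level intermediate
    for audit) and a heat-map-ready line x pair call matrix.
    """
    mix_labels = [a for a in plates.agent.unique() if "+" in a]
    if len(mix_labels) != 1:
        raise ValueError("expected exactly one mixture block (agent label 'A+B')")
    mix_label = mix_labels[0]
    agent_a, agent_b = mix_label.split("+", 1)
    rows = []
    for line_id, block in plates.groupby("line_id", sort=True):
        data = {}
        for label in (agent_a, agent_b, mix_label):
            data[label] = normalize_block(block[block.agent == label])
        design = _design_from_mix(block[block.agent == mix_label], agent_a, agent_b)
        res = analyze_combination(
            data[agent_a], data[agent_b], data[mix_label], design, rule
        )
        row = dict(
            line_id=line_id,
            pair=mix_label,
            summary_ci=res.summary_ci,
            call=res.call,
            reason=res.reason or "",
        )
        for name in ("gic50", "gic100", "dec50"):
            lv = res.levels.get(name)
            row[f"ci_{name}"] = lv.ci if lv else np.nan
            row[f"d_total_{name}"] = lv.d_total if lv else np.nan
            row[f"dx1_{name}"] = lv.dx1 if lv and lv.dx1 is not None else np.nan
            row[f"dx2_{name}"] = lv.dx2 if lv and lv.dx2 is not None else np.nan
            row[f"fold_a_{name}"] = (
                lv.fold_shift_a if lv and lv.fold_shift_a is not None else np.nan
            )
            row[f"fold_b_{name}"] = (
                lv.fold_shift_b if lv and lv.fold_shift_b is not None else np.nan
            )
            row[f"flag_{name}"] = bool(lv.monotherapy_incapable) if lv else False
        rows.append(row)
    results = pd.DataFrame(rows)
    call_matrix = results.pivot(index="line_id", columns="pair", values="call")
    return results, call_matrix.reset_index()


def run_invivo(
    volumes: pd.DataFrame,
    endpoint_volume: float,
    final_study_day: float,
    control_group: str = "vehicle",
    tgi_day: float | None = None,
) -> dict[str, pd.DataFrame]:
    """In-vivo efficacy analysis versus a control arm.

    Returns the per-animal TTE table, a per-group comparison table
    (%TGD, log-rank chi-square and p, optionally TGI at ``tgi_day`` with a
    Mann-Whitney p), and Kaplan-Meier step coordinates.
    """
    study = EfficacyStudy(volumes, endpoint_volume, final_study_day)
    tte = compute_tte(study)
    if control_group not in set(tte.group):
        raise ValueError(f"control group '{control_group}' not in study")

    def records(g):
        sub = tte[tte.group == g]
        return [
            TTERecord(r.animal_id, r.tte, bool(r.event)) for r in sub.itertuples()
        ]

    ctrl = records(control_group)
    comp_rows = []
    for group in study.groups():
        if group == control_group:
            continue
        arm = records(group)
        tgd, censored_median = percent_tgd(arm, ctrl)
        chi2, p = logrank_test(arm, ctrl)
        row = dict(
            group=group,
            control=control_group,
            median_tte=float(np.median([r.tte for r in arm])),
            median_tte_control=float(np.median([r.tte for r in ctrl])),
            pct_tgd=tgd,
            censored_in_median=censored_median,
            logrank_chi2=chi2,
            logrank_p=p,
        )
        if tgi_day is not None:
            day_t = volumes[(volumes.group == group) & (volumes.day == tgi_day)]
            day_c = volumes[
                (volumes.group == control_group) & (volumes.day == tgi_day)
            ]
            base_t = volumes[(volumes.group == group) & (volumes.day == 0)]
            base_c = volumes[(volumes.group == control_group) & (volumes.day == 0)]
            if len(day_t) and len(day_c):
                day_t = day_t.set_index("animal_id")["volume_mm3"]
                day_c = day_c.set_index("animal_id")["volume_mm3"]
                base_t = base_t.set_index("animal_id")["volume_mm3"].reindex(
                    day_t.index
                )
                base_c = base_c.set_index("animal_id")["volume_mm3"].reindex(
                    day_c.index
                )
                tgi, mw_p = tumor_growth_inhibition(day_t, day_c, base_t, base_c)
                row["tgi_pct"] = tgi if tgi is not None else np.nan
                row["tgi_mannwhitney_p"] = mw_p
        comp_rows.append(row)
    return {
        "tte": tte,
        "comparisons": pd.DataFrame(comp_rows),
        "km": km_curve_data(tte),
    }
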