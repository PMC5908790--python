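"""Mutation-vs-potency association and phenotype enrichment statistics.

Gene-level (any protein-changing mutation) and residue-level (e.g. KRAS_G12)
binary markers are screened against log10-transformed gIC50 values with a
two-sided Wilcoxon rank-sum test; right-censored potencies enter at their
maximum tested concentration (a conservative lower bound, matching the
"> max" reporting convention). Binary phenotypes (net cell death, synergy
call, RAS-pathway mutation) are cross-tabulated with Fisher's exact test.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MutationMatrix",
    "AssociationRecord",
    "Enrichment2x2",
    "rank_sum_test",
    "resolve_censored_potency",
    "wilcoxon_marker_test",
    "screen_all_markers",
    "enrichment_2x2",
    "build_binary_phenotypes",
    "RAS_PATHWAY_GENES",
]

RAS_PATHWAY_GENES = frozenset({"KRAS", "NRAS", "HRAS", "BRAF", "NF1"})

# missense-like protein change: reference residue + position (alt optional)
_RESIDUE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)(?!_)")


@dataclass(frozen=True)
class MutationMatrix:
    """Cell line x marker binary mutation calls.

    ``calls``: lines x genes 0/1 matrix (any protein-changing mutation).
    ``residue_groups``: lines x gene_residue 0/1 matrix derived from
    missense-style protein-change strings ("G12D" -> KRAS_G12); frameshift
    and splice notations contribute to the gene level only.
    """

    calls: pd.DataFrame
    residue_groups: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def lines(self) -> pd.Index:
        return self.calls.index

    @property
    def genes(self) -> pd.Index:
        return self.calls.columns

    def markers(self) -> pd.DataFrame:
        """All binary marker columns: genes first, then residue groups."""
        return pd.concat([self.calls, self.residue_groups], axis=1)

    @classmethod
    def from_maf(cls, maf: pd.DataFrame, lines: list[str] | pd.Index) -> "MutationMatrix":
        """Build from a MAF-like table (line_id, gene, protein_change)."""
        idx = pd.Index(lines, name="line_id")
        genes = sorted(maf["gene"].unique()) if len(maf) else []
        calls = pd.DataFrame(0, index=idx, columns=pd.Index(genes), dtype=int)
        residues: dict[str, set] = {}
        for row in maf.itertuples():
            if row.line_id not in calls.index:
                continue
            calls.loc[row.line_id, row.gene] = 1
            pc = str(row.protein_change)
            m = _RESIDUE_RE.match(pc)
            if m and not pc.endswith("fs") and "splice" not in pc:
                key = f"{row.gene}_{m.group(1)}{m.group(2)}"
                residues.setdefault(key, set()).add(row.line_id)
        res = pd.DataFrame(0, index=idx, columns=pd.Index(sorted(residues)), dtype=int)
        for key, members in residues.items():
            res.loc[sorted(members), key] = 1
        return cls(calls, res, maf.copy())


@dataclass(frozen=True)
class AssociationRecord:
    marker: str
    n_mut: int
    n_wt: int
    median_log10_mut: float
    median_log10_wt: float
    median_nM_mut: float
    median_nM_wt: float
    direction: str
    p_value: float


@dataclass(frozen=True)
class Enrichment2x2:
    table: np.ndarray
    odds_ratio: float
    p_value: float


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when the combined sample size is <= 20 with no
    ties; otherwise the normal approximation with continuity and tie
    correction. Perfectly balanced ranks (U equal to its null mean, e.g.
    identical multisets) give p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    n = pooled.size
    ties = np.unique(pooled).size < n
    method = "exact" if (n <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    if method == "asymptotic" and abs(res.statistic - x.size * y.size / 2.0) < 1e-12:
        return 1.0
    return float(min(res.pvalue, 1.0))


def resolve_censored_potency(
    metrics: pd.DataFrame,
    value_col: str = "gic50_nM",
    censor_col: str = "gic50_censor",
    max_col: str = "max_tested_conc_nM",
) -> pd.DataFrame:
    """Numeric log10 potencies with censored values substituted.

    Censored gIC50s are replaced by the maximum tested concentration (a
    conservative lower bound on the true value, so ranks are preserved at
    worst conservatively); substitutions are flagged. Lines with neither a
    value nor a bound are dropped with a warning.
    """
    out = []
    dropped = []
    for line_id, row in metrics.iterrows():
        kind = row.get(censor_col)
        censored = isinstance(kind, str) and kind != ""
        val = row.get(value_col)
        if censored or pd.isna(val):
            # ">max"-censored rows already carry the bound in the value
            # column; otherwise fall back to the max tested concentration
            if pd.isna(val):
                val = row.get(max_col)
            if pd.isna(val):
                dropped.append(line_id)
                continue
            out.append((line_id, np.log10(float(val)), True))
        else:
            out.append((line_id, np.log10(float(val)), False))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} lines lacking gIC50 value and bound")
    return pd.DataFrame(
        out, columns=["line_id", "log10_gic50", "substituted"]
    ).set_index("line_id")


def wilcoxon_marker_test(marker: pd.Series, log10_potency: pd.Series) -> AssociationRecord:
    """Association of one binary marker with log10 potency."""
    marker, pot = marker.align(log10_potency, join="inner")
    mut = pot[marker.astype(bool)].to_numpy()
    wt = pot[~marker.astype(bool)].to_numpy()
    if mut.size == 0 or wt.size == 0:
        raise ValueError("marker must split lines into nonempty groups")
    p = rank_sum_test(mut, wt)
    mm, mw = float(np.median(mut)), float(np.median(wt))
    if mm > mw:
        direction = "resistance"
    elif mm < mw:
        direction = "sensitivity"
    else:
        direction = "none"
    return AssociationRecord(
        str(marker.name),
        int(mut.size),
        int(wt.size),
        mm,
        mw,
        float(10.0**mm),
        float(10.0**mw),
        direction,
        p,
    )


def screen_all_markers(
    matrix: MutationMatrix,
    log10_potency: pd.Series,
    min_mutants: int = 1,
) -> pd.DataFrame:
    """Screen every gene- and residue-level marker against potency.

    Returns a table sorted by ascending p with the unadjusted p < 0.05
    significance column and Benjamini-Hochberg q-values alongside. Markers
    with fewer than ``min_mutants`` mutant or zero wild-type lines are
    skipped (count in ``.attrs['n_skipped']``).
    """
    markers = matrix.markers()
    markers, pot = markers.align(log10_potency, join="inner", axis=0)
    records = []
    skipped = 0
    for name in markers.columns:
        col = markers[name]
        n_mut = int(col.sum())
        if n_mut < min_mutants or n_mut == len(col):
            skipped += 1
            continue
        records.append(wilcoxon_marker_test(col, pot))
    columns = [f.name for f in dataclasses.fields(AssociationRecord)]
    df = pd.DataFrame([r.__dict__ for r in records], columns=columns)
    df["significant_p05"] = df["p_value"] < 0.05
    df["q_value"] = np.nan
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    df.attrs["n_skipped"] = skipped
    return df


def enrichment_2x2(x, y) -> Enrichment2x2:
    """Fisher's exact test between two paired binary traits.

    The two-sided p sums hypergeometric probabilities no larger than the
    observed table's; the point estimate is the sample odds ratio with a
    Haldane 0.5 correction when any cell is empty. Degenerate margins
    (a trait constant) give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("traits must be paired")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    table = np.array([[a, b], [c, d]])
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 margin; enrichment test uninformative")
        return Enrichment2x2(table, float("nan"), 1.0)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return Enrichment2x2(table, float(orr), min(p, 1.0))


def build_binary_phenotypes(
    metrics: pd.DataFrame,
    synergy_calls: pd.Series | None,
    matrix: MutationMatrix | None = None,
    ras_genes=RAS_PATHWAY_GENES,
) -> pd.DataFrame:
    """Binary per-line phenotypes for enrichment analyses.

    ``net_death`` — fitted-curve minimum fell below T0 (ymin - T0 < 0);
    ``synergy`` — combination call synergistic or stronger;
    ``ras_pathway_mut`` — any protein-changing mutation in a RAS-family
    gene, BRAF, or NF1.
    """
    out = pd.DataFrame(index=metrics.index)
    out["net_death"] = metrics["ymin_minus_t0"] < 0
    if synergy_calls is not None:
        calls = synergy_calls.reindex(metrics.index)
        out["synergy"] = calls.isin(["synergistic", "strongly_synergistic"])
    if matrix is not None:
        present = [g for g in ras_genes if g in matrix.calls.columns]
        ras = (
            matrix.calls[present].sum(axis=1).astype(bool)
            if present
            else pd.Series(False, index=matrix.lines)
        )
        out["ras_pathway_mut"] = ras.reindex(metrics.index).fillna(False)
    return out
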