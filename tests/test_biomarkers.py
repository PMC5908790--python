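import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synscreen.biomarkers import (
    MutationMatrix,
    build_binary_phenotypes,
    enrichment_2x2,
    rank_sum_test,
    resolve_censored_potency,
    screen_all_markers,
    wilcoxon_marker_test,
)


def ranksum_enumeration_p(x, y):
    """Independent oracle: exact two-sided rank-sum p by full enumeration."""
    pooled = sorted(list(x) + list(y))
    n1, n = len(x), len(x) + len(y)
    obs = sum(pooled.index(v) + 1 for v in x)
    mean = n1 * (n + 1) / 2.0
    dev = abs(obs - mean)
    dist = [sum(c) for c in itertools.combinations(range(1, n + 1), n1)]
    return sum(1 for s in dist if abs(s - mean) >= dev - 1e-9) / len(dist)


def fisher_enumeration_p(a, b, c, d):
    """Independent oracle: sum hypergeometric probs <= observed table's."""
    n1, n0, m1 = a + b, c + d, a + c
    N = n1 + n0

    def prob(k):
        return math.comb(n1, k) * math.comb(n0, m1 - k) / math.comb(N, m1)

    p_obs = prob(a)
    lo, hi = max(0, m1 - n0), min(n1, m1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestRankSum:
    def test_worked_example(self):
        # mut {3,4,5} vs wt {1,2}: most extreme of C(5,3)=10 splits, doubled
        assert rank_sum_test([3.0, 4.0, 5.0], [1.0, 2.0]) == pytest.approx(0.2)

    def test_identical_multisets_give_p_one(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_constant_vector_gives_p_one(self):
        assert rank_sum_test([5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_enumeration_for_sampled_partitions(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            n1 = int(rng.integers(1, n))
            vals = rng.permutation(np.arange(1.0, n + 1))
            x, y = vals[:n1], vals[n1:]
            assert rank_sum_test(x, y) == pytest.approx(
                ranksum_enumeration_p(list(x), list(y)), abs=1e-12
            )


class TestResolveCensoredPotency:
    def _metrics(self):
        return pd.DataFrame(
            {
                "gic50_nM": [550.0, 29300.0, np.nan, np.nan],
                "gic50_censor": ["", ">max", "unreachable", ""],
                "max_tested_conc_nM": [29300.0, 29300.0, 29300.0, np.nan],
            },
            index=pd.Index(["L1", "L2", "L3", "L4"], name="line_id"),
        )

    def test_substitution_policy(self):
        with pytest.warns(UserWarning, match="dropped 1 lines"):
            out = resolve_censored_potency(self._metrics())
        assert out.loc["L1", "log10_gic50"] == pytest.approx(np.log10(550.0))
        assert not out.loc["L1", "substituted"]
        assert out.loc["L2", "log10_gic50"] == pytest.approx(4.4669, abs=1e-3)
        assert out.loc["L2", "substituted"]
        assert out.loc["L3", "log10_gic50"] == pytest.approx(np.log10(29300.0))
        assert "L4" not in out.index

    def test_all_lines_censored_at_same_bound_gives_p_one(self):
        pot = pd.Series(np.log10(29300.0), index=[f"L{i}" for i in range(10)])
        marker = pd.Series([1] * 4 + [0] * 6, index=pot.index, name="G")
        rec = wilcoxon_marker_test(marker, pot)
        assert rec.p_value == 1.0


class TestMutationMatrix:
    def _maf(self):
        return pd.DataFrame(
            {
                "line_id": ["L1", "L2", "L3", "L3"],
                "gene": ["KRAS", "KRAS", "NF1", "TP53"],
                "protein_change": ["G12D", "G12V", "X123_splice", "R175fs"],
            }
        )

    def test_residue_groups_from_missense(self):
        m = MutationMatrix.from_maf(self._maf(), ["L1", "L2", "L3", "L4"])
        assert "KRAS_G12" in m.residue_groups.columns
        assert m.residue_groups["KRAS_G12"].sum() == 2
        assert m.calls.loc["L1", "KRAS"] == 1

    def test_splice_and_frameshift_fall_back_to_gene_level(self):
        m = MutationMatrix.from_maf(self._maf(), ["L1", "L2", "L3"])
        assert m.calls.loc["L3", "NF1"] == 1
        assert not any(col.startswith("NF1_") for col in m.residue_groups.columns)
        assert not any(col.startswith("TP53_") for col in m.residue_groups.columns)

    def test_residue_marker_implies_gene_marker(self):
        m = MutationMatrix.from_maf(self._maf(), ["L1", "L2", "L3"])
        for col in m.residue_groups.columns:
            gene = col.split("_")[0]
            carriers = m.residue_groups[col] == 1
            assert (m.calls.loc[carriers, gene] == 1).all()


class TestScreenAllMarkers:
    def _screen_inputs(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        lines = [f"L{i}" for i in range(n)]
        pot = pd.Series(rng.normal(2.7, 0.5, n), index=lines)
        maf_rows = []
        for g, freq in [("KRAS", 0.4), ("TP53", 0.5), ("APC", 0.3)]:
            for i in np.nonzero(rng.random(n) < freq)[0]:
                maf_rows.append((lines[i], g, "G12D"))
        maf = pd.DataFrame(maf_rows, columns=["line_id", "gene", "protein_change"])
        return MutationMatrix.from_maf(maf, lines), pot

    def test_no_mutations_gives_empty_table(self):
        maf = pd.DataFrame(columns=["line_id", "gene", "protein_change"])
        m = MutationMatrix.from_maf(maf, ["L1", "L2"])
        out = screen_all_markers(m, pd.Series([1.0, 2.0], index=["L1", "L2"]))
        assert len(out) == 0

    def test_invariant_to_line_and_marker_order(self):
        matrix, pot = self._screen_inputs()
        base = screen_all_markers(matrix, pot)
        perm = np.random.default_rng(3).permutation(len(pot))
        matrix2 = MutationMatrix(
            matrix.calls.iloc[perm, ::-1],
            matrix.residue_groups.iloc[perm],
            matrix.annotations,
        )
        shuffled = screen_all_markers(matrix2, pot.iloc[perm])
        a = base.set_index("marker")[["n_mut", "p_value", "q_value"]].sort_index()
        b = shuffled.set_index("marker")[["n_mut", "p_value", "q_value"]].sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_planted_resistance_marker_is_top_ranked(self):
        from synscreen.simulate import PanelConfig, synth_single_agent_panel
        from synscreen.workflows import run_screen

        cfg = PanelConfig(
            n_lines=120,
            noise_cv=0.02,
            mutation_freqs={"KRAS": 0.25, "TP53": 0.45, "APC": 0.2, "NF1": 0.1},
            effect_multipliers={"KRAS": 3.0},
            seed=77,
        )
        plates, _, muts = synth_single_agent_panel(cfg)
        _, assoc = run_screen(plates, muts)
        genes = assoc[~assoc.marker.str.contains("_")].reset_index(drop=True)
        assert genes.marker.iloc[0] == "KRAS"
        assert genes.direction.iloc[0] == "resistance"
        assert genes.p_value.iloc[0] < 0.05

    def test_null_p_values_stochastically_above_uniform(self):
        # 200 null markers: one-sided KS must not reject "p >= uniform"
        rng = np.random.default_rng(5)
        n = 200
        lines = [f"L{i}" for i in range(n)]
        pot = pd.Series(rng.normal(2.7, 0.7, n), index=lines)
        pvals = []
        for _ in range(200):
            marker = pd.Series(rng.random(n) < 0.3, index=lines, name="M")
            if 0 < marker.sum() < n:
                pvals.append(rank_sum_test(pot[marker], pot[~marker]))
        res = stats.ks_1samp(pvals, stats.uniform.cdf, alternative="greater")
        assert res.pvalue > 0.01


class TestEnrichment2x2:
    def test_diagonal_table_matches_enumeration(self):
        res = enrichment_2x2([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert res.p_value == pytest.approx(2.0 / 252.0)

    def test_balanced_table_is_null(self):
        x = [1, 1, 1, 1, 0, 0, 0, 0]
        y = [1, 1, 0, 0, 1, 1, 0, 0]
        res = enrichment_2x2(x, y)
        assert res.p_value == 1.0
        assert res.odds_ratio == pytest.approx(1.0)

    def test_degenerate_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = enrichment_2x2([1, 1, 1], [1, 0, 1])
        assert res.p_value == 1.0

    def test_haldane_correction_on_zero_cell(self):
        res = enrichment_2x2([1, 1, 0, 0], [1, 1, 1, 0])
        a, b, c, d = 2, 0, 1, 1
        assert res.odds_ratio == pytest.approx(
            (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        )

    @pytest.mark.parametrize("total", [8, 14, 22, 30])
    def test_matches_hypergeometric_enumeration(self, total):
        rng = np.random.default_rng(total)
        tested = 0
        while tested < 40:
            a, b, c, d = rng.multinomial(total, [0.25] * 4)
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                continue
            x = [1] * (a + b) + [0] * (c + d)
            y = [1] * a + [0] * b + [1] * c + [0] * d
            res = enrichment_2x2(x, y)
            assert res.p_value == pytest.approx(
                fisher_enumeration_p(a, b, c, d), abs=1e-9
            )
            tested += 1

    def test_exact_test_type_i_error_is_conservative(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_tables = 1000
        for _ in range(n_tables):
            x = rng.random(24) < 0.5
            y = rng.random(24) < 0.4  # independent traits
            if min(x.sum(), (~x).sum()) == 0 or min(y.sum(), (~y).sum()) == 0:
                continue
            if enrichment_2x2(x, y).p_value < 0.05:
                rejections += 1
        assert rejections / n_tables <= 0.05


class TestBinaryPhenotypes:
    def test_sign_rules_and_ras_pathway(self):
        metrics = pd.DataFrame(
            {"ymin_minus_t0": [-12.0, 30.0, 5.0]},
            index=pd.Index(["L1", "L2", "L3"], name="line_id"),
        )
        calls = pd.Series(
            ["synergistic", "additive", "strongly_synergistic"],
            index=metrics.index,
        )
        maf = pd.DataFrame(
            {"line_id": ["L2"], "gene": ["NF1"], "protein_change": ["D2184G"]}
        )
        matrix = MutationMatrix.from_maf(maf, list(metrics.index))
        ph = build_binary_phenotypes(metrics, calls, matrix)
        assert ph.net_death.tolist() == [True, False, False]
        assert ph.synergy.tolist() == [True, False, True]
        assert ph.ras_pathway_mut.tolist() == [False, True, False]
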