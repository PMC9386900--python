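import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lemnomics.dge import (
    DegSet,
    call_degs,
    compare_compounds,
    compute_lfcut,
    core_set,
    direction_summary,
    overlap_percent,
    pearson,
    quadrant_concordance,
    read_dge_table,
    recovery_percent,
    select_top_expressed,
)
from lemnomics.synthetic import make_dge_tables


def table(genes, lfc_raw, lfc_shrunk, padj, mean=10.0):
    n = len(genes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "mean_expression": [mean] * n,
            "lfc_raw": lfc_raw,
            "lfc_shrunk": lfc_shrunk,
            "pvalue": padj,
            "padj": padj,
        }
    )


class TestLfcut:
    def test_linear_interpolation_order_statistics(self):
        assert compute_lfcut([1, 2, 3, 4]) == pytest.approx(3.25)

    def test_constant_vector(self):
        assert compute_lfcut([2.0] * 8) == 2.0

    def test_missing_values_dropped(self):
        assert compute_lfcut([1, 2, np.nan, 3, 4, np.nan]) == pytest.approx(3.25)

    def test_sign_is_ignored(self):
        assert compute_lfcut([-1, 2, -3, 4]) == pytest.approx(3.25)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            compute_lfcut([np.nan, np.nan])
        with pytest.raises(ValueError):
            compute_lfcut([1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-20, 20), min_size=4, max_size=60),
        st.floats(0.01, 50),
    )
    def test_positive_scaling_equivariance(self, values, c):
        assert compute_lfcut([c * v for v in values]) == pytest.approx(
            c * compute_lfcut(values), rel=1e-9, abs=1e-12
        )


class TestCallDegs:
    def _table(self):
        # LFcut = 0.75-quantile of |raw| = 1.75 over [1,2,1,1]... construct explicitly
        return table(
            ["a", "b", "c", "d"],
            lfc_raw=[1.0, 2.0, 3.0, 4.0],  # LFcut = 3.25
            lfc_shrunk=[0.5, 3.5, -3.5, 3.0],
            padj=[0.04, 0.04, 0.04, 0.04],
        )

    def test_dual_criterion(self):
        degs = call_degs(self._table())
        assert degs.lfcut == pytest.approx(3.25)
        assert degs.genes == {"b": "up", "c": "down"}

    def test_padj_above_alpha_excluded(self):
        t = self._table()
        t.loc[1, "padj"] = 0.06
        assert "b" not in call_degs(t).genes

    def test_missing_padj_never_deg(self):
        t = self._table()
        t.loc[1, "padj"] = np.nan
        assert "b" not in call_degs(t).genes

    def test_deg_set_shrinks_with_alpha(self):
        rng = np.random.default_rng(0)
        t = table(
            [f"g{i}" for i in range(50)],
            lfc_raw=rng.normal(0, 2, 50),
            lfc_shrunk=rng.normal(0, 2, 50),
            padj=rng.uniform(0, 0.2, 50),
        )
        for lo, hi in [(0.01, 0.05), (0.05, 0.1)]:
            assert call_degs(t, alpha=lo).gene_ids <= call_degs(t, alpha=hi).gene_ids

    def test_planted_strong_degs_recovered(self):
        tables, truth = make_dge_tables(n_genes=1000, n_de=100, effect_lfc=2.0, seed=5)
        degs = call_degs(tables["rna_ec5"])
        planted = {g for g, s in truth.de_status.items() if s != "null"}
        recall = len(degs.gene_ids & planted) / len(planted)
        assert recall >= 0.9

    def test_false_discovery_proportion_controlled(self):
        """Planted-truth FDP among called DEGs stays below 2*alpha."""
        fdps = []
        for seed in range(20):
            tables, truth = make_dge_tables(n_genes=1000, n_de=100, seed=seed)
            degs = call_degs(tables["rna_ec5"], alpha=0.05)
            if len(degs) == 0:
                continue
            false = sum(1 for g in degs.gene_ids if truth.de_status[g] == "null")
            fdps.append(false / len(degs))
        assert np.mean(fdps) <= 0.1


class TestDirectionSummary:
    def test_counts_and_percentages(self):
        degs = DegSet("x", 1.0, {"a": "up", "b": "up", "c": "up", "d": "down"})
        assert direction_summary(degs) == (3, 1, 75, 25)

    def test_all_up(self):
        degs = DegSet("x", 1.0, {"a": "up", "b": "up"})
        assert direction_summary(degs) == (2, 0, 100, 0)

    def test_empty(self):
        assert direction_summary(DegSet("x", 1.0, {})) == (0, 0, 0, 0)

    def test_planted_asymmetry_recovered(self):
        tables, _ = make_dge_tables(n_genes=500, n_de=100, frac_up=0.25, seed=9)
        d = direction_summary(call_degs(tables["rna_ec5"]))
        assert d.pct_down > d.pct_up


class TestCoreSet:
    def test_intersection_and_shares(self):
        a = DegSet("EC5", 1, {g: "up" for g in ("g1", "g2", "g3")})
        b = DegSet("EC20", 1, {g: "up" for g in ("g2", "g3", "g4")})
        core = core_set(a, b)
        assert core.genes == {"g2", "g3"}
        assert core.pct_of_low == 67

    def test_disjoint(self):
        a = DegSet("EC5", 1, {"g1": "up"})
        b = DegSet("EC20", 1, {"g2": "up"})
        core = core_set(a, b)
        assert core.genes == set() and core.pct_of_low == 0

    def test_symmetric_intersection(self):
        a = DegSet("EC5", 1, {g: "up" for g in ("g1", "g2")})
        b = DegSet("EC20", 1, {g: "up" for g in ("g2", "g3")})
        assert core_set(a, b).genes == core_set(b, a).genes
        assert len(core_set(a, b).genes) <= min(len(a), len(b))

    def test_share_arithmetic_from_reported_counts(self):
        assert overlap_percent(115, 142) == 81


class TestPearson:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 3.0, 5.0, 9.0])
        # direct formula: sum of centred products over product of norms
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        res = pearson(x, y)
        assert res.r == pytest.approx(expected, rel=1e-12)
        # two-sided p from the t transform with n-2 df
        t = expected * math.sqrt((len(x) - 2) / (1 - expected**2))
        from scipy import stats

        assert res.pvalue == pytest.approx(2 * stats.t.sf(abs(t), len(x) - 2), rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestQuadrantConcordance:
    def test_mixed_signs(self):
        assert quadrant_concordance([1, -1, 2], [2, -3, -1]) == pytest.approx(2 / 3)

    def test_identical_vectors(self):
        assert quadrant_concordance([1, -2, 3], [1, -2, 3]) == 1.0

    def test_opposite_vectors(self):
        assert quadrant_concordance([1, -2, 3], [-1, 2, -3]) == 0.0

    def test_zero_products_excluded_from_denominator(self):
        assert quadrant_concordance([1, 0, 2], [1, 5, 3]) == 1.0

    def test_all_zero_products_undefined(self):
        assert math.isnan(quadrant_concordance([0, 0], [1, 2]))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            quadrant_concordance([1, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5).filter(lambda v: abs(v) > 1e-6),
                st.floats(-5, 5).filter(lambda v: abs(v) > 1e-6),
            ),
            min_size=1,
            max_size=30,
        ),
        st.floats(0.01, 100),
    )
    def test_invariant_to_positive_rescaling(self, pairs, c):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        assert quadrant_concordance([c * v for v in a], b) == quadrant_concordance(a, b)

    def test_planted_concordance_is_perfect_at_one(self):
        tables, truth = make_dge_tables(
            n_genes=300, n_de=60, concordance=1.0, seed=3
        )
        de = [g for g, s in truth.de_status.items() if s != "null"]
        rna = tables["rna_ec5"].set_index("gene_id").loc[de, "lfc_shrunk"]
        prot = tables["protein_ec5"].set_index("gene_id").loc[de, "lfc_shrunk"]
        assert quadrant_concordance(rna.to_numpy(), prot.to_numpy()) == 1.0


class TestCompareCompounds:
    def test_reported_share_arithmetic(self):
        atv = {f"a{i}" for i in range(115)}
        btz = {f"b{i}" for i in range(1295 - 48)} | {f"a{i}" for i in range(48)}
        res = compare_compounds(atv, btz)
        assert len(res.intersection) == 48
        assert res.pct_of_a == 42
        assert res.pct_of_b == 4

    def test_disjoint(self):
        res = compare_compounds({"g1"}, {"g2"})
        assert res.pct_of_a == 0 and res.intersection == set()

    def test_specific_sets_partition_inputs(self):
        a, b = {"g1", "g2", "g3"}, {"g2", "g4"}
        res = compare_compounds(a, b)
        assert res.only_a | res.intersection == a
        assert res.only_b | res.intersection == b


class TestTopExpressed:
    def test_descending_selection(self):
        means = {"g1": 5.0, "g2": 10.0, "g3": 1.0}
        assert select_top_expressed(["g1", "g2", "g3"], means, k=2) == ["g2", "g1"]

    def test_fewer_than_k_returns_all(self):
        means = {"g1": 5.0, "g2": 10.0}
        assert select_top_expressed(["g1", "g2"], means, k=50) == ["g2", "g1"]

    def test_ties_broken_by_gene_id(self):
        means = {"g2": 5.0, "g1": 5.0, "g3": 5.0}
        assert select_top_expressed(["g3", "g2", "g1"], means, k=2) == ["g1", "g2"]

    def test_missing_expression_errors(self):
        with pytest.raises(ValueError):
            select_top_expressed(["g1"], {}, k=1)


class TestRecoveryPercent:
    @pytest.mark.parametrize(
        "nominal, measured, expected",
        [
            (30.0, 27.1, 90.3),
            (90.0, 84.6, 94.0),
            (700.0, 716.5, 102.4),
            (1000.0, 922.8, 92.3),
            (42.0, 42.0, 100.0),
        ],
    )
    def test_measured_over_nominal(self, nominal, measured, expected):
        assert recovery_percent(nominal, measured) == expected

    def test_zero_nominal_errors(self):
        with pytest.raises(ValueError):
            recovery_percent(0.0, 1.0)


def test_read_dge_table_validates_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"gene_id": ["g1"], "padj": [0.1]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="missing column"):
        read_dge_table(path)
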