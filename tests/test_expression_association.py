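"""BH adjustment, effect sizes, enrichment ladder, quantile trends, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from cpgbm.expression_association import (bh_adjust,
                                          component_enrichment_table,
                                          component_expression_contrast,
                                          effect_size, finalize_de_table,
                                          load_de_table, quantile_trend,
                                          spearman)
from cpgbm.mixture_model import ComponentSplit


def bh_step_up(pvalues):
    """Hand implementation of the BH step-up rule (independent oracle)."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * pvalues[i] / rank)
        adjusted[i] = running
    return adjusted


class TestBhAdjust:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ([0.7], [0.7]),
    ])
    def test_worked_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected, abs=1e-12)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 60)))
            assert bh_adjust(p) == pytest.approx(bh_step_up(list(p)), abs=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.random(500)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEffectSize:
    def test_identity_and_ln(self):
        assert effect_size(5.0, 5.0) == 0.0
        assert effect_size(math.e, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self):
        assert effect_size(3.0, 7.0) == pytest.approx(-effect_size(7.0, 3.0))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            effect_size(0.0, 1.0)


class TestDeTable:
    def test_load_computes_effect_and_padj(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text(
            "gene_id\tmean_a\tmean_b\tpvalue\n"
            "g1\t2.0\t1.0\t0.01\n"
            "g2\t0.0\t1.0\t0.02\n"
            "g3\t1.0\t1.0\t0.03\n"
        )
        de = load_de_table(path)
        assert de.loc[0, "effect"] == pytest.approx(math.log(2.0))
        assert math.isnan(de.loc[1, "effect"])  # zero mean: no effect size
        assert de["padj"].tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_existing_padj_is_kept(self):
        frame = pd.DataFrame({"gene_id": ["g1"], "mean_a": [1.0],
                              "mean_b": [1.0], "pvalue": [0.01],
                              "padj": [0.5]})
        assert finalize_de_table(frame)["padj"].tolist() == [0.5]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tmean_a\n" "g1\t1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_de_table(path)


class TestEnrichmentTable:
    def _split(self, n_low, n_high):
        labels = {f"L{i}": "LOW" for i in range(n_low)}
        labels.update({f"H{i}": "HIGH" for i in range(n_high)})
        return ComponentSplit(0.5, labels)

    def _de(self, split, sig_low, sig_high):
        rows = []
        for g, lab in split.labels.items():
            n_sig = sig_low if lab == "LOW" else sig_high
            idx = int(g[1:])
            sig = idx < n_sig
            rows.append({"gene_id": g, "mean_a": 1.0, "mean_b": 1.0,
                         "pvalue": 0.5, "padj": 0.001 if sig else 0.9})
        return pd.DataFrame(rows)

    def test_counts_partition_each_component(self):
        split = self._split(100, 200)
        de = self._de(split, 10, 40)
        rows = component_enrichment_table(de, split, cutoffs=[0.01])
        r = rows[0]
        assert (r.low_sig + r.low_not, r.high_sig + r.high_not) == (100, 200)
        assert (r.low_sig, r.high_sig) == (10, 40)

    def test_equal_proportions_are_not_enriched(self):
        split = self._split(100, 100)
        de = self._de(split, 10, 10)
        rows = component_enrichment_table(de, split, cutoffs=[0.01])
        assert rows[0].p > 0.5

    def test_significance_cutoff_is_strict(self):
        split = self._split(2, 2)
        de = pd.DataFrame({
            "gene_id": ["L0", "L1", "H0", "H1"],
            "mean_a": 1.0, "mean_b": 1.0, "pvalue": 0.5,
            "padj": [0.01, 0.5, 0.009999, 0.5],
        })
        r = component_enrichment_table(de, split, cutoffs=[0.01])[0]
        assert (r.low_sig, r.high_sig) == (0, 1)  # padj == cutoff is not significant

    def test_unlabeled_de_genes_rejected(self):
        split = self._split(2, 2)
        de = pd.DataFrame({"gene_id": ["x"], "mean_a": [1.0],
                           "mean_b": [1.0], "pvalue": [0.5], "padj": [0.5]})
        with pytest.raises(ValueError):
            component_enrichment_table(de, split)

    def test_bad_cutoff_rejected(self):
        split = self._split(2, 2)
        with pytest.raises(ValueError):
            component_enrichment_table(self._de(split, 1, 1), split, cutoffs=[1.5])


class TestQuantileTrend:
    def test_remainder_goes_to_earliest_quantiles(self):
        x = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        y = pd.Series(np.ones(10), index=x.index)
        trend = quantile_trend(x, y, 3)
        assert trend["count"].tolist() == [4, 3, 3]

    def test_equal_sizes_when_divisible(self):
        n, q = 12_575, 25
        x = pd.Series(np.random.default_rng(0).random(n),
                      index=[f"g{i:05d}" for i in range(n)])
        y = pd.Series(np.zeros(n), index=x.index)
        trend = quantile_trend(x, y, q)
        assert trend["count"].tolist() == [503] * q
        assert trend["count"].sum() == n

    def test_constant_metric(self):
        x = pd.Series(np.arange(20.0), index=[f"g{i}" for i in range(20)])
        y = pd.Series(np.full(20, 3.5), index=x.index)
        trend = quantile_trend(x, y, 4)
        assert trend["mean_y"].tolist() == [3.5] * 4
        assert trend["se_y"].tolist() == [0.0] * 4

    def test_mean_x_is_sorted(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.random(100), index=[f"g{i:03d}" for i in range(100)])
        y = pd.Series(rng.random(100), index=x.index)
        trend = quantile_trend(x, y, 7)
        assert trend["mean_x"].is_monotonic_increasing
        assert trend["count"].max() - trend["count"].min() <= 1

    def test_too_many_quantiles_rejected(self):
        x = pd.Series(np.arange(5.0), index=list("abcde"))
        with pytest.raises(ValueError):
            quantile_trend(x, x, 6)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(1, 10, 50)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.random(20)
        y = rng.random(20)
        rho, _ = spearman(x, y)

        def avg_ranks(v):
            order = np.argsort(v)
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        pearson = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(pearson, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestExpressionContrast:
    def _fixture(self, shift, n=500, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:04d}" for i in range(2 * n)]
        labels = {g: ("LOW" if i < n else "HIGH") for i, g in enumerate(genes)}
        expr = np.concatenate([rng.normal(shift, 1.0, n), rng.normal(0.0, 1.0, n)])
        return (pd.Series(expr, index=genes), ComponentSplit(0.5, labels),
                dict(zip(genes, rng.random(2 * n))))

    def test_shifted_components_detected(self):
        expr, split, cpg = self._fixture(shift=1.0)
        out = component_expression_contrast(expr, split, cpg_oe=cpg)
        assert out["welch_p"] < 1e-10
        assert out["welch_t"] > 0  # LOW mean above HIGH mean

    def test_anova_detects_quantile_structure(self):
        # expression increasing in CpG O/E -> quantile means differ
        rng = np.random.default_rng(3)
        genes = [f"g{i:04d}" for i in range(1000)]
        cpg = dict(zip(genes, rng.random(1000)))
        expr = pd.Series([3 * cpg[g] + rng.normal(0, 0.3) for g in genes],
                         index=genes)
        labels = {g: ("LOW" if cpg[g] < 0.5 else "HIGH") for g in genes}
        out = component_expression_contrast(expr, ComponentSplit(0.5, labels),
                                            cpg_oe=cpg)
        assert out["anova_p"] < 1e-10

    def test_tiny_component_rejected(self):
        genes = ["a", "b", "c"]
        labels = {"a": "LOW", "b": "HIGH", "c": "HIGH"}
        expr = pd.Series([1.0, 2.0, 3.0], index=genes)
        with pytest.raises(ValueError):
            component_expression_contrast(expr, ComponentSplit(0.5, labels))
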