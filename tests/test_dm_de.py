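import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elementdm import dm_de
from elementdm.data_io import ExpressionTable


def _expr(fpkm_rows, info_rows=None, samples=None):
    samples = samples or [f"s{i}" for i in range(len(next(iter(fpkm_rows.values()))))]
    fpkm = pd.DataFrame(fpkm_rows, index=samples).T
    fpkm.index.name = "gene"
    if info_rows is None:
        info_rows = {g: ("chr1", 1000, "+", 1000, 4000) for g in fpkm.index}
    info = pd.DataFrame(
        [info_rows[g] for g in fpkm.index],
        columns=["chrom", "tss", "strand", "start", "end"],
        index=fpkm.index,
    )
    return ExpressionTable(fpkm, info)


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "case_mean, ctrl_mean, kept",
        [(0.4, 8.0, True), (0.5, 0.8, False), (1.0, 0.2, True)],
        ids=["one-group-high", "both-low", "boundary-inclusive"],
    )
    def test_mean_fpkm_rule(self, case_mean, ctrl_mean, kept):
        expr = _expr({"g": [case_mean] * 3 + [ctrl_mean] * 3})
        groups = pd.Series(["case"] * 3 + ["control"] * 3, index=expr.fpkm.columns)
        out = dm_de.filter_expressed(expr, groups)
        assert ("g" in out.fpkm.index) == kept


class TestMapUnitsToGenes:
    def _gene_info(self, strand="+"):
        if strand == "+":
            return pd.DataFrame(
                {"chrom": ["chr1"], "tss": [10000], "strand": ["+"],
                 "start": [10000], "end": [15000]},
                index=pd.Index(["G"], name="gene"),
            )
        return pd.DataFrame(
            {"chrom": ["chr1"], "tss": [14999], "strand": ["-"],
             "start": [10000], "end": [15000]},
            index=pd.Index(["G"], name="gene"),
        )

    def _units(self, positions):
        return pd.DataFrame(
            {"chrom": "chr1", "start": positions, "end": [p + 1 for p in positions]},
            index=[f"u{i}" for i in range(len(positions))],
        )

    def test_upstream_window_plus_strand(self):
        units = self._units([9000, 7900, 12000])  # 1 kb upstream, 2.1 kb upstream, intronic
        mapping = dm_de.map_units_to_genes(units, self._gene_info("+"))
        assert mapping.get("u0") == ("G",)
        assert "u1" not in mapping
        assert mapping.get("u2") == ("G",)

    def test_upstream_window_minus_strand(self):
        units = self._units([16000, 17000])  # 1 kb and 2 kb past the - strand TSS
        mapping = dm_de.map_units_to_genes(units, self._gene_info("-"))
        assert mapping.get("u0") == ("G",)
        assert "u1" not in mapping

    def test_unit_can_map_to_multiple_genes(self):
        info = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "tss": [10000, 11000], "strand": ["+", "+"],
             "start": [10000, 11000], "end": [15000, 16000]},
            index=pd.Index(["A", "B"], name="gene"),
        )
        mapping = dm_de.map_units_to_genes(self._units([12000]), info)
        assert mapping["u0"] == ("A", "B")


class TestCorrelate:
    def _setup(self, meth_rows, expr_vals, n=None):
        samples = [f"s{i}" for i in range(len(expr_vals))]
        meth = pd.DataFrame([meth_rows], index=["u1"], columns=samples)
        expr = _expr({"G": expr_vals}, samples=samples)
        return expr, meth, {"u1": ("G",)}

    def test_perfect_linear_relationship(self):
        m = np.linspace(0.1, 0.9, 9)
        expr, meth, mapping = self._setup(m, 10 * m + 2)
        out = dm_de.correlate(expr, meth, mapping)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["significant"].iloc[0]

    def test_rho_point_seven_at_n_ten_not_significant(self, rng):
        # rho = 0.7 with n = 10 gives p ~ 0.024: passes |rho| but fails p < 0.005
        target = 0.7
        for _ in range(200):
            x = rng.normal(size=10)
            y = target * x + np.sqrt(1 - target**2) * rng.normal(size=10)
            r, p = stats.pearsonr(x, y)
            if abs(r - 0.7) < 0.005:
                break
        t = r * np.sqrt(8) / np.sqrt(1 - r**2)
        assert 2 * stats.t.sf(abs(t), 8) == pytest.approx(p, rel=1e-9)
        expr, meth, mapping = self._setup((x - x.min()) / np.ptp(x), y + 5)
        out = dm_de.correlate(expr, meth, mapping)
        assert abs(out["rho"].iloc[0]) > 0.65
        assert not out["significant"].iloc[0]

    def test_constant_methylation_skipped(self):
        expr, meth, mapping = self._setup([0.5] * 6, [1, 2, 3, 4, 5, 6])
        out = dm_de.correlate(expr, meth, mapping)
        assert len(out) == 0
        assert out.attrs["skipped"] == 1

    def test_sample_permutation_invariance(self, rng):
        m = rng.uniform(size=8)
        e = rng.uniform(1, 10, size=8)
        expr, meth, mapping = self._setup(m, e)
        out1 = dm_de.correlate(expr, meth, mapping)
        perm = list(rng.permutation(meth.columns))
        out2 = dm_de.correlate(
            ExpressionTable(expr.fpkm[perm], expr.gene_info), meth[perm], mapping
        )
        assert out1["rho"].iloc[0] == pytest.approx(out2["rho"].iloc[0], rel=1e-12)

    def test_conjunctive_criteria_monotonicity(self, rng):
        # dropping either criterion can only enlarge the flagged set
        samples = [f"s{i}" for i in range(10)]
        meth = pd.DataFrame(rng.uniform(size=(30, 10)),
                            index=[f"u{i}" for i in range(30)], columns=samples)
        fpkm = {}
        for i in range(30):
            m = meth.iloc[i].to_numpy()
            fpkm[f"g{i}"] = 5 + 3 * m + rng.normal(0, 0.5 + 2 * rng.random(), 10)
        expr = _expr(fpkm, samples=samples)
        mapping = {f"u{i}": (f"g{i}",) for i in range(30)}
        both = dm_de.correlate(expr, meth, mapping)
        p_only = dm_de.correlate(expr, meth, mapping, rho_cut=0.0)
        rho_only = dm_de.correlate(expr, meth, mapping, p_cut=1.1)
        flagged = set(both.loc[both["significant"], "unit_id"])
        assert flagged <= set(p_only.loc[p_only["significant"], "unit_id"])
        assert flagged <= set(rho_only.loc[rho_only["significant"], "unit_id"])


class TestOverlap:
    def test_cross_product_example(self):
        corrs = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(1500)], "significant": True,
             "unit_id": "u", "level": "cpg", "rho": 0.9, "p": 1e-4,
             "n_samples": 10, "sign": "positive"}
        )
        universe = {f"g{i}" for i in range(10000)}
        dm_genes = {f"g{i}" for i in range(1200, 2200)}  # overlap 300 of 1000 DM
        res, _ = dm_de.overlap_dm_correlated(dm_genes, corrs, universe)
        assert res.n_overlap == 300
        assert res.odds_ratio == pytest.approx((300 * 7800) / (700 * 1200), rel=1e-6)

    def test_independence_gives_or_one(self):
        # overlap equal to the random expectation n_dm * n_corr / universe
        universe = {f"g{i}" for i in range(1000)}
        corr_genes = {f"g{i}" for i in range(500)}  # half the universe
        dm_genes = {f"g{i}" for i in range(400, 600)}  # overlap 100 = 200*500/1000
        corrs = pd.DataFrame({"gene": sorted(corr_genes), "significant": True})
        res, _ = dm_de.overlap_dm_correlated(dm_genes, corrs, universe)
        assert res.odds_ratio == pytest.approx(1.0, rel=1e-6)

    def test_overlap_fraction_definition(self):
        corrs = pd.DataFrame({"gene": ["a", "b"], "significant": True})
        res, _ = dm_de.overlap_dm_correlated({"a", "c", "d", "e"}, corrs, set("abcdefghij"))
        assert res.overlap_fraction == pytest.approx(1 / 4)

    def test_empty_universe_rejected(self):
        corrs = pd.DataFrame({"gene": [], "significant": []})
        with pytest.raises(Exception):
            dm_de.overlap_dm_correlated(set(), corrs, set())


class TestStringencySweep:
    def test_identical_thresholds_identical_rows(self, segmented_dataset):
        ds, bm, _, _, _ = segmented_dataset
        from elementdm import dm_testing as dmt

        recs = dmt.test_units(bm.beta, bm.groups, level="cpg")
        recs = dmt.classify_stringent(dmt.adjust_bh(recs))
        man = ds.annotation.manifest
        gene_map = {p: man.loc[p, "genes"] for p in bm.beta.index}
        expr_f = dm_de.filter_expressed(ds.expression, bm.groups)
        corrs = dm_de.correlate(expr_f, bm.beta, gene_map)
        universe = set(expr_f.fpkm.index)
        sweep = dm_de.stringency_sweep(
            recs, gene_map, corrs, universe,
            [{"p_cut": 0.05}, {"p_cut": 0.05}, {"p_cut": 0.01}],
        )
        assert sweep.iloc[0].equals(sweep.iloc[1])
        assert len(sweep) == 3
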