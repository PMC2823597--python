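import numpy as np
import pandas as pd
import pytest

import mirnaprep as mp
from mirnaprep import normalize
from mirnaprep.errors import MirnaPrepError

from oracles import median_polish_oracle


def probe_frame(design, values):
    """Feature-level frame with the (gene, probe, replicate) MultiIndex."""
    index = pd.MultiIndex.from_tuples(
        [
            (g, p, r)
            for g in design.gene_ids
            for p in design.probes_per_gene[g]
            for r in range(design.replicates_per_probe[p])
        ],
        names=["gene_id", "probe_id", "replicate"],
    )
    return pd.DataFrame(values, index=index)


def tiny_design(replicates):
    """One gene, one probe, given replicate count."""
    return mp.ArrayDesign(["g"], {"g": ["p"]}, {"p": replicates})


class TestCollapseReplicates:
    @pytest.mark.parametrize(
        "values,expected",
        [([[1.0], [2.0], [9.0]], 2.0),   # odd count: middle value
         ([[1.0], [3.0]], 2.0),          # even count: mean of middle pair
         ([[5.0]], 5.0)],                # single replicate: identity
    )
    def test_median_conventions(self, values, expected):
        design = tiny_design(len(values))
        pm = mp.collapse_replicates(probe_frame(design, values), design)
        assert pm.values.iloc[0, 0] == expected

    def test_zero_replicate_design_rejected(self):
        design = mp.ArrayDesign(["g"], {"g": ["p"]}, {"p": 1})
        design.replicates_per_probe["p"] = 0
        with pytest.raises(MirnaPrepError):
            mp.collapse_replicates(probe_frame(tiny_design(1), [[1.0]]), design)


class TestMedianPolish:
    def test_all_zero(self):
        fit = mp.median_polish(np.zeros((2, 2)))
        assert fit.overall == 0.0
        assert np.all(fit.row_effects == 0) and np.all(fit.col_effects == 0)
        assert np.all(fit.residuals == 0)

    def test_exactly_additive(self):
        r = np.array([0.0, 2.0])
        c = np.array([1.0, 5.0, 3.0])
        m = r[:, None] + c[None, :]
        fit = mp.median_polish(m)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
        est = fit.overall + fit.row_effects[:, None] + fit.col_effects[None, :]
        np.testing.assert_allclose(est, m, atol=1e-12)

    def test_reconstruction_identity_and_oracle(self):
        """Fits match an independent straight-from-definition implementation
        cell-for-cell on 100 random small matrices."""
        rng = np.random.default_rng(202)
        for _ in range(100):
            shape = rng.integers(1, 7, 2)
            m = rng.normal(0, 3, shape)
            if rng.random() < 0.5:  # sprinkle an outlier cell
                m[rng.integers(shape[0]), rng.integers(shape[1])] += 50
            fit = mp.median_polish(m)
            recon = (fit.overall + fit.row_effects[:, None]
                     + fit.col_effects[None, :] + fit.residuals)
            np.testing.assert_allclose(recon, m, atol=1e-12)
            o_all, o_row, o_col, o_res = median_polish_oracle(m.tolist())
            assert fit.overall == pytest.approx(o_all, abs=1e-9)
            np.testing.assert_allclose(fit.row_effects, o_row, atol=1e-9)
            np.testing.assert_allclose(fit.col_effects, o_col, atol=1e-9)
            np.testing.assert_allclose(fit.residuals, o_res, atol=1e-9)

    def test_effect_medians_near_zero(self):
        rng = np.random.default_rng(7)
        m = rng.normal(0, 1, (5, 6))
        fit = mp.median_polish(m)
        assert abs(np.median(fit.row_effects)) < 1e-9
        assert abs(np.median(fit.col_effects)) < 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(MirnaPrepError):
            mp.median_polish(np.array([[1.0, np.nan]]))


class TestRmaSummarize:
    def _pm(self, design, values, arrays):
        probes = sorted(design.replicates_per_probe)
        df = pd.DataFrame(values, index=probes, columns=arrays)
        return mp.ProbeMatrix(df, scale="log2", gene_of=dict(design.gene_of))

    def test_single_probe_gene_passthrough(self):
        design = mp.ArrayDesign(["g"], {"g": ["p"]}, {"p": 16})
        pm = self._pm(design, [[1.0, 2.0, 3.0]], ["a", "b", "c"])
        em = mp.rma_summarize(pm, design)
        np.testing.assert_array_equal(em.values.loc["g"], [1.0, 2.0, 3.0])

    def test_identical_probe_rows(self):
        design = mp.ArrayDesign(["g"], {"g": ["p1", "p2", "p3"]},
                                {"p1": 6, "p2": 5, "p3": 5})
        row = [2.0, 4.0, 8.0]
        pm = self._pm(design, [row, row, row], ["a", "b", "c"])
        em = mp.rma_summarize(pm, design)
        np.testing.assert_allclose(em.values.loc["g"], row)

    def test_probe_affinities_cancel(self):
        """4 probes x 8 arrays with additive affinities: per-array estimates
        recover the generating expression profile."""
        rng = np.random.default_rng(3)
        theta = rng.normal(8, 1, 8)
        phi = np.array([-1.0, 0.2, 0.3, 0.5])  # median 0.25
        m = theta[None, :] + phi[:, None] + rng.normal(0, 0.05, (4, 8))
        design = mp.ArrayDesign(["g"], {"g": [f"p{i}" for i in range(4)]},
                                {f"p{i}": 4 for i in range(4)})
        pm = self._pm(design, m, [f"a{j}" for j in range(8)])
        est = mp.rma_summarize(pm, design).values.loc["g"].to_numpy()
        # identifiable up to a constant: compare centered profiles
        np.testing.assert_allclose(est - est.mean(), theta - theta.mean(),
                                   atol=0.1)

    def test_probe_order_invariance_and_array_equivariance(self):
        rng = np.random.default_rng(9)
        design = mp.ArrayDesign(["g"], {"g": ["p1", "p2", "p3"]},
                                {"p1": 6, "p2": 5, "p3": 5})
        m = rng.normal(5, 1, (3, 4))
        arrays = ["a", "b", "c", "d"]
        pm = self._pm(design, m, arrays)
        base = mp.rma_summarize(pm, design).values

        pm_shuf = mp.ProbeMatrix(pm.values.iloc[[2, 0, 1]], scale="log2",
                                 gene_of=pm.gene_of)
        np.testing.assert_allclose(
            mp.rma_summarize(pm_shuf, design).values, base, atol=1e-12)

        perm = [3, 1, 0, 2]
        pm_cols = mp.ProbeMatrix(pm.values.iloc[:, perm], scale="log2",
                                 gene_of=pm.gene_of)
        np.testing.assert_allclose(
            mp.rma_summarize(pm_cols, design).values.to_numpy(),
            base.to_numpy()[:, perm], atol=1e-12)

    def test_constant_shift_equivariance(self):
        rng = np.random.default_rng(10)
        design = mp.ArrayDesign(["g"], {"g": ["p1", "p2"]}, {"p1": 8, "p2": 8})
        m = rng.normal(5, 1, (2, 4))
        pm = self._pm(design, m, list("abcd"))
        pm2 = self._pm(design, m + 1.5, list("abcd"))
        a = mp.rma_summarize(pm, design).values
        b = mp.rma_summarize(pm2, design).values
        np.testing.assert_allclose(b.to_numpy(), a.to_numpy() + 1.5, atol=1e-12)

    def test_missing_gene_is_integrity_error(self):
        design = mp.ArrayDesign(["g", "h"], {"g": ["p"], "h": ["q"]},
                                {"p": 1, "q": 1})
        pm = mp.ProbeMatrix(pd.DataFrame([[1.0, 2.0]], index=["p"],
                                         columns=["a", "b"]),
                            scale="log2", gene_of={"p": "g", "q": "h"})
        with pytest.raises(MirnaPrepError):
            mp.rma_summarize(pm, design)


class TestComputeTgs:
    def _tables(self, bgsub_by_probe, design, arrays=("a1", "a2")):
        """Build FeatureTables with given per-probe replicate bgsub values."""
        tables = []
        for aid in arrays:
            rows = []
            k = 0
            for g in design.gene_ids:
                for p in design.probes_per_gene[g]:
                    for v in bgsub_by_probe[p]:
                        k += 1
                        rows.append((p, g, abs(v) + 1000.0, v, 0, 1, k, 1))
            df = pd.DataFrame(rows, columns=[
                "probe_id", "gene_id", "mean_signal", "bgsub_signal",
                "control_type", "is_gene_detected", "row", "col"])
            tables.append(mp.FeatureTable(aid, df))
        return tables

    def test_all_equal_replicates(self):
        design = mp.ArrayDesign(["g"], {"g": ["p1", "p2"]}, {"p1": 8, "p2": 8})
        tables = self._tables({"p1": [3.0] * 8, "p2": [3.0] * 8}, design)
        em = mp.compute_tgs(tables, design)
        assert em.method == "TGS_raw" and em.scale == "linear"
        np.testing.assert_array_equal(em.values.loc["g"], [48.0, 48.0])

    def test_single_probe_single_replicate(self):
        design = mp.ArrayDesign(["g"], {"g": ["p"]}, {"p": 1})
        em = mp.compute_tgs(self._tables({"p": [7.5]}, design), design)
        np.testing.assert_array_equal(em.values.loc["g"], [7.5, 7.5])

    def test_median_ignores_outlier(self):
        design = mp.ArrayDesign(["g"], {"g": ["p"]}, {"p": 8})
        vals = [4.0] * 7 + [10_000.0]
        em = mp.compute_tgs(self._tables({"p": vals}, design), design)
        np.testing.assert_array_equal(em.values.loc["g"], [32.0, 32.0])

    def test_trimmed_mean_option(self):
        design = mp.ArrayDesign(["g"], {"g": ["p"]}, {"p": 8})
        vals = [4.0] * 7 + [10_000.0]
        em = mp.compute_tgs(
            self._tables({"p": vals}, design), design,
            mp.TgsOptions(robust_average="outlier_trimmed_mean"))
        np.testing.assert_array_equal(em.values.loc["g"], [32.0, 32.0])

    def test_negative_tgs_allowed(self):
        design = mp.ArrayDesign(["g"], {"g": ["p"]}, {"p": 2})
        em = mp.compute_tgs(self._tables({"p": [-5.0, -5.0]}, design), design)
        np.testing.assert_array_equal(em.values.loc["g"], [-10.0, -10.0])


class TestProcess:
    def test_all_methods_run_full_design(self, default_experiment):
        tables, _, design = default_experiment
        for method in mp.METHODS:
            em = mp.process(tables, method, design=design)
            assert em.method == method and em.scale == "log2"
            assert em.values.shape == (design.n_genes, len(tables))
            assert np.isfinite(em.values.to_numpy()).all()

    def test_nor75_contract(self, small_experiment):
        tables, _, design = small_experiment
        em = mp.process(tables, "nor75", design=design)
        linear = 2.0 ** em.values
        for c in linear.columns:
            assert np.quantile(linear[c], 0.75) == pytest.approx(1.0, abs=1e-9)

    def test_norq_columns_share_distribution(self, small_experiment):
        tables, _, design = small_experiment
        em = mp.process(tables, "norQ", design=design)
        cols = np.sort(em.values.to_numpy(), axis=0)
        for j in range(1, cols.shape[1]):
            np.testing.assert_allclose(cols[:, 0], cols[:, j], atol=1e-9)

    def test_norrma_equals_norrmabg_with_known_tiny_background(
            self, small_experiment):
        """When the background correction is the identity (mu, sigma -> 0)
        the two RMA routes coincide."""
        tables, truth, design = small_experiment
        p = mp.BgParams(alpha=1.0 / truth.config.exp_rate_scale,
                        mu=1e-9, sigma=1e-9)
        a = mp.process(tables, "norRMA", design=design).values
        b = mp.process(tables, "norRMAbg", design=design,
                       bg_params={t.array_id: p for t in tables}).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_unknown_method_rejected(self, small_experiment):
        tables, _, design = small_experiment
        with pytest.raises(ValueError, match="unknown method"):
            mp.process(tables, "loess", design=design)

    def test_bg_params_logged(self, small_experiment):
        tables, _, design = small_experiment
        log: dict = {}
        mp.process(tables, "norRMAbg", design=design, bg_params_log=log)
        assert set(log) == {t.array_id for t in tables}
        assert all(p.alpha > 0 and p.sigma > 0 for p in log.values())
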