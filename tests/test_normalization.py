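import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletview.errors import ConfigError, EmptyDatasetError
from isletview import normalization as norm


def _counts(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


class TestFilterSamples:
    def test_strictly_below_threshold_removed(self):
        c = _counts([[9_999_999, 10_000_000, 12_000_000]])
        kept, removed = norm.filter_samples(c)
        assert removed == ["s0"]
        assert list(kept.columns) == ["s1", "s2"]

    def test_known_depths(self, rng):
        depths = [5_000_000, 12_000_000, 30_000_000]
        raw = rng.multinomial(1, np.full(100, 0.01), size=3)  # placeholder shape
        c = _counts(np.column_stack([rng.multinomial(d, np.full(100, 0.01)) for d in depths]))
        kept, removed = norm.filter_samples(c)
        assert removed == ["s0"] and kept.shape[1] == 2

    def test_all_removed_is_error(self):
        with pytest.raises(EmptyDatasetError):
            norm.filter_samples(_counts([[1, 2]]))


class TestFpkmAndGeneFilter:
    def test_closed_form(self):
        c = _counts([[10]])
        out = norm.fpkm(c, pd.Series({"g0": 1000}), pd.Series({"s0": 1e7}))
        assert out.iloc[0, 0] == pytest.approx(1.0)

    def test_zero_count_zero_fpkm(self):
        c = _counts([[0, 5], [3, 2]])
        out = norm.fpkm(c, pd.Series({"g0": 500, "g1": 800}))
        assert out.iloc[0, 0] == 0.0

    def test_matches_independent_formula(self, rng):
        c = _counts(rng.integers(0, 500, size=(40, 8)))
        lengths = pd.Series(rng.integers(200, 5000, size=40), index=c.index)
        lib = c.sum(axis=0)
        out = norm.fpkm(c, lengths)
        for g in range(40):
            for s in range(8):
                expect = c.iloc[g, s] * 1e9 / (lengths.iloc[g] * lib.iloc[s])
                assert abs(out.iloc[g, s] - expect) < 1e-12

    def test_gene_filter_rules(self):
        n = 100
        f = pd.DataFrame(
            {
                "mostly_zero": [0.0] * 6 + [5.0] * 94,  # nonzero in 94% -> out
                "low_mean": [0.9] * 100,  # mean 0.9 <= 1 -> out
                "all_zero": [0.0] * 100,  # out
                "good": [2.0] * 100,  # in
                "boundary_mean": [1.0] * 100,  # mean exactly 1, "more than 1" -> out
            }
        ).T
        kept = norm.filter_genes(f)
        assert list(kept) == ["good"]

    def test_idempotent_on_own_output(self, rng):
        f = pd.DataFrame(rng.uniform(0, 5, size=(50, 30)))
        f[f < 0.5] = 0.0
        kept = norm.filter_genes(f)
        again = norm.filter_genes(f.loc[kept])
        assert list(kept) == list(again)


class TestTmm:
    def test_identical_columns_unit_factors(self):
        col = np.array([100, 50, 400, 10, 1000])
        f = norm.tmm_factors(_counts(np.column_stack([col, col])))
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_difference_unit_factors(self, rng):
        col = rng.integers(10, 2000, size=200)
        f = norm.tmm_factors(_counts(np.column_stack([col, 2 * col])))
        assert np.allclose(f.factors, 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self, rng):
        c = _counts(rng.integers(0, 3000, size=(300, 6)))
        f = norm.tmm_factors(c)
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_asymmetric_de_direction_and_hand_value(self, rng):
        # 20% of genes 8-fold up in sample B only: B's factor must drop below 1.
        n = 100
        base = rng.integers(100, 1000, size=n)
        b = base.copy()
        b[:20] *= 8
        c = _counts(np.column_stack([base, b]))
        f = norm.tmm_factors(c)
        assert f.factors["s1"] < 1.0 < f.factors["s0"]
        # hand computation: trimmed inverse-variance weighted mean of M vs s0
        y, lib = c.to_numpy(dtype=float), c.sum(axis=0).to_numpy(dtype=float)
        f75 = np.quantile(y / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        other = 1 - ref
        m = np.log2((y[:, other] / lib[other]) / (y[:, ref] / lib[ref]))
        a = 0.5 * np.log2((y[:, other] / lib[other]) * (y[:, ref] / lib[ref]))
        v = (lib[other] - y[:, other]) / (lib[other] * y[:, other]) + (
            lib[ref] - y[:, ref]
        ) / (lib[ref] * y[:, ref])
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        keep = (
            (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        )
        log_f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        expected = np.array([1.0, 1.0])
        expected[other] = 2.0 ** log_f
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f.factors.to_numpy(), expected, atol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_oracle(self, tmp_path, rng):
        c = _counts(rng.integers(0, 5000, size=(400, 5)) + 1)
        c.to_csv(tmp_path / "c.tsv", sep="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- read.delim('{tmp_path}/c.tsv', row.names=1);"
            "f <- calcNormFactors(as.matrix(x), method='TMM');"
            "cat(sprintf('%.10f', f), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        mine = norm.tmm_factors(c).factors.to_numpy()
        assert np.allclose(mine, expected, atol=1e-6)

    def test_single_sample_is_error(self):
        with pytest.raises(ConfigError):
            norm.tmm_factors(_counts([[1], [2]]))


class TestLog2Cpm:
    def test_closed_form_zero_count(self):
        c = _counts([[0]])
        out = norm.log2cpm(c, pd.Series({"s0": 1e6}), prior=0.5)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5 / 1_000_001 * 1e6), abs=1e-12)

    def test_scale_invariance(self, rng):
        # holds up to the prior term, i.e. for counts well above the 0.5 prior
        c = _counts(rng.integers(500, 5000, size=(50, 4)))
        a = norm.log2cpm(c)
        b = norm.log2cpm(2 * c)
        assert np.max(np.abs(a.to_numpy() - b.to_numpy())) < 1e-3

    def test_matches_independent_formula(self, rng):
        c = _counts(rng.integers(0, 1000, size=(30, 5)))
        lib = c.sum(axis=0)
        out = norm.log2cpm(c)
        expect = np.log2(
            (c.to_numpy() + 0.5) / (lib.to_numpy() + 1.0)[None, :] * 1e6
        )
        assert np.max(np.abs(out.to_numpy() - expect)) < 1e-12


class TestPrecisionWeights:
    def _design(self, n):
        return np.ones((n, 1))

    def test_constant_variance_gives_flat_weights(self, rng):
        # equal-abundance genes, equal dispersion -> near-flat trend
        mu = np.full((200, 40), 500.0)
        c = _counts(rng.poisson(mu))
        w = norm.precision_weights(c, self._design(40))
        assert w.to_numpy().max() / w.to_numpy().min() < 1.5

    def test_weights_increase_with_abundance_for_nb_counts(self, rng):
        # NB counts: log-scale variance falls with abundance, so weights rise
        base = rng.lognormal(3, 1.5, size=300)
        mu = np.outer(base, np.full(30, 1.0))
        lam = rng.gamma(10.0, mu / 10.0)
        c = _counts(rng.poisson(lam))
        c = c[c.sum(axis=1) > 0]
        w = norm.precision_weights(c, self._design(30))
        rho = stats.spearmanr(w.mean(axis=1), c.mean(axis=1)).statistic
        assert rho > 0

    def test_all_weights_positive(self, rng):
        c = _counts(rng.integers(0, 100, size=(50, 12)))
        w = norm.precision_weights(c, self._design(12))
        assert (w.to_numpy() > 0).all()

    def test_too_few_samples_is_error(self, rng):
        c = _counts(rng.integers(1, 100, size=(20, 3)))
        with pytest.raises(ConfigError):
            norm.precision_weights(c, np.column_stack([np.ones(3), [0, 1, 2], [1, 0, 1]]))


class TestBatchAdjust:
    def test_single_batch_identity(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 10)))
        batch = pd.Series(["b1"] * 10, index=x.columns)
        out = norm.batch_adjust(x, batch)
        pd.testing.assert_frame_equal(out, x)

    def test_planted_offset_removed(self, rng):
        n_g, n_s = 200, 40
        x = pd.DataFrame(rng.normal(0, 1, size=(n_g, n_s)))
        batch = pd.Series(["b1"] * 20 + ["b2"] * 20, index=x.columns)
        x.loc[:, batch == "b2"] += 1.0
        out = norm.batch_adjust(x, batch)
        diff = out.loc[:, batch == "b2"].mean(axis=1) - out.loc[:, batch == "b1"].mean(axis=1)
        assert abs(diff.mean()) < 0.05
        assert out.shape == x.shape and list(out.index) == list(x.index)

    def test_singleton_batch_is_error(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 5)))
        batch = pd.Series(["b1"] * 4 + ["lonely"], index=x.columns)
        with pytest.raises(ConfigError, match="lonely"):
            norm.batch_adjust(x, batch)

    def test_random_labels_preserve_variance(self, rng):
        x = pd.DataFrame(rng.normal(0, 1, size=(300, 60)))
        batch = pd.Series(rng.permutation(["b1"] * 30 + ["b2"] * 30), index=x.columns)
        out = norm.batch_adjust(x, batch)
        ratio = out.var(axis=1).mean() / x.var(axis=1).mean()
        assert 0.9 < ratio < 1.1

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_sva_combat_oracle(self, tmp_path, rng):
        x = pd.DataFrame(
            rng.normal(5, 1, size=(100, 20)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"s{j}" for j in range(20)],
        )
        batch = pd.Series(["b1"] * 10 + ["b2"] * 10, index=x.columns)
        x.loc[:, batch == "b2"] += 0.7
        x.to_csv(tmp_path / "x.tsv", sep="\t")
        script = (
            "suppressMessages(library(sva));"
            f"x <- as.matrix(read.delim('{tmp_path}/x.tsv', row.names=1));"
            "b <- factor(rep(c('b1','b2'), each=10));"
            "y <- ComBat(dat=x, batch=b, par.prior=TRUE, mean.only=FALSE);"
            f"write.table(y, '{tmp_path}/y.tsv', sep='\\t', quote=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        expected = pd.read_csv(tmp_path / "y.tsv", sep="\t")
        mine = norm.batch_adjust(x, batch)
        assert np.allclose(mine.to_numpy(), expected.to_numpy(), atol=1e-3)


class TestPurityAndExpression:
    def test_linear_gene_rho_one(self):
        purity = pd.Series([40.0, 55.0, 60.0, 75.0, 90.0])
        x = pd.DataFrame([2 * purity.to_numpy() + 1, -purity.to_numpy()], index=["up", "down"])
        x.columns = purity.index
        out = norm.purity_correlation(x, purity)
        assert out.at["up", "rho"] == pytest.approx(1.0)
        assert out.at["down", "rho"] == pytest.approx(-1.0)

    def test_independent_gene_small_rho(self, rng):
        n, reps = 100, 200
        purity = pd.Series(rng.uniform(40, 100, n))
        x = pd.DataFrame(rng.normal(size=(reps, n)), columns=purity.index)
        out = norm.purity_correlation(x, purity)
        assert (out["rho"].abs() < 0.3).mean() >= 0.95

    def test_constant_purity_is_error(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.raises(ConfigError):
            norm.purity_correlation(x, pd.Series(np.full(10, 80.0), index=x.columns))

    def test_expressed_mask_threshold(self):
        # 12 islet samples with a gene at CPM >= 1 in exactly 10 (83%) vs 9 (75%)
        n = 12
        lib_unit = 1_000_000
        counts = np.zeros((3, n))
        counts[0, :10] = 2  # CPM 2 in 10/12 -> expressed
        counts[1, :9] = 2  # 9/12 -> not expressed
        # filler gene keeps library size at 1e6 per sample
        counts[2] = lib_unit - counts[:2].sum(axis=0)
        c = _counts(counts.astype(int))
        tissue = pd.Series(["islet"] * n, index=c.columns)
        mask = norm.expressed_mask(c, tissue)
        assert bool(mask.at["g0", "islet"]) is True
        assert bool(mask.at["g1", "islet"]) is False

    def test_all_zero_gene_not_expressed(self, rng):
        c = _counts(np.vstack([np.zeros(8, dtype=int), rng.integers(1, 100, size=(3, 8))]))
        tissue = pd.Series(["islet"] * 4 + ["fat"] * 4, index=c.columns)
        mask = norm.expressed_mask(c, tissue)
        assert not mask.loc["g0"].any()
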