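import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletview import eqtl as eqtl_mod
from isletview.io_formats import GeneAnnotation, GenotypeMatrix


def _gm(positions, dosage, chrom="chr1"):
    n_v = len(positions)
    return GenotypeMatrix(
        variant_id=np.array([f"v{i}" for i in range(n_v)]),
        chrom=np.array([chrom] * n_v),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * n_v),
        alt=np.array(["G"] * n_v),
        dosage=np.asarray(dosage, dtype=float),
        samples=[f"s{j}" for j in range(np.asarray(dosage).shape[1])],
    )


class TestCisPairs:
    GENE = GeneAnnotation("G1", "G1", "chr1", 5_000_000, 5_010_000, "+", 1000)

    def test_boundary_inclusive(self):
        gm = _gm([3_000_000], np.ones((1, 4)))
        pairs = eqtl_mod.cis_pairs([self.GENE], gm)
        assert len(pairs) == 1
        assert pairs["distance"].iloc[0] == -2_000_000

    def test_just_outside_excluded(self):
        gm = _gm([2_999_999], np.ones((1, 4)))
        assert eqtl_mod.cis_pairs([self.GENE], gm).empty

    def test_gene_body_distance_zero(self):
        gm = _gm([5_005_000], np.ones((1, 4)))
        assert eqtl_mod.cis_pairs([self.GENE], gm)["distance"].iloc[0] == 0

    def test_downstream_positive_distance(self):
        gm = _gm([5_010_500], np.ones((1, 4)))
        assert eqtl_mod.cis_pairs([self.GENE], gm)["distance"].iloc[0] == 500

    def test_other_chromosome_excluded(self):
        gm = _gm([5_005_000], np.ones((1, 4)), chrom="chr2")
        assert eqtl_mod.cis_pairs([self.GENE], gm).empty


class TestResidualize:
    def test_intercept_only_mean_centers(self, rng):
        y = rng.normal(size=(5, 30))
        out = eqtl_mod.residualize(y, None)
        assert np.allclose(out, y - y.mean(axis=1, keepdims=True))

    def test_idempotence(self, rng):
        y = rng.normal(size=(5, 30))
        cov = rng.normal(size=(30, 3))
        once = eqtl_mod.residualize(y, cov)
        twice = eqtl_mod.residualize(once, cov)
        assert np.allclose(once, twice, atol=1e-10)

    def test_matches_per_row_regression_oracle(self, rng):
        y = rng.normal(size=(8, 40))
        cov = rng.normal(size=(40, 2))
        out = eqtl_mod.residualize(y, cov)
        x = np.column_stack([np.ones(40), cov])
        for g in range(8):
            beta, *_ = np.linalg.lstsq(x, y[g], rcond=None)
            assert np.allclose(out[g], y[g] - x @ beta, atol=1e-10)


class TestScan:
    def test_closed_form_slope(self):
        y = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["G1"], columns=[f"s{j}" for j in range(6)])
        gm = _gm([100], [[0, 0, 1, 1, 2, 2]])
        gene = GeneAnnotation("G1", "G1", "chr1", 50, 150, "+", 100)
        rec = eqtl_mod.eqtl_scan(y, gm, eqtl_mod.cis_pairs([gene], gm))
        assert rec["beta"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_exact_proportionality(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        y = pd.DataFrame([3.0 * g], index=["G1"], columns=[f"s{j}" for j in range(8)])
        gm = _gm([100], [g])
        gene = GeneAnnotation("G1", "G1", "chr1", 50, 150, "+", 100)
        rec = eqtl_mod.eqtl_scan(y, gm, eqtl_mod.cis_pairs([gene], gm))
        assert rec["beta"].iloc[0] == pytest.approx(3.0)
        assert rec["p"].iloc[0] < 1e-40  # at the numerical floor for n = 8

    def test_permuted_genotypes_give_uniform_p(self, rng):
        # calibration: expression independent of dosage
        n = 60
        reps = 1000
        y = pd.DataFrame(
            rng.normal(size=(reps, n)),
            index=[f"G{i}" for i in range(reps)],
            columns=[f"s{j}" for j in range(n)],
        )
        dosage = rng.binomial(2, 0.3, size=(reps, n)).astype(float)
        gm = GenotypeMatrix(
            variant_id=np.array([f"v{i}" for i in range(reps)]),
            chrom=np.array(["chr1"] * reps),
            pos=np.arange(1, reps + 1, dtype=np.int64) * 100,
            ref=np.array(["A"] * reps),
            alt=np.array(["G"] * reps),
            dosage=dosage,
            samples=list(y.columns),
        )
        pairs = pd.DataFrame(
            {
                "gene_id": y.index,
                "variant_id": gm.variant_id,
                "gene_idx": np.arange(reps),
                "variant_idx": np.arange(reps),
                "distance": 0,
            }
        )
        rec = eqtl_mod.eqtl_scan(y, gm, pairs)
        assert stats.kstest(rec["p"], "uniform").pvalue > 0.01

    def test_zero_variance_dosage_skipped(self):
        y = pd.DataFrame([[1.0, 2, 3, 4]], index=["G1"], columns=[f"s{j}" for j in range(4)])
        gm = _gm([100, 120], [[1, 1, 1, 1], [0, 1, 2, 1]])
        gene = GeneAnnotation("G1", "G1", "chr1", 50, 150, "+", 100)
        rec = eqtl_mod.eqtl_scan(y, gm, eqtl_mod.cis_pairs([gene], gm))
        assert list(rec["variant_id"]) == ["v1"]

    def test_vectorized_equals_per_pair_oracle(self, rng):
        n, n_genes, n_vars = 50, 10, 20
        y = pd.DataFrame(
            rng.normal(size=(n_genes, n)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n)],
        )
        cov = rng.normal(size=(n, 2))
        dosage = rng.binomial(2, 0.3, size=(n_vars, n)).astype(float)
        gm = _gm(np.arange(1, n_vars + 1) * 10, dosage)
        genes = [GeneAnnotation(f"G{i}", f"G{i}", "chr1", 1, 500, "+", 100) for i in range(n_genes)]
        pairs = eqtl_mod.cis_pairs(genes, gm)
        rec = eqtl_mod.eqtl_scan(y, gm, pairs, covariates=cov)
        x = np.column_stack([np.ones(n), cov])
        q, _ = np.linalg.qr(x)
        d = n - 1 - x.shape[1]  # nuisance rank plus the tested dosage
        for row in rec.itertuples():
            yr = y.loc[row.gene_id].to_numpy()
            gr = dosage[int(row.variant_id[1:])]
            yr = yr - q @ (q.T @ yr)
            gr = gr - q @ (q.T @ gr)
            r = float(np.dot(yr, gr) / np.sqrt(np.dot(yr, yr) * np.dot(gr, gr)))
            t = r * np.sqrt(d / (1 - r ** 2))
            p = 2 * stats.t.sf(abs(t), df=d)
            beta = float(np.dot(yr, gr) / np.dot(gr, gr))
            assert row.beta == pytest.approx(beta, abs=1e-8)
            assert row.t == pytest.approx(t, abs=1e-8)
            assert row.p == pytest.approx(p, abs=1e-8)


class TestGeneSummaries:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["variant_id", "gene_id", "beta", "se", "t", "p", "fdr", "distance", "ea"]
        )

    def test_single_pair_is_lead(self):
        rec = self._records([["v1", "G1", 1, 0.1, 10, 1e-5, 1e-4, 100, "G"]])
        out = eqtl_mod.gene_summaries(rec)
        assert out["G1"]["lead"]["variant_id"] == "v1"

    def test_tie_broken_by_distance(self):
        rec = self._records(
            [
                ["far", "G1", 1, 0.1, 10, 1e-5, 1e-4, 50_000, "G"],
                ["near", "G1", 1, 0.1, 10, 1e-5, 1e-4, -100, "G"],
            ]
        )
        assert eqtl_mod.gene_summaries(rec)["G1"]["lead"]["variant_id"] == "near"

    def test_default_k_is_10(self, rng):
        import inspect

        assert inspect.signature(eqtl_mod.gene_summaries).parameters["k"].default == 10
        rows = [
            [f"v{i}", "G1", 1, 0.1, 10, p, p, i, "G"]
            for i, p in enumerate(rng.uniform(size=15))
        ]
        out = eqtl_mod.gene_summaries(self._records(rows))
        assert len(out["G1"]["top"]) == 10
        assert out["G1"]["n_tested"] == 15


class TestTssAnchor:
    def test_tss_window_uses_strand(self):
        # + strand: TSS = start; a variant near the end+2Mb edge falls outside
        gene_plus = GeneAnnotation("G1", "G1", "chr1", 5_000_000, 5_500_000, "+", 1000)
        gene_minus = GeneAnnotation("G2", "G2", "chr1", 5_000_000, 5_500_000, "-", 1000)
        gm = _gm([7_200_000], np.ones((1, 4)))
        assert eqtl_mod.cis_pairs([gene_plus], gm, anchor="tss").empty
        assert len(eqtl_mod.cis_pairs([gene_minus], gm, anchor="tss")) == 1

    def test_unknown_anchor_rejected(self):
        from isletview.errors import ConfigError

        gm = _gm([100], np.ones((1, 4)))
        with pytest.raises(ConfigError):
            eqtl_mod.cis_pairs([], gm, anchor="midpoint")
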