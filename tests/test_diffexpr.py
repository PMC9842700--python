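"""Moderated differential expression: GLS, consensus correlation, empirical
Bayes moderation, BH adjustment, and calls — each against an independent oracle."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from conftest import dense_gls_oracle
from transcortex.diffexpr import (
    DEModelSpec,
    bh_adjust,
    call_de,
    ebayes_moderate,
    estimate_consensus_correlation,
    fit_f_dist,
    fit_gene_models,
    make_design,
    run_de,
)
from transcortex.normalization import normalize
from transcortex.synthetic_data import SimulationConfig, generate_dataset


def _frame(arr):
    arr = np.atleast_2d(arr)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestModelSpec:
    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            DEModelSpec(design=np.ones((4, 2)), block=np.array(["a"] * 4))

    def test_block_must_cover_samples(self):
        with pytest.raises(ValueError, match="cover"):
            DEModelSpec(design=make_design(np.array([0, 0, 1, 1])),
                        block=np.array(["a", "a", "b"]))


class TestConsensusCorrelation:
    def test_singleton_blocks_return_zero(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(50, 6)))
        design = make_design(np.array([0, 0, 0, 1, 1, 1], dtype=float))
        rho = estimate_consensus_correlation(X, design, np.arange(6))
        assert rho == 0.0

    def test_null_data_near_zero(self):
        cfg = SimulationConfig(n_donors=6, samples_per_donor=200, n_genes=2000,
                               donor_batch_sd=0.0, intra_donor_correlation=0.0,
                               n_planted_de=0, probes_per_gene_distribution={1: 1.0},
                               seed=12)
        atlas = generate_dataset(cfg)
        X = atlas.gene_matrix
        aff = np.isin(X.columns, atlas.truth.true_affected_samples).astype(float)
        rho = estimate_consensus_correlation(X, make_design(aff),
                                             atlas.donor_of().loc[X.columns].to_numpy())
        assert abs(rho) < 0.03


class TestGlsFit:
    def test_rho_zero_equals_ols(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(10, 12))
        aff = np.array([0.0] * 6 + [1.0] * 6)
        design = make_design(aff)
        block = np.repeat(["a", "b", "c"], 4)
        fits = fit_gene_models(_frame(Y), design, block, consensus_rho=0.0)
        beta_ols, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
        np.testing.assert_allclose(fits["coef_1"], beta_ols[1], atol=1e-10)

    def test_balanced_two_group_lfc_is_mean_difference(self):
        Y = np.array([[1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0]])
        aff = np.array([0.0] * 4 + [1.0] * 4)
        block = np.array(["a"] * 4 + ["b"] * 4)
        fits = fit_gene_models(_frame(Y), make_design(aff), block, consensus_rho=0.0)
        assert fits["coef_1"].iloc[0] == pytest.approx(9.0)

    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 6))
        aff = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
        block = np.array(["a", "a", "a", "b", "b", "b"])
        rho = 0.5
        design = make_design(aff)
        Sigma = np.kron(np.eye(2), (1 - rho) * np.eye(3) + rho)
        fits = fit_gene_models(_frame(Y), design, block, consensus_rho=rho)
        beta, sigma2, se_u = dense_gls_oracle(Y, design, Sigma)
        np.testing.assert_allclose(fits[["coef_0", "coef_1"]].to_numpy(), beta, atol=1e-8)
        np.testing.assert_allclose(fits["sigma2"], sigma2, atol=1e-8)
        np.testing.assert_allclose(fits["se_unscaled_1"], se_u[1], atol=1e-10)

    def test_t_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(40, 16))
        aff = np.tile([0.0, 1.0], 8)
        block = np.repeat(["a", "b"], 8)
        f1 = fit_gene_models(_frame(Y), make_design(aff), block, 0.2)
        _, m1 = ebayes_moderate(f1)
        f2 = fit_gene_models(_frame(Y), make_design(1 - aff), block, 0.2)
        _, m2 = ebayes_moderate(f2)
        np.testing.assert_allclose(m1["moderated_t"], -m2["moderated_t"], atol=1e-10)
        np.testing.assert_allclose(m1["p_value"], m2["p_value"], atol=1e-12)


def _moment_oracle(s2: np.ndarray, df: float):
    """Independent scaled-F fit: solve the trigamma equation with brentq."""
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        return np.inf, float(np.exp(z.mean()))
    half_d0 = optimize.brentq(lambda x: special.polygamma(1, x) - evar, 1e-6, 1e8)
    d0 = 2 * half_d0
    s0 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    return d0, float(s0)


class TestEbayes:
    def _fits(self, Y, aff, block, rho=0.0):
        return fit_gene_models(_frame(Y), make_design(aff), block, consensus_rho=rho)

    def test_prior_matches_moment_oracle(self):
        rng = np.random.default_rng(4)
        s2 = 0.05 * 4 / rng.chisquare(4, 500) * rng.chisquare(20, 500) / 20
        prior = fit_f_dist(s2, 20.0)
        d0, s0 = _moment_oracle(s2, 20.0)
        assert prior.d0 == pytest.approx(d0, rel=1e-6)
        assert prior.s0_sq == pytest.approx(s0, rel=1e-6)

    def test_identical_variances_give_complete_pooling(self):
        rng = np.random.default_rng(5)
        n = 8
        aff = np.array([0.0] * 4 + [1.0] * 4)
        block = np.array(["a"] * n)
        Y = rng.normal(size=(50, n))
        fits = self._fits(Y, aff, block)
        fits["sigma2"] = 0.7  # force a common sample variance
        prior, out = ebayes_moderate(fits)
        assert np.isinf(prior.d0)
        np.testing.assert_allclose(out["s2_post"], prior.s0_sq)
        # moderated t = ordinary t computed with the common value
        want = fits["coef_1"] / (np.sqrt(prior.s0_sq) * fits["se_unscaled_1"])
        np.testing.assert_allclose(out["moderated_t"], want, atol=1e-10)

    def test_d0_zero_recovers_ordinary_t(self):
        rng = np.random.default_rng(6)
        aff = np.array([0.0] * 5 + [1.0] * 5)
        Y = rng.normal(size=(40, 10))
        fits = self._fits(Y, aff, np.array(["a"] * 10))
        _, out = ebayes_moderate(fits, d0_override=0)
        t_ord = fits["coef_1"] / np.sqrt(fits["sigma2"]) / fits["se_unscaled_1"]
        np.testing.assert_allclose(out["moderated_t"], t_ord, atol=1e-12)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), 8)
        np.testing.assert_allclose(out["p_value"], p_ord, atol=1e-12)

    def test_d0_infinite_recovers_pooled_variance_t(self):
        rng = np.random.default_rng(7)
        aff = np.array([0.0] * 5 + [1.0] * 5)
        Y = rng.normal(size=(40, 10))
        fits = self._fits(Y, aff, np.array(["a"] * 10))
        prior, out = ebayes_moderate(fits, d0_override=np.inf)
        pooled = fits["sigma2"].mean()
        assert prior.s0_sq == pytest.approx(pooled)
        want = fits["coef_1"] / (np.sqrt(pooled) * fits["se_unscaled_1"])
        np.testing.assert_allclose(out["moderated_t"], want, atol=1e-10)

    def test_prior_recovery_within_20_percent(self):
        rng = np.random.default_rng(8)
        d0_true, s0_true, df, G = 4.0, 0.05, 60.0, 5000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, G)
        s2 = sigma2 * rng.chisquare(df, G) / df
        prior = fit_f_dist(s2, df)
        assert abs(prior.d0 - d0_true) / d0_true < 0.20
        assert abs(prior.s0_sq - s0_true) / s0_true < 0.20

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_f_dist(np.array([0.1, 0.0, 0.2]), 10.0)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_stepup_definition(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.2)), 0.2)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        p = rng.random(200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(10)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCalls:
    def test_boundary_q_not_called(self):
        table = pd.DataFrame({"lfc": [1.0, -1.0, 2.0],
                              "q_value": [0.05, 0.049, 0.01]},
                             index=["a", "b", "c"])
        higher, lower = call_de(table, alpha=0.05)
        assert higher == {"c"}
        assert lower == {"b"}


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaCrossCheck:
    def test_moderated_t_matches_limma(self, tmp_path):
        """Independent route: limma's lmFit+eBayes on the same matrix (rho=0)."""
        rng = np.random.default_rng(11)
        G, n = 60, 14
        aff = np.array([0.0] * 7 + [1.0] * 7)
        Y = rng.normal(size=(G, n)) + 0.8 * aff * (rng.random((G, 1)) < 0.2)
        np.savetxt(tmp_path / "y.tsv", Y, delimiter="\t")
        np.savetxt(tmp_path / "aff.tsv", aff, delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            Y <- as.matrix(read.table(args[1]))
            aff <- scan(args[2], quiet=TRUE)
            design <- cbind(1, aff)
            fit <- eBayes(lmFit(Y, design))
            out <- cbind(fit$t[,2], fit$p.value[,2], fit$df.prior, fit$s2.prior)
            write.table(out, args[3], row.names=FALSE, col.names=FALSE)
        """)
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "y.tsv"),
                        str(tmp_path / "aff.tsv"), str(tmp_path / "out.tsv")],
                       check=True, capture_output=True)
        oracle = np.loadtxt(tmp_path / "out.tsv")
        fits = fit_gene_models(_frame(Y), make_design(aff), np.array(["a"] * n), 0.0)
        prior, out = ebayes_moderate(fits)
        np.testing.assert_allclose(out["moderated_t"], oracle[:, 0], rtol=1e-6)
        np.testing.assert_allclose(out["p_value"], oracle[:, 1], rtol=1e-6)
        assert prior.d0 == pytest.approx(oracle[0, 2], rel=1e-4)
        assert prior.s0_sq == pytest.approx(oracle[0, 3], rel=1e-4)


class TestWholeModuleOracle:
    def test_twenty_gene_fixture_end_to_end(self):
        """Dense-matrix route: explicit Sigma inverse + brentq moment equations."""
        rng = np.random.default_rng(12)
        G = 20
        block = np.repeat(["a", "b", "c", "d"], 5)
        aff = np.tile([1.0, 0.0, 0.0, 0.0, 0.0], 4)
        rho = 0.3
        design = make_design(aff)
        Sigma = np.kron(np.eye(4), (1 - rho) * np.eye(5) + rho)
        Y = rng.normal(size=(G, 20))
        fits = fit_gene_models(_frame(Y), design, block, consensus_rho=rho)
        beta, sigma2, se_u = dense_gls_oracle(Y, design, Sigma)
        np.testing.assert_allclose(fits["coef_1"], beta[:, 1], atol=1e-8)
        np.testing.assert_allclose(fits["sigma2"], sigma2, atol=1e-8)
        prior, out = ebayes_moderate(fits)
        d0_o, s0_o = _moment_oracle(sigma2, 18.0)
        df_tot = 18.0 + d0_o
        s2_post = (d0_o * s0_o + 18.0 * sigma2) / df_tot if np.isfinite(d0_o) else s0_o
        t_o = beta[:, 1] / (np.sqrt(s2_post) * se_u[1])
        p_o = 2 * stats.t.sf(np.abs(t_o), df_tot) if np.isfinite(d0_o) \
            else 2 * stats.norm.sf(np.abs(t_o))
        np.testing.assert_allclose(out["moderated_t"], t_o, atol=1e-8)
        np.testing.assert_allclose(out["p_value"], p_o, atol=1e-8)


class TestOnSyntheticData:
    def test_planted_recall_and_fdr(self, cortical_selection, small_atlas):
        X, donors, affected = cortical_selection
        norm = normalize(X, donors)
        de = run_de(norm, affected, donors.to_numpy())
        higher, lower = de.called()
        called = higher | lower
        planted = set(small_atlas.truth.planted_de_genes)
        assert len(called & planted) / len(planted) >= 0.8
        assert len(called - planted) / max(len(called), 1) <= 0.10
        for g in called & planted:
            sign = small_atlas.truth.planted_de_genes[g] > 0
            assert (g in higher) == sign
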