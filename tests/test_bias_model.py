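"""Tests for log-bias estimation, effect sizes and permutation inference."""

import numpy as np
import pandas as pd
import pytest

import mockbias as mb
from mockbias import datasets, pipeline
from mockbias.bias_model import empirical_pvalue


def _clr_frames(rng, n=16, j=8, protocols=("Base", "Enzymes", "Lifeguard",
                                           "RNAProtect")):
    """Random row-aligned clr-like observation/truth matrices and design."""
    obs = rng.normal(size=(n, j))
    obs -= obs.mean(axis=1, keepdims=True)
    truth = rng.normal(size=j)
    truth -= truth.mean()
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "sample_set": "ZMC",
            "protocol": [protocols[i % len(protocols)] for i in range(n)],
            "replicate": [i // len(protocols) + 1 for i in range(n)],
            "product": "",
        }
    )
    Y = pd.DataFrame(obs, index=meta["sample_id"],
                     columns=[f"t{k}" for k in range(j)])
    design = mb.build_design(meta)
    design.index = Y.index
    return Y, pd.Series(truth, index=Y.columns), design, meta


class TestFitBias:
    def test_zero_bias_when_observation_equals_truth(self):
        rng = np.random.default_rng(0)
        Y, truth, design, _ = _clr_frames(rng)
        Y.iloc[:] = np.broadcast_to(truth.to_numpy(), Y.shape)
        fit = mb.fit_bias(Y, truth, design)
        np.testing.assert_allclose(fit.beta_hat.to_numpy(), 0.0, atol=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_constant_protocol_rows_returned_exactly(self):
        rng = np.random.default_rng(1)
        Y, truth, design, meta = _clr_frames(rng)
        v = rng.normal(size=Y.shape[1])
        base_rows = meta["protocol"].eq("Base").to_numpy()
        Y.iloc[base_rows] = truth.to_numpy() + v
        fit = mb.fit_bias(Y, truth, design)
        np.testing.assert_allclose(fit.beta_hat.loc["Base"], v, atol=1e-10)

    def test_equals_per_protocol_mean_oracle(self):
        rng = np.random.default_rng(2)
        Y, truth, design, meta = _clr_frames(rng)
        fit = mb.fit_bias(Y, truth, design)
        R = Y.to_numpy() - truth.to_numpy()
        for k in design.columns:
            rows = meta["protocol"].eq(k).to_numpy()
            np.testing.assert_allclose(
                fit.beta_hat.loc[k], R[rows].mean(axis=0), atol=1e-10
            )

    def test_rss_is_squared_frobenius_norm_of_residuals(self):
        rng = np.random.default_rng(3)
        Y, truth, design, _ = _clr_frames(rng)
        fit = mb.fit_bias(Y, truth, design)
        assert fit.rss == pytest.approx(
            float((fit.residuals.to_numpy() ** 2).sum()), rel=1e-10
        )

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(4)
        Y, truth, design, _ = _clr_frames(rng)
        design = design.copy()
        design["Extra"] = design["Base"]
        with pytest.raises(ValueError, match="rank-deficient"):
            mb.fit_bias(Y, truth, design)

    def test_column_centering_preserves_contrasts_and_distances(self):
        rng = np.random.default_rng(5)
        Y, truth, design, _ = _clr_frames(rng)
        fit = mb.fit_bias(Y, truth, design)
        centered = fit.center()
        assert centered.centered
        np.testing.assert_allclose(
            centered.beta_hat.sum(axis=0), 0.0, atol=1e-10
        )
        for pair in [("Base", "Enzymes"), ("Lifeguard", "RNAProtect")]:
            assert mb.effect_size(fit, pair) == pytest.approx(
                mb.effect_size(centered, pair), rel=1e-12
            )
        np.testing.assert_allclose(
            mb.bias_distance_matrix(fit).values(),
            mb.bias_distance_matrix(centered).values(),
            atol=1e-12,
        )


class TestFitRelativeBias:
    def test_single_pair_recovers_clr_difference(self):
        rng = np.random.default_rng(6)
        Y, _, _, meta = _clr_frames(rng, n=2, protocols=("Base", "Enzymes"))
        fit = mb.fit_relative_bias(Y, meta, reference="Enzymes")
        np.testing.assert_allclose(
            fit.beta_hat.loc["Base"],
            Y.iloc[0].to_numpy() - Y.iloc[1].to_numpy(),
            atol=1e-12,
        )
        np.testing.assert_allclose(fit.beta_hat.loc["Enzymes"], 0.0)

    def test_common_shift_of_all_samples_cancels(self):
        rng = np.random.default_rng(7)
        Y, _, _, meta = _clr_frames(rng)
        fit1 = mb.fit_relative_bias(Y, meta, reference="RNAProtect")
        shifted = Y + rng.normal(size=Y.shape[1])
        fit2 = mb.fit_relative_bias(shifted, meta, reference="RNAProtect")
        np.testing.assert_allclose(
            fit1.beta_hat.to_numpy(), fit2.beta_hat.to_numpy(), atol=1e-10
        )

    def test_matches_direct_fit_row_differences_with_exhaustive_pairs(
        self, prepared
    ):
        Y, meta, t_clr, design = prepared
        direct = mb.fit_bias(Y, t_clr, design)
        rel = mb.fit_relative_bias(Y, meta, reference="RNAProtect")
        for k in ("Base", "Enzymes", "Lifeguard"):
            np.testing.assert_allclose(
                rel.beta_hat.loc[k] - rel.beta_hat.loc["RNAProtect"],
                direct.beta_hat.loc[k] - direct.beta_hat.loc["RNAProtect"],
                atol=1e-10,
            )

    def test_single_protocol_group_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        Y, _, _, meta = _clr_frames(rng, n=6, protocols=("Base", "Enzymes"))
        meta["product"] = ["P1"] * 4 + ["P2"] * 2
        meta.loc[meta["product"] == "P2", "protocol"] = "Base"
        with pytest.warns(UserWarning, match="single protocol"):
            fit = mb.fit_relative_bias(Y, meta, reference="Enzymes",
                                       pair_within="product")
        assert fit.beta_hat.shape[0] == 2

    def test_no_usable_pairs_raises(self):
        rng = np.random.default_rng(9)
        Y, _, _, meta = _clr_frames(rng, n=4, protocols=("Base",))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable"):
                mb.fit_relative_bias(Y, meta, reference="Base")


class TestEffectSize:
    def test_published_per_protocol_value(self, zmc_beta):
        assert mb.effect_size(zmc_beta, "Base") == pytest.approx(0.141, abs=0.002)

    def test_published_pairwise_value(self, zmc_beta):
        assert mb.effect_size(zmc_beta, ("Base", "Enzymes")) == pytest.approx(
            0.016, abs=0.002
        )

    def test_zero_matrix(self):
        beta = pd.DataFrame(np.zeros((2, 4)), index=["Base", "Enzymes"])
        assert mb.effect_size(beta, "Base") == 0.0
        assert mb.effect_size(beta, [("Base", "Enzymes"), "Base"]) == 0.0

    def test_unknown_row_raises(self, zmc_beta):
        with pytest.raises(KeyError):
            mb.effect_size(zmc_beta, "Phenol")


class TestPermutationFTest:
    def test_rejects_invalid_n_perm(self, prepared):
        Y, _, t_clr, design = prepared
        with pytest.raises(ValueError):
            mb.permutation_f_test(Y, t_clr, design, mb.NullSpec.no_bias("Base"),
                                  n_perm=0)

    def test_ill_posed_contrast_rejected(self):
        rng = np.random.default_rng(10)
        Y, truth, design, _ = _clr_frames(rng, n=4, protocols=("Base",))
        with pytest.raises(ValueError, match="ill-posed"):
            mb.permutation_f_test(
                Y, truth, design, mb.NullSpec.equal(("Base",)), n_perm=10
            )

    def test_zero_residual_reports_infinite_f(self):
        rng = np.random.default_rng(11)
        Y, truth, design, meta = _clr_frames(rng, n=8)
        # protocol-constant responses: the saturated model fits exactly
        for k in meta["protocol"].unique():
            rows = meta["protocol"].eq(k).to_numpy()
            Y.iloc[rows] = truth.to_numpy() + len(k)
        res = mb.permutation_f_test(
            Y, truth, design, mb.NullSpec.no_bias("Base"), n_perm=20, seed=0
        )
        assert np.isinf(res.f_stat)
        assert 0.0 <= res.p_value <= 1.0

    def test_deterministic_under_fixed_seed(self, prepared):
        Y, _, t_clr, design = prepared
        kw = dict(n_perm=50, seed=123)
        a = mb.permutation_f_test(Y, t_clr, design,
                                  mb.NullSpec.no_bias("Base"), **kw)
        b = mb.permutation_f_test(Y, t_clr, design,
                                  mb.NullSpec.no_bias("Base"), **kw)
        assert a.p_value == b.p_value and a.f_stat == b.f_stat

    def test_detects_a_strongly_biased_protocol(self, prepared):
        Y, _, t_clr, design = prepared
        res = mb.permutation_f_test(
            Y, t_clr, design, mb.NullSpec.no_bias("Base"), n_perm=500, seed=2
        )
        assert res.p_value < 0.01

    def test_label_scheme_also_detects_bias(self, prepared):
        Y, _, t_clr, design = prepared
        res = mb.permutation_f_test(
            Y, t_clr, design, mb.NullSpec.no_bias("Base"), n_perm=500, seed=2,
            scheme="labels",
        )
        assert res.p_value < 0.01

    def test_single_protocol_type_one_error_near_nominal(self):
        """Rejection rate at alpha=0.05 over null simulations stays in a
        generous Monte-Carlo band (the bulk of the permutation distribution
        is conservative at this tiny design, but the tail is calibrated)."""
        rej = 0
        n_sim = 200
        for s in range(n_sim):
            study = mb.simulate_counts(mb.SimulationConfig(seed=70_000 + s))
            Y, meta = pipeline.prepare_clr(study.counts, study.meta)
            t_clr = pipeline.truth_clr(
                pd.Series(study.truth.iloc[0], index=Y.columns), Y.columns
            )
            design = mb.build_design(meta)
            design.index = Y.index
            res = mb.permutation_f_test(
                Y, t_clr, design, mb.NullSpec.no_bias("Base"),
                n_perm=100, seed=s,
            )
            rej += res.p_value <= 0.05
        assert 0.01 <= rej / n_sim <= 0.11

    def test_effect_size_matches_generating_bias(self, prepared, mock_study):
        Y, _, t_clr, design = prepared
        res = mb.permutation_f_test(
            Y, t_clr, design, mb.NullSpec.no_bias("Lifeguard"), n_perm=10,
            seed=0,
        )
        truth_es = float(
            np.mean(mock_study.beta_true.loc["Lifeguard"].to_numpy() ** 2)
        )
        # clr-centering of the generating rows shifts each by its row mean,
        # so agreement is approximate but close at depth 1e5
        assert res.effect_size == pytest.approx(truth_es, abs=0.05)


class TestRelativePermutationTest:
    def test_null_data_gives_moderate_p(self):
        study = mb.simulate_paired_study(
            mb.SimulationConfig(seed=21, products=3, depth=5e4)
        )
        Y, meta = pipeline.prepare_clr(study.counts, study.meta)
        res = mb.relative_bias_permutation_test(
            Y, meta, reference="RNAProtect",
            null_spec=mb.NullSpec.equal(("Base", "Enzymes")),
            pair_within="product", n_perm=99, seed=0,
        )
        assert res.p_value > 0.05

    def test_biased_data_gives_small_p(self, zmc_beta):
        beta = zmc_beta.to_numpy()[:, :8] * 3
        study = mb.simulate_paired_study(
            mb.SimulationConfig(seed=22, products=3, depth=1e5,
                                n_taxa_paired=8, beta_true=beta)
        )
        Y, meta = pipeline.prepare_clr(study.counts, study.meta)
        # a zero row in the relative model means "equal to the reference"
        res = mb.relative_bias_permutation_test(
            Y, meta, reference="RNAProtect",
            null_spec=mb.NullSpec.no_bias("Enzymes"),
            pair_within="product", n_perm=99, seed=0,
        )
        assert res.p_value < 0.05


class TestRecoveryImprovesWithReplicates:
    def test_rmse_decreases_from_2_to_8_replicates(self, zmc_beta):
        """Centered-beta RMSE shrinks as replication grows (averaged over
        seeds to stay within Monte-Carlo error)."""
        beta = zmc_beta.to_numpy()
        truth = datasets.zymo_truth(tuple(zmc_beta.columns))
        rmse = {}
        for reps in (2, 4, 8):
            errs = []
            for seed in range(6):
                cfg = mb.SimulationConfig(
                    truth=truth, beta_true=beta, taxa=tuple(zmc_beta.columns),
                    replicates=reps, depth=1e5, seed=1000 * reps + seed,
                )
                study = mb.simulate_counts(cfg)
                Y, meta = pipeline.prepare_clr(study.counts, study.meta)
                t_clr = pipeline.truth_clr(
                    pd.Series(truth, index=Y.columns), Y.columns
                )
                design = mb.build_design(meta)
                design.index = Y.index
                est = mb.fit_bias(Y, t_clr, design).center().beta_hat.to_numpy()
                target = beta - beta.mean(axis=0)
                errs.append(np.sqrt(np.mean((est - target) ** 2)))
            rmse[reps] = np.mean(errs)
        assert rmse[8] < rmse[4] < rmse[2]


class TestEmpiricalPvalue:
    def test_add_one_mode_never_zero(self):
        assert empirical_pvalue(10.0, np.array([1.0, 2.0]), "add_one") == 1 / 3

    def test_literal_mode_counts_strictly_greater(self):
        assert empirical_pvalue(2.0, np.array([1.0, 2.0, 3.0]), "literal") == 1 / 3

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.array([1.0]), "bayes")
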