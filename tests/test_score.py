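import json

import numpy as np
import pandas as pd
import pytest

from gmspipe import (build_gms_model, compute_gms, fit_species_associations,
                     clr_transform, filter_species, inverse_sqrt_correlation,
                     tertile_assign, validate_gms, GmsModel)
from gmspipe.prep import ClrMatrix
from tests.conftest import COVARIATES


def random_correlation(k, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(k, k + 10))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestInverseSqrt:
    def test_identity(self):
        np.testing.assert_allclose(
            inverse_sqrt_correlation(np.eye(4)), np.eye(4), atol=1e-12)

    def test_two_by_two_closed_form(self):
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        W = inverse_sqrt_correlation(sigma)
        # eigenvalues 1.5 and 0.5; W = sum of lambda^{-1/2} projectors
        expected_diag = 0.5 * (1.5 ** -0.5 + 0.5 ** -0.5)
        expected_off = 0.5 * (1.5 ** -0.5 - 0.5 ** -0.5)
        np.testing.assert_allclose(np.diag(W), expected_diag, atol=1e-10)
        assert W[0, 1] == pytest.approx(expected_off, abs=1e-10)
        assert W[0, 1] == pytest.approx(-0.2989, abs=1e-4)
        assert W[0, 0] == pytest.approx(1.1154, abs=1e-4)

    def test_whitening_property(self):
        for seed, k in [(0, 3), (1, 8), (2, 15)]:
            sigma = random_correlation(k, seed)
            W = inverse_sqrt_correlation(sigma)
            np.testing.assert_allclose(W @ sigma @ W, np.eye(k), atol=1e-6)
            np.testing.assert_allclose(W, W.T, atol=1e-12)

    def test_singular_input_floored(self, caplog):
        sigma = np.array([[1.0, 1.0], [1.0, 1.0]])  # duplicated species
        with caplog.at_level("WARNING", logger="gmspipe.score"):
            W = inverse_sqrt_correlation(sigma)
        assert np.all(np.isfinite(W))
        assert any("flooring" in r.message for r in caplog.records)
        # whitening property fails gracefully rather than blowing up
        assert not np.allclose(W @ sigma @ W, np.eye(2), atol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="symmetric"):
            inverse_sqrt_correlation(np.array([[1.0, 0.2], [0.4, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            inverse_sqrt_correlation(np.array([[2.0, 0.0], [0.0, 2.0]]))


def diff_frame(species, lfc, p):
    return pd.DataFrame({
        "species_id": species, "stratum": "noncarrier", "lfc": lfc,
        "se": 0.1, "p_value": p, "q_value": p, "n_used": 100,
    })


def clr_fixture(seed=0, k=5, n=400):
    # independent rows standing in for a few selected species out of many
    # (centering over the full species set would add only ~ -1/K correlation)
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(k, n))
    return ClrMatrix(pd.DataFrame(values,
                                  index=[f"sp{i}" for i in range(k)],
                                  columns=[f"s{j}" for j in range(n)]),
                     pseudocount=0.5)


class TestBuildModel:
    def test_beta_passthrough(self):
        clr = clr_fixture(k=5)
        diff = diff_frame([f"sp{i}" for i in range(5)],
                          [0.5, -0.2, 0.3, 0.1, -0.4],
                          [0.001, 0.01, 0.002, 0.04, 0.001])
        model = build_gms_model(diff, clr)
        assert model.k == 5
        np.testing.assert_allclose(model.beta, diff["lfc"])
        np.testing.assert_allclose(np.diag(model.sigma), 1.0, atol=1e-10)

    def test_selection_by_p(self):
        clr = clr_fixture(k=5)
        diff = diff_frame([f"sp{i}" for i in range(5)],
                          [0.5, -0.2, 0.3, 0.1, -0.4],
                          [0.001, 0.2, 0.002, 0.5, 0.3])
        model = build_gms_model(diff, clr)
        assert model.species_ids == ["sp0", "sp2"]

    def test_too_few_selected(self):
        clr = clr_fixture(k=3)
        diff = diff_frame(["sp0", "sp1", "sp2"], [0.5, 0.2, 0.1],
                          [0.001, 0.2, 0.9])
        with pytest.raises(ValueError, match="at least 2"):
            build_gms_model(diff, clr)

    def test_constant_clr_row_rejected(self):
        clr = clr_fixture(k=3)
        clr.values.iloc[1] = 0.0
        diff = diff_frame(["sp0", "sp1", "sp2"], [0.5, 0.2, 0.1],
                          [0.001, 0.002, 0.9])
        with pytest.raises(ValueError, match="constant"):
            build_gms_model(diff, clr)

    def test_independent_species_whitening_near_identity(self):
        clr = clr_fixture(seed=5, k=4, n=5000)
        diff = diff_frame([f"sp{i}" for i in range(4)], [1.0, 1.0, 1.0, 1.0],
                          [0.001] * 4)
        model = build_gms_model(diff, clr)
        np.testing.assert_allclose(model.whitening, np.eye(4), atol=0.06)
        scores = compute_gms(model, clr)
        plain = model.beta @ clr.values.loc[model.species_ids].to_numpy()
        r = np.corrcoef(scores.scores, plain)[0, 1]
        assert r > 0.99

    def test_permutation_invariance(self):
        clr = clr_fixture(k=5)
        species = [f"sp{i}" for i in range(5)]
        diff = diff_frame(species, [0.5, -0.2, 0.3, 0.1, -0.4], [0.01] * 5)
        base = compute_gms(build_gms_model(diff, clr), clr)
        shuffled = diff.iloc[[3, 1, 4, 0, 2]].reset_index(drop=True)
        perm = compute_gms(build_gms_model(shuffled, clr), clr)
        np.testing.assert_allclose(base.scores, perm.scores, atol=1e-10)

    def test_json_roundtrip(self, tmp_path):
        clr = clr_fixture(k=4)
        diff = diff_frame([f"sp{i}" for i in range(4)],
                          [0.5, -0.2, 0.3, 0.1], [0.01] * 4)
        model = build_gms_model(diff, clr)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = GmsModel.from_json(path)
        assert back.species_ids == model.species_ids
        np.testing.assert_allclose(back.whitening, model.whitening)
        scores_a = compute_gms(model, clr).scores
        scores_b = compute_gms(back, clr).scores
        np.testing.assert_allclose(scores_a, scores_b, atol=1e-12)


class TestComputeGms:
    def test_scalar_case(self):
        clr = clr_fixture(k=1)
        model = GmsModel(stratum="noncarrier", species_ids=["sp0"],
                         beta=np.array([2.0]), sigma=np.eye(1),
                         whitening=np.eye(1))
        scores = compute_gms(model, clr, assign_tertiles=False)
        np.testing.assert_allclose(scores.scores,
                                   2.0 * clr.values.loc["sp0"], atol=1e-12)

    def test_identity_sigma_plain_weighted_sum(self):
        clr = clr_fixture(k=3)
        beta = np.array([1.0, -0.5, 0.25])
        model = GmsModel(stratum="noncarrier",
                         species_ids=["sp0", "sp1", "sp2"],
                         beta=beta, sigma=np.eye(3), whitening=np.eye(3))
        scores = compute_gms(model, clr, assign_tertiles=False)
        np.testing.assert_allclose(scores.scores,
                                   beta @ clr.values.to_numpy(), atol=1e-12)

    def test_two_species_hand_value(self):
        values = pd.DataFrame([[1.0], [1.0]], index=["a", "b"],
                              columns=["s0"])
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        model = GmsModel(stratum="x", species_ids=["a", "b"],
                         beta=np.array([1.0, 1.0]), sigma=sigma,
                         whitening=inverse_sqrt_correlation(sigma))
        scores = compute_gms(model, ClrMatrix(values, 0.5),
                             assign_tertiles=False)
        assert scores.scores.iloc[0] == pytest.approx(1.633, abs=1e-3)

    def test_linearity_in_beta(self):
        clr = clr_fixture(k=3)
        sigma = random_correlation(3, 7)
        model = GmsModel(stratum="x", species_ids=["sp0", "sp1", "sp2"],
                         beta=np.array([0.5, -0.3, 0.2]), sigma=sigma,
                         whitening=inverse_sqrt_correlation(sigma))
        doubled = GmsModel(stratum="x", species_ids=model.species_ids,
                           beta=2 * model.beta, sigma=sigma,
                           whitening=model.whitening)
        a = compute_gms(model, clr, assign_tertiles=False).scores
        b = compute_gms(doubled, clr, assign_tertiles=False).scores
        np.testing.assert_allclose(b, 2 * a, atol=1e-12)

    def test_missing_species_listed(self):
        clr = clr_fixture(k=2)
        model = GmsModel(stratum="x", species_ids=["sp0", "ghost"],
                         beta=np.array([1.0, 1.0]), sigma=np.eye(2),
                         whitening=np.eye(2))
        with pytest.raises(KeyError, match="ghost"):
            compute_gms(model, clr)

    def test_in_sample_whitening(self, planted_cohort):
        cohort, counts, _ = planted_cohort
        filt = filter_species(counts)
        clr = clr_transform(filt)
        diff = fit_species_associations(filt, cohort, "noncarrier", COVARIATES)
        samples = cohort.index[cohort.genotype_group == "noncarrier"].tolist()
        model = build_gms_model(diff, clr, samples, stratum="noncarrier")
        X = clr.values.loc[model.species_ids, samples].to_numpy()
        whitened = model.whitening @ X
        corr = np.corrcoef(whitened)
        np.testing.assert_allclose(corr, np.eye(model.k), atol=0.05)


class TestTertiles:
    def test_balanced_split(self):
        np.testing.assert_array_equal(tertile_assign([1, 2, 3, 4, 5, 6]),
                                      [1, 1, 2, 2, 3, 3])

    def test_seven_values(self):
        sizes = np.bincount(tertile_assign(np.arange(1.0, 8.0)))[1:]
        assert sizes.tolist() == [3, 2, 2]

    def test_order_independent_of_input_order(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        perm = rng.permutation(30)
        assert (tertile_assign(x)[perm] == tertile_assign(x[perm])).all()

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            tertile_assign([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            tertile_assign([1.0, 2.0])

    def test_near_balanced_sizes(self):
        for n in (9, 10, 11, 50, 101):
            sizes = np.bincount(tertile_assign(np.arange(float(n))))[1:]
            assert sizes.max() - sizes.min() <= 1


class TestValidateGms:
    def test_matching_stratum_significant(self, planted_cohort):
        cohort, counts, _ = planted_cohort
        filt = filter_species(counts)
        clr = clr_transform(filt)
        diff = fit_species_associations(filt, cohort, "noncarrier", COVARIATES)
        samples = cohort.index[cohort.genotype_group == "noncarrier"].tolist()
        model = build_gms_model(diff, clr, samples, stratum="noncarrier")
        scores = compute_gms(model, clr)
        res = validate_gms(scores.scores, cohort, "noncarrier", COVARIATES)
        assert res["p_value"] < 1e-6
        assert res["direction"] == "positive"

    def test_noise_score_null(self, null_cohort):
        cohort, _, _ = null_cohort
        rng = np.random.default_rng(8)
        noise = pd.Series(rng.normal(size=len(cohort)), index=cohort.index)
        res = validate_gms(noise, cohort, "noncarrier", COVARIATES)
        assert abs(res["coef"]) < 0.15
        assert res["p_value"] > 0.001

    def test_constant_alcohol_rejected(self, null_cohort):
        cohort, _, _ = null_cohort
        flat = cohort.copy()
        flat["alcohol_level"] = 1
        noise = pd.Series(0.0, index=cohort.index)
        with pytest.raises(ValueError):
            validate_gms(noise, flat, "noncarrier", COVARIATES)
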