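"""Design construction, identifiability, and parameter recovery."""

import numpy as np
import pytest

from bosbench import fragregress as fg
from bosbench.errors import ValidationError
from bosbench.fragmentation import FragmentCode

ALL_CODES = FragmentCode.all_codes()


def random_truth(seed, d_scale=0.01, f_scale=0.005,
                 beta0=0.3, gamma1=0.05, gamma2=0.004):
    # beta0 keeps the noise-free surface inside [0, 1] at N = 8
    # (0.3 + 8 * 0.05 + 64 * 0.004 < 1), so clipping never distorts it
    rng = np.random.default_rng(seed)
    d = rng.normal(0, d_scale, 8)
    d -= d.mean()
    f = rng.normal(0, f_scale, 28)
    f -= f.mean()
    return fg.make_truth(beta0, gamma1, gamma2, d, f)


class TestDesign:
    def test_all_present_row(self):
        row = fg.build_design([FragmentCode("11111111")]).iloc[0]
        assert row["const"] == 1
        assert all(row[f"F{i}"] == 1 for i in range(1, 9))
        assert row["N"] == 8 and row["N2"] == 64
        assert all(row[f"F{i}F{j}"] == 1 for i, j in fg.PAIRS)

    def test_all_absent_row(self):
        row = fg.build_design([FragmentCode("00000000")]).iloc[0]
        assert row.drop("const").sum() == 0

    def test_full_design_rank_is_37(self):
        X = fg.build_design(ALL_CODES).to_numpy()
        assert X.shape == (256, 39)
        assert np.linalg.matrix_rank(X) == 37

    def test_collinearity_identities_on_the_cube(self):
        X = fg.build_design(ALL_CODES)
        F = X[[f"F{i}" for i in range(1, 9)]].to_numpy()
        P = X[[f"F{i}F{j}" for i, j in fg.PAIRS]].to_numpy()
        assert np.array_equal(X["N"].to_numpy(), F.sum(axis=1))
        assert np.array_equal(X["N2"].to_numpy(),
                              F.sum(axis=1) + 2 * P.sum(axis=1))


class TestFit:
    def test_constant_response_gives_pure_intercept(self):
        res = fg.FragmentRegression(np.full(256, 0.8), ALL_CODES).fit()
        assert res.beta0 == pytest.approx(0.8, abs=1e-12)
        for v in (res.gamma1, res.gamma2, *res.d, *res.f):
            assert abs(v) < 1e-10

    def test_sum_to_zero_constraints_hold(self):
        R = fg.simulate_accuracies(random_truth(0), 0.01, rng=1)
        res = fg.FragmentRegression(R, ALL_CODES).fit()
        assert res.d.sum() == pytest.approx(0.0, abs=1e-10)
        assert res.f.sum() == pytest.approx(0.0, abs=1e-10)

    def test_two_stage_equals_one_stage_on_balanced_design(self):
        R = fg.simulate_accuracies(random_truth(5), 0.01, rng=2)
        m = fg.FragmentRegression(R, ALL_CODES)
        a, b = m.fit("two-stage"), m.fit("one-stage")
        assert abs(a.beta0 - b.beta0) < 1e-8
        assert abs(a.gamma1 - b.gamma1) < 1e-8
        assert abs(a.gamma2 - b.gamma2) < 1e-8
        assert np.abs(a.d - b.d).max() < 1e-8
        assert np.abs(a.f - b.f).max() < 1e-8

    def test_f8_only_effect_yields_maximal_d8(self):
        rng = np.random.default_rng(3)
        R = np.full(256, 0.6)
        f8 = np.array([c.present(8) for c in ALL_CODES])
        R[f8] += 0.2
        R += rng.normal(0, 0.005, 256)
        res = fg.FragmentRegression(np.clip(R, 0, 1), ALL_CODES).fit()
        assert np.argmax(res.d) == 7

    def test_too_few_distinct_codes_rejected(self):
        codes = ALL_CODES[:30]
        with pytest.raises(ValidationError):
            fg.FragmentRegression(np.full(30, 0.5), codes)

    def test_stage1_invariant_under_fragment_permutation(self):
        R = fg.simulate_accuracies(random_truth(7), 0.0, rng=0)
        perm = np.array([3, 1, 4, 0, 6, 2, 7, 5])
        permuted = [FragmentCode("".join(c.digits[p] for p in perm))
                    for c in ALL_CODES]
        a = fg.FragmentRegression(R, ALL_CODES).fit()
        b = fg.FragmentRegression(R, permuted).fit()
        assert a.gamma1 == pytest.approx(b.gamma1, abs=1e-10)
        assert a.gamma2 == pytest.approx(b.gamma2, abs=1e-10)
        assert a.beta0 == pytest.approx(b.beta0, abs=1e-10)

    def test_predict_reproduces_noise_free_response(self):
        truth = random_truth(11)
        R = fg.simulate_accuracies(truth, 0.0, rng=0)
        res = fg.FragmentRegression(R, ALL_CODES).fit()
        assert np.abs(res.predict(ALL_CODES) - R).max() < 1e-9

    def test_parameter_recovery_within_three_se(self):
        truth = random_truth(21)
        hits = total = 0
        for rep in range(30):
            R = fg.simulate_accuracies(truth, 0.005, rng=1000 + rep)
            res = fg.FragmentRegression(R, ALL_CODES).fit()
            est = np.concatenate([[res.beta0, res.gamma1, res.gamma2],
                                  res.d, res.f])
            se = np.concatenate([[res.bse_beta0], res.bse_gamma,
                                 res.bse_d, res.bse_f])
            tru = np.concatenate([[truth.beta0, truth.gamma1, truth.gamma2],
                                  truth.d, truth.f])
            hits += int((np.abs(est - tru) <= 3 * se).sum())
            total += len(tru)
        assert hits / total >= 0.95


class TestAvailabilityCurve:
    def test_null_quadratic_recovered(self):
        truth = random_truth(2, gamma2=0.0)
        R = fg.simulate_accuracies(truth, 0.003, rng=4)
        res = fg.FragmentRegression(R, ALL_CODES).fit()
        assert abs(res.gamma2) < 3 * res.bse_gamma[1] + 1e-3

    def test_f8_strata_separated_by_injected_offset(self):
        R = np.full(256, 0.55)
        f8 = np.array([c.present(8) for c in ALL_CODES])
        R[f8] += 0.3
        res = fg.FragmentRegression(R, ALL_CODES).fit()
        out = fg.availability_curve(res)
        mid = 4.0
        present = (out["f8_present"]["beta0"] + out["f8_present"]["gamma1"]
                   * mid + out["f8_present"]["gamma2"] * mid ** 2)
        absent = (out["f8_absent"]["beta0"] + out["f8_absent"]["gamma1"]
                  * mid + out["f8_absent"]["gamma2"] * mid ** 2)
        assert present - absent == pytest.approx(0.3, abs=0.02)

    def test_scatter_has_one_point_per_code(self):
        R = fg.simulate_accuracies(random_truth(6), 0.01, rng=5)
        res = fg.FragmentRegression(R, ALL_CODES).fit()
        assert len(fg.availability_curve(res)["scatter"]) == 256


class TestSimulate:
    def test_zero_noise_returns_mean_surface(self):
        truth = random_truth(9)
        R = fg.simulate_accuracies(truth, 0.0, rng=0)
        assert np.allclose(R, truth.predict(ALL_CODES))

    def test_sample_variance_matches_sigma(self):
        truth = random_truth(10, d_scale=0.0, f_scale=0.0,
                             gamma1=0.0, gamma2=0.0)
        sigma = 0.01
        draws = np.stack([fg.simulate_accuracies(truth, sigma, rng=s)
                          for s in range(60)])
        assert np.sqrt(draws.var(axis=0).mean()) == pytest.approx(sigma,
                                                                  rel=0.1)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            fg.simulate_accuracies(random_truth(0), -0.1)

    def test_summary_and_frames_render(self):
        R = fg.simulate_accuracies(random_truth(12), 0.01, rng=3)
        res = fg.FragmentRegression(R, ALL_CODES).fit()
        assert "gamma1" in res.summary()
        frame = res.to_frame()
        assert len(frame) == 39
        mat = res.interaction_matrix
        assert np.isfinite(mat.to_numpy()[np.triu_indices(8, 1)]).all()
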