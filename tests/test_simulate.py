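import numpy as np
import pytest

from pvbcorrect import (
    ScenarioConfig,
    apply_mar_verification,
    cross_tabulate,
    expected_verification_rate,
    generate_complete,
    generate_valid_scenario,
    multinomial_cell_probs,
)
from pvbcorrect.simulate import (
    GRID_PREVALENCES,
    GRID_SNSP_PAIRS,
    ScenarioError,
    dataset_is_valid,
    grid_configs,
)


def _config(**kw):
    base = dict(p=0.4, sn_true=0.3, sp_true=0.6, n=200)
    base.update(kw)
    return ScenarioConfig(**base)


class TestCellProbs:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0.4, 0.3, 0.6), (0.12, 0.28, 0.24, 0.36)),
            ((0.1, 0.9, 0.9), (0.09, 0.01, 0.09, 0.81)),
        ],
    )
    def test_hand_products(self, args, expected):
        assert multinomial_cell_probs(*args) == pytest.approx(expected)

    def test_sum_to_one_across_grid(self):
        for p in GRID_PREVALENCES:
            for sn, sp in GRID_SNSP_PAIRS:
                assert sum(multinomial_cell_probs(p, sn, sp)) == pytest.approx(1.0)

    def test_rejects_boundary_probabilities(self):
        with pytest.raises(ValueError):
            multinomial_cell_probs(0.0, 0.5, 0.5)


class TestExpectedVerificationRate:
    def test_hand_evaluation(self):
        assert expected_verification_rate(_config()) == pytest.approx(0.544)
        assert expected_verification_rate(_config(sn_true=0.9)) == pytest.approx(0.64)

    def test_equal_lambdas_collapse_to_common_rate(self):
        cfg = _config(lambda1=0.55, lambda0=0.55)
        assert expected_verification_rate(cfg) == pytest.approx(0.55)

    @pytest.mark.parametrize(
        "p, printed",
        [(0.4, [0.54, 0.47, 0.59, 0.52, 0.64, 0.57]),
         (0.1, [0.56, 0.45, 0.57, 0.46, 0.58, 0.47])],
    )
    def test_matches_published_rates_to_2dp(self, p, printed):
        rates = [
            expected_verification_rate(_config(p=p, sn_true=sn, sp_true=sp))
            for sn, sp in GRID_SNSP_PAIRS
        ]
        assert [round(r, 2) for r in rates] == printed


class TestGenerateComplete:
    def test_exact_size_and_all_verified(self, rng):
        data = generate_complete(_config(n=4), rng)
        assert data.n == 4 and data.is_complete

    def test_cell_fractions_within_3se(self, rng):
        n = 1_000_000
        data = generate_complete(_config(n=n), rng)
        table = cross_tabulate(data)
        for observed, pi in zip(table.cells, (0.12, 0.28, 0.24, 0.36)):
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(observed / n - pi) < 3 * se

    def test_deterministic_under_fixed_seed(self):
        a = generate_complete(_config(), np.random.default_rng(42))
        b = generate_complete(_config(), np.random.default_rng(42))
        assert np.array_equal(a.t, b.t) and np.array_equal(a.d, b.d)


class TestMARVerification:
    def test_full_verification_is_identity(self, rng):
        complete = generate_complete(_config(), rng)
        masked = apply_mar_verification(complete, 1.0, 1.0, rng)
        assert np.array_equal(masked.d, complete.d) and masked.is_complete

    def test_zero_verification_masks_everything(self, rng):
        complete = generate_complete(_config(), rng)
        masked = apply_mar_verification(complete, 0.0, 0.0, rng)
        assert masked.n1 == 0

    def test_verification_rates_converge_to_lambdas(self, rng):
        cfg = _config(n=100_000)
        complete = generate_complete(cfg, rng)
        masked = apply_mar_verification(complete, 0.8, 0.4, rng)
        for t, lam in ((1, 0.8), (0, 0.4)):
            sel = masked.t == t
            rate = masked.v[sel].mean()
            se = np.sqrt(lam * (1 - lam) / sel.sum())
            assert abs(rate - lam) < 3 * se

    def test_overall_rate_matches_analytic_value(self, rng):
        cfg = _config(n=200_000)
        complete = generate_complete(cfg, rng)
        masked = apply_mar_verification(complete, 0.8, 0.4, rng)
        assert masked.v.mean() == pytest.approx(0.544, abs=0.005)

    def test_missingness_ignorable_given_test_result(self, rng):
        """Within a test stratum, verified and unverified subjects have
        the same underlying disease rate (MAR through T only)."""
        cfg = _config(n=200_000)
        complete = generate_complete(cfg, rng)
        masked = apply_mar_verification(complete, 0.8, 0.4, rng)
        for t in (0, 1):
            sel = complete.t == t
            d_true = complete.d[sel]
            v = masked.v[sel]
            diff = d_true[v == 1].mean() - d_true[v == 0].mean()
            assert abs(diff) < 0.02


class TestValidityScreening:
    def test_returned_pair_passes_validity(self, rng):
        complete, pvb, attempts = generate_valid_scenario(_config(), rng)
        assert dataset_is_valid(complete) and dataset_is_valid(pvb)
        assert attempts >= 1

    def test_sparse_scenario_exhausts_retry_budget(self, rng):
        cfg = _config(p=0.001, n=20)
        with pytest.raises(ScenarioError, match="p=0.001"):
            generate_valid_scenario(cfg, rng, max_attempts=50)

    def test_reproducible_under_fixed_seed(self):
        a = generate_valid_scenario(_config(), np.random.default_rng(7))[1]
        b = generate_valid_scenario(_config(), np.random.default_rng(7))[1]
        assert np.array_equal(a.d, b.d) and np.array_equal(a.v, b.v)


class TestConfigValidation:
    def test_grid_has_24_cells(self):
        assert len(list(grid_configs())) == 24

    @pytest.mark.parametrize(
        "kw", [dict(p=0.0), dict(sn_true=1.0), dict(n=3), dict(B=0), dict(lambda1=1.5)]
    )
    def test_rejects_invalid_settings(self, kw):
        with pytest.raises(ValueError):
            _config(**{**dict(B=10), **kw})
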