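import numpy as np
import pytest

from pvbcorrect import (
    BalanceSpec,
    ScenarioConfig,
    draw_valid_resample,
    fit_propensity,
    generate_valid_scenario,
    ipb_estimate,
    sipw_estimate,
    sipw_weights,
    sipwb_estimate,
    sipwb_weights,
)
from pvbcorrect.data import PVBDataError, cell_ids
from pvbcorrect.resampling import PropensityError, ResamplingError, _resample_cell_counts

from conftest import brute_force_resampling_expectation, make_dataset


def _random_pvb(rng, n=150):
    cfg = ScenarioConfig(
        p=rng.uniform(0.15, 0.6),
        sn_true=rng.uniform(0.3, 0.9),
        sp_true=rng.uniform(0.3, 0.9),
        n=n,
    )
    while True:
        _, pvb, _ = generate_valid_scenario(cfg, rng)
        rates = [pvb.v[pvb.t == t].mean() for t in (0, 1)]
        if all(0 < r < 1 for r in rates):
            return pvb


class TestFitPropensity:
    def test_saturated_model_equals_stratum_proportions(self, spec_example_pvb):
        ps = fit_propensity(spec_example_pvb)
        assert ps[spec_example_pvb.t == 1] == pytest.approx(0.8, abs=1e-6)
        assert ps[spec_example_pvb.t == 0] == pytest.approx(0.4, abs=1e-6)

    def test_constant_verification_gives_constant_ps(self):
        data = make_dataset((6, 2, 2, 6), unverified_t1=8, unverified_t0=8)
        ps = fit_propensity(data)
        assert np.ptp(ps) == pytest.approx(0.0, abs=1e-6)

    def test_fully_verified_stratum_reports_separation(self):
        data = make_dataset((5, 2, 3, 4), unverified_t0=6)
        with pytest.raises(PropensityError, match="entirely"):
            fit_propensity(data)

    def test_recovers_lambdas_at_large_n(self, rng):
        cfg = ScenarioConfig(p=0.4, sn_true=0.3, sp_true=0.6, n=100_000)
        _, pvb, _ = generate_valid_scenario(cfg, rng)
        ps = fit_propensity(pvb)
        for t, lam in ((1, 0.8), (0, 0.4)):
            sel = pvb.t == t
            se = np.sqrt(lam * (1 - lam) / sel.sum())
            assert abs(ps[sel][0] - lam) < 3 * se


class TestSIPWWeights:
    def test_arithmetic_example(self):
        # 4 verified at PS 0.8 and 2 at PS 0.4: IPW 1.25x4, 2.5x2, sum 10
        data = make_dataset((2, 1, 2, 1), unverified_t1=1, unverified_t0=1)
        ps = np.where(data.t == 1, 0.8, 0.4)
        w = sipw_weights(data, ps)
        t_v = data.t[w.index]
        assert w.sipw[t_v == 1] == pytest.approx(0.125)
        assert w.sipw[t_v == 0] == pytest.approx(0.25)

    def test_constant_ps_gives_uniform_weights(self, spec_example_pvb):
        w = sipw_weights(spec_example_pvb, np.full(spec_example_pvb.n, 0.5))
        assert w.sipw == pytest.approx(1.0 / spec_example_pvb.n1)

    def test_weights_normalize_on_random_datasets(self, rng):
        for _ in range(25):
            pvb = _random_pvb(rng)
            w = sipw_weights(pvb, fit_propensity(pvb))
            assert w.sipw.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w.ipw * w.ps == pytest.approx(1.0))


class TestSIPWBWeights:
    def test_hand_execution_of_balancing_steps(self):
        # verified: 2 diseased (PS .8), 4 non-diseased (PS .8), rel_size 1
        data = make_dataset((1, 1, 2, 2), unverified_t1=2, unverified_t0=2)
        ps = np.full(data.n, 0.8)
        w = sipwb_weights(data, ps, BalanceSpec(1.0))
        d_v = data.d[w.index]
        assert w.sipw[d_v == 1] == pytest.approx(0.25)
        assert w.sipw[d_v == 0] == pytest.approx(0.125)
        assert w.ipw[d_v == 1] == pytest.approx(2.5)

    @pytest.mark.parametrize("rel_size", [0.5, 1.0, 3.0])
    def test_diseased_mass_identity(self, rel_size, rng):
        """After rebalancing the diseased probability mass is exactly
        1/(1+rel_size), whatever the data."""
        for _ in range(10):
            pvb = _random_pvb(rng)
            w = sipwb_weights(pvb, fit_propensity(pvb), BalanceSpec(rel_size))
            mass = w.sipw[pvb.d[w.index] == 1].sum()
            assert mass == pytest.approx(1.0 / (1.0 + rel_size), abs=1e-12)
            assert w.sipw.sum() == pytest.approx(1.0, abs=1e-12)

    def test_native_ratio_with_constant_ps_reduces_to_sipw(self, rng):
        pvb = _random_pvb(rng)
        ps = np.full(pvb.n, 0.5)
        d_v = pvb.d[pvb.verified_index]
        rel_init = (d_v == 0).sum() / (d_v == 1).sum()
        w_b = sipwb_weights(pvb, ps, BalanceSpec(rel_init))
        w = sipw_weights(pvb, ps)
        assert w_b.sipw == pytest.approx(w.sipw)

    def test_requires_both_disease_classes_verified(self):
        data = make_dataset((3, 2, 0, 0), unverified_t1=2, unverified_t0=3)
        with pytest.raises(PVBDataError, match="with and without"):
            sipwb_weights(data, np.full(data.n, 0.6), BalanceSpec(1.0))


class TestDrawValidResample:
    def test_resample_always_valid(self, spec_example_pvb, rng):
        w = sipw_weights(spec_example_pvb, fit_propensity(spec_example_pvb))
        for _ in range(20):
            res = draw_valid_resample(spec_example_pvb, w, size=50, rng=rng)
            counts = np.bincount(cell_ids(res.t, res.d), minlength=4)
            assert res.n == 50 and np.all(counts > 0)

    def test_degenerate_weights_exhaust_budget(self, spec_example_pvb, rng):
        idx = spec_example_pvb.verified_index
        # all mass on a single (T, D) combination: a valid table is impossible
        sipw = np.zeros(idx.size)
        sipw[0] = 1.0
        from pvbcorrect.resampling import WeightSet

        w = WeightSet(index=idx, ps=np.full(idx.size, 0.5), ipw=np.ones(idx.size), sipw=sipw)
        with pytest.raises(ResamplingError):
            draw_valid_resample(spec_example_pvb, w, size=20, rng=rng, max_tries=30)

    def test_marginal_inclusion_proportional_to_weights(self, rng):
        """Unconditionally on acceptance, subject i appears with
        frequency proportional to its scaled weight (multinomial check,
        rejection effectively disabled by a well-populated table)."""
        data = make_dataset((5, 5, 5, 5), unverified_t1=4, unverified_t0=4)
        ps = np.where(data.t == 1, 0.8, 0.4)
        w = sipw_weights(data, ps)
        draws = 2000
        size = 50
        counts = np.zeros(data.n)
        for _ in range(draws):
            res_idx = np.searchsorted(np.cumsum(w.sipw), rng.random(size))
            np.add.at(counts, w.index[res_idx], 1)
        freq = counts[w.index] / (draws * size)
        se = np.sqrt(w.sipw * (1 - w.sipw) / (draws * size))
        assert np.all(np.abs(freq - w.sipw) < 4 * se)


class TestResamplingEstimators:
    def test_sipw_matches_brute_force_enumeration(self):
        """On a 6-subject dataset, the SIPW expectation over valid
        resamples equals exhaustive enumeration of all 6^6 index tuples
        weighted by products of scaled weights, conditioned on validity."""
        data = make_dataset((2, 2, 1, 1))
        ps = np.array([0.8, 0.8, 0.4, 0.4, 0.8, 0.4])
        w = sipw_weights(data, ps)
        cells = cell_ids(data.t, data.d)
        expected_sn, expected_sp = brute_force_resampling_expectation(
            cells, w.sipw, size=6
        )
        est, sn_list, sp_list = sipw_estimate(data, b=40_000, rng=11, ps=ps)
        tol_sn = 4 * sn_list.std() / np.sqrt(sn_list.size)
        tol_sp = 4 * sp_list.std() / np.sqrt(sp_list.size)
        assert est.sn == pytest.approx(expected_sn, abs=tol_sn)
        assert est.sp == pytest.approx(expected_sp, abs=tol_sp)

    def test_point_estimates_are_means_of_lists(self, spec_example_pvb):
        est, sn_list, sp_list = sipw_estimate(spec_example_pvb, b=200, rng=3)
        assert est.sn == pytest.approx(sn_list.mean())
        assert est.sp == pytest.approx(sp_list.mean())
        assert sn_list.size == 200
        assert np.all((sn_list >= 0) & (sn_list <= 1))

    def test_resample_sizes_differ_between_ipb_and_sipw(self, rng):
        """IPB bootstraps the verified subset (size n1) while SIPW
        restores the full size n, so SIPW's per-resample estimates are
        less dispersed on sparse verification."""
        cfg = ScenarioConfig(p=0.4, sn_true=0.3, sp_true=0.6, n=600)
        _, pvb, _ = generate_valid_scenario(cfg, rng)
        _, sn_ipb, _ = ipb_estimate(pvb, b=400, rng=1)
        _, sn_sipw, _ = sipw_estimate(pvb, b=400, rng=2)
        assert sn_ipb.std() > sn_sipw.std()

    def test_sipwb_resamples_are_half_diseased_at_unit_ratio(self, rng):
        cfg = ScenarioConfig(p=0.2, sn_true=0.6, sp_true=0.8, n=500)
        _, pvb, _ = generate_valid_scenario(cfg, rng)
        ps = fit_propensity(pvb)
        w = sipwb_weights(pvb, ps, BalanceSpec(1.0))
        cells = cell_ids(pvb.t[w.index], pvb.d[w.index])
        counts = _resample_cell_counts(cells, w.sipw, size=500, b=300, rng=rng)
        diseased_frac = (counts[:, 0] + counts[:, 1]) / 500.0
        assert diseased_frac.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(300 * 500))

    @pytest.mark.parametrize("rel_size", [1.0, 3.0])
    def test_sipwb_diseased_fraction_tracks_rel_size(self, rel_size, rng):
        cfg = ScenarioConfig(p=0.3, sn_true=0.7, sp_true=0.7, n=400)
        _, pvb, _ = generate_valid_scenario(cfg, rng)
        ps = fit_propensity(pvb)
        w = sipwb_weights(pvb, ps, BalanceSpec(rel_size))
        mass = w.sipw[pvb.d[w.index] == 1].sum()
        assert mass == pytest.approx(1.0 / (1.0 + rel_size), abs=1e-12)

    def test_estimates_reproducible_with_seeded_rng(self, spec_example_pvb):
        a, _, _ = sipwb_estimate(spec_example_pvb, b=100, rng=5)
        b, _, _ = sipwb_estimate(spec_example_pvb, b=100, rng=5)
        assert a.sn == b.sn and a.sp == b.sp
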