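import math

import numpy as np
import pytest

import growthmodes as gm
from growthmodes import ModelParams
from growthmodes.params import ConstrictionParams, GrowthMode, NoiseKind, ReplicationParams
from growthmodes.simulate import SimulationError

LN2 = math.log(2.0)


class TestLineage:
    def test_zero_noise_adder_fixed_point(self):
        p = ModelParams(cv_lambda=0.0, sigma_n=0.0)
        lineage = gm.simulate_lineage(p, 10)
        for r in lineage:
            assert r.Lb == pytest.approx(1.73, abs=1e-12)
            assert r.Ld == pytest.approx(3.46, abs=1e-12)
            assert r.Td == pytest.approx(212.0, abs=1e-9)

    def test_symmetric_division_is_exact(self, exp_lineage):
        for a, b in zip(exp_lineage[:-1], exp_lineage[1:]):
            assert b.Lb == a.Ld / 2.0

    def test_same_seed_reproduces_lineage_bit_for_bit(self):
        p = ModelParams(seed=11)
        a = gm.simulate_lineage(p, 300)
        b = gm.simulate_lineage(p, 300)
        assert [(r.Lb, r.Ld, r.Td, r.rate) for r in a] == [
            (r.Lb, r.Ld, r.Td, r.rate) for r in b
        ]

    def test_stationary_log_size_variance_matches_prediction(self, exp_params):
        # sigma_x^2 = sigma_n^2 / (alpha (2 - alpha)) = 0.03 at the adder
        vars_ = []
        for s in range(10):
            lineage = gm.simulate_lineage(ModelParams(seed=s), 2500)
            x = np.log([r.Lb for r in lineage]) - math.log(1.73)
            vars_.append(np.var(x))
        se = np.std(vars_, ddof=1) / math.sqrt(len(vars_))
        # first-order theory: allow a small-noise second-order margin on top of MC noise
        assert np.mean(vars_) == pytest.approx(0.03, abs=3 * se + 0.15 * 0.03)

    def test_generation_time_variance_matches_prediction(self, exp_params, lin_params):
        for params in (exp_params, lin_params):
            mom = gm.stationary_moments(params)
            vals = []
            for s in range(8):
                lineage = gm.simulate_lineage(
                    ModelParams.from_dict({**params.to_dict(), "seed": 50 + s}), 2000
                )
                vals.append(np.var([r.Td for r in lineage]))
            se = np.std(vals, ddof=1) / math.sqrt(len(vals))
            assert np.mean(vals) == pytest.approx(
                mom.var_Td, abs=3 * se + 0.15 * mom.var_Td
            )

    def test_noise_type_equivalence_under_half_mapping(self):
        # sigma_n = sigma_bd / 2 makes the two noise conventions agree to
        # first order in the (Lb, Ld, Td) means and variances
        stats = {}
        for kind, key in ((NoiseKind.TIME_ADDITIVE, "t"), (NoiseKind.SIZE_ADDITIVE, "s")):
            lbs, tds = [], []
            for s in range(8):
                lineage = gm.simulate_lineage(
                    ModelParams(noise_kind=kind, sigma_n=0.15, sigma_bd=0.30,
                                seed=100 + s),
                    2000,
                )
                lbs.append(np.mean([r.Lb for r in lineage]))
                tds.append(np.var([r.Td for r in lineage]))
            stats[key] = (np.mean(lbs), np.mean(tds))
        # the mapping is exact to first order; the conventions differ at
        # O(sigma^2) (log-multiplicative vs additive noise), hence the margin
        assert stats["t"][0] == pytest.approx(stats["s"][0], rel=0.03)
        assert stats["t"][1] == pytest.approx(stats["s"][1], rel=0.10)

    def test_timer_limit_variance_grows_along_lineage(self):
        # at alpha = 0 the log birth size performs a random walk whose
        # windowed variance grows ~ linearly with window length, in contrast
        # to the stationary variance reached for 0 < alpha <= 1
        ratios = []
        for s in range(5):
            lineage = gm.simulate_lineage(
                ModelParams(alpha=0.0, seed=s), 2000, burn_in=0
            )
            x = np.log([r.Lb for r in lineage])
            ratios.append(np.var(x) / np.var(x[:100]))
        assert np.mean(ratios) > 3.0

    def test_invalid_inputs_raise(self, exp_params):
        with pytest.raises(ValueError):
            gm.simulate_lineage(exp_params, 0)
        with pytest.raises(ValueError):
            ModelParams(alpha=3.0)

    def test_runaway_rejection_rate_aborts(self):
        with pytest.raises(SimulationError):
            gm.simulate_lineage(ModelParams(sigma_n=5.0, cv_lambda=0.0, seed=0), 500)


class TestSuperExponential:
    def test_zero_k_reduces_to_exponential_simulator(self):
        pe = ModelParams(seed=5)
        ps = ModelParams(growth_mode=GrowthMode.SUPER_EXPONENTIAL, superexp_k=0.0, seed=5)
        a = gm.simulate_lineage(pe, 100)
        b = gm.simulate_superexponential_lineage(ps, 100)
        for ra, rb in zip(a, b):
            assert ra.Ld == pytest.approx(rb.Ld, abs=1e-12)
            assert ra.Td == pytest.approx(rb.Td, abs=1e-9)

    def test_rate_is_continuous_and_non_decreasing_past_crossover(self):
        p = ModelParams(growth_mode=GrowthMode.SUPER_EXPONENTIAL, mean_Td=242.0)
        ages = np.linspace(0.0, 1.0, 101)
        curve = gm.growth_rate_age_curve(GrowthMode.SUPER_EXPONENTIAL, p, ages)
        lam0 = p.mean_growth_rate
        assert curve[ages <= 0.5] == pytest.approx(lam0)
        late = curve[ages >= 0.5]
        assert np.all(np.diff(late) >= 0)
        # continuity at the crossover
        assert curve[ages == 0.5][0] == pytest.approx(lam0)

    def test_realized_mean_rate_exceeds_initial_rate(self):
        p = ModelParams(growth_mode=GrowthMode.SUPER_EXPONENTIAL, mean_Td=242.0, seed=3)
        lineage = gm.simulate_superexponential_lineage(p, 50)
        for r in lineage[:10]:
            mean_rate = math.log(r.Ld / r.Lb) / r.Td
            assert mean_rate > r.rate


@pytest.fixture(scope="module")
def apo():
    return gm.simulate_adder_per_origin(ModelParams(seed=1), ReplicationParams(), 1500)


class TestAdderPerOrigin:
    def test_origin_counts_are_powers_of_two(self, apo):
        for r in apo:
            assert r.n_origins & (r.n_origins - 1) == 0

    def test_growth_from_initiation_to_division_spans_cd_period(self, apo):
        # Ld = Li exp(lambda (C+D)) up to rate redraws at cycle boundaries:
        # the mean of ln(Ld/Li)/lambda recovers the mean C+D period
        spans = [
            math.log(r.Ld / m["Li"]) / m["rate"]
            for r, m in zip(apo, apo.division_meta)
        ]
        rep = ReplicationParams()
        assert np.mean(spans) == pytest.approx(rep.cd_mean, rel=0.05)
        # and the scheduled intervals themselves average to the C+D mean
        se = rep.cd_mean * rep.cd_cv / math.sqrt(len(apo))
        assert np.mean([m["cd"] for m in apo.division_meta]) == pytest.approx(
            rep.cd_mean, abs=4 * se + rep.dt
        )

    def test_zero_noise_steady_state(self):
        p = ModelParams(cv_lambda=0.0, seed=0)
        rep = ReplicationParams(delta_ii_cv=0.0, cd_cv=0.0)
        apo = gm.simulate_adder_per_origin(p, rep, 50)
        lam = p.mean_growth_rate
        for r in apo[10:]:
            assert r.Td == pytest.approx(LN2 / lam, abs=2 * rep.dt)
            # division size reflects exponential growth over C+D from initiation
            li = r.Lb * math.exp(lam * r.Ti)
            assert math.log(r.Ld / li) / lam == pytest.approx(rep.cd_mean, abs=2 * rep.dt)

    def test_event_times_ordered(self, apo):
        for r in apo:
            if r.Ti is not None:
                assert 0.0 <= r.Ti <= r.Td


class TestConstriction:
    def test_zero_noise_geometry(self):
        p = ModelParams(cv_lambda=0.0, seed=0)
        con = ConstrictionParams(delta_bn_cv=0.0, delta_nd_cv=0.0)
        lineage = gm.simulate_constriction_lineage(p, con, 5)
        for r in lineage:
            ln_len = r.Lb + 1.18
            assert r.Ld == pytest.approx(ln_len + 0.53, abs=1e-12)
            assert r.Tn / r.Td == pytest.approx(
                math.log(ln_len / r.Lb) / math.log(r.Ld / r.Lb)
            )

    def test_stochastic_increment_statistics(self):
        p = ModelParams(seed=2)
        lineage = gm.simulate_constriction_lineage(p, ConstrictionParams(), 3000)
        lam = np.array([r.rate for r in lineage])
        tn = np.array([r.Tn for r in lineage])
        lb = np.array([r.Lb for r in lineage])
        d_bn = lb * np.exp(lam * tn) - lb
        assert d_bn.mean() == pytest.approx(1.18, rel=0.03)
        assert d_bn.std() == pytest.approx(0.23 * 1.18, rel=0.10)

    def test_constriction_within_cycle(self):
        lineage = gm.simulate_constriction_lineage(
            ModelParams(seed=3), ConstrictionParams(), 2000
        )
        for r in lineage:
            assert 0.0 <= r.Tn <= r.Td


class TestPopulation:
    def test_zero_noise_population_is_clonal(self):
        p = ModelParams(cv_lambda=0.0, sigma_n=0.0, seed=0)
        pop = gm.simulate_population_snapshot(p, 100)
        lams = {r.rate for r in pop}
        assert len(lams) == 1
        for r in pop:
            assert r.Td == pytest.approx(LN2 / r.rate)

    def test_small_noise_population_mean_identity(self):
        # <lambda> = ln2 <1/Td> holds to first order in the noise
        p = ModelParams(sigma_n=0.05, cv_lambda=0.05, seed=4)
        pop = gm.simulate_population_snapshot(p, 4000)
        lam = np.mean([r.rate for r in pop])
        inv_td = np.mean([1.0 / r.Td for r in pop])
        assert lam / inv_td == pytest.approx(LN2, rel=0.03)

    def test_requires_at_least_two_cells(self, exp_params):
        with pytest.raises(ValueError):
            gm.simulate_population_snapshot(exp_params, 1)


class TestTrajectory:
    def test_exponential_closed_form_on_grid(self, exp_params):
        lam = LN2 / 212.0
        rec = gm.CellCycleRecord(generation=0, Lb=1.73, Ld=3.46, Td=212.0, rate=lam)
        tr = gm.sample_trajectory(rec, exp_params, dt=4.0)
        assert tr.lengths[1] == pytest.approx(1.73 * math.exp(4 * lam), abs=1e-12)
        assert np.allclose(tr.lengths, 1.73 * np.exp(lam * tr.times))
        assert tr.times[-1] <= rec.Td

    def test_linear_closed_form_on_grid(self, lin_params):
        speed = 1.73 / 212.0
        rec = gm.CellCycleRecord(generation=0, Lb=1.73, Ld=3.46, Td=212.0, rate=speed)
        tr = gm.sample_trajectory(rec, lin_params, dt=4.0)
        assert np.allclose(tr.lengths, 1.73 + speed * tr.times)

    def test_zero_noise_extension_continues_mother_growth_law(self):
        # two half-size daughters at the same rate sum to the mother's law
        p = ModelParams(cv_lambda=0.0, sigma_n=0.0)
        lam = p.mean_growth_rate
        rec = gm.CellCycleRecord(generation=0, Lb=1.73, Ld=3.46, Td=212.0, rate=lam)
        tr = gm.sample_trajectory(rec, p, dt=4.0, post_division_window=12.0)
        assert tr.is_extended
        assert np.allclose(tr.lengths, 1.73 * np.exp(lam * tr.times))
        assert tr.times[-1] > rec.Td

    def test_lengths_positive_and_nondecreasing(self, exp_trajectories):
        for tr in exp_trajectories[:50]:
            assert np.all(tr.lengths > 0)
            assert np.all(np.diff(tr.lengths) >= 0)

    def test_dt_larger_than_cycle_raises(self, exp_params):
        rec = gm.CellCycleRecord(generation=0, Lb=1.73, Ld=3.46, Td=10.0, rate=0.07)
        with pytest.raises(ValueError):
            gm.sample_trajectory(rec, exp_params, dt=20.0)
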