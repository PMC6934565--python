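"""Exchange/relaxation fitting, hetNOE and R2/R1 mobility classification."""

import numpy as np
import pytest

import ubidyn as u
from ubidyn import models
from ubidyn.relaxometry import replicate_scatter, trimmed_mean_sd
from ubidyn.synth import gen_curve


class TestFitMexico:
    def test_round_trip(self):
        c = gen_curve("mexico", {"k_hx": 5.0, "r1": 2.0, "r1w": 0.31},
                      np.linspace(0.01, 0.25, 9))
        fit = u.fit_mexico(c, r1w=0.31)
        assert fit.k_hx == pytest.approx(5.0, abs=1e-6)
        assert fit.r1 == pytest.approx(2.0, rel=1e-5)

    def test_all_zero_signal_flagged_unidentifiable(self):
        c = u.DecayCurve(abscissa=np.linspace(0.01, 0.25, 6),
                         intensity=np.zeros(6), kind="mexico")
        fit = u.fit_mexico(c)
        assert not fit.ok
        assert any("unidentifiable" in f for f in fit.flags)

    def test_grid_search_oracle(self):
        """Optimizer lands within one lattice cell of the best grid point."""
        c = gen_curve("mexico", {"k_hx": 3.7, "r1": 1.4, "r1w": 0.31},
                      np.linspace(0.01, 0.25, 12))
        ks = np.linspace(0.5, 8.0, 76)   # 0.1 steps
        rs = np.linspace(0.2, 4.0, 39)   # 0.1 steps
        best, best_cost = None, np.inf
        for k in ks:
            for r in rs:
                cost = float(np.sum(
                    (models.mexico_signal(c.abscissa, k, r, 0.31) - c.intensity) ** 2
                ))
                if cost < best_cost:
                    best, best_cost = (k, r), cost
        fit = u.fit_mexico(c, r1w=0.31)
        assert abs(fit.k_hx - best[0]) <= 0.1
        assert abs(fit.r1 - best[1]) <= 0.1

    def test_signal_model_invariants(self):
        t = np.linspace(0, 1, 50)
        s = models.mexico_signal(t, 4.0, 1.5, 0.31)
        assert s[0] == 0.0
        assert np.all(s >= 0)

    def test_too_few_points_rejected(self):
        c = u.DecayCurve(abscissa=[0.01, 0.05, 0.1, 0.2],
                         intensity=[0.1, 0.3, 0.4, 0.5], kind="mexico")
        with pytest.raises(u.ValidationError):
            u.fit_mexico(c)


class TestFitExpDecay:
    def test_t2_round_trip(self):
        delays = np.linspace(0.008, 0.296, 10)
        c = gen_curve("t2", {"i0": 1.0, "t_relax": 0.100}, delays)
        fit = u.fit_exp_decay(c)
        assert fit.t_relax == pytest.approx(0.100, rel=1e-9)
        assert fit.rate == pytest.approx(10.0, rel=1e-9)

    def test_constant_curve_flagged(self):
        c = u.DecayCurve(abscissa=np.linspace(0.01, 3.0, 8),
                         intensity=np.ones(8), kind="t1")
        fit = u.fit_exp_decay(c)
        assert any("non-decaying" in f for f in fit.flags)

    def test_log_linear_oracle(self):
        delays = np.linspace(0.01, 3.0, 12)
        c = gen_curve("t1", {"i0": 2.0, "t_relax": 0.77}, delays)
        slope, intercept = np.polyfit(delays, np.log(c.intensity), 1)
        fit = u.fit_exp_decay(c)
        assert fit.t_relax == pytest.approx(-1.0 / slope, rel=1e-9)
        assert fit.i0 == pytest.approx(np.exp(intercept), rel=1e-9)

    def test_intensity_rescale_leaves_t_unchanged(self):
        delays = np.linspace(0.01, 1.0, 8)
        c1 = gen_curve("t1", {"i0": 1.0, "t_relax": 0.4}, delays)
        c2 = u.DecayCurve(abscissa=delays, intensity=7.3 * c1.intensity, kind="t1")
        f1, f2 = u.fit_exp_decay(c1), u.fit_exp_decay(c2)
        assert f1.t_relax == pytest.approx(f2.t_relax, rel=1e-9)
        assert f2.i0 == pytest.approx(7.3 * f1.i0, rel=1e-9)

    def test_replicate_scatter_rule(self):
        x = np.array([0.1, 0.1, 0.5, 0.5, 1.0])
        y = np.array([1.0, 1.2, 0.5, 0.7, 0.2])
        c = u.DecayCurve(abscissa=x, intensity=y, kind="t2")
        sd1 = np.std([1.0, 1.2], ddof=1)
        sd2 = np.std([0.5, 0.7], ddof=1)
        assert replicate_scatter(c) == pytest.approx((sd1 + sd2) / 2)


class TestHetNoe:
    def _list(self, intensities):
        return u.PeakList(entries={
            u.ResidueKey.of_ubiquitin(i): u.Peak(8.0, 120.0, v)
            for i, v in intensities.items()
        })

    def test_identical_lists_ratio_one(self):
        a = self._list({2: 1.0, 3: 2.0, 4: 0.5})
        series, omitted = u.het_noe(a, a)
        assert all(series.value(i) == 1.0 for i in series.indices())
        assert omitted == set()

    def test_global_scaling(self):
        unsat = self._list({2: 1.0, 3: 2.0})
        sat = self._list({2: 0.8, 3: 1.6})
        series, _ = u.het_noe(sat, unsat)
        assert series.value(2) == pytest.approx(0.8)
        assert series.value(3) == pytest.approx(0.8)

    def test_replicate_error_is_mean_sd(self):
        sat1, unsat1 = self._list({2: 0.80, 3: 0.60}), self._list({2: 1.0, 3: 1.0})
        sat2, unsat2 = self._list({2: 0.84, 3: 0.66}), self._list({2: 1.0, 3: 1.0})
        series, _ = u.het_noe(sat1, unsat1, replicates=[(sat2, unsat2)])
        sd2 = np.std([0.80, 0.84], ddof=1)
        sd3 = np.std([0.60, 0.66], ddof=1)
        expected = (sd2 + sd3) / 2
        assert series.error(2) == pytest.approx(expected)
        assert series.error(3) == pytest.approx(expected)

    def test_zero_unsaturated_omitted(self):
        sat = self._list({2: 0.8, 3: 0.5})
        unsat = self._list({2: 1.0, 3: 0.0})
        series, omitted = u.het_noe(sat, unsat)
        assert omitted == {3}
        assert 3 not in series.indices()


class TestClassifyMobility:
    def _series(self, vals, unit="1/s"):
        return u.ResidueSeries(values={
            u.ResidueKey.of_ubiquitin(i): (v, 0.0) for i, v in vals.items()
        }, unit=unit)

    def test_constant_ratio_empty_sets(self):
        r1 = self._series({i: 1.0 for i in range(2, 12)})
        r2 = self._series({i: 5.0 for i in range(2, 12)})
        mob = u.classify_mobility(r1, r2)
        assert mob.trimmed_mean == pytest.approx(5.0)
        assert mob.slow == set() and mob.fast == set()

    def test_outlier_excluded_by_trimming_sort_slice_oracle(self, rng):
        vals = {i: 1.0 for i in range(2, 12)}
        ratios = {i: float(5.0 + rng.normal(0, 0.1)) for i in range(2, 12)}
        ratios[11] = 50.0  # one extreme outlier in 10 values
        r1 = self._series(vals)
        r2 = self._series(ratios)
        mob = u.classify_mobility(r1, r2, trim=0.10)
        arr = np.sort(np.array(list(ratios.values())))
        core = arr[1:-1]  # floor(0.1*10)=1 from each tail
        assert mob.trimmed_mean == pytest.approx(core.mean())
        assert mob.trimmed_sd == pytest.approx(core.std(ddof=1))
        assert 11 in mob.slow

    def test_positive_scaling_of_ratios_scales_statistics_linearly(self, rng):
        vals = {i: 1.0 for i in range(2, 22)}
        ratios = {i: float(rng.uniform(3, 8)) for i in range(2, 22)}
        r1 = self._series(vals)
        mob1 = u.classify_mobility(r1, self._series(ratios))
        mob2 = u.classify_mobility(
            r1, self._series({i: 3.0 * v for i, v in ratios.items()})
        )
        assert mob2.trimmed_mean == pytest.approx(3.0 * mob1.trimmed_mean)
        assert mob2.trimmed_sd == pytest.approx(3.0 * mob1.trimmed_sd)
        assert mob2.slow == mob1.slow and mob2.fast == mob1.fast

    def test_exchange_suspect_needs_high_r2_too(self):
        # Residue 20: high ratio AND high R2 (suspect). Residue 21: equally
        # high ratio achieved through low R1, with unremarkable R2.
        r2_vals = {**{i: 5.0 for i in range(2, 20)}, 20: 15.0, 21: 5.0}
        r1_vals = {**{i: 1.0 for i in range(2, 20)}, 20: 1.0, 21: 1.0 / 3.0}
        mob = u.classify_mobility(self._series(r1_vals), self._series(r2_vals))
        assert 20 in mob.exchange_suspect
        assert 21 in mob.slow and 21 not in mob.exchange_suspect

    def test_too_few_residues_rejected(self):
        r = self._series({2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0})
        with pytest.raises(u.ValidationError):
            u.classify_mobility(r, r)


class TestTrimmedMean:
    def test_matches_scipy(self, rng):
        vals = rng.normal(5, 2, size=37)
        from scipy.stats import trim_mean

        mean, _sd = trimmed_mean_sd(vals, 0.10)
        assert mean == pytest.approx(trim_mean(vals, 0.10))


class TestDeltaKhx:
    def _series(self, vals_errs):
        return u.ResidueSeries(values={
            u.ResidueKey.of_ubiquitin(i): ve for i, ve in vals_errs.items()
        }, unit="1/s")

    def test_identical_inputs_zero(self):
        s = self._series({8: (3.0, 0.3), 9: (2.0, 0.2)})
        dk = u.delta_khx(s, s)
        assert all(dk.value(i) == 0.0 for i in dk.indices())

    def test_quadrature_error(self):
        a = self._series({8: (3.0, 0.3)})
        b = self._series({8: (2.0, 0.4)})
        dk = u.delta_khx(a, b)
        assert dk.error(8) == pytest.approx(0.5)

    def test_slower_dimer_exchange_is_negative(self):
        dimer = self._series({8: (1.0, 0.0)})
        monomer = self._series({8: (4.0, 0.0)})
        assert u.delta_khx(dimer, monomer).value(8) == pytest.approx(-3.0)


def test_recovery_bias_under_noise_seeded():
    """Fit bias stays under 2% at 5%-of-max Gaussian noise (100 replicates each).

    Covers the three per-residue fits: exchange build-up (k_HX), T1 and T2
    decays.  Noise is 5% of the noiseless curve maximum.
    """
    t2_delays = np.linspace(0.008, 0.296, 10)
    t1_delays = np.linspace(0.01, 3.0, 12)
    tm = np.linspace(0.01, 0.25, 12)
    s_max = float(models.mexico_signal(tm, 5.0, 2.0, 0.31).max())
    t1_est, t2_est, k_est = [], [], []
    for rep in range(100):
        c2 = gen_curve("t2", {"i0": 1.0, "t_relax": 0.1}, t2_delays,
                       noise_sd=0.05, seed=1000 + rep)
        t2_est.append(u.fit_exp_decay(c2).t_relax)
        c1 = gen_curve("t1", {"i0": 1.0, "t_relax": 0.77}, t1_delays,
                       noise_sd=0.05, seed=4000 + rep)
        t1_est.append(u.fit_exp_decay(c1).t_relax)
        cm = gen_curve("mexico", {"k_hx": 5.0, "r1": 2.0, "r1w": 0.31}, tm,
                       noise_sd=0.05 * s_max, seed=2000 + rep)
        k_est.append(u.fit_mexico(cm, r1w=0.31).k_hx)
    assert abs(np.mean(t2_est) / 0.1 - 1) < 0.02
    assert abs(np.mean(t1_est) / 0.77 - 1) < 0.02
    assert abs(np.mean(k_est) / 5.0 - 1) < 0.02
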