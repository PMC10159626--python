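import numpy as np
import pytest

from wormmem.datamodel import exchange_protocol
from wormmem.regression import (
    TrialAveragedActivity,
    crossval_fit,
    fit_linear_combo,
    incremental_fit,
    trial_average,
    within_animal_R2,
)
from oracles import oracle_ols
from wormmem.traces import NormalizedTrace


def _random_tas(rng, names, T=30):
    return [TrialAveragedActivity(n, "c", rng.normal(size=(6, T))) for n in names]


class TestFitLinearCombo:
    def test_exact_mixture_recovered(self, rng):
        regs = _random_tas(rng, ["AWA", "ASE"])
        y = 2.0 * regs[0].values + 0.5 * regs[1].values
        fit = fit_linear_combo(TrialAveragedActivity("AIY", "c", y), regs)
        np.testing.assert_allclose(fit.beta, [2.0, 0.5], atol=1e-10)
        assert fit.R2 == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 5))
            regs = _random_tas(rng, [f"n{i}" for i in range(k)], T=int(rng.integers(3, 12)))
            y = rng.normal(size=regs[0].values.shape)
            fit = fit_linear_combo(TrialAveragedActivity("y", "c", y), regs)
            beta_o, r2_o = oracle_ols(y.ravel(), np.column_stack([r.concatenated for r in regs]))
            np.testing.assert_allclose(fit.intercept, beta_o[0], atol=1e-8)
            np.testing.assert_allclose(fit.beta, beta_o[1:], atol=1e-8)
            assert fit.R2 == pytest.approx(r2_o, abs=1e-8)

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        regs = _random_tas(rng, ["a", "b", "c"])
        y = regs[0].values + rng.normal(size=regs[0].values.shape)
        fit = fit_linear_combo(TrialAveragedActivity("y", "c", y), regs)
        assert fit.adjusted_R2 <= fit.R2

    def test_collinear_design_names_culprit(self, rng):
        a = _random_tas(rng, ["AWA"])[0]
        dup = TrialAveragedActivity("AWA_copy", "c", 2.0 * a.values)
        with pytest.raises(ValueError, match="AWA_copy"):
            fit_linear_combo(TrialAveragedActivity("y", "c", a.values), [a, dup])

    def test_coefficient_ci_coverage_at_ten_percent_noise(self, rng):
        true_beta = np.array([1.5, -0.8, 0.4])
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            regs = _random_tas(rng, ["a", "b", "c"], T=20)
            signal = sum(b * r.values for b, r in zip(true_beta, regs))
            y = signal + rng.normal(scale=0.1 * signal.std(), size=signal.shape)
            fit = fit_linear_combo(TrialAveragedActivity("y", "c", y), regs)
            lo, hi = fit.coef_CI[:, 0], fit.coef_CI[:, 1]
            hits += int(np.all((true_beta >= lo) & (true_beta <= hi)))
        # joint coverage of three 95% CIs is >= 85%; marginal >= 90 is implied
        assert hits >= 80

    def test_null_response_r2_near_zero(self, rng):
        regs = _random_tas(rng, ["a", "b"], T=50)
        y = rng.normal(size=regs[0].values.shape)
        fit = fit_linear_combo(TrialAveragedActivity("y", "c", y), regs)
        assert fit.R2 < 0.05


class TestIncrementalFit:
    def test_r2_non_decreasing(self, rng):
        regs = _random_tas(rng, list("abcde"))
        y = regs[0].values - regs[3].values + rng.normal(size=regs[0].values.shape)
        inc = incremental_fit(TrialAveragedActivity("y", "c", y), regs)
        assert len(inc) == 5
        assert np.all(np.diff(inc["R2"].to_numpy()) >= -1e-12)

    def test_jump_at_the_informative_regressor(self, rng):
        # orthonormal-ish regressors; only the third one matters
        regs = _random_tas(rng, ["a", "b", "c"], T=200)
        y = 1.0 * regs[2].values + rng.normal(scale=0.05, size=regs[2].values.shape)
        inc = incremental_fit(TrialAveragedActivity("y", "c", y), regs)
        r2 = inc["R2"].to_numpy()
        # analytic variance decomposition: independent regressors, so the
        # signal's variance share (~1/(1+0.05^2) ~ 0.9975) lands on prefix 3
        assert r2[1] < 0.05
        assert r2[2] > 0.95
        assert r2[2] - r2[1] == pytest.approx(0.9975, abs=0.02)


class TestCrossval:
    def test_noiseless_test_r2_is_one(self, rng):
        regs = _random_tas(rng, ["a", "b"])
        y = 3.0 * regs[0].values - 1.0 * regs[1].values
        train, test = crossval_fit(TrialAveragedActivity("y", "c", y), regs, seed=0)
        assert train == pytest.approx(1.0)
        assert test == pytest.approx(1.0)

    def test_pure_noise_test_r2_nonpositive_on_average(self, rng):
        vals = []
        for i in range(30):
            regs = _random_tas(rng, ["a", "b"], T=10)
            y = rng.normal(size=regs[0].values.shape)
            _, test = crossval_fit(TrialAveragedActivity("y", "c", y), regs, seed=i)
            vals.append(test)
        assert np.mean(vals) <= 0.0

    def test_same_seed_same_split(self, rng):
        regs = _random_tas(rng, ["a"])
        y = regs[0].values + rng.normal(size=regs[0].values.shape)
        ta = TrialAveragedActivity("y", "c", y)
        assert crossval_fit(ta, regs, seed=5) == crossval_fit(ta, regs, seed=5)


class TestTrialAverage:
    def setup_method(self):
        self.schedule = exchange_protocol()
        self.t = np.arange(480) / 2.0

    def _trace(self, vals, animal):
        return NormalizedTrace(vals, self.t, "ground_state", 1.0,
                               neuron_id="AWA", animal_id=animal)

    def test_single_animal_is_identity(self, rng):
        vals = rng.normal(size=480)
        ta = trial_average([self._trace(vals, "a1")], self.schedule, window_s=15.0)
        assert ta.values.shape == (6, 30)
        sw0 = self.schedule.switch_times[0]
        mask = (self.t >= sw0) & (self.t < sw0 + 15.0)
        np.testing.assert_allclose(ta.values[0], vals[mask])

    def test_opposite_animals_cancel(self, rng):
        vals = rng.normal(size=480)
        ta = trial_average([self._trace(vals, "a1"), self._trace(-vals, "a2")],
                           self.schedule)
        np.testing.assert_allclose(ta.values, 0.0, atol=1e-12)

    def test_six_trials_out(self, rng):
        ta = trial_average([self._trace(rng.normal(size=480), "a1")], self.schedule)
        assert ta.values.shape[0] == 6


class TestWithinAnimalR2:
    def setup_method(self):
        self.schedule = exchange_protocol()
        self.t = np.arange(480) / 2.0

    def _pair(self, rng, noise_scale, animal):
        awa_vals = rng.normal(size=480)
        aiy_vals = awa_vals + rng.normal(scale=noise_scale, size=480)
        awa = NormalizedTrace(awa_vals, self.t, "ground_state", 1.0,
                              neuron_id="AWA", animal_id=animal)
        aiy = NormalizedTrace(aiy_vals, self.t, "ground_state", 1.0,
                              neuron_id="AIY", animal_id=animal)
        return awa, aiy

    def test_identity_gives_r2_one(self, rng):
        awa, _ = self._pair(rng, 1.0, "a1")
        out = within_animal_R2({"STAP-T": [(awa, awa)]}, self.schedule)
        assert out["R2"].iloc[0] == pytest.approx(1.0)

    def test_snr_one_gives_half(self, rng):
        # R2 = SNR^2/(1+SNR^2); SNR=1 (noise sd = signal sd) -> R2 = 0.5
        r2s = []
        for i in range(50):
            pairs = [self._pair(rng, 1.0, f"a{j}") for j in range(3)]
            out = within_animal_R2({"c": pairs}, self.schedule)
            r2s.append(out["R2"].iloc[0])
        assert np.mean(r2s) == pytest.approx(0.5, abs=0.05)

    def test_unpaired_traces_rejected(self, rng):
        awa, _ = self._pair(rng, 1.0, "a1")
        _, aiy = self._pair(rng, 1.0, "a2")
        with pytest.raises(ValueError, match="unpaired"):
            within_animal_R2({"c": [(awa, aiy)]}, self.schedule)
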