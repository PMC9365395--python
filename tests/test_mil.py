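"""Missed-event-corrected likelihood and global fitting."""

import numpy as np
import pytest
import scipy.linalg

import patchkin as pk
from patchkin.schemes import OPEN, SHUT

from conftest import DEAD_TIME, S1_TRUTH, simulate_conditioned


def dense_ideal_loglik(scheme, bursts, concentrations=None):
    """Independent oracle: ideal (t_d = 0) likelihood via dense expm on the
    full generator sub-blocks, no spectral decomposition, no scan."""
    g = pk.build_generator(scheme, concentrations or {})
    idx = {OPEN: g.class_indices(OPEN), SHUT: g.class_indices(SHUT)}
    total = 0.0
    for burst in bursts:
        cls0 = OPEN if burst.classes[0] == 1 else SHUT
        v = pk.class_entry_vector(g, cls0)
        log_scale = 0.0
        for i in range(len(burst)):
            a = OPEN if burst.classes[i] == 1 else SHUT
            b = SHUT if a == OPEN else OPEN
            qaa = g.q[np.ix_(idx[a], idx[a])]
            qab = g.q[np.ix_(idx[a], idx[b])]
            v = v @ scipy.linalg.expm(qaa * burst.durations[i]) @ qab
            s = np.abs(v).max()
            v = v / s
            log_scale += np.log(s)
        total += log_scale + np.log(v.sum())
    return total


class TestCorrectedKernels:
    def test_zero_dead_time_reduces_to_ideal(self, s1_generator):
        kern = pk.corrected_semi_markov_kernels(s1_generator, 0.0)
        ts = np.geomspace(1e-5, 1e-2, 40)
        for cls in (OPEN, SHUT):
            ideal = pk.ideal_dwell_density(s1_generator, cls, ts)
            apparent = kern.apparent_density(cls, ts)
            assert np.allclose(apparent, ideal, rtol=1e-10)

    def test_two_state_apparent_open_rate(self, two_state):
        # missed closures thin the apparent closing rate to
        # alpha * exp(-k_open * t_d) exactly for a single shut state
        g = pk.build_generator(two_state)
        t_d = 2e-3
        kern = pk.corrected_semi_markov_kernels(g, t_d)
        alpha_app = 200.0 * np.exp(-100.0 * t_d)
        assert kern.q_corr[OPEN][0, 0] == pytest.approx(-alpha_app, rel=1e-12)
        assert kern.apparent_mean_dwell(OPEN) == pytest.approx(
            t_d + 1.0 / alpha_app, rel=1e-9
        )

    def test_apparent_open_dwell_lengthens(self, s1_generator):
        kern = pk.corrected_semi_markov_kernels(s1_generator, DEAD_TIME)
        assert kern.apparent_mean_dwell(OPEN) > 1.0 / 310.0

    def test_apparent_matches_simulated_dead_time_record(self, s1):
        # simulation + impose_dead_time is the brute-force oracle for the
        # first-order corrected mean
        ev = simulate_conditioned(s1, seed=31, n_events=20_000)
        g = pk.build_generator(s1)
        kern = pk.corrected_semi_markov_kernels(g, DEAD_TIME)
        opens = ev.open_durations()
        se = opens.std() / np.sqrt(opens.size)
        assert abs(opens.mean() - kern.apparent_mean_dwell(OPEN)) < 4 * se

    def test_huge_dead_time_warns(self, s1_generator):
        with pytest.warns(UserWarning, match="first-order"):
            pk.corrected_semi_markov_kernels(s1_generator, 1e-3)


class TestSequenceLoglik:
    def test_two_state_closed_form(self, two_state):
        burst = pk.EventList(np.array([0, 1]), np.array([0.01, 0.005]))
        problem = pk.FitProblem(
            scheme=two_state,
            datasets=[(pk.BurstSet([burst], np.inf), {})],
            dead_time=0.0,
        )
        expected = np.log(100.0) - 1.0 + np.log(200.0) - 1.0
        assert pk.sequence_loglik(problem) == pytest.approx(expected,
                                                            rel=1e-12)

    @pytest.mark.parametrize("preset,kwargs,conc", [
        ("S1", {}, {}),
        ("S2", {"blocker": "QX-222"}, {"QX-222": 30.0}),
    ])
    def test_matches_dense_expm_oracle(self, preset, kwargs, conc):
        scheme = pk.scheme_preset(preset, **kwargs)
        ev = simulate_conditioned(scheme, seed=17, n_events=200,
                                  concentrations=conc, dead_time=0.0)
        bursts = pk.define_bursts(ev, 2e-3)
        bs = pk.BurstSet(bursts.bursts[:20], bursts.tau_crit)
        problem = pk.FitProblem(scheme=scheme, datasets=[(bs, conc)],
                                dead_time=0.0)
        ll = pk.sequence_loglik(problem)
        oracle = dense_ideal_loglik(scheme, bs, conc)
        assert ll == pytest.approx(oracle, rel=1e-8)

    def test_truth_beats_perturbed_rates(self, s1, s1_recording):
        bs = pk.BurstSet([s1_recording], np.inf)
        problem = pk.FitProblem(scheme=s1, datasets=[(bs, {})],
                                dead_time=DEAD_TIME)
        ll_truth = pk.sequence_loglik(problem)
        worse = dict(S1_TRUTH, alpha_1=620.0)
        assert ll_truth > pk.sequence_loglik(problem, worse)

    def test_state_reordering_invariance(self, s1, s1_recording):
        perm = pk.KineticScheme(
            "S1perm", (s1.states[2], s1.states[0], s1.states[1]),
            s1.transitions,
        )
        bs = pk.BurstSet([s1_recording], np.inf)
        ll = pk.sequence_loglik(pk.FitProblem(
            scheme=s1, datasets=[(bs, {})], dead_time=DEAD_TIME))
        ll_perm = pk.sequence_loglik(pk.FitProblem(
            scheme=perm, datasets=[(bs, {})], dead_time=DEAD_TIME))
        assert ll_perm == pytest.approx(ll, rel=1e-10)

    def test_splitting_recording_at_burst_boundary(self, s1):
        ev = simulate_conditioned(s1, seed=19, n_events=2000)
        bursts = pk.define_bursts(ev, 5e-4)
        whole = pk.FitProblem(scheme=s1, datasets=[(bursts, {})],
                              dead_time=DEAD_TIME)
        half = len(bursts) // 2
        split = pk.FitProblem(
            scheme=s1,
            datasets=[
                (pk.BurstSet(bursts.bursts[:half], bursts.tau_crit), {}),
                (pk.BurstSet(bursts.bursts[half:], bursts.tau_crit), {}),
            ],
            dead_time=DEAD_TIME,
        )
        assert pk.sequence_loglik(split) == pytest.approx(
            pk.sequence_loglik(whole), rel=1e-12
        )

    def test_unconditioned_record_rejected(self, s1):
        ev = pk.EventList(np.array([1, 1, 0]), np.array([1e-3, 1e-3, 1e-3]))
        problem = pk.FitProblem(
            scheme=s1, datasets=[(pk.BurstSet([ev], np.inf), {})],
            dead_time=0.0,
        )
        with pytest.raises(pk.FitError, match="alternate"):
            pk.sequence_loglik(problem)


class TestGlobalFit:
    def test_all_fixed_is_noop(self, s1, s1_recording):
        bs = pk.BurstSet([s1_recording], np.inf)
        problem = pk.FitProblem(scheme=s1, datasets=[(bs, {})],
                                dead_time=DEAD_TIME,
                                fixed_symbols=dict(S1_TRUTH))
        res = pk.global_fit(problem)
        assert res.estimates == {}
        assert res.fixed == S1_TRUTH
        assert res.loglik == pytest.approx(pk.sequence_loglik(problem))

    def test_duplicate_data_shrinks_se(self, s1):
        ev = simulate_conditioned(s1, seed=23, n_events=4000)
        bs = pk.BurstSet([ev], np.inf)
        base = pk.FitProblem(scheme=s1, datasets=[(bs, {})],
                             dead_time=DEAD_TIME, seed=0)
        doubled = pk.FitProblem(scheme=s1, datasets=[(bs, {}), (bs, {})],
                                dead_time=DEAD_TIME, seed=0)
        r1 = pk.global_fit(base, n_starts=1)
        r2 = pk.global_fit(doubled, n_starts=1)
        for sym in S1_TRUTH:
            assert r2.rate(sym) == pytest.approx(r1.rate(sym), rel=0.02)
            assert r2.se(sym) == pytest.approx(r1.se(sym) / np.sqrt(2),
                                               rel=0.15)

    def test_constrained_to_own_optimum_reproduces_loglik(self, s1):
        ev = simulate_conditioned(s1, seed=29, n_events=3000)
        bs = pk.BurstSet([ev], np.inf)
        problem = pk.FitProblem(scheme=s1, datasets=[(bs, {})],
                                dead_time=DEAD_TIME, seed=0)
        free = pk.global_fit(problem, n_starts=1)
        res_c, res_f = pk.constrained_refit(
            problem, free.all_rates(), n_starts=1
        )
        assert res_c.loglik == pytest.approx(free.loglik, abs=1e-6)
        assert res_f.loglik == pytest.approx(free.loglik, abs=1e-4)

    def test_se_scales_as_inverse_root_n(self, s1):
        ses = []
        for n in (2000, 8000):
            ev = simulate_conditioned(s1, seed=37, n_events=n)
            problem = pk.FitProblem(
                scheme=s1, datasets=[(pk.BurstSet([ev], np.inf), {})],
                dead_time=DEAD_TIME, seed=0,
            )
            res = pk.global_fit(problem, n_starts=1)
            ses.append(res.se("alpha_1"))
        slope = np.log(ses[1] / ses[0]) / np.log(8000 / 2000)
        assert slope == pytest.approx(-0.5, abs=0.15)
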