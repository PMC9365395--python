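"""Idealization, risetime correction, dead time, tau_crit, bursts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import patchkin as pk
from patchkin.simulate import filter_sigma_samples


class TestIdealize:
    def test_noiseless_square_pulse(self):
        fs = 100_000.0
        n = int(3e-3 * fs)
        tr = np.zeros(n)
        tr[int(1e-3 * fs):int(2e-3 * fs)] = 16.0
        ev = pk.idealize_trace(tr, fs, 16.0, 0.0)
        opens = ev.open_durations()
        assert opens.size == 1
        assert opens[0] == pytest.approx(1e-3, abs=1.5 / fs)

    def test_inverted_polarity_equivalent(self):
        fs = 100_000.0
        rng = np.random.default_rng(0)
        tr = np.where(rng.random(3000) > 0.7, 16.0, 0.0)
        a = pk.idealize_trace(tr, fs, 16.0, 0.0)
        b = pk.idealize_trace(16.0 - tr, fs, 0.0, 16.0)
        assert a == b

    def test_flat_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="never crosses"):
            ev = pk.idealize_trace(np.zeros(100), 1e5, 16.0, 0.0)
        assert len(ev) == 0

    def test_round_trip_recovers_long_dwells(self, s1):
        # all dwells far above the filter risetime: idealization must give
        # the events back one-for-one
        fc, fs = 10_000.0, 500_000.0
        rng = np.random.default_rng(21)
        n = 41
        durations = rng.uniform(0.5e-3, 5e-3, size=n)
        ev = pk.EventList(np.arange(n) % 2, durations)
        cfg = pk.SimulationConfig(scheme=s1, seed=21, n_events=1,
                                  sample_rate=fs, filter_fc=fc,
                                  noise_sd=0.2)
        _, tr = pk.simulate_trace(ev, cfg)
        rec = pk.idealize_trace(tr, fs, 16.0, 0.0)
        assert len(rec) == n
        assert list(rec.classes) == list(ev.classes)
        # interior dwells match within a risetime (edge dwells are censored)
        risetime = 0.34 / fc
        assert np.allclose(rec.durations[1:-1], durations[1:-1],
                           atol=risetime)


class TestRisetimeCorrection:
    def test_long_dwells_pass_through(self):
        fc = 10_000.0
        risetime = 0.34 / fc
        ev = pk.EventList(np.array([1, 0, 1]),
                          np.array([10, 12, 20]) * risetime)
        out = pk.correct_risetime(ev, fc)
        assert np.allclose(out.durations, ev.durations, rtol=0.01)

    def test_correction_monotone_and_upward(self):
        fc = 10_000.0
        apparent = np.linspace(0.2, 3.0, 30) * (0.34 / fc)
        ev = pk.EventList(np.ones(30, dtype=int) - (np.arange(30) % 2),
                          apparent)
        out = pk.correct_risetime(ev, fc)
        corrections = out.durations - apparent
        assert np.all(corrections >= -1e-12)
        assert np.all(np.diff(corrections) <= 1e-9)  # shorter => larger

    def test_infinite_bandwidth_is_identity(self):
        ev = pk.EventList(np.array([1, 0]), np.array([1e-4, 2e-4]))
        out = pk.correct_risetime(ev, 1e9)
        assert np.allclose(out.durations, ev.durations, rtol=1e-9)

    def test_inverts_numerical_convolution(self, s1):
        # a brief filtered pulse idealized at half-amplitude comes out short;
        # the correction must recover the true duration
        fc, fs = 5_000.0, 5_000_000.0
        sigma = filter_sigma_samples(fc, fs)
        for true_dur in (0.8 / fc, 0.4 / fc, 0.25 / fc):
            n = int(20 * sigma)
            tr = np.zeros(6 * n)
            start = 3 * n
            tr[start:start + int(round(true_dur * fs))] = 16.0
            from scipy.ndimage import gaussian_filter1d

            filt = gaussian_filter1d(tr, sigma)
            ev = pk.idealize_trace(filt, fs, 16.0, 0.0)
            opens = ev.open_durations()
            assert opens.size == 1
            corrected = pk.correct_risetime(ev, fc)
            got = corrected.open_durations()[0]
            assert got == pytest.approx(true_dur, rel=0.02)


class TestDeadTime:
    def test_forced_merge(self):
        ev = pk.EventList(np.array([1, 0, 1]),
                          np.array([1e-3, 10e-6, 2e-3]))
        out = pk.impose_dead_time(ev, 18.83e-6)
        assert len(out) == 1
        assert out.durations[0] == pytest.approx(3.01e-3)
        assert out.classes[0] == 1

    def test_identity_when_all_resolvable(self):
        ev = pk.EventList(np.array([1, 0, 1]),
                          np.array([1e-3, 1e-3, 2e-3]))
        out = pk.impose_dead_time(ev, 18.83e-6)
        assert out == ev

    @staticmethod
    def _recursive_merge_oracle(classes, durations, t_d):
        """Repeatedly delete the first sub-dead-time event, merging its
        neighbours (dropping it when unmergeable at a record edge)."""
        cls = list(classes)
        dur = list(durations)
        while True:
            # merge same-class neighbours first so edges are canonical
            i = 1
            while i < len(cls):
                if cls[i] == cls[i - 1]:
                    dur[i - 1] += dur.pop(i)
                    cls.pop(i)
                else:
                    i += 1
            short = [i for i, d in enumerate(dur) if d < t_d]
            if not short:
                return np.array(cls), np.array(dur)
            i = short[0]
            if i == 0:
                cls.pop(0)
                dur.pop(0)
            elif i == len(cls) - 1:
                # trailing short event: its time accrues to the previous dwell
                dur[i - 1] += dur.pop(i)
                cls.pop(i)
            else:
                merged = dur[i - 1] + dur[i] + dur[i + 1]
                cls[i - 1:i + 2] = [cls[i - 1]]
                dur[i - 1:i + 2] = [merged]

    @given(
        n=st.integers(2, 30),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_recursive_merge_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        classes = (np.arange(n) + rng.integers(2)) % 2
        durations = rng.exponential(30e-6, size=n) + 1e-9
        t_d = 18.83e-6
        ev = pk.impose_dead_time(
            pk.EventList(classes, durations), t_d
        )
        ocls, odur = self._recursive_merge_oracle(classes, durations, t_d)
        assert list(ev.classes) == list(ocls)
        assert np.allclose(ev.durations, odur)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_idempotent_and_duration_conserving(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        classes = np.arange(n) % 2
        durations = rng.exponential(40e-6, size=n) + 1e-9
        t_d = 18.83e-6
        ev = pk.EventList(classes, durations)
        once = pk.impose_dead_time(ev, t_d)
        if len(once) == 0:
            return
        twice = pk.impose_dead_time(once, t_d)
        assert once == twice
        # duration conserved apart from dropped leading events
        n_lead = 0
        while n_lead < n and durations[n_lead] < t_d:
            n_lead += 1
        assert once.total_duration == pytest.approx(
            durations[n_lead:].sum(), rel=1e-12
        )
        assert once.durations.min() >= t_d


class TestTauCrit:
    def test_closed_form_example(self):
        # fast component 0.06 ms (70 %), slow 500 ms (30 %)
        tc = pk.determine_tau_crit([(0.7, 0.06e-3), (0.3, 500e-3)])
        assert tc == pytest.approx(0.593e-3, abs=1e-6)

    def test_matches_numeric_root(self):
        a1, t1, a2, t2 = 0.55, 80e-6, 0.45, 3e-3
        tc = pk.determine_tau_crit([(a1, t1), (a2, t2)])
        f = lambda t: a1 / t1 * np.exp(-t / t1) - a2 / t2 * np.exp(-t / t2)
        root = brentq(f, t1, t2)
        assert tc == pytest.approx(root, rel=1e-10)
        assert t1 < tc < t2

    def test_area_scaling_invariance(self):
        comps = [(0.7, 0.06e-3), (0.3, 500e-3)]
        scaled = [(a * 13.0, t) for a, t in comps]
        assert pk.determine_tau_crit(scaled) == pytest.approx(
            pk.determine_tau_crit(comps)
        )

    def test_equal_components_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            pk.determine_tau_crit([(0.5, 1e-3), (0.5, 1e-3)])

    def test_no_intersection_rejected(self):
        # overwhelming slow component: densities never cross after t=0
        with pytest.raises(ValueError, match="intersect"):
            pk.determine_tau_crit([(1e-9, 0.9999e-3), (1.0, 1e-3)])


class TestBursts:
    def test_gap_partitioning(self):
        # shut gaps 2, 10, 1 ms with tau_crit 5 ms -> two bursts
        classes = np.array([1, 0, 1, 0, 1, 0, 1])
        durs = np.array([3, 2, 3, 10, 3, 1, 3]) * 1e-3
        bs = pk.define_bursts(pk.EventList(classes, durs), 5e-3)
        assert len(bs) == 2
        assert bs.n_events[0] == 3 and bs.n_events[1] == 3

    def test_popen_arithmetic(self):
        burst = pk.EventList(np.array([1, 0, 1]),
                             np.array([3e-3, 0.06e-3, 3e-3]))
        bs = pk.define_bursts(burst, 1.0)
        assert bs.popen[0] == pytest.approx(6.0 / 6.06, rel=1e-9)

    def test_infinite_tau_crit_single_burst(self, s1_recording):
        bs = pk.define_bursts(s1_recording, np.inf)
        assert len(bs) == 1
        assert bs.n_events[0] >= len(s1_recording) - 2

    def test_short_bursts_dropped(self):
        classes = np.array([1, 0, 1, 0, 1])
        durs = np.array([3e-3, 10e-3, 3e-3, 10e-3, 3e-3])
        bs = pk.define_bursts(pk.EventList(classes, durs), 5e-3)
        assert len(bs) == 0  # every fragment is a lone opening


class TestPopenFilter:
    def _bursts_from(self, popens):
        bursts = []
        for p in popens:
            p = min(max(p, 1e-6), 1 - 1e-6)
            bursts.append(pk.EventList(
                np.array([1, 0, 1]),
                np.array([p / 2, 1 - p, p / 2]) * 1e-2,
            ))
        return pk.BurstSet(bursts, 1.0)

    def test_constructed_outlier_removed(self):
        rng = np.random.default_rng(8)
        popens = list(0.99 - 0.005 * rng.random(40)) + [0.01]
        out = pk.filter_bursts_by_popen(self._bursts_from(popens))
        assert len(out) < 41
        assert out.popen.min() > 0.5

    def test_retained_is_subset_with_unchanged_popen(self, s1_recording):
        bs = pk.define_bursts(s1_recording, 3e-4)
        out = pk.filter_bursts_by_popen(bs)
        assert len(out) <= len(bs)
        assert len(out) >= 0.8 * len(bs)   # homogeneous population survives
        original = set(np.round(bs.popen, 12))
        assert all(np.round(p, 12) in original for p in out.popen)

    def test_too_few_bursts_pass_through(self):
        bs = self._bursts_from([0.9, 0.95, 0.99])
        with pytest.warns(UserWarning, match="too few"):
            out = pk.filter_bursts_by_popen(bs)
        assert len(out) == 3
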