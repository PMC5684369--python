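"""Trace analytics: proximity frequencies, sensitivity, timing ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from widedock import (InvalidArgumentError, ProximityEvents, TimingBreakdown,
                      TraceRecord, UndefinedMetricError, acceleration, asof,
                      checks_per_accept, decision_cost, decision_cost_series,
                      events_from_traces, frame_means, g_sensitivity,
                      g_sensitivity_series, metrics_table, rmsd_success, sof)


def three_walker_events():
    """The canonical 2-D illustration: walkers A, B, C over steps 1-4."""
    ev = ProximityEvents(n=3)
    A, B, C = 0, 1, 2
    ev.add(A, 2, {C})             # t=2: A near C's history
    ev.add(A, 3, {B})             # t=3: A near B, B near C
    ev.add(B, 3, {C})
    ev.add(A, 4, {B})             # t=4: A near B; B near A and C; C near B
    ev.add(B, 4, {A, C})
    ev.add(C, 4, {B})
    return ev


class TestSofAsof:
    def test_no_events_zero(self):
        ev = ProximityEvents(n=3)
        assert sof(ev, 0, 5) == 0.0
        assert asof(ev, 5) == 0.0

    def test_two_neighbors_at_t4(self):
        ev = three_walker_events()
        assert sof(ev, 1, 4) == pytest.approx(0.5)   # near A and C: 2/4

    def test_t_zero_invalid(self):
        ev = three_walker_events()
        with pytest.raises(InvalidArgumentError):
            sof(ev, 0, 0)
        with pytest.raises(InvalidArgumentError):
            asof(ev, 0)

    def test_illustration_sequence(self):
        ev = three_walker_events()
        assert asof(ev, 1) == 0.0
        assert round(asof(ev, 2), 3) == 0.167
        assert round(asof(ev, 3), 3) == 0.222
        assert round(asof(ev, 4), 3) == 0.333

    def test_cumulative_mode_matches_running_sum_oracle(self, rng):
        n, t_max = 4, 12
        ev = ProximityEvents(n=n)
        for t in range(1, t_max + 1):
            for i in range(n):
                near = {j for j in range(n)
                        if j != i and rng.random() < 0.3}
                if near:
                    ev.add(i, t, near)
        for i in range(n):
            for t in range(1, t_max + 1):
                running = sum(len(ev.near(i, tau))
                              for tau in range(1, t + 1)) / t
                assert sof(ev, i, t, mode="cumulative") == \
                    pytest.approx(running)

    def test_asof_bounded_by_walker_count(self, rng):
        ev = ProximityEvents(n=5)
        for t in range(1, 6):
            for i in range(5):
                ev.add(i, t, set(range(5)) - {i})
        for t in range(1, 6):
            assert 0.0 <= asof(ev, t) <= 5.0

    def test_self_proximity_rejected(self):
        ev = ProximityEvents(n=2)
        with pytest.raises(InvalidArgumentError):
            ev.add(0, 1, {0})


class TestEventsFromTraces:
    def test_single_walker_never_has_events(self, rng):
        hist = rng.uniform(0, 30, size=(40, 3))
        ev = events_from_traces([hist])
        assert ev.events == {}

    def test_trailing_walker_sees_leader_history(self):
        lead = np.array([[1.0 * t, 0.0, 0.0] for t in range(10)])
        trail = lead - np.array([1.0, 0.0, 0.0])    # one step behind
        ev = events_from_traces([lead, trail], radius=2.0)
        for t in range(1, 10):
            assert 0 in ev.near(1, t)

    def test_matches_all_pairs_bruteforce(self, rng):
        n, t_len = 4, 25
        hists = [rng.uniform(0, 20, size=(t_len, 5)) for _ in range(n)]
        ev = events_from_traces(hists, radius=6.0)
        for i in range(n):
            for t in range(1, t_len):
                expect = set()
                for j in range(n):
                    if j == i:
                        continue
                    d = np.linalg.norm(hists[j][:t, :3]
                                       - hists[i][t, :3], axis=1)
                    if np.any(d <= 6.0):
                        expect.add(j)
                assert set(ev.near(i, t)) == expect

    def test_frame_means_partition(self):
        series = np.arange(10, dtype=float)
        fm = frame_means(series, 4)
        assert np.allclose(fm, [1.5, 5.5, 8.5])


def rec(outcome, p1=0, p2=0, walker=0, step=1, end=False, score=0.0):
    return TraceRecord(walker=walker, step=step, outcome=outcome, p1=p1,
                       p2=p2, is_end_point=end, score=score)


class TestDecisionAnalytics:
    def test_all_global_sensitivity_one(self):
        assert g_sensitivity([rec("G") for _ in range(5)]) == 1.0

    def test_mixed_sensitivity(self):
        trace = [rec("G")] * 3 + [rec("I")] * 9
        assert g_sensitivity(trace) == 0.25

    def test_no_buffered_acceptance_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            g_sensitivity([rec("D"), rec("R")])

    def test_default_accepts_cost_nothing(self):
        assert decision_cost([rec("D") for _ in range(4)]) == 0

    def test_worked_example_cost(self):
        assert decision_cost([rec("I", p1=8, p2=32)]) == 40

    def test_cost_matches_per_record_oracle(self, rng):
        trace = [rec(rng.choice(["G", "I", "D", "R"]),
                     p1=int(rng.integers(0, 10)), p2=int(rng.integers(0, 30)))
                 for _ in range(200)]
        expect = sum(r.p1 + r.p2 for r in trace if r.outcome != "R")
        assert decision_cost(trace) == expect

    def test_windowed_series(self):
        trace = [rec("G"), rec("R", p1=2, p2=2), rec("I", p1=1, p2=3),
                 rec("I", p1=0, p2=5), rec("G", p1=2), rec("D")]
        # G/I windows: [G,R,I] and [I,G]; the trailing D has no pass
        sens = g_sensitivity_series(trace, passes_per_window=2)
        assert sens.tolist() == [0.5, 0.5]
        # pass windows (G/I/D): [G,R,I,I] cost 0+4+5, then [G,D] cost 2
        cost = decision_cost_series(trace, passes_per_window=3)
        assert cost.tolist() == [9, 2]

    def test_checks_per_accept(self):
        trace = [rec("G", p1=1), rec("I", p1=2, p2=4), rec("R", p1=9, p2=9)]
        assert checks_per_accept(trace) == pytest.approx(3.5)


class TestRmsdSuccess:
    def test_identical_coordinates(self, rng):
        a = rng.uniform(0, 10, (8, 3))
        rmsd, ok = rmsd_success(a, a.copy())
        assert rmsd == 0.0 and ok

    def test_uniform_translation_fails_at_three_angstrom(self, rng):
        a = rng.uniform(0, 10, (8, 3))
        rmsd, ok = rmsd_success(a + np.array([0.0, 0.0, 3.0]), a)
        assert rmsd == pytest.approx(3.0) and not ok

    def test_matches_direct_formula(self, rng):
        a = rng.uniform(0, 10, (12, 3))
        b = a + rng.normal(0, 1, a.shape)
        rmsd, _ = rmsd_success(b, a)
        expect = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert rmsd == pytest.approx(expect, abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(InvalidArgumentError):
            rmsd_success(np.zeros((3, 3)), np.zeros((4, 3)))


class TestAcceleration:
    def test_identical_timings_unity(self):
        t = TimingBreakdown(search=10.0, overhead=2.0)
        assert acceleration(t, t, base=1) == (1.0, 1.0, 1.0)

    def test_normalized_by_base(self):
        ref = TimingBreakdown(search=90.0, overhead=10.0)
        new = TimingBreakdown(search=40.0, overhead=10.0)
        a_ts, a_to, norm = acceleration(ref, new, base=4)
        assert a_to == pytest.approx(2.0)
        assert norm == pytest.approx(8.0)

    def test_invalid_base(self):
        t = TimingBreakdown(search=1.0, overhead=0.0)
        with pytest.raises(InvalidArgumentError):
            acceleration(t, t, base=3)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.floats(0.1, 1e4), st.floats(0.0, 1e4),
           st.floats(0.1, 1e4), st.floats(0.0, 1e4),
           st.sampled_from([1, 2, 4]))
    def test_normalization_is_exact_multiple(self, s1, h1, s2, h2, base):
        ref = TimingBreakdown(search=s1, overhead=h1)
        new = TimingBreakdown(search=s2, overhead=h2)
        _, a_to, norm = acceleration(ref, new, base=base)
        assert norm == a_to * base
        assert ref.overall == ref.search + ref.overhead


class TestAsofSensitivityCorrelation:
    def test_computable_on_synthetic_run(self):
        from widedock import (SearchConfig, asof_sensitivity_correlation,
                              make_two_well_landscape, run_search)
        land = make_two_well_landscape(seed=9, box_size=30.0,
                                       min_separation=15.0, n_rough=30)
        res = run_search(SearchConfig(objective=land, exhaustiveness=4,
                                      seed=2, max_steps=600))
        r = asof_sensitivity_correlation(res.histories, res.trace,
                                         frame_len=100)
        assert -1.0 <= r <= 1.0

    def test_undefined_without_sensitivity_frames(self, rng):
        from widedock import asof_sensitivity_correlation
        hists = [rng.uniform(0, 20, size=(41, 3)) for _ in range(2)]
        trace = [rec("R", walker=w, step=s)
                 for w in range(2) for s in range(1, 41)]
        with pytest.raises(UndefinedMetricError):
            asof_sensitivity_correlation(hists, trace, frame_len=10)


class TestMetricsTable:
    def test_columns_and_frames(self, rng):
        hists = [rng.uniform(0, 20, size=(61, 3)) for _ in range(3)]
        trace = [rec(rng.choice(["G", "I", "D", "R"]), p1=1, p2=2,
                     walker=w, step=s)
                 for w in range(3) for s in range(1, 61)]
        table = metrics_table(hists, trace, radius=5.0, frame_len=20)
        assert list(table.columns) == ["frame", "asof", "g_sensitivity",
                                       "decision_cost"]
        assert len(table) == 3
        assert np.all(table["asof"] >= 0.0)
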