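"""Binding-event extraction, residence statistics and exchange counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memlip.contacts import ContactConfig, OccupancySeries, SiteDefinition
from memlip.residence import (BindingEvent, count_single_lipid_exchanges,
                              cutoff_sensitivity, extract_events,
                              longest_events, mean_residence,
                              DEFAULT_DELTA_GRID)
from memlip.system import SystemError_

from test_contacts import make_system, make_traj

SITE = SiteDefinition("s", "INNER", (1, 2))


def series_from_zeta(zeta, occupants=None, interval=0.3):
    zeta = np.asarray(zeta, dtype=np.int8)
    if occupants is None:
        occupants = [frozenset({1}) if z else frozenset() for z in zeta]
    times = np.arange(len(zeta)) * interval
    d = np.where(zeta, 0.5, 2.0)
    return OccupancySeries(SITE, "CL", times, d, zeta, list(occupants), 0.7,
                           interval)


class TestExtractEvents:
    def test_hand_run_length_example(self):
        events = extract_events(series_from_zeta([0, 1, 1, 1, 0, 1, 0]))
        assert [e.duration for e in events] == [pytest.approx(0.9),
                                                pytest.approx(0.3)]
        assert not any(e.censored for e in events)

    def test_all_zero_and_all_one(self):
        assert extract_events(series_from_zeta([0] * 6)) == []
        events = extract_events(series_from_zeta([1] * 6))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(6 * 0.3)
        assert events[0].censored   # touches both ends

    def test_censoring_flags(self):
        events = extract_events(series_from_zeta([1, 1, 0, 1, 0, 1]))
        assert [e.censored for e in events] == [True, False, True]
        assert mean_residence(events) == pytest.approx(0.3)
        assert mean_residence(events, exclude_censored=False) == pytest.approx(
            (0.6 + 0.3 + 0.3) / 3)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_duration_conservation(self, zeta):
        """Sum of event durations equals interval x number of zeta=1 samples."""
        events = extract_events(series_from_zeta(zeta))
        total = sum(e.duration for e in events)
        assert total == pytest.approx(0.3 * sum(zeta))


class TestLongestEvents:
    def _mk(self, durations_samples):
        z = []
        for n in durations_samples:
            z += [1] * n + [0]
        return extract_events(series_from_zeta([0] + z))

    def test_sorting(self):
        ev = self._mk([5, 9, 1])
        top = longest_events(ev, 2)
        assert [e.n_samples for e in top] == [9, 5]

    def test_k_larger_than_n(self):
        ev = self._mk([2, 3])
        assert len(longest_events(ev, 10)) == 2

    def test_tie_broken_by_earlier_start(self):
        ev = self._mk([4, 4, 4])
        top = longest_events(ev, 2)
        assert [e.start_index for e in top] == sorted(
            e.start_index for e in ev)[:2]

    def test_k_must_be_positive(self):
        with pytest.raises(SystemError_):
            longest_events([], 0)


def oracle_exchanges(sets):
    """Independent re-statement of the exchange rule: walk the samples,
    remember the last sole occupant seen, count identity changes."""
    n_changes = 0
    last = None
    n_single = 0
    n_occupied = 0
    for s in sets:
        if len(s) >= 1:
            n_occupied += 1
        if len(s) == 1:
            n_single += 1
            cur = list(s)[0]
            if last is not None and cur != last:
                n_changes += 1
            last = cur
    frac = n_single / n_occupied if n_occupied else 0.0
    return n_changes, frac


class TestExchanges:
    def test_hand_enumerated_fixture(self):
        sets = [frozenset(x) for x in
                ({"a"}, {"a"}, {"a", "b"}, {"b"}, {"b"}, {"c"})]
        n, frac = count_single_lipid_exchanges(sets)
        assert n == 2
        assert frac == pytest.approx(5 / 6)

    def test_degenerate_sequences(self):
        assert count_single_lipid_exchanges(
            [frozenset({"a"})] * 3) == (0, 1.0)
        assert count_single_lipid_exchanges(
            [frozenset({"a", "b"})] * 2) == (0, 0.0)

    def test_against_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        ids = ["a", "b", "c"]
        for _ in range(1000):
            length = rng.integers(1, 21)
            sets = []
            for _ in range(length):
                k = rng.integers(0, 4)
                sets.append(frozenset(rng.choice(ids, size=k, replace=False)))
            assert count_single_lipid_exchanges(sets) == oracle_exchanges(sets)

    def test_event_carries_exchange_stats(self):
        occ = [frozenset(), frozenset({1}), frozenset({2}), frozenset({2}),
               frozenset()]
        events = extract_events(series_from_zeta([0, 1, 1, 1, 0], occ))
        assert events[0].n_exchanges == 1
        assert events[0].single_occupancy_fraction == 1.0
        assert events[0].max_occupants == 1


class TestCutoffSensitivity:
    def test_longest_non_decreasing_default_grid(self, default_run):
        system, traj, truth = default_run
        site = truth.sites[0]
        curve = cutoff_sensitivity(traj, system, site, "CL")
        assert curve["delta_nm"].iloc[0] == pytest.approx(0.8)
        assert curve["delta_nm"].iloc[-1] == pytest.approx(1.6)
        assert (np.diff(curve["longest_ns"]) >= -1e-12).all()

    def test_oscillating_lipid_merges_at_larger_delta(self):
        """A lipid hopping between 0.9 and 1.2 nm gives fragmented events at
        delta = 1.0 but one merged event at delta = 1.3."""
        system = make_system(["CL"])
        frames = []
        for k in range(6):
            d = 0.9 if k % 2 == 0 else 1.2
            frames.append(np.array([[1.0, 1.0, 1.0], [1.2, 1.0, 1.0],
                                    [1.0 + d, 1.0, 1.0]]))
        traj = make_traj(frames)
        curve = cutoff_sensitivity(traj, system, SITE, "CL",
                                   delta_grid=[1.0, 1.3])
        assert curve.loc[0, "n_events"] == 3
        assert curve.loc[1, "n_events"] == 1
        assert curve.loc[1, "longest_ns"] == pytest.approx(6 * 0.3)

    def test_bad_grids_rejected(self, default_run):
        system, traj, truth = default_run
        with pytest.raises(SystemError_):
            cutoff_sensitivity(traj, system, truth.sites[0], "CL",
                               delta_grid=[])
        with pytest.raises(SystemError_):
            cutoff_sensitivity(traj, system, truth.sites[0], "CL",
                               delta_grid=[1.0, 0.9])
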