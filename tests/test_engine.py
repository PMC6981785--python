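"""Dynamic engine: the three analysis modes, causality, determinism."""

import numpy as np
import pandas as pd
import pytest

from dynagra import (
    MonitoringPanel,
    RunConfig,
    WindowConfig,
    cross_dimension_series,
    cross_point_matrix,
    grey_relational_degrees,
    pairwise_degree,
    point_correlation_series,
    variable_correlation_series,
)
from dynagra.engine import decide_window_at
from dynagra.errors import LookupError_, NotComputableError, ShapeError

from conftest import make_panel


@pytest.fixture
def multi_panel(rng):
    n = 240
    src = np.cumsum(rng.normal(size=n)) * 0.2 + np.sin(np.arange(n) / 10.0)
    cols = {("HS", "PM2.5"): src,
            ("HS", "PM10"): 0.9 * src + rng.normal(0, 0.2, n),
            ("HS", "CO"): 0.5 * src + rng.normal(0, 0.2, n),
            ("HS", "TVOC"): rng.normal(0, 1, n)}
    for k, s in enumerate(["N1", "N2", "N3", "N4"], 1):
        cols[(s, "PM2.5")] = (1 - 0.2 * k) * src + rng.normal(0, 0.2, n)
    return make_panel(cols)


class TestVariableMode:
    def test_record_count_bounded(self, multi_panel, config):
        recs = variable_correlation_series(
            multi_panel, "HS", "PM2.5", ["PM10", "CO", "TVOC"], config)
        assert 0 < len(recs) <= 3 * (240 - config.window.L0)
        assert all(r.method == "asw_gra" and 0 < r.degree <= 1 for r in recs)
        assert all(config.window.Lmin <= r.window_length <= 24 for r in recs)

    def test_identical_candidate_scores_one(self, config, rng):
        x = np.cumsum(rng.normal(size=60))
        panel = make_panel({("A", "obj"): x, ("A", "twin"): x.copy()})
        recs = variable_correlation_series(panel, "A", "obj", ["twin"], config)
        assert recs and all(r.degree == 1.0 for r in recs)

    def test_matches_fresh_gra_on_trailing_window(self, multi_panel, config):
        """Each record equals a from-scratch joint GRA over the same window."""
        cand = ["PM10", "CO", "TVOC"]
        recs = variable_correlation_series(multi_panel, "HS", "PM2.5", cand, config)
        times = multi_panel.timestamps
        obj = multi_panel.array("HS", "PM2.5")
        arrays = [multi_panel.array("HS", v) for v in cand]
        for t in [recs[0].time, recs[len(recs) // 2].time, recs[-1].time]:
            at_t = [r for r in recs if r.time == t]
            i = times.get_loc(t)
            L = at_t[0].window_length
            lo = i - L + 1
            want = grey_relational_degrees(
                obj[lo:i + 1], np.vstack([a[lo:i + 1] for a in arrays]))
            for r, w in zip(at_t, want):
                assert r.degree == pytest.approx(w, abs=1e-14)

    def test_object_among_candidates_rejected(self, multi_panel, config):
        with pytest.raises(ShapeError):
            variable_correlation_series(multi_panel, "HS", "PM2.5",
                                        ["PM2.5", "CO"], config)

    def test_unknown_variable_rejected(self, multi_panel, config):
        with pytest.raises(LookupError_):
            variable_correlation_series(multi_panel, "HS", "PM2.5", ["NOx"], config)


class TestPointMode:
    def test_duplicated_station_scores_one(self, config, rng):
        x = np.cumsum(rng.normal(size=60))
        panel = make_panel({("HS", "PM2.5"): x, ("GHOST", "PM2.5"): x.copy()})
        recs = point_correlation_series(panel, "PM2.5", "HS", ["GHOST"], config)
        assert recs and all(r.degree == 1.0 for r in recs)

    def test_stable_under_candidate_permutation(self, multi_panel, config):
        a = point_correlation_series(multi_panel, "PM2.5", "HS",
                                     ["N1", "N2", "N3", "N4"], config)
        b = point_correlation_series(multi_panel, "PM2.5", "HS",
                                     ["N4", "N2", "N1", "N3"], config)
        key = lambda r: (r.time, r.associated_station)
        assert sorted(a, key=key) == sorted(b, key=key)

    def test_pairwise_degree_independent_of_candidate_set(self, multi_panel, config):
        full = point_correlation_series(multi_panel, "PM2.5", "HS",
                                        ["N1", "N2"], config)
        solo = point_correlation_series(multi_panel, "PM2.5", "HS", ["N1"], config)
        full_n1 = {r.time: r.degree for r in full if r.associated_station == "N1"}
        for r in solo:
            assert r.degree == full_n1[r.time]


class TestCrossDimension:
    def test_identical_series_pair_scores_one(self, config, rng):
        x = np.cumsum(rng.normal(size=60))
        panel = make_panel({("A", "x"): x, ("B", "y"): x.copy()})
        recs = cross_dimension_series(panel, [(("A", "x"), ("B", "y"))], config)
        assert recs and all(r.degree == 1.0 for r in recs)

    def test_reduces_to_point_mode_case(self, multi_panel, config):
        via_cross = cross_dimension_series(
            multi_panel, [(("HS", "PM2.5"), ("N1", "PM2.5"))], config)
        via_point = point_correlation_series(multi_panel, "PM2.5", "HS",
                                             ["N1"], config)
        assert [(r.time, r.degree) for r in via_cross] == \
               [(r.time, r.degree) for r in via_point]

    def test_self_pair_rejected(self, multi_panel, config):
        with pytest.raises(ShapeError):
            cross_dimension_series(multi_panel,
                                   [(("HS", "PM2.5"), ("HS", "PM2.5"))], config)


class TestCrossPointMatrix:
    def test_two_identical_stations_matrix_of_ones(self, config, rng):
        x = np.cumsum(rng.normal(size=60))
        panel = make_panel({("A", "x"): x, ("B", "x"): x.copy()})
        m = cross_point_matrix(panel, "x", panel.timestamps[-1], config)
        np.testing.assert_array_equal(m.degrees.to_numpy(), np.ones((2, 2)))

    def test_symmetric_unit_diagonal(self, multi_panel, config):
        m = cross_point_matrix(multi_panel, "PM2.5", multi_panel.timestamps[100],
                               config)
        g = m.degrees.to_numpy()
        assert g.shape == (5, 5)
        np.testing.assert_array_equal(np.diag(g), np.ones(5))
        np.testing.assert_array_equal(g, g.T)
        assert ((g > 0) & (g <= 1)).all()

    def test_entries_match_elementwise_recomputation(self, multi_panel, config):
        t = multi_panel.timestamps[150]
        i = 150
        m = cross_point_matrix(multi_panel, "PM2.5", t, config)
        wcfg = config.window.resolved(multi_panel.n_hours)
        for p in m.degrees.index:
            for q in m.degrees.columns:
                if p == q:
                    continue
                a = multi_panel.array(p, "PM2.5")
                b = multi_panel.array(q, "PM2.5")
                L = max(decide_window_at(a, i, wcfg), decide_window_at(b, i, wcfg))
                want = pairwise_degree(a[i - L + 1: i + 1], b[i - L + 1: i + 1])
                assert m.degrees.loc[p, q] == pytest.approx(want, abs=1e-14)

    def test_strongest_pair_is_offdiagonal_argmax(self, multi_panel, config):
        m = cross_point_matrix(multi_panel, "PM2.5", multi_panel.timestamps[100],
                               config)
        p, q, d = m.strongest_pair
        assert p != q
        off = m.degrees.to_numpy(copy=True)
        np.fill_diagonal(off, -np.inf)
        assert d == off.max()

    def test_insufficient_history_lists_earliest_time(self, multi_panel, config):
        with pytest.raises(NotComputableError, match="earliest"):
            cross_point_matrix(multi_panel, "PM2.5", multi_panel.timestamps[3],
                               config)


class TestCausalityAndDeterminism:
    def test_truncation_leaves_past_records_unchanged(self, multi_panel, config):
        full = variable_correlation_series(multi_panel, "HS", "PM2.5",
                                           ["PM10", "CO"], config)
        cut = 120
        truncated = MonitoringPanel(multi_panel.values.iloc[:cut])
        part = variable_correlation_series(truncated, "HS", "PM2.5",
                                           ["PM10", "CO"], config)
        t_max = truncated.timestamps[-1]
        assert part == [r for r in full if r.time <= t_max]

    def test_repeated_runs_bit_identical(self, multi_panel, config):
        run = lambda: point_correlation_series(multi_panel, "PM2.5", "HS",
                                               ["N1", "N2"], config)
        assert run() == run()


class TestMissingData:
    def test_small_gaps_tolerated_large_gaps_skipped(self, rng):
        n = 80
        x = np.cumsum(rng.normal(size=n))
        y = x + rng.normal(0, 0.1, n)
        y_gappy = y.copy()
        y_gappy[40:52] = np.nan  # a 12-hour outage
        panel = make_panel({("A", "x"): x, ("B", "x"): y_gappy})
        cfg = RunConfig(window=WindowConfig(L0=10, Lmin=10, Lmax=20),
                        max_gap_fraction=0.10)
        recs = cross_dimension_series(panel, [(("A", "x"), ("B", "x"))], cfg)
        times = {r.time for r in recs}
        # steps whose window is swallowed by the outage are absent
        assert panel.timestamps[45] not in times
        # but the engine recovers once the outage leaves the window
        assert panel.timestamps[79] in times
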