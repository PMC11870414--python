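"""Tracking, lifeline conversion, and the survival statistics.

The Cox fitter is cross-checked two ways: against an independent
brute-force maximization of a straightforwardly coded Efron partial
likelihood on tiny datasets, and against ``lifelines`` on larger ones.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from imnpheno.core import ParameterError
from imnpheno.survival import (
    Detection,
    Lifeline,
    SeparationError,
    cox_fit,
    fit_cox,
    fit_km,
    link_detections,
    logrank_pairwise,
    logrank_statistic,
    sample_lifelines,
    tracks_to_lifelines,
)


def efron_loglik_reference(beta, durations, events, x):
    """Independent Efron partial log-likelihood: plain loops, no reuse."""
    ll = 0.0
    times = sorted({t for t, e in zip(durations, events) if e == 1})
    for t in times:
        D = [i for i in range(len(durations)) if durations[i] == t and events[i] == 1]
        R = [i for i in range(len(durations)) if durations[i] >= t]
        s_r = sum(math.exp(beta * x[i]) for i in R)
        s_d = sum(math.exp(beta * x[i]) for i in D)
        d = len(D)
        ll += sum(beta * x[i] for i in D)
        for l in range(d):
            ll -= math.log(s_r - (l / d) * s_d)
    return ll


def brute_force_loghr(durations, events, x, bound=8.0):
    res = minimize_scalar(
        lambda b: -efron_loglik_reference(b, durations, events, x),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return res.x


def _lifelines(durs, events, group="g"):
    return [
        Lifeline(f"s{i}", group, 0.0, float(d), int(e))
        for i, (d, e) in enumerate(zip(durs, events))
    ]


def _sim_group(rng, lam, n, censor=34.0):
    t = rng.exponential(1.0 / lam, n)
    ev = (t <= censor).astype(int)
    return np.minimum(t, censor), ev


class TestLinking:
    def _drifting(self, n_frames=18, n_cells=1, spacing=100.0, drift=1.0):
        frames = []
        for f in range(n_frames):
            frames.append(
                [
                    Detection(frame=f, row=50.0 + i * spacing + drift * f, col=50.0)
                    for i in range(n_cells)
                ]
            )
        return frames

    def test_single_drifting_cell_single_track(self):
        tracks = link_detections(self._drifting(), max_dist_um=20.0, pixel_size=1.0)
        assert len(tracks) == 1
        assert len(tracks[0].detections) == 18

    def test_two_distant_cells_two_pure_tracks(self):
        tracks = link_detections(self._drifting(n_cells=2), max_dist_um=20.0, pixel_size=1.0)
        assert len(tracks) == 2
        for t in tracks:
            rows = [d.row for d in t.detections]
            assert np.ptp(np.diff(rows)) == pytest.approx(0.0, abs=1e-9)  # constant drift

    def test_single_frame_dropout_bridged_by_gap(self):
        frames = self._drifting()
        frames[7] = []
        tracks = link_detections(frames, max_dist_um=20.0, max_gap=1, pixel_size=1.0)
        assert len(tracks) == 1
        assert tracks[0].last_seen_frame == 17

    def test_gap_beyond_max_terminates_track(self):
        frames = self._drifting()
        frames[7] = frames[8] = []
        tracks = link_detections(frames, max_dist_um=20.0, max_gap=1, pixel_size=1.0)
        assert len(tracks) == 2


class TestLifelines:
    DAYS = tuple(float(d) for d in range(12, 47, 2))

    def _track_frames(self, first, last):
        return [Detection(frame=f, row=1.0, col=1.0) for f in range(first, last + 1)]

    def test_survivor_censored_at_last_day(self):
        from imnpheno.survival import Track

        tracks = [Track(0, self._track_frames(0, 17))]
        lls, _ = tracks_to_lifelines(tracks, self.DAYS)
        assert lls[0].duration_days == 34.0 and lls[0].event == 0

    def test_disappearance_is_event(self):
        from imnpheno.survival import Track

        tracks = [Track(0, self._track_frames(0, 4))]  # D12..D20
        lls, _ = tracks_to_lifelines(tracks, self.DAYS)
        assert lls[0].duration_days == 8.0 and lls[0].event == 1

    def test_entry_at_first_imn_classification(self):
        from imnpheno.survival import Track

        dets = [
            Detection(frame=f, row=1.0, col=1.0, cell_class="non_neuron" if f < 2 else "iMN")
            for f in range(0, 10)
        ]  # iMN from D16, last seen D30
        lls, _ = tracks_to_lifelines([Track(0, dets)], self.DAYS)
        assert lls[0].entry_day == 16.0
        assert lls[0].duration_days == 14.0 and lls[0].event == 1

    def test_never_imn_excluded_and_counted(self):
        from imnpheno.survival import Track

        dets = [Detection(frame=f, row=1.0, col=1.0, cell_class="dead") for f in range(5)]
        lls, excluded = tracks_to_lifelines([Track(0, dets)], self.DAYS)
        assert lls == [] and excluded == 1


class TestSampling:
    def test_seed_reproducible(self):
        lls = _lifelines(np.arange(1, 51), np.ones(50))
        a = sample_lifelines(lls, 10, seed=3)
        b = sample_lifelines(lls, 10, seed=3)
        assert [l.subject_id for l in a] == [l.subject_id for l in b]

    def test_full_population_identity(self):
        lls = _lifelines([1, 2, 3], [1, 1, 0])
        assert sample_lifelines(lls, 3, seed=0) == lls

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ParameterError):
            sample_lifelines(_lifelines([1], [1]), 0)


class TestKaplanMeier:
    def test_hand_product_limit_oracle(self):
        # durations 1 (event), 2 (censored), 3 (event), 4 (censored):
        # S(1) = 3/4; S(3) = 3/4 * (1 - 1/2) = 0.375
        km = fit_km(_lifelines([1, 2, 3, 4], [1, 0, 1, 0]))
        assert km.survival_at(1.0) == pytest.approx(0.75)
        assert km.survival_at(3.0) == pytest.approx(0.375)

    def test_all_events_at_five(self):
        km = fit_km(_lifelines([5, 5, 5], [1, 1, 1]))
        assert km.survival_at(4.999) == 1.0
        assert km.survival_at(5.0) == 0.0

    def test_no_events_flat_curve(self):
        km = fit_km(_lifelines([3, 7, 9], [0, 0, 0]))
        assert np.all(km.survival == 1.0)

    def test_matches_lifelines_package(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        durs, evs = _sim_group(rng, 0.05, 150)
        km = fit_km(_lifelines(durs, evs))
        kmf = KaplanMeierFitter().fit(durs, evs)
        for t in (5.0, 15.0, 30.0):
            assert km.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    @given(
        st.lists(
            st.tuples(st.floats(0.5, 40.0), st.integers(0, 1)), min_size=1, max_size=30
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_from_one(self, pairs):
        km = fit_km(_lifelines([p[0] for p in pairs], [p[1] for p in pairs]))
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))


class TestLogrank:
    def test_identical_groups_null(self):
        durs, evs = [2, 4, 6, 8], [1, 0, 1, 1]
        chi2, p = logrank_statistic(durs, evs, durs, evs)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_hazard_difference_detected(self):
        rng = np.random.default_rng(10)
        d1, e1 = _sim_group(rng, 0.02, 200)
        d2, e2 = _sim_group(rng, 0.2, 200)
        _, p = logrank_statistic(d1, e1, d2, e2)
        assert p < 1e-3

    def test_matches_lifelines_package(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(11)
        d1, e1 = _sim_group(rng, 0.03, 80)
        d2, e2 = _sim_group(rng, 0.06, 90)
        chi2, p = logrank_statistic(d1, e1, d2, e2)
        ref = logrank_test(d1, d2, e1, e2)
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)

    def test_pairwise_reports_all_pairs_with_bonferroni(self):
        rng = np.random.default_rng(12)
        groups = {
            name: _lifelines(*_sim_group(rng, lam, 60), group=name)
            for name, lam in (("a", 0.03), ("b", 0.05), ("c", 0.08))
        }
        table = logrank_pairwise(groups)
        assert len(table) == 3
        assert np.all(table["p_bonferroni"] >= table["p"] - 1e-15)
        assert np.all(table["p_bonferroni"] <= 1.0)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ParameterError):
            logrank_pairwise({"only": _lifelines([1], [1])})


class TestCox:
    def test_tiny_dataset_matches_brute_force(self):
        durs = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        evs = [1, 1, 1, 0, 1, 0]
        x = [1.0, 1.0, 0.0, 1.0, 0.0, 0.0]
        res = cox_fit(durs, evs, np.array(x).reshape(-1, 1))
        assert res.coef[0] == pytest.approx(brute_force_loghr(durs, evs, x), abs=1e-4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_random_tiny_datasets_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.integers(0, 2, n).astype(float)
        durs = np.round(rng.exponential(10.0, n), 1) + 0.5
        evs = rng.integers(0, 2, n)
        # both covariate arms need an event, else the likelihood is monotone
        if evs[x == 1].sum() == 0 or evs[x == 0].sum() == 0:
            return
        try:
            res = cox_fit(durs, evs, x.reshape(-1, 1))
        except SeparationError:
            return
        if abs(res.coef[0]) > 6:  # near-degenerate: brute-force bound would bind
            return
        assert res.coef[0] == pytest.approx(brute_force_loghr(durs, evs, x), abs=1e-4)

    def test_null_covariate_within_three_se(self):
        rng = np.random.default_rng(21)
        durs, evs = _sim_group(rng, 0.05, 400)
        x = rng.permutation(np.repeat([0.0, 1.0], 200))
        res = cox_fit(durs, evs, x.reshape(-1, 1))
        assert abs(res.coef[0]) <= 3 * res.se[0]

    def test_true_hazard_ratio_recovered(self):
        rng = np.random.default_rng(22)
        x = np.repeat([0.0, 1.0], 500)
        lam = 0.03 * np.exp(math.log(2.0) * x)
        t = rng.exponential(1.0 / lam)
        ev = (t <= 34.0).astype(int)
        res = cox_fit(np.minimum(t, 34.0), ev, x.reshape(-1, 1))
        assert abs(res.coef[0] - math.log(2.0)) <= 3 * res.se[0]

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(23)
        x = np.repeat([0.0, 1.0], 150)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
        ev = (t <= 34.0).astype(int)
        t = np.ceil(np.minimum(t, 34.0) / 2) * 2  # 2-day imaging grid -> heavy ties
        res = cox_fit(t, ev, x.reshape(-1, 1))
        cph = CoxPHFitter().fit(pd.DataFrame({"T": t, "E": ev, "x": x}), "T", "E")
        assert res.coef[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_ci_is_plus_minus_196_se(self):
        rng = np.random.default_rng(24)
        durs, evs = _sim_group(rng, 0.05, 100)
        x = rng.integers(0, 2, 100).astype(float)
        res = cox_fit(durs, evs, x.reshape(-1, 1))
        assert res.ci_upper[0] - res.coef[0] == pytest.approx(1.96 * res.se[0], rel=1e-3)

    def test_separation_raises_named_error(self):
        # covariate 1 ⇔ early event: monotone likelihood
        durs = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        evs = [1, 1, 1, 0, 0, 0]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        with pytest.raises(SeparationError):
            cox_fit(durs, evs, np.array(x).reshape(-1, 1))

    def test_group_indicator_wrapper(self):
        rng = np.random.default_rng(25)
        lls = _lifelines(*_sim_group(rng, 0.03, 80), group="control") + _lifelines(
            *_sim_group(rng, 0.08, 80), group="mutant"
        )
        res = fit_cox(lls, reference_group="control")
        assert res.names == ["mutant_vs_control"]
        assert res.coef[0] > 0
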