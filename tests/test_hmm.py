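"""HMM caller: emissions, decoding vs the exhaustive oracle, EM, unit calling."""

import math

import numpy as np
import pytest

from nascentscan.hmm import (
    HMMParams,
    TranscriptUnit,
    brute_force_decode,
    call_transcripts,
    emission_loglik,
    fit_emissions,
    merge_unit_sets,
    moment_init,
    units_from_path,
    viterbi,
)
from nascentscan.tracks import WindowedTrack

# moderate transitions so short test sequences can actually switch states
SOFT = HMMParams(
    shape_n=5.0, neg_log_trans_t_to_n=3.0, neg_log_trans_n_to_t=3.0,
    scale_n=0.3, shape_t=2.0, scale_t=4.0, zero_mass_n=0.7, zero_mass_t=0.05,
)


def random_instance(rng):
    n = int(rng.integers(1, 13))
    obs = np.where(rng.random(n) < 0.5, 0.0, rng.gamma(2.0, 3.0, n))
    return obs


class TestEmissions:
    def test_zero_count_draws_point_mass(self):
        p = HMMParams(scale_n=1, shape_t=1, scale_t=1, zero_mass_n=0.8,
                      zero_mass_t=0.1)
        assert emission_loglik(0.0, "N", p) == pytest.approx(math.log(0.8))

    def test_zero_count_with_no_zero_mass_is_impossible(self):
        p = HMMParams(scale_n=1, shape_t=1, scale_t=1, zero_mass_n=0.0,
                      zero_mass_t=0.1)
        assert emission_loglik(0.0, "N", p) == -math.inf

    def test_exponential_special_case(self):
        # shape 1, scale 1 gamma is Exp(1): logpdf(2) = -2
        p = HMMParams(shape_n=1.0, scale_n=1.0, shape_t=1, scale_t=1,
                      zero_mass_n=0.0, zero_mass_t=0.0)
        assert emission_loglik(2.0, "N", p) == pytest.approx(-2.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            emission_loglik(-1.0, "N", SOFT)


class TestViterbi:
    def test_all_zero_observations_decode_to_all_n(self):
        path = viterbi(np.zeros(30), SOFT)
        assert not path.any()

    def test_single_observation_tie_breaks_to_n(self):
        p = HMMParams(shape_n=2, scale_n=1, shape_t=2, scale_t=1,
                      zero_mass_n=0.5, zero_mass_t=0.5,
                      neg_log_trans_t_to_n=3, neg_log_trans_n_to_t=3)
        assert viterbi([0.0], p)[0] == 0
        assert viterbi([4.0], p)[0] == 0

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            obs = random_instance(rng)
            assert np.array_equal(viterbi(obs, SOFT),
                                  brute_force_decode(obs, SOFT))

    def test_oracle_rejects_long_sequences(self):
        with pytest.raises(ValueError, match="16"):
            brute_force_decode(np.zeros(17), SOFT)

    def test_raising_exit_penalty_never_increases_unit_count(self):
        rng = np.random.default_rng(7)
        vals = np.where(rng.random(2000) < 0.8, 0.0, rng.gamma(2, 3, 2000))
        vals[300:400] += rng.gamma(4, 5, 100)
        vals[900:1000] += rng.gamma(4, 5, 100)
        counts = []
        for neg_log in (2.0, 5.0, 20.0, 200.0):
            p = HMMParams(
                shape_n=5, neg_log_trans_t_to_n=neg_log, neg_log_trans_n_to_t=5.0,
                scale_n=0.5, shape_t=3.0, scale_t=5.0,
                zero_mass_n=0.8, zero_mass_t=0.05,
            )
            track = WindowedTrack("chr1", "+", 25, vals)
            counts.append(len(call_transcripts(track, p)))
        assert counts == sorted(counts, reverse=True)


class TestFitEmissions:
    @staticmethod
    def _sample_from_model(rng, n, params):
        trans = np.exp(params.log_transition_matrix())
        states = np.empty(n, dtype=int)
        states[0] = 0
        for i in range(1, n):
            states[i] = rng.random() < trans[states[i - 1], 1]
        obs = np.empty(n)
        for s, (shape, scale, zm) in enumerate(
            ((params.shape_n, params.scale_n, params.zero_mass_n),
             (params.shape_t, params.scale_t, params.zero_mass_t))
        ):
            m = states == s
            vals = rng.gamma(shape, scale, m.sum())
            vals[rng.random(m.sum()) < zm] = 0.0
            obs[m] = vals
        return obs, states

    def test_recovers_scales_from_simulated_mixture(self):
        truth = HMMParams(
            shape_n=5.0, neg_log_trans_t_to_n=4.0, neg_log_trans_n_to_t=6.0,
            scale_n=0.2, shape_t=4.0, scale_t=3.0,
            zero_mass_n=0.7, zero_mass_t=0.02,
        )
        rng = np.random.default_rng(11)
        obs, _ = self._sample_from_model(rng, 100_000, truth)
        start = HMMParams(shape_n=5.0, neg_log_trans_t_to_n=4.0,
                          neg_log_trans_n_to_t=6.0)
        fitted = fit_emissions(obs, start, max_iter=50)
        assert fitted.scale_n == pytest.approx(truth.scale_n, rel=0.15)
        assert fitted.scale_t == pytest.approx(truth.scale_t, rel=0.15)

    def test_loglik_is_monotone_across_iterations(self):
        rng = np.random.default_rng(5)
        obs, _ = self._sample_from_model(rng, 5000, SOFT)
        _, history = fit_emissions(obs, HMMParams(shape_n=5,
                                                  neg_log_trans_t_to_n=3,
                                                  neg_log_trans_n_to_t=3),
                                   max_iter=25, tol=0.0, return_history=True)
        assert len(history) > 2
        diffs = np.diff(history)
        assert np.all(diffs >= -1e-6 * np.abs(history[:-1]))

    def test_max_iter_zero_returns_initialization(self):
        out = fit_emissions(np.array([0, 1, 5, 0.0]), SOFT, max_iter=0)
        assert out == SOFT

    def test_all_zero_track_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_emissions(np.zeros(10), HMMParams())

    def test_moment_init_splits_at_positive_median(self):
        obs = np.array([0.0] * 90 + [1.0] * 5 + [20.0] * 5)
        init = moment_init(obs, HMMParams())
        assert init.emissions_set
        assert init.scale_t * init.shape_t > init.scale_n * 5  # T mean >> N mean


class TestUnitExtraction:
    def _track(self, n, vals=None):
        v = np.zeros(n) if vals is None else np.asarray(vals, float)
        return WindowedTrack("chr1", "+", 25, v)

    def test_run_to_interval_arithmetic(self):
        path = np.array([0, 0, 1, 1, 1, 0], dtype=np.int8)
        (unit,) = units_from_path(path, self._track(6, [0, 0, 5, 6, 7, 0]))
        assert (unit.start, unit.end) == (50, 125)
        assert unit.mean_signal == pytest.approx(6.0)

    def test_all_n_path_gives_no_units(self):
        assert units_from_path(np.zeros(5, dtype=np.int8), self._track(5)) == []

    def test_adjacent_runs_are_not_merged(self):
        path = np.array([1, 1, 0, 1, 1], dtype=np.int8)
        units = units_from_path(path, self._track(5, [3, 3, 0, 3, 3]))
        assert [(u.start, u.end) for u in units] == [(0, 50), (75, 125)]

    def test_min_length_filter_drops_short_runs(self):
        path = np.array([1, 0, 1, 1, 1], dtype=np.int8)
        units = units_from_path(path, self._track(5, [3, 0, 3, 3, 3]),
                                min_length=50)
        assert [(u.start, u.end) for u in units] == [(50, 125)]

    def test_units_never_overlap_on_a_strand(self):
        rng = np.random.default_rng(3)
        vals = np.where(rng.random(3000) < 0.7, 0.0, rng.gamma(2, 2, 3000))
        track = WindowedTrack("chr1", "+", 25, vals)
        units = call_transcripts(track, SOFT)
        for a, b in zip(units, units[1:]):
            assert a.end <= b.start

    def test_union_merge_collapses_overlapping_calls(self):
        from nascentscan.intervals import GenomicInterval

        def u(s, e, strand="+"):
            iv = GenomicInterval("chr1", s, e, strand, f"u{s}")
            return TranscriptUnit(iv, 1.0, iv.name)

        merged = merge_unit_sets([[u(0, 100), u(500, 600)], [u(50, 200)]])
        assert [(m.start, m.end) for m in merged] == [(0, 200), (500, 600)]
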