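"""Cross-correlation signal, dyad-calling and NFR tests."""

import numpy as np
import pytest

from atacnuc import caller, evaluation, fragments, occupancy, simulate
from atacnuc.caller import (
    CallerError,
    NucleosomeCall,
    SignalTrack,
    background_and_sd,
    call_nfrs,
    candidate_dyads,
    filter_calls,
    log_likelihood_ratio,
    nonredundant_map,
    raw_signal,
    zscore,
)

REGION = ("chrS", 200, 4400)


class TestRawSignal:
    def test_zero_fragments(self):
        assert raw_signal(np.zeros((4, 5)), np.ones((4, 5))) == 0.0

    def test_indicator_picks_out_entry(self):
        V = np.arange(20.0).reshape(4, 5)
        F = np.zeros((4, 5))
        F[2, 3] = 1.0
        assert raw_signal(F, V) == V[2, 3]

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(40)
        F = rng.uniform(0, 3, size=(4, 5))
        V = rng.uniform(0, 2, size=(4, 5))
        expected = sum(F[i, j] * V[i, j] for i in range(4) for j in range(5))
        assert raw_signal(F, V) == pytest.approx(expected)

    def test_dimension_mismatch_fatal(self):
        with pytest.raises(CallerError):
            raw_signal(np.zeros((4, 5)), np.zeros((5, 4)))

    def test_additive_over_disjoint_fragment_sets(self):
        rng = np.random.default_rng(41)
        V = rng.uniform(0, 1, size=(6, 7))
        F1 = rng.poisson(2, size=(6, 7)).astype(float)
        F2 = rng.poisson(2, size=(6, 7)).astype(float)
        assert raw_signal(F1 + F2, V) == pytest.approx(
            raw_signal(F1, V) + raw_signal(F2, V)
        )


class TestBackgroundAndSd:
    def test_constant_v_has_zero_variance(self):
        rng = np.random.default_rng(42)
        B = rng.dirichlet(np.ones(30)).reshape(5, 6)
        V = np.full((5, 6), 3.7)
        bg, sd = background_and_sd(B, V, 100)
        assert bg == pytest.approx(370.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_point_mass_background_zero_variance(self):
        B = np.zeros((5, 6))
        B[2, 2] = 1.0
        V = np.arange(30.0).reshape(5, 6)
        _, sd = background_and_sd(B, V, 50)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_zero_fragments(self):
        assert background_and_sd(np.full((2, 2), 0.25), np.ones((2, 2)), 0) == (0.0, 0.0)

    def test_matches_multinomial_monte_carlo(self):
        # the full 20-instance comparison runs in the acceptance suite
        rng = np.random.default_rng(43)
        for _ in range(3):
            B = rng.dirichlet(np.ones(108)).reshape(12, 9)
            V = rng.uniform(0, 2, size=(12, 9))
            _, sd = background_and_sd(B, V, 200)
            draws = rng.multinomial(200, B.ravel(), size=100_000) @ V.ravel()
            assert sd**2 == pytest.approx(draws.var(ddof=1), rel=0.02)


class TestZscore:
    def test_null_is_zero(self):
        assert zscore(5.0, 5.0, 2.0) == 0.0

    def test_three_sigma(self):
        assert zscore(16.0, 10.0, 2.0) == pytest.approx(3.0)

    def test_zero_sd_sentinels(self):
        assert zscore(5.0, 5.0, 0.0) == 0.0
        assert zscore(6.0, 5.0, 0.0) == np.inf
        assert zscore(4.0, 5.0, 0.0) == -np.inf


class TestLogLikelihoodRatio:
    def test_uniform_template_is_zero(self):
        rng = np.random.default_rng(44)
        B = rng.dirichlet(np.ones(12)).reshape(3, 4)
        F = rng.poisson(3, size=(3, 4)).astype(float)
        assert log_likelihood_ratio(F, np.ones((3, 4)), B) == pytest.approx(0.0, abs=1e-9)

    def test_positive_when_data_follow_template(self):
        B = np.full((3, 3), 1 / 9)
        V = np.array([[9.0, 1, 1], [1, 1, 1], [1, 1, 1]])
        F = np.zeros((3, 3))
        F[0, 0] = 10.0
        assert log_likelihood_ratio(F, V, B) > 0

    def test_hand_computed_toy(self):
        B = np.array([[0.2, 0.3], [0.1, 0.4]])
        V = np.array([[2.0, 1.0], [1.0, 0.5]])
        F = np.array([[3.0, 0.0], [1.0, 2.0]])
        p1 = V * B + 1e-9
        p1 /= p1.sum()
        p0 = B + 1e-9
        p0 /= p0.sum()
        expected = (F * (np.log(p1) - np.log(p0))).sum()
        assert log_likelihood_ratio(F, V, B) == pytest.approx(expected)

    def test_empty_data_zero(self):
        assert log_likelihood_ratio(np.zeros((2, 2)), np.ones((2, 2)),
                                    np.full((2, 2), 0.25)) == 0.0


def _track_from_norm(norm: np.ndarray, start: int = 0) -> SignalTrack:
    kernel = occupancy.gaussian_kernel(caller.SMOOTH_WINDOW, caller.SMOOTH_WINDOW / 6)
    smoothed = occupancy.smooth_track(norm, kernel)
    zeros = np.zeros_like(norm)
    return SignalTrack("c", start, norm, zeros, norm, smoothed, zeros, zeros)


class TestCandidateDyads:
    def test_monotonic_track_has_no_candidates(self):
        assert candidate_dyads(_track_from_norm(np.linspace(0, 10, 200))) == []

    def test_triangular_bump_yields_apex(self):
        norm = np.concatenate([np.linspace(0, 5, 50), np.linspace(5, 0, 50)[1:]])
        cands = candidate_dyads(_track_from_norm(norm))
        assert [p for p, _ in cands] == [49]

    def test_rippled_peak_matches_exhaustive_scan(self):
        x = np.arange(400)
        norm = np.exp(-0.5 * ((x - 200) / 60.0) ** 2) * (1 + 0.3 * np.cos(2 * np.pi * x / 10))
        track = _track_from_norm(norm)
        combined = track.smoothed + track.norm
        expected = [
            i
            for i in range(1, len(x) - 1)
            if combined[i] > combined[i - 1] and combined[i] > combined[i + 1]
            and norm[i] > 0
        ]
        assert [p for p, _ in candidate_dyads(track)] == expected
        assert len(expected) > 3  # the ripple produces several candidates

    def test_plateau_yields_center(self):
        norm = np.array([0.0, 1, 2, 3, 3, 3, 2, 1, 0])
        zeros = np.zeros_like(norm)
        track = SignalTrack("c", 0, norm, zeros, norm, zeros, zeros, zeros)
        assert [p for p, _ in candidate_dyads(track)] == [4]


class TestNonredundantMap:
    def test_hand_traced_greedy(self):
        assert nonredundant_map([(100, 5.0), (150, 4.0), (300, 3.0)]) == [100, 300]

    def test_single_candidate(self):
        assert nonredundant_map([(42, 1.0)]) == [42]

    def test_tie_breaks_leftmost(self):
        assert nonredundant_map([(200, 4.0), (150, 4.0)]) == [150]

    def test_120_is_inclusive_exclusion(self):
        assert nonredundant_map([(100, 5.0), (220, 4.0)]) == [100]
        assert nonredundant_map([(100, 5.0), (221, 4.0)]) == [100, 221]

    def test_pairwise_spacing_invariant(self):
        rng = np.random.default_rng(45)
        cands = [(int(p), float(s)) for p, s in
                 zip(rng.integers(0, 3000, 200), rng.uniform(0, 10, 200))]
        kept = nonredundant_map(cands)
        diffs = np.diff(kept)
        assert np.all(diffs > 120)


class TestFilterCalls:
    def _call(self, z, llr):
        return NucleosomeCall("c", 0, 1.0, z, llr)

    def test_strict_boundaries(self):
        assert filter_calls([self._call(3.0, 1.0)]) == []
        assert filter_calls([self._call(5.0, -1.0)]) == []
        assert filter_calls([self._call(5.0, 0.0)]) == []
        kept = filter_calls([self._call(3.001, 0.001)])
        assert len(kept) == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(46)
        calls = [self._call(z, l) for z, l in
                 zip(rng.normal(3, 2, 10), rng.normal(0, 2, 10))]
        expected = [c for c in calls if c.z > 3 and c.llr > 0]
        assert filter_calls(calls) == expected


class TestEndToEnd:
    def test_planted_dyads_recovered(self, called, truth):
        _, calls, _ = called
        test_pos = np.array(sorted(c.dyad for c in calls))
        sens, _ = evaluation.sensitivity_specificity(test_pos, truth.dyads, d=25)
        assert sens >= 0.9
        assert evaluation.distance_auc(test_pos, truth.dyads) >= 0.9

    def test_rotational_positions_recovered(self, called, truth):
        _, _, redundant = called
        redpos = np.array([c.dyad for c in redundant])
        frac = evaluation.rotational_specificity(redpos, truth.rotational_positions())
        assert frac >= 0.3

    def test_filtered_calls_satisfy_thresholds(self, called):
        _, calls, redundant = called
        assert all(c.z > 3 and c.llr > 0 for c in redundant)
        kept = sorted(c.dyad for c in calls)
        assert np.all(np.diff(kept) > 120)

    def test_pooled_replicates_normalized_signal_is_additive(
        self, truth, template, size_dist
    ):
        rep1 = simulate.simulate_fragments(truth, 5000, 0.7, seed=50)
        rep2 = simulate.simulate_fragments(truth, 5000, 0.7, seed=51)
        region = ("chrS", 1000, 1400)
        s1 = caller.compute_signal(rep1, region, template, size_dist, mnase=True)
        s2 = caller.compute_signal(rep2, region, template, size_dist, mnase=True)
        pooled = caller.compute_signal(rep1 + rep2, region, template, size_dist, mnase=True)
        assert np.allclose(pooled.norm, s1.norm + s2.norm, atol=1e-8)

    def test_null_normalized_signal_mean_near_zero(self, template, size_dist):
        # fragments drawn from the background itself: small-scale version of
        # the acceptance-suite null calibration
        rng = np.random.default_rng(52)
        from atacnuc import bias as bias_mod

        B = bias_mod.uniform_background(size_dist)
        b, v = B.ravel(), template.mat.ravel()
        loci, n_frag = 2000, 150
        idx = rng.choice(len(b), size=loci * n_frag, p=b)
        raw = v[idx].reshape(loci, n_frag).sum(axis=1)
        norm = raw - n_frag * (b * v).sum()
        se = norm.std(ddof=1) / np.sqrt(loci)
        assert abs(norm.mean()) < 3 * se


class TestCallNfrs:
    def test_full_occupancy_yields_none(self, frags):
        n = 600
        occ = occupancy.OccupancyTrack("chrS", 200, 5, *(np.ones(n),) * 3)
        calls = [NucleosomeCall("chrS", d, 1, 5, 1, nonredundant=True)
                 for d in (1000, 1348)]
        assert call_nfrs(occ, calls, frags, ("chrS", 200, 3200)) == []

    def test_planted_promoter_bounds(self, occ_track, called, frags, truth):
        _, calls, _ = called
        nfrs = call_nfrs(occ_track, calls, frags, REGION)
        interior = [r for r in nfrs if r.left_call is not None and r.right_call is not None]
        assert len(interior) >= 3
        matched = 0
        for s, e in truth.nfr_intervals:
            for r in interior:
                if abs(r.start - s) <= 15 and abs(r.end - e) <= 15:
                    matched += 1
                    break
        assert matched >= 3
        assert all(r.mean_occ < 0.2 for r in interior)

    def test_no_coverage_blocks_call(self, occ_track, called, truth):
        # same low-occupancy landscape but zero fragments: depletion cannot
        # be distinguished from missing data, so nothing is called
        _, calls, _ = called
        nfrs = call_nfrs(occ_track, calls, [], REGION)
        assert nfrs == []
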