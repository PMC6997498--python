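"""Sparseness statistics, similarity matrices, Fano factors, vocal decoding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from audlearn.synthetic import VocalSpec, generate_vocal_responses, naive_vocal_spec
from audlearn.vocal import (
    decode_vocal_pair,
    fano_factor,
    lifetime_sparseness,
    population_sparseness,
    similarity_matrix,
    syllable_significance,
)


def brute_force_sparseness(r):
    """Direct transcription of the sparseness formula, kept independent."""
    r = np.asarray(r, dtype=float)
    n = r.size
    num = 1.0 - (r.sum() / n) ** 2 / np.sum(r**2 / n)
    return 100.0 * num / (1.0 - 1.0 / n)


class TestLifetimeSparseness:
    def test_dense_limit_zero(self):
        assert lifetime_sparseness([3, 3, 3, 3]) == pytest.approx(0.0)

    def test_single_nonzero_is_hundred(self):
        assert lifetime_sparseness([2, 0, 0, 0]) == pytest.approx(100.0)

    def test_hand_computed_example(self):
        # [3,1,0,0]: numerator 1 - 1/2.5 = 0.6, denominator 0.75 -> 80%
        assert lifetime_sparseness([3, 1, 0, 0]) == pytest.approx(80.0)

    def test_all_binary_patterns_up_to_n6(self):
        # S = 100 iff exactly one syllable responds; 0 iff all respond equally
        for n in range(2, 7):
            for bits in itertools.product([0, 1], repeat=n):
                r = np.array(bits, dtype=float)
                if r.sum() == 0:
                    assert np.isnan(lifetime_sparseness(r))
                    continue
                s = lifetime_sparseness(r)
                assert s == pytest.approx(brute_force_sparseness(r))
                if r.sum() == 1:
                    assert s == pytest.approx(100.0)
                elif r.sum() == n:
                    assert s == pytest.approx(0.0)
                else:
                    assert 0.0 < s < 100.0

    @given(
        st.lists(st.floats(0.01, 100), min_size=2, max_size=12),
        st.floats(0.1, 50),
    )
    def test_scale_invariance(self, r, c):
        assert lifetime_sparseness(np.array(r) * c) == pytest.approx(
            lifetime_sparseness(np.array(r)), abs=1e-6
        )

    def test_all_zero_flagged(self):
        assert np.isnan(lifetime_sparseness([0.0, 0.0, 0.0]))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            lifetime_sparseness([1.0])
        with pytest.raises(ValueError):
            lifetime_sparseness([1.0, -0.5])


class TestPopulationSparseness:
    def test_all_responsive_is_zero(self):
        assert population_sparseness(np.ones((10, 3), dtype=bool))[0] == 0.0

    def test_three_of_ten(self):
        mask = np.zeros((10, 1), dtype=bool)
        mask[:3, 0] = True
        assert population_sparseness(mask)[0] == pytest.approx(70.0)

    def test_binomial_expectation_from_generator(self):
        spec = VocalSpec(
            n_neurons=200, responsive_fraction=0.45, evoked_rate=6.0,
            spont_rate=0.2, n_trials=16, seed=3,
        )
        srs = generate_vocal_responses(spec)
        pop = population_sparseness(syllable_significance(srs))
        assert abs(pop.mean() - 55.0) < 5.0

    def test_zero_neurons_rejected(self):
        with pytest.raises(ValueError):
            population_sparseness(np.zeros((0, 4), dtype=bool))


class TestSimilarityMatrix:
    def test_unit_diagonal_and_symmetry(self):
        srs = generate_vocal_responses(naive_vocal_spec(20, seed=1))
        sm = similarity_matrix(srs)
        assert np.allclose(np.diag(sm.matrix), 1.0)
        assert np.allclose(sm.matrix, sm.matrix.T, equal_nan=True)
        off = sm.matrix[~np.eye(len(sm.speeding_factors), dtype=bool)]
        assert np.all(off[np.isfinite(off)] <= 1.0)
        assert np.all(off[np.isfinite(off)] >= -1.0)

    def test_anticorrelated_patterns(self):
        resp = np.zeros((1, 2, 4, 50), dtype=np.int64)
        resp[0, 0] = np.array([4, 3, 1, 0])[:, None]
        resp[0, 1] = np.array([0, 1, 3, 4])[:, None]
        from audlearn.synthetic.vocal import SyllableResponseSet

        srs = SyllableResponseSet(
            speeding_factors=(1.0, 0.9),
            syllable_windows_ms=np.column_stack([np.arange(4) * 250.0, np.arange(4) * 250.0 + 100]),
            responses=resp, spont_counts=np.zeros_like(resp),
            mean_rates=resp.mean(axis=3),
        )
        sm = similarity_matrix(srs)
        assert sm.matrix[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_neurons_excluded(self):
        resp = np.zeros((2, 2, 4, 10), dtype=np.int64)
        resp[0, 0] = np.array([5, 1, 0, 2])[:, None]
        resp[0, 1] = np.array([5, 1, 0, 2])[:, None]
        # neuron 1 is silent: excluded from the pair mean
        from audlearn.synthetic.vocal import SyllableResponseSet

        srs = SyllableResponseSet(
            speeding_factors=(1.0, 0.9),
            syllable_windows_ms=np.column_stack([np.arange(4) * 250.0, np.arange(4) * 250.0 + 100]),
            responses=resp, spont_counts=np.zeros_like(resp),
            mean_rates=resp.mean(axis=3),
        )
        sm = similarity_matrix(srs)
        assert sm.n_excluded[0, 1] == 1
        assert sm.matrix[0, 1] == pytest.approx(1.0)

    def test_psth_mode_requires_spike_times(self):
        srs = generate_vocal_responses(naive_vocal_spec(5, seed=0))
        with pytest.raises(ValueError, match="spike times"):
            similarity_matrix(srs, mode="psth")

    def test_psth_mode_on_spiketime_fixture(self):
        spec = naive_vocal_spec(6, seed=2, with_spike_times=True)
        sm = similarity_matrix(generate_vocal_responses(spec), mode="psth")
        assert np.allclose(np.diag(sm.matrix), 1.0)


class TestFanoFactor:
    def test_constant_counts_zero(self):
        assert fano_factor(np.full(10, 4)) == 0.0

    def test_poisson_limit(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, 100_000)
        assert 0.98 < fano_factor(counts) < 1.02

    def test_matches_direct_definition(self):
        counts = np.array([0, 2] * 50)
        expected = counts.var(ddof=1) / counts.mean()
        assert fano_factor(counts) == pytest.approx(expected)

    def test_zero_mean_flagged(self):
        assert np.isnan(fano_factor(np.zeros(10)))


class TestVocalDecoding:
    def test_identical_variants_show_no_spurious_signal(self):
        # leave-one-out on a fixed null sample is pessimistically biased
        # (excluding a trial shifts its class mean away from it), so chance
        # data must land at or below 0.5 — never spuriously above it
        spec = VocalSpec(
            n_neurons=40, speeding_factors=(1.0, 0.9),
            similarity_targets={0.9: 1.0}, seed=5,
        )
        srs = generate_vocal_responses(spec)
        curve = decode_vocal_pair(
            srs, 1.0, 0.9, n_neurons=37, k_values=[1, 6, 12],
            n_iterations=50, seed=0,
        )
        assert curve.accuracy.max() < 0.5 + 3 * np.sqrt(0.25 / 100)
        assert curve.accuracy.min() > 0.2  # bias is bounded, not degenerate

    def test_information_accumulates_over_syllables(self):
        accs = []
        for seed in range(5):
            srs = generate_vocal_responses(naive_vocal_spec(40, seed=seed))
            curve = decode_vocal_pair(
                srs, 1.0, 0.9, n_neurons=37, k_values=[1, 12],
                n_iterations=40, seed=seed,
            )
            accs.append(curve.accuracy.to_numpy())
        accs = np.array(accs)
        assert accs[:, 1].mean() >= accs[:, 0].mean()

    def test_too_few_neurons_rejected(self):
        srs = generate_vocal_responses(naive_vocal_spec(10, seed=0))
        with pytest.raises(ValueError, match="neurons"):
            decode_vocal_pair(srs, 1.0, 0.9, n_neurons=37)
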