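"""Single-neuron characterization: windows, FRA, BF, selectivity, correlations."""

import numpy as np
import pytest

from audlearn.grids import StimulusGrid
from audlearn.synthetic import (
    BFComponent,
    EnsembleSpec,
    generate_tuning_ensemble,
    naive_tone_spec,
)
from audlearn.tuning import (
    FRA,
    PSTH,
    build_fra,
    compute_psth,
    ensemble_summaries,
    find_response_window,
    pairwise_signal_correlations,
    responsiveness_test,
    signal_correlation,
    summarize_neuron,
)


def make_psth(counts, bin_ms=1.0, t_start=0.0):
    counts = np.asarray(counts, dtype=float)
    edges = t_start + np.arange(counts.size + 1) * bin_ms
    return PSTH(bin_edges_ms=edges, counts=counts, n_trials=10)


class TestResponseWindow:
    def test_boxcar_burst_found(self):
        counts = np.zeros(300)
        counts[20:120] = 1.0
        win = find_response_window(make_psth(counts))
        assert win.onset_ms == 20.0 and win.duration_ms == 100.0

    def test_uniform_psth_ties_to_earliest(self):
        win = find_response_window(make_psth(np.ones(300)))
        assert win.onset_ms == 0.0 and win.tied

    def test_all_zero_flagged(self):
        win = find_response_window(make_psth(np.zeros(200)))
        assert win.onset_ms == 0.0 and win.all_zero

    def test_second_larger_burst_wins(self):
        counts = np.zeros(400)
        counts[10:60] = 1.0
        counts[250:350] = 2.0
        win = find_response_window(make_psth(counts))
        assert 150 < win.onset_ms <= 250

    def test_matches_brute_force_on_random_psths(self, rng):
        for _ in range(100):
            counts = rng.poisson(1.0, size=rng.integers(120, 400)).astype(float)
            psth = make_psth(counts)
            win = find_response_window(psth)
            # independent exhaustive scan
            sums = [counts[i : i + 100].sum() for i in range(counts.size - 99)]
            assert counts[int(win.onset_ms) : int(win.onset_ms) + 100].sum() == max(sums)
            assert int(win.onset_ms) == int(np.argmax(sums))

    def test_short_psth_rejected(self):
        with pytest.raises(ValueError):
            find_response_window(make_psth(np.ones(50)))


class TestResponsiveness:
    def test_identical_samples_not_responsive(self):
        x = np.ones(12)
        p, responsive = responsiveness_test(x, x)
        assert p == 1.0 and not responsive

    def test_strong_response_detected(self, rng):
        evoked = rng.poisson(10.0, 12)
        spont = rng.poisson(0.05, 12)
        _, responsive = responsiveness_test(evoked, spont)
        assert responsive

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            responsiveness_test(np.array([1.0]), np.array([0.0, 0.0]))


class TestFRA:
    def test_null_fra_has_empty_mask(self, grid, rng):
        counts = rng.poisson(0.5, size=(18, 4, 12))
        spont = rng.poisson(0.5, size=(18, 4, 12))
        fra = build_fra(counts, spont, grid)
        assert fra.significant.sum() <= 1  # Bonferroni keeps false positives rare

    def test_single_hot_combination(self, grid):
        rng = np.random.default_rng(5)
        counts = rng.poisson(0.2, size=(18, 4, 12))
        spont = rng.poisson(0.2, size=(18, 4, 12))
        counts[7, 2] = rng.poisson(4.0, 12)
        fra = build_fra(counts, spont, grid)
        assert fra.significant[7, 2]
        assert fra.significant.sum() == 1

    def test_bonferroni_factor_is_grid_size(self, grid):
        # 18 x 4 grid: the per-combination level is alpha / 72
        assert grid.n_frequencies * grid.n_levels == 72

    def test_missing_combinations_rejected(self, grid):
        with pytest.raises(ValueError, match="combinations"):
            build_fra(np.zeros((17, 4, 10)), np.zeros((17, 4, 10)), grid)


class TestNeuronSummary:
    def _fra(self, grid, rates, sig=None):
        rates = np.asarray(rates, dtype=float)
        sig = np.zeros_like(rates, dtype=bool) if sig is None else sig
        return FRA(rates=rates, significant=sig, p_values=np.ones_like(rates),
                   response_window_ms=100.0, grid=grid)

    def test_single_peak_bf(self, grid):
        rates = np.full((18, 4), 0.1)
        bf_idx = grid.nearest_index(10.0)
        rates[bf_idx, :] = 5.0
        summ = summarize_neuron(self._fra(grid, rates), np.zeros((18, 4, 5)))
        assert summ.bf_khz == pytest.approx(grid.frequencies_khz[bf_idx])

    def test_bf_tie_goes_to_lower_frequency(self, grid):
        rates = np.zeros((18, 4))
        rates[4], rates[9] = 3.0, 3.0
        summ = summarize_neuron(self._fra(grid, rates), np.zeros((18, 4, 5)))
        assert summ.bf_khz == pytest.approx(grid.frequencies_khz[4])

    def test_selectivity_percentage(self, grid):
        sig = np.zeros((18, 4), dtype=bool)
        sig.ravel()[:18] = True  # 18 of 72 combos
        summ = summarize_neuron(
            self._fra(grid, np.ones((18, 4)), sig), np.zeros((18, 4, 5))
        )
        assert summ.selectivity_pct == pytest.approx(25.0)

    def test_bf_invariant_to_rate_scaling(self, grid, rng):
        rates = rng.random((18, 4))
        a = summarize_neuron(self._fra(grid, rates), np.zeros((18, 4, 5)))
        b = summarize_neuron(self._fra(grid, 7.3 * rates), np.zeros((18, 4, 5)))
        assert a.bf_khz == b.bf_khz

    def test_bf_recovery_at_high_snr(self, grid):
        # all true BFs inside the band, peak >= 10x spont, >= 50 trials:
        # estimated BFs must all land inside the band
        spec = EnsembleSpec(
            n_neurons=25, seed=6, n_trials=50,
            peak_rate_hz=60.0, spontaneous_rate_hz=3.0, rate_heterogeneity=0.0,
            bf_distribution=[
                BFComponent(center_octave=float(np.log2(8.5)), spread_octave=0.05)
            ],
            tuning_shape=dict(sigma_octave_range=(0.3, 0.5), bimodal_prob=0.0),
        )
        ens = generate_tuning_ensemble(spec, grid)
        summaries = ensemble_summaries(ens)
        assert ((summaries.bf_khz >= 7.1) & (summaries.bf_khz <= 10.0)).all()


class TestSignalCorrelation:
    def _fra(self, grid, rates):
        return FRA(rates=rates, significant=np.zeros_like(rates, dtype=bool),
                   p_values=np.ones_like(rates), response_window_ms=100.0, grid=grid)

    def test_identity_and_reflection(self, grid, rng):
        rates = rng.random((18, 4)) + 0.1
        a = self._fra(grid, rates)
        assert signal_correlation(a, a) == pytest.approx(1.0)
        assert signal_correlation(a, self._fra(grid, 5.0 - rates)) == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self, grid, rng):
        flat = self._fra(grid, np.ones((18, 4)))
        other = self._fra(grid, rng.random((18, 4)))
        assert np.isnan(signal_correlation(flat, other))

    def test_null_distribution_of_independent_fras(self, grid):
        rng = np.random.default_rng(17)
        hits = 0
        n_pairs = 1000
        for _ in range(n_pairs):
            a = self._fra(grid, rng.random((18, 4)))
            b = self._fra(grid, rng.random((18, 4)))
            if abs(signal_correlation(a, b)) < 0.4:
                hits += 1
        assert hits / n_pairs >= 0.95  # 72 entries: |r| rarely exceeds 0.4 by chance

    def test_expert_concentration_raises_signal_correlation(self, grid):
        # when expert BFs crowd the band, same-site tuning overlaps more
        naive = generate_tuning_ensemble(
            naive_tone_spec(40, seed=21, pv_fraction=0.0), grid
        )
        expert_spec = EnsembleSpec(
            n_neurons=40, group_label="expert", seed=22, pv_fraction=0.0,
            bf_distribution=[
                BFComponent(center_octave=float(np.log2(8.5)), spread_octave=0.25)
            ],
        )
        expert = generate_tuning_ensemble(expert_spec, grid)
        r_naive = pairwise_signal_correlations(naive).r
        r_expert = pairwise_signal_correlations(expert).r
        assert np.nanmean(r_expert) > np.nanmean(r_naive)


def test_compute_psth_and_latency():
    spikes = [np.array([52.0, 53.0, 150.0]), np.array([51.0, 54.0])]
    psth = compute_psth(spikes, t_start_ms=0.0, t_stop_ms=200.0)
    assert psth.counts.sum() == pytest.approx(5 / 2)
    from audlearn.tuning import peak_latency

    lat = peak_latency(psth)
    assert 45 <= lat <= 60  # smoothed peak near the spike cluster
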