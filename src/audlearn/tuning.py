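"""Single-neuron response characterization.

PSTH construction, response-window selection (the 100 ms after stimulus onset
with the maximal response integral), evoked-response significance, the
frequency-response area (FRA) with Bonferroni-corrected per-combination
significance, best frequency, selectivity, training-band rate, latency,
spontaneous rate, and pairwise signal correlations between FRAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import RESPONSE_WINDOW_MS, StimulusGrid, TRAINING_BAND_KHZ
from .synthetic.tuning import TuningEnsemble


@dataclass(frozen=True)
class PSTH:
    """Mean spike count per time bin (averaged over trials)."""

    bin_edges_ms: np.ndarray
    counts: np.ndarray  # mean count per bin
    n_trials: int

    def __post_init__(self) -> None:
        if self.counts.size != self.bin_edges_ms.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise ValueError("PSTH counts must be non-negative")
        if np.any(np.diff(self.bin_edges_ms) <= 0):
            raise ValueError("bin edges must be increasing")

    @property
    def bin_ms(self) -> float:
        return float(np.mean(np.diff(self.bin_edges_ms)))

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def compute_psth(
    spike_times_ms: list[np.ndarray],
    t_start_ms: float = -100.0,
    t_stop_ms: float = 300.0,
    bin_ms: float = 1.0,
) -> PSTH:
    """PSTH from per-trial spike-time arrays (times in ms, stimulus at 0)."""
    if not spike_times_ms:
        raise ValueError("need at least one trial")
    edges = np.arange(t_start_ms, t_stop_ms + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for trial in spike_times_ms:
        counts += np.histogram(np.asarray(trial, dtype=float), bins=edges)[0]
    return PSTH(edges, counts / len(spike_times_ms), len(spike_times_ms))


@dataclass(frozen=True)
class ResponseWindow:
    onset_ms: float
    duration_ms: float
    tied: bool
    all_zero: bool


def find_response_window(
    psth: PSTH, stimulus_onset_ms: float = 0.0, window_ms: float = RESPONSE_WINDOW_MS
) -> ResponseWindow:
    """The post-onset window of ``window_ms`` maximizing the summed PSTH.

    Candidate windows start at each bin edge at or after stimulus onset and
    must fit inside the PSTH; ties go to the earliest window.  An all-zero
    PSTH yields the earliest window, flagged.
    """
    edges = psth.bin_edges_ms
    starts = [
        i for i, e in enumerate(edges[:-1])
        if e >= stimulus_onset_ms and e + window_ms <= edges[-1] + 1e-9
    ]
    if not starts:
        raise ValueError("PSTH must cover at least one full window after onset")
    cum = np.concatenate([[0.0], np.cumsum(psth.counts)])
    n_bins = int(round(window_ms / psth.bin_ms))
    sums = np.array([cum[i + n_bins] - cum[i] for i in starts])
    best = int(np.argmax(sums))  # argmax returns the first (earliest) maximum
    tied = bool(np.sum(np.isclose(sums, sums[best])) > 1)
    return ResponseWindow(
        onset_ms=float(edges[starts[best]]),
        duration_ms=float(window_ms),
        tied=tied,
        all_zero=bool(np.all(psth.counts == 0)),
    )


def responsiveness_test(
    evoked_counts: np.ndarray, spontaneous_counts: np.ndarray, alpha: float = 0.05
) -> tuple[float, bool]:
    """Two-sample t-test of evoked vs. matched pre-stimulus window counts."""
    a = np.asarray(evoked_counts, dtype=float).ravel()
    b = np.asarray(spontaneous_counts, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per sample")
    if a.var() == 0 and b.var() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    return p, bool(p < alpha)


@dataclass(frozen=True)
class FRA:
    """Frequency-response area: trial-averaged window counts and significance."""

    rates: np.ndarray  # (F, L) mean evoked-window counts
    significant: np.ndarray  # (F, L) boolean, Bonferroni-corrected
    p_values: np.ndarray  # (F, L)
    response_window_ms: float
    grid: StimulusGrid

    def __post_init__(self) -> None:
        if self.significant.shape != self.rates.shape:
            raise ValueError("mask shape must equal rate-matrix shape")


def build_fra(
    counts: np.ndarray,
    spont_counts: np.ndarray,
    grid: StimulusGrid,
    alpha: float = 0.05,
    response_window_ms: float = RESPONSE_WINDOW_MS,
) -> FRA:
    """FRA for one neuron from (F, L, T) evoked and matched spontaneous counts.

    Each (frequency, level) combination is tested against its pre-stimulus
    counts with a two-sample t-test at the Bonferroni-corrected level
    alpha / (F * L).
    """
    c = np.asarray(counts)
    s = np.asarray(spont_counts)
    expected = (grid.n_frequencies, grid.n_levels)
    if c.ndim != 3 or c.shape[:2] != expected:
        missing = f"expected (F, L, T) with (F, L) = {expected}, got {c.shape}"
        raise ValueError(f"missing or misshapen stimulus combinations: {missing}")
    if s.shape != c.shape:
        raise ValueError("spontaneous counts must match evoked counts in shape")
    n_comb = grid.n_frequencies * grid.n_levels
    p = np.ones(expected)
    for i in range(expected[0]):
        for j in range(expected[1]):
            p[i, j], _ = responsiveness_test(c[i, j], s[i, j], alpha=1.0)
    return FRA(
        rates=c.mean(axis=2),
        significant=p < alpha / n_comb,
        p_values=p,
        response_window_ms=response_window_ms,
        grid=grid,
    )


@dataclass(frozen=True)
class NeuronSummary:
    bf_khz: float
    selectivity_pct: float
    evoked_rate_bf_hz: float
    rate_training_band_hz: float
    spontaneous_hz: float
    latency_ms: float | None
    is_responsive: bool

    def __post_init__(self) -> None:
        if not (0 <= self.selectivity_pct <= 100):
            raise ValueError("selectivity must be in [0, 100]")


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def peak_latency(psth: PSTH, smooth_ms: float = 5.0, after_ms: float = 0.0) -> float:
    """Time after onset at which the (lightly smoothed) PSTH peaks."""
    width = max(1, int(round(smooth_ms / psth.bin_ms)))
    sm = _smooth(psth.counts, width)
    centers = psth.bin_centers_ms
    mask = centers >= after_ms
    idx = int(np.argmax(sm[mask]))
    return float(centers[mask][idx])


def summarize_neuron(
    fra: FRA,
    spont_counts: np.ndarray,
    psth: PSTH | None = None,
    training_band_khz: tuple[float, float] = TRAINING_BAND_KHZ,
    window_s: float = RESPONSE_WINDOW_MS / 1000.0,
) -> NeuronSummary:
    """Tuning summary of one neuron.

    BF is the frequency whose level-averaged response is maximal (ties to the
    lower frequency); selectivity is the percentage of significant
    frequency-level combinations; the training-band rate averages in-band
    frequencies across all levels.  Rates are converted to Hz with the
    100-ms response window.
    """
    level_avg = fra.rates.mean(axis=1)
    bf_idx = int(np.argmax(level_avg))  # first maximum = lowest frequency on ties
    bf_khz = float(fra.grid.frequencies_khz[bf_idx])
    selectivity = 100.0 * fra.significant.mean()
    band = fra.grid.band_mask(training_band_khz)
    band_rate = float(fra.rates[band].mean()) / window_s if band.any() else float("nan")
    spont = float(np.asarray(spont_counts, dtype=float).mean()) / window_s
    _, responsive = _overall_responsiveness(fra)
    return NeuronSummary(
        bf_khz=bf_khz,
        selectivity_pct=float(selectivity),
        evoked_rate_bf_hz=float(fra.rates[bf_idx].mean()) / window_s,
        rate_training_band_hz=band_rate,
        spontaneous_hz=spont,
        latency_ms=peak_latency(psth) if psth is not None else None,
        is_responsive=responsive,
    )


def _overall_responsiveness(fra: FRA) -> tuple[float, bool]:
    """A neuron is responsive if any combination survives Bonferroni."""
    return float(fra.p_values.min()), bool(fra.significant.any())


def signal_correlation(fra_a: FRA, fra_b: FRA) -> float:
    """Pearson r over all (frequency, level) entries of two FRA matrices.

    Returns NaN when either FRA has zero variance (undefined correlation).
    """
    if fra_a.rates.shape != fra_b.rates.shape:
        raise ValueError("FRAs must share the same grid")
    a, b = fra_a.rates.ravel(), fra_b.rates.ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def ensemble_summaries(
    ensemble: TuningEnsemble,
    training_band_khz: tuple[float, float] = TRAINING_BAND_KHZ,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron FRA summaries for a whole ensemble."""
    rows = []
    for i in range(ensemble.n_neurons):
        fra = build_fra(
            ensemble.counts[i], ensemble.spont_counts[i], ensemble.grid, alpha=alpha
        )
        summ = summarize_neuron(
            fra, ensemble.spont_counts[i], training_band_khz=training_band_khz
        )
        rows.append(
            dict(
                neuron_id=ensemble.neurons.neuron_id.iloc[i],
                group=ensemble.neurons.group.iloc[i],
                cell_class=ensemble.neurons.cell_class.iloc[i],
                site=ensemble.neurons.site.iloc[i],
                bf_khz=summ.bf_khz,
                selectivity_pct=summ.selectivity_pct,
                evoked_rate_bf_hz=summ.evoked_rate_bf_hz,
                rate_training_band_hz=summ.rate_training_band_hz,
                spontaneous_hz=summ.spontaneous_hz,
                is_responsive=summ.is_responsive,
            )
        )
    return pd.DataFrame(rows)


def pairwise_signal_correlations(
    ensemble: TuningEnsemble, within_site: bool = True
) -> pd.DataFrame:
    """Signal correlations between neuron pairs (same-site pairs by default).

    The site label stands in for anatomical neighborhood: only cells recorded
    at the same penetration are paired when ``within_site`` is set.
    """
    fras = [
        build_fra(ensemble.counts[i], ensemble.spont_counts[i], ensemble.grid)
        for i in range(ensemble.n_neurons)
    ]
    sites = ensemble.neurons.site.to_numpy()
    ids = ensemble.neurons.neuron_id.to_numpy()
    rows = []
    for i in range(ensemble.n_neurons):
        for j in range(i + 1, ensemble.n_neurons):
            if within_site and sites[i] != sites[j]:
                continue
            rows.append(
                dict(
                    neuron_a=ids[i], neuron_b=ids[j], site_a=sites[i], site_b=sites[j],
                    r=signal_correlation(fras[i], fras[j]),
                )
            )
    return pd.DataFrame(rows)
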