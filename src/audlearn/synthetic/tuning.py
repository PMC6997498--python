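"""Grid-stimulus tuning ensembles with Poisson trial noise.

:func:`generate_tuning_ensemble` draws per-neuron tuning parameters from an
:class:`EnsembleSpec`, evaluates expected response-window counts on a
:class:`~audlearn.grids.StimulusGrid`, and samples independent Poisson counts
per (frequency, level, trial) plus matched pre-stimulus (spontaneous) counts.
Spike counts are generated directly — no continuous spike times — since every
grid-stimulus analysis operates on response-window counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ..grids import StimulusGrid, TRAINING_BAND_KHZ
from .populations import ParametricPopulation


class BFComponent(BaseModel):
    """One component of the best-frequency mixture, on the octave axis."""

    kind: Literal["normal", "uniform"] = "normal"
    center_octave: Optional[float] = None
    spread_octave: Optional[float] = None
    low_octave: Optional[float] = None  # uniform bounds; None = grid span
    high_octave: Optional[float] = None
    weight: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "BFComponent":
        if self.kind == "normal":
            if self.center_octave is None or self.spread_octave is None:
                raise ValueError("normal component needs center_octave and spread_octave")
            if self.spread_octave < 0:
                raise ValueError("spread_octave must be >= 0")
        return self


class TuningShape(BaseModel):
    """Ranges (uniform draws) for per-neuron tuning-shape parameters.

    Widths below and above BF are drawn independently, so curves are
    asymmetric by default; with probability ``bimodal_prob`` a second mode is
    added at a random octave offset.
    """

    sigma_octave_range: tuple[float, float] = (0.25, 0.6)
    bimodal_prob: float = Field(0.2, ge=0, le=1)
    second_offset_octave_range: tuple[float, float] = (0.8, 1.6)
    second_weight_range: tuple[float, float] = (0.3, 0.7)

    @model_validator(mode="after")
    def _check(self) -> "TuningShape":
        lo, hi = self.sigma_octave_range
        if not (0 < lo <= hi):
            raise ValueError("sigma_octave_range must be positive and ordered")
        return self


class EnsembleSpec(BaseModel):
    """Recipe for a synthetic tuning ensemble."""

    n_neurons: int = Field(100, ge=0)
    group_label: Literal["naive", "expert"] = "naive"
    bf_distribution: list[BFComponent] = Field(
        default_factory=lambda: [BFComponent(kind="uniform")]
    )
    tuning_shape: TuningShape = Field(default_factory=TuningShape)
    peak_rate_hz: float = Field(60.0, ge=0)
    spontaneous_rate_hz: float = Field(5.0, ge=0)
    rate_heterogeneity: float = Field(
        0.5, ge=0, description="CV of the per-neuron gamma-distributed peak rate"
    )
    training_band_khz: tuple[float, float] = TRAINING_BAND_KHZ
    n_trials: int = Field(20, ge=0)
    level_gains: tuple[float, ...] = (0.55, 0.75, 0.9, 1.0)
    pv_fraction: float = Field(0.15, ge=0, le=1)
    site_size: int = Field(5, ge=1, description="neurons per recording site label")
    window_s: float = Field(0.1, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EnsembleSpec":
        lo, hi = self.training_band_khz
        if not (0 < lo < hi):
            raise ValueError("training band must satisfy 0 < lo < hi")
        if any(g < 0 for g in self.level_gains):
            raise ValueError("level gains must be non-negative")
        return self


@dataclass
class TuningEnsemble:
    """Trial-resolved spike counts over a frequency x level grid.

    Attributes
    ----------
    grid : StimulusGrid
    neurons : DataFrame with neuron_id, group, cell_class (PV+/PV-), site,
        bf_true_khz.
    rate_curves : (N, F) expected counts per window, averaged over levels —
        the true r_i(f) each analysis tries to recover.
    counts : (N, F, L, T) integer evoked-window counts.
    spont_counts : (N, F, L, T) integer counts from the matched 100-ms
        pre-stimulus window.
    """

    grid: StimulusGrid
    neurons: pd.DataFrame
    rate_curves: np.ndarray
    counts: np.ndarray
    spont_counts: np.ndarray
    level_gains: np.ndarray
    population: ParametricPopulation | None = None
    group_label: str = "naive"

    def __post_init__(self) -> None:
        n, f = self.rate_curves.shape if self.rate_curves.size else (len(self.neurons), 0)
        if len(self.neurons) != self.counts.shape[0]:
            raise ValueError("neurons table and counts disagree on N")
        if self.counts.size and (
            not np.issubdtype(self.counts.dtype, np.integer) or self.counts.min() < 0
        ):
            raise ValueError("counts must be non-negative integers")
        if self.counts.shape != self.spont_counts.shape:
            raise ValueError("counts and spont_counts must have equal shapes")
        if self.counts.size and self.counts.shape[1] != self.grid.n_frequencies:
            raise ValueError("counts frequency axis does not match the grid")

    @property
    def n_neurons(self) -> int:
        return int(len(self.neurons))

    @property
    def n_trials(self) -> int:
        return int(self.counts.shape[3]) if self.counts.ndim == 4 else 0

    def mean_curves(self) -> np.ndarray:
        """Trial- and level-averaged measured counts, shape (N, F)."""
        return self.counts.mean(axis=(2, 3))


def _draw_bfs(
    spec: EnsembleSpec, grid: StimulusGrid, rng: np.random.Generator
) -> np.ndarray:
    comps = spec.bf_distribution
    weights = np.array([c.weight for c in comps], dtype=float)
    weights /= weights.sum()
    lo_span, hi_span = grid.log2_axis[0], grid.log2_axis[-1]
    which = rng.choice(len(comps), size=spec.n_neurons, p=weights)
    bfs = np.empty(spec.n_neurons)
    for i, ci in enumerate(which):
        c = comps[ci]
        if c.kind == "uniform":
            lo = lo_span if c.low_octave is None else c.low_octave
            hi = hi_span if c.high_octave is None else c.high_octave
            bfs[i] = rng.uniform(lo, hi)
        else:
            # resample into the grid span, clip as a last resort
            for _ in range(100):
                x = rng.normal(c.center_octave, c.spread_octave)
                if lo_span <= x <= hi_span:
                    break
            bfs[i] = np.clip(x, lo_span, hi_span)
    return bfs


def generate_tuning_ensemble(spec: EnsembleSpec, grid: StimulusGrid) -> TuningEnsemble:
    """Sample a tuning ensemble: parameters, expected curves, Poisson counts."""
    lo, hi = spec.training_band_khz
    if not (grid.frequencies_khz[0] <= lo and hi <= grid.frequencies_khz[-1]):
        raise ValueError("training band must lie within the grid span")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    shape = spec.tuning_shape

    bfs = _draw_bfs(spec, grid, rng)
    sig_lo, sig_hi = shape.sigma_octave_range
    sigma_below = rng.uniform(sig_lo, sig_hi, n)
    sigma_above = rng.uniform(sig_lo, sig_hi, n)
    peak_mean = spec.peak_rate_hz * spec.window_s
    if spec.rate_heterogeneity > 0 and peak_mean > 0:
        k = 1.0 / spec.rate_heterogeneity**2
        peaks = rng.gamma(k, peak_mean / k, n)
    else:
        peaks = np.full(n, peak_mean)
    sponts = np.full(n, spec.spontaneous_rate_hz * spec.window_s)

    bimodal = rng.random(n) < shape.bimodal_prob
    off = rng.uniform(*shape.second_offset_octave_range, n) * rng.choice([-1, 1], n)
    second_bf = np.where(bimodal, bfs + off, np.nan)
    second_w = np.where(bimodal, rng.uniform(*shape.second_weight_range, n), 0.0)

    pop = ParametricPopulation(
        bf_octave=bfs,
        sigma_below=sigma_below,
        sigma_above=sigma_above,
        peak=peaks,
        spont=sponts,
        second_bf_octave=second_bf,
        second_weight=second_w,
    )

    gains = np.asarray(spec.level_gains, dtype=float)
    evoked = pop.peak[:, None] * pop.evoked_shape(grid.log2_axis)  # (N, F)
    # expected counts per (neuron, freq, level)
    lam = pop.spont[:, None, None] + evoked[:, :, None] * gains[None, None, :]
    counts = rng.poisson(lam[..., None], size=lam.shape + (spec.n_trials,))
    spont_lam = np.broadcast_to(pop.spont[:, None, None, None], counts.shape)
    spont_counts = rng.poisson(spont_lam)
    rate_curves = pop.spont[:, None] + evoked * gains.mean()

    neurons = pd.DataFrame(
        {
            "neuron_id": [f"{spec.group_label}_{i:04d}" for i in range(n)],
            "group": spec.group_label,
            "cell_class": np.where(rng.random(n) < spec.pv_fraction, "PV+", "PV-"),
            "site": [f"site_{i // spec.site_size:03d}" for i in range(n)],
            "bf_true_khz": 2.0**bfs,
        }
    )
    return TuningEnsemble(
        grid=grid,
        neurons=neurons,
        rate_curves=rate_curves,
        counts=counts.astype(np.int64),
        spont_counts=spont_counts.astype(np.int64),
        level_gains=gains,
        population=pop,
        group_label=spec.group_label,
    )


def naive_tone_spec(n_neurons: int = 100, seed: int = 0, **kw) -> EnsembleSpec:
    """Naive-group default: best frequencies uniform over the grid span."""
    return EnsembleSpec(
        n_neurons=n_neurons, group_label="naive", seed=seed,
        bf_distribution=[BFComponent(kind="uniform")], **kw,
    )


def expert_tone_spec(n_neurons: int = 100, seed: int = 1, **kw) -> EnsembleSpec:
    """Expert-group default: half the BF mass pulled toward the training band.

    The concentration is a calibration choice (the BF histograms of trained
    animals shift toward the 7.1–10 kHz band, but no quantitative parameters
    are reported), implemented as a mixture of a uniform floor and a normal
    component centered mid-band.
    """
    center = float(np.log2(np.sqrt(7.1 * 10.0)))  # geometric band center
    return EnsembleSpec(
        n_neurons=n_neurons, group_label="expert", seed=seed,
        bf_distribution=[
            BFComponent(kind="uniform", weight=1.0),
            BFComponent(kind="normal", center_octave=center, spread_octave=0.3, weight=1.0),
        ],
        **kw,
    )
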