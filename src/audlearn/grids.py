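"""Stimulus geometry: the tone grid and octave arithmetic.

The discrimination experiments probe a logarithmic tone grid (by default 18
pure tones spanning 3–40 kHz at four sound levels).  All frequency arithmetic
in the package is done on the log2 ("octave") axis, x = log2(f / 1 kHz), which
is the natural perceptual metric for frequency discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Interval spanned by the target (10 kHz) and hardest non-target (7.1 kHz)
#: training tones, in kHz.
TRAINING_BAND_KHZ: tuple[float, float] = (7.1, 10.0)

#: Default response window used throughout the tuning analyses, in ms.
RESPONSE_WINDOW_MS: float = 100.0


def octaves_between(f1_khz: float, f2_khz: float) -> float:
    """Unsigned separation between two frequencies in octaves."""
    if f1_khz <= 0 or f2_khz <= 0:
        raise ValueError("frequencies must be positive")
    return abs(float(np.log2(f2_khz / f1_khz)))


def percent_octave(f1_khz: float, f2_khz: float) -> float:
    """Separation between two tones expressed as %/octave (e.g. 7.1 -> 10 kHz is 49)."""
    return 100.0 * octaves_between(f1_khz, f2_khz)


def tone_train_duration_s(
    n_tones: int = 6, tone_ms: float = 100.0, gap_ms: float = 300.0
) -> float:
    """Total duration of a tone series: n tones separated by silent gaps.

    The default six 100-ms tones with 300-ms inter-tone intervals give the
    2.1-s trial stimulus used in the go/no-go task.
    """
    if n_tones < 1:
        raise ValueError("n_tones must be >= 1")
    return (n_tones * tone_ms + (n_tones - 1) * gap_ms) / 1000.0


@dataclass(frozen=True)
class StimulusGrid:
    """Frequency x level stimulus grid.

    Parameters
    ----------
    frequencies_khz : array-like
        Tone frequencies in kHz, strictly increasing.
    levels_db : array-like
        Sound pressure levels in dB SPL.
    """

    frequencies_khz: np.ndarray
    levels_db: np.ndarray = field(
        default_factory=lambda: np.array([42.0, 52.0, 62.0, 72.0])
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frequencies_khz", np.asarray(self.frequencies_khz, dtype=float)
        )
        object.__setattr__(self, "levels_db", np.asarray(self.levels_db, dtype=float))
        f = self.frequencies_khz
        if f.ndim != 1 or f.size < 1:
            raise ValueError("frequencies_khz must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.levels_db.ndim != 1 or self.levels_db.size < 1:
            raise ValueError("levels_db must be a non-empty 1-D array")

    @classmethod
    def default(
        cls,
        n_frequencies: int = 18,
        f_min_khz: float = 3.0,
        f_max_khz: float = 40.0,
        levels_db: tuple[float, ...] = (42.0, 52.0, 62.0, 72.0),
    ) -> "StimulusGrid":
        """The standard grid: log-spaced tones between 3 and 40 kHz, 4 levels."""
        freqs = np.geomspace(f_min_khz, f_max_khz, n_frequencies)
        return cls(frequencies_khz=freqs, levels_db=np.asarray(levels_db, dtype=float))

    @property
    def log2_axis(self) -> np.ndarray:
        """Per-frequency octave coordinate x = log2(f / 1 kHz)."""
        return np.log2(self.frequencies_khz)

    @property
    def n_frequencies(self) -> int:
        return int(self.frequencies_khz.size)

    @property
    def n_levels(self) -> int:
        return int(self.levels_db.size)

    @property
    def step_octaves(self) -> float:
        """Grid step in octaves (the mean log2 spacing; exact for log-spaced grids)."""
        if self.n_frequencies < 2:
            raise ValueError("need at least two frequencies for a step size")
        return float(np.mean(np.diff(self.log2_axis)))

    @property
    def span_octaves(self) -> float:
        return float(self.log2_axis[-1] - self.log2_axis[0])

    def band_mask(self, band_khz: tuple[float, float] = TRAINING_BAND_KHZ) -> np.ndarray:
        """Boolean mask of grid frequencies inside [lo, hi] kHz (inclusive)."""
        lo, hi = band_khz
        if not (lo < hi):
            raise ValueError("band must satisfy lo < hi")
        return (self.frequencies_khz >= lo) & (self.frequencies_khz <= hi)

    def nearest_index(self, f_khz: float) -> int:
        """Index of the grid frequency nearest to f_khz on the octave axis."""
        return int(np.argmin(np.abs(self.log2_axis - np.log2(f_khz))))
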