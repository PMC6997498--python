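"""Dynamic time-warp of a syllable waveform.

A variant call is produced by re-mapping time inside each syllable with a
local speed multiplier that ramps linearly from ``s`` at syllable onset to
``2 - s`` at the offset, then interpolating the original waveform at the
warped positions.  Because the ramp integrates to 1, total syllable duration
is preserved; e.g. at s = 0.6 the onset plays 0.4 slower and the offset 0.4
faster than the original.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def warp_positions(n_samples: int, s: float) -> np.ndarray:
    """Source sample positions for each output sample under the linear ramp.

    With normalized output time u in [0, 1], the instantaneous speed is
    v(u) = s + 2(1-s)u, so the source position is the integral
    tau(u) = s*u + (1-s)*u**2 (normalized), which maps 0 -> 0 and 1 -> 1.
    """
    if not (0 < s <= 1):
        raise ValueError("speeding factor must satisfy 0 < s <= 1")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    u = np.linspace(0.0, 1.0, n_samples)
    return (n_samples - 1) * (s * u + (1.0 - s) * u**2)


def warp_syllable(waveform: np.ndarray, s: float) -> np.ndarray:
    """Warp a sampled syllable by speeding factor ``s`` (cubic interpolation)."""
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ValueError("waveform must be 1-D")
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform must be finite")
    pos = warp_positions(w.size, s)
    if s == 1.0:
        return w.copy()
    return CubicSpline(np.arange(w.size), w)(pos)
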