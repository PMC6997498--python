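"""Signal-detection behavioral metrics for go/no-go trial logs.

Sensitivity is quantified with d' = z(hit) - z(FA), the criterion-free
discriminability index of signal detection theory, where z is the inverse
cumulative standard normal.  Extreme rates are clipped to [1/(2N), 1 - 1/(2N)]
(N = trials of that class) so d' stays finite — the standard correction; the
choice does not affect interior rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic.behavior import BehaviorLog


def clipped_rate(k: int, n: int) -> float:
    """Proportion k/n clipped to [1/(2n), 1 - 1/(2n)]."""
    if n < 1:
        raise ValueError("need at least one trial")
    return float(np.clip(k / n, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))


@dataclass(frozen=True)
class DPrimeResult:
    hit_rate: float
    fa_rate: float
    dprime: float
    n_target: int
    n_nontarget: int
    clipped: bool


def dprime(hits: int, misses: int, fas: int, crs: int) -> DPrimeResult:
    """d' from raw outcome counts, with 1/(2N) extreme-rate clipping."""
    for name, v in dict(hits=hits, misses=misses, fas=fas, crs=crs).items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n_t, n_n = hits + misses, fas + crs
    if n_t < 1 or n_n < 1:
        raise ValueError("need at least one target and one non-target trial")
    hr, fr = clipped_rate(hits, n_t), clipped_rate(fas, n_n)
    clipped = (hr != hits / n_t) or (fr != fas / n_n)
    d = float(stats.norm.ppf(hr) - stats.norm.ppf(fr))
    return DPrimeResult(hr, fr, d, n_t, n_n, clipped)


def dprime_from_log(trials: pd.DataFrame) -> DPrimeResult:
    """d' over the non-catch trials of a log slice."""
    oc = trials.outcome.value_counts()
    return dprime(
        int(oc.get("hit", 0)), int(oc.get("miss", 0)),
        int(oc.get("fa", 0)), int(oc.get("cr", 0)),
    )


def learning_curve(log: BehaviorLog, bin_trials: int = 20) -> pd.DataFrame:
    """Blockwise hit rate, FA rate and d' over consecutive trial bins.

    Bins are non-overlapping, in trial order, over non-catch trials; a final
    partial bin is kept if it contains both trial classes.
    """
    if bin_trials < 1:
        raise ValueError("bin_trials must be >= 1")
    df = log.trials[log.trials.stimulus_kind != "catch"].reset_index(drop=True)
    if df.empty:
        raise ValueError("empty behavior log")
    rows = []
    for b, start in enumerate(range(0, len(df), bin_trials)):
        chunk = df.iloc[start : start + bin_trials]
        oc = chunk.outcome.value_counts()
        n_t = int(oc.get("hit", 0) + oc.get("miss", 0))
        n_n = int(oc.get("fa", 0) + oc.get("cr", 0))
        if n_t == 0 or n_n == 0:
            continue
        r = dprime_from_log(chunk)
        rows.append(
            dict(bin=b, n_trials=len(chunk), hit_rate=r.hit_rate,
                 fa_rate=r.fa_rate, dprime=r.dprime)
        )
    return pd.DataFrame(rows)


def stage_dprime(log: BehaviorLog, final_fraction: float = 1 / 3) -> pd.DataFrame:
    """Per-stage d' from the last ``final_fraction`` of each stage's trials."""
    if not (0 < final_fraction <= 1):
        raise ValueError("final_fraction must be in (0, 1]")
    rows = []
    for sid in log.stages:
        df = log.stage(sid)
        df = df[df.stimulus_kind != "catch"]
        tail = df.iloc[int(np.ceil(len(df) * (1 - final_fraction))):]
        r = dprime_from_log(tail)
        rows.append(
            dict(stage_id=sid, n_trials=len(tail), hit_rate=r.hit_rate,
                 fa_rate=r.fa_rate, dprime=r.dprime)
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PsychometricFit:
    catch_frequencies_khz: np.ndarray
    lick_proportions: np.ndarray
    floor: float
    ceiling: float
    slope: float  # per octave, on the log2 frequency axis
    inflection_octave: float
    decision_boundary_khz: float
    degenerate: bool
    message: str = ""

    def predict(self, f_khz: np.ndarray) -> np.ndarray:
        x = np.log2(np.asarray(f_khz, dtype=float))
        return _logistic4(x, self.floor, self.ceiling, self.slope, self.inflection_octave)


def _logistic4(x, lo, hi, k, x0):
    return lo + (hi - lo) / (1.0 + np.exp(-k * (x - x0)))


def fit_psychometric(freq_khz: np.ndarray, licked: np.ndarray) -> PsychometricFit:
    """4-parameter logistic fit of lick probability vs. log2 frequency.

    The decision boundary is the fitted inflection point, reported in kHz.
    Flat or non-converging data are returned flagged (``degenerate=True``)
    rather than raising.
    """
    f = np.asarray(freq_khz, dtype=float)
    y = np.asarray(licked, dtype=float)
    if f.shape != y.shape:
        raise ValueError("freq_khz and licked must have equal length")
    uniq = np.unique(f)
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct catch frequencies")
    props = np.array([y[f == u].mean() for u in uniq])
    x = np.log2(uniq)

    direction = 1.0 if props[-1] >= props[0] else -1.0
    p0 = [props.min(), props.max(), direction * 5.0, float(np.median(x))]
    bounds = ([0.0, 0.0, -100.0, x.min() - 1], [1.0, 1.0, 100.0, x.max() + 1])
    try:
        popt, _ = optimize.curve_fit(
            _logistic4, x, props, p0=p0, bounds=bounds, maxfev=20000
        )
        lo, hi, k, x0 = (float(v) for v in popt)
        degenerate = abs(k) < 0.1 or abs(hi - lo) < 0.05
        msg = "flat or near-flat psychometric curve" if degenerate else ""
    except RuntimeError as e:  # pragma: no cover - depends on optimizer path
        lo, hi, k, x0 = props.min(), props.max(), 0.0, float(np.median(x))
        degenerate, msg = True, f"fit did not converge: {e}"
    return PsychometricFit(
        catch_frequencies_khz=uniq, lick_proportions=props,
        floor=lo, ceiling=hi, slope=k, inflection_octave=x0,
        decision_boundary_khz=float(2.0**x0), degenerate=degenerate, message=msg,
    )


@dataclass(frozen=True)
class DetectionTime:
    time_ms: float | None
    p_values: np.ndarray
    bin_centers_ms: np.ndarray
    detected: bool


def _bin_licks(rasters: list[np.ndarray], edges: np.ndarray) -> np.ndarray:
    return np.stack([np.histogram(np.asarray(r, float), bins=edges)[0] for r in rasters])


def detection_time(
    hit_lick_rasters: list[np.ndarray],
    cr_lick_rasters: list[np.ndarray],
    duration_ms: float,
    bin_ms: float = 50.0,
    alpha: float = 0.001,
) -> DetectionTime:
    """Earliest bin at which hit vs. correct-rejection lick counts diverge.

    Per 50-ms bin (default), a two-sample t-test compares per-trial lick
    counts between the two classes; the detection time is the first bin
    center with p < alpha.  The first crossing is used, without correction
    across bins.  Returns a flagged (``detected=False``) result when no bin
    crosses alpha.
    """
    if len(hit_lick_rasters) < 10 or len(cr_lick_rasters) < 10:
        raise ValueError("need at least 10 trials per class")
    for r in list(hit_lick_rasters) + list(cr_lick_rasters):
        arr = np.asarray(r, dtype=float)
        if arr.size and arr.max() > duration_ms:
            raise ValueError("lick time beyond the stated raster duration")
    edges = np.arange(0.0, duration_ms + bin_ms, bin_ms)
    hits = _bin_licks(hit_lick_rasters, edges)
    crs = _bin_licks(cr_lick_rasters, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pvals = np.ones(centers.size)
    for j in range(centers.size):
        a, b = hits[:, j], crs[:, j]
        if a.var() == 0 and b.var() == 0:
            pvals[j] = 1.0 if a.mean() == b.mean() else 0.0
        else:
            pvals[j] = stats.ttest_ind(a, b, equal_var=False).pvalue
    crossing = np.flatnonzero(pvals < alpha)
    if crossing.size == 0:
        return DetectionTime(None, pvals, centers, False)
    return DetectionTime(float(centers[crossing[0]]), pvals, centers, True)
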