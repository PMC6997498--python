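"""Population discriminability: Poisson Fisher information and linear decoding.

For a Poisson neuron with tuning curve r_i(f) (f on the octave axis), the
Fisher information about the stimulus is

    I_i(f) = r_i'(f)^2 / r_i(f),

and the total information of an independent population is the sum over
neurons.  For fine discrimination between frequencies Δf apart, a large,
noise-independent population supports a maximum-likelihood discriminability
of d' = Δf * sqrt(total FI); the linear soft-margin SVM decoder implemented
here approaches that bound when single trials carry enough information for
its 16-trial training sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC


@dataclass(frozen=True)
class FisherInformationProfile:
    """Per-frequency Fisher information, in octave^-2 (counts per window)."""

    x_octaves: np.ndarray
    per_neuron: np.ndarray  # (N, F)
    total: np.ndarray  # (F,) = per_neuron.sum(axis=0)

    def __post_init__(self) -> None:
        if self.per_neuron.shape[1] != self.x_octaves.size:
            raise ValueError("per-neuron FI must have one column per frequency")
        if np.any(self.per_neuron < 0):
            raise ValueError("Fisher information must be non-negative")


def fisher_information(
    rate_curves: np.ndarray, x_octaves: np.ndarray, floor_eps: float = 1e-6
) -> FisherInformationProfile:
    """FI profile of an ensemble of tuning curves sampled on the octave axis.

    Derivatives are central differences (one-sided at the ends); rates are
    floored at ``floor_eps`` before division so silent frequencies do not
    blow up the quotient.
    """
    r = np.atleast_2d(np.asarray(rate_curves, dtype=float))
    x = np.asarray(x_octaves, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("rate curves must be finite")
    if r.shape[1] != x.size:
        raise ValueError("rate curves and frequency axis disagree")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    deriv = np.gradient(r, x, axis=1)
    per_neuron = deriv**2 / np.maximum(r, floor_eps)
    return FisherInformationProfile(
        x_octaves=x, per_neuron=per_neuron, total=per_neuron.sum(axis=0)
    )


@dataclass
class DecodingResult:
    f1: float
    f2: float
    errors: np.ndarray  # per-iteration test error
    mean_error: float
    dprime: float
    n_neurons: int
    n_iterations: int
    degenerate: bool = False

    @property
    def accuracy(self) -> float:
        return 1.0 - self.mean_error


def dprime_from_error(mean_error: float, n_test_total: int = 2000) -> float:
    """Convert a decoder's mean test error to an equal-variance d'.

    Uses the symmetric-criterion convention d' = 2 z(1 - error), with the
    same 1/(2N) clipping as the behavioral metrics (N = total test trials),
    so a zero measured error maps to a finite d'.
    """
    if not (0 <= mean_error <= 1):
        raise ValueError("error must be in [0, 1]")
    lo = 1.0 / (2 * n_test_total)
    err = float(np.clip(mean_error, lo, 1.0 - lo))
    return float(2.0 * stats.norm.ppf(1.0 - err))


def decode_pair(
    rates_f1: np.ndarray,
    rates_f2: np.ndarray,
    f1: float = 0.0,
    f2: float = 0.0,
    n_train: int = 16,
    n_test: int = 4,
    max_iter: int = 500,
    C: float = 1.0,
    seed: int = 0,
    converge_tol: float = 1e-3,
    converge_window: int = 50,
) -> DecodingResult:
    """Linear-SVM discrimination of two frequencies from spike-count vectors.

    Each iteration draws fresh independent Poisson trials at both
    frequencies (``n_train`` train + ``n_test`` test per class), standardizes
    counts per neuron with train-set statistics, trains a soft-margin linear
    SVM (slack cost ``C``), and scores the held-out trials.  Iterations stop
    early once the running mean error moves less than ``converge_tol`` over
    ``converge_window`` iterations.
    """
    r1 = np.asarray(rates_f1, dtype=float)
    r2 = np.asarray(rates_f2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rate vectors must be 1-D and of equal length")
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("rates must be non-negative")
    if r1.size == 0:
        raise ValueError("need at least one neuron")
    rng = np.random.default_rng(seed)
    if not (np.any(r1 > 0) or np.any(r2 > 0)):
        # all-silent population: decoding is undefined, report chance
        return DecodingResult(
            f1, f2, np.full(1, 0.5), 0.5, 0.0, r1.size, 0, degenerate=True
        )
    errors = []
    y_train = np.repeat([0, 1], n_train)
    y_test = np.repeat([0, 1], n_test)
    running = None
    for it in range(max_iter):
        x1 = rng.poisson(r1, size=(n_train + n_test, r1.size))
        x2 = rng.poisson(r2, size=(n_train + n_test, r2.size))
        x_train = np.vstack([x1[:n_train], x2[:n_train]]).astype(float)
        x_test = np.vstack([x1[n_train:], x2[n_train:]]).astype(float)
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((x_train - mu) / sd, y_train)
        pred = clf.predict((x_test - mu) / sd)
        errors.append(float(np.mean(pred != y_test)))
        mean_now = float(np.mean(errors))
        if it + 1 >= 2 * converge_window:
            prev = float(np.mean(errors[: it + 1 - converge_window]))
            if abs(mean_now - prev) < converge_tol:
                running = mean_now
                break
        running = mean_now
    errors = np.asarray(errors)
    mean_error = float(errors.mean())
    n_test_total = errors.size * 2 * n_test
    return DecodingResult(
        f1=f1, f2=f2, errors=errors, mean_error=mean_error,
        dprime=dprime_from_error(mean_error, n_test_total),
        n_neurons=r1.size, n_iterations=int(errors.size),
    )


def performance_vs_n(
    rates_f1: np.ndarray,
    rates_f2: np.ndarray,
    n_values,
    seed: int = 0,
    **decode_kwargs,
) -> list[DecodingResult]:
    """Decoder performance as a function of the number of neurons used.

    For each N, a random subset of N neurons is drawn (without replacement)
    and :func:`decode_pair` is run on it.  Accuracy is non-decreasing in N
    in expectation (more neurons, more information).
    """
    r1 = np.asarray(rates_f1, dtype=float)
    r2 = np.asarray(rates_f2, dtype=float)
    n_values = list(n_values)
    if not n_values:
        raise ValueError("n_values must be non-empty")
    if max(n_values) > r1.size:
        raise ValueError("requested more neurons than available")
    if min(n_values) < 1:
        raise ValueError("population sizes must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for n in n_values:
        idx = rng.choice(r1.size, size=int(n), replace=False)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(decode_pair(r1[idx], r2[idx], seed=sub_seed, **decode_kwargs))
    return out
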