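"""Generative SVD basis-function model of tuning-curve ensembles.

Each neuron's tuning curve is modeled as a weighted sum of K orthogonal basis
functions over the (log-spaced) frequency grid,

    r_i(f) = sum_l  a_l^i  g_l(f),

with the basis taken from the K largest singular directions of the N x F
matrix of measured trial-averaged rates, lightly smoothed with a moving
average.  To act as a *generative* model, the joint distribution of the
fitted coefficients is approximated as factorized: new neurons draw each
coefficient independently from the corresponding empirical (per-component)
distribution.  Single-trial responses are then independent Poisson counts
with means r_i(f); no noise correlations are modeled.

Unlike parametric (e.g. Gaussian) tuning fits, the basis expansion captures
asymmetric and bimodal curve shapes while still regularizing single-trial
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


def moving_average(vectors: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average along the last axis, edges replicated."""
    if window <= 1:
        return np.asarray(vectors, dtype=float).copy()
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    v = np.asarray(vectors, dtype=float)
    half = window // 2
    padded = np.concatenate(
        [np.repeat(v[..., :1], half, axis=-1), v, np.repeat(v[..., -1:], half, axis=-1)],
        axis=-1,
    )
    kernel = np.ones(window) / window
    return np.apply_along_axis(lambda a: np.convolve(a, kernel, mode="valid"), -1, padded)


@dataclass
class ModelNeuronEnsemble:
    """Rate curves of generated ("model") neurons, with provenance."""

    rate_curves: np.ndarray  # (n, F) expected counts per window, floored at 0
    model_id: str
    seed: int
    n_floored: int = 0
    coefficients: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return int(self.rate_curves.shape[0])


class IndependentBasisModel(BaseEstimator):
    """SVD basis-function generative model of a tuning-curve ensemble.

    Parameters
    ----------
    n_components : int
        Number K of retained basis functions (six is the default model
        order; see :func:`select_k`).
    smooth_window : int
        Width of the centered moving average applied to the SVD frequency
        vectors to form the generative basis (odd; 1 disables smoothing).
    coefficients_from_smoothed : bool
        If True, fit coefficients against the smoothed basis instead of the
        raw (orthonormal) SVD basis.  Default False: coefficients are exact
        SVD projections; only curve assembly uses the smoothed basis.
    sampling : {"empirical", "binned"}
        "empirical" bootstrap-resamples observed coefficient values (the
        zero-bin-width limit of histogram sampling); "binned" samples a
        Freedman–Diaconis histogram with uniform within-bin jitter.

    Attributes
    ----------
    basis_ : (K, F) raw SVD basis vectors (orthonormal rows).
    smoothed_basis_ : (K, F) moving-averaged copies used for generation.
    coefficients_ : (N, K) fitted a_l^i for the observed neurons.
    singular_values_ : all singular values of the fitted matrix.
    explained_variance_ratio_ : per-component fraction of sum of squares.
    rank_ : effective rank of the fitted matrix.
    """

    def __init__(
        self,
        n_components: int = 6,
        smooth_window: int = 3,
        coefficients_from_smoothed: bool = False,
        sampling: str = "empirical",
    ) -> None:
        self.n_components = n_components
        self.smooth_window = smooth_window
        self.coefficients_from_smoothed = coefficients_from_smoothed
        self.sampling = sampling

    def fit(self, X: np.ndarray, y=None) -> "IndependentBasisModel":
        """Fit the basis and coefficients to an (N neurons, F frequencies) rate matrix."""
        R = np.asarray(X, dtype=float)
        if R.ndim != 2:
            raise ValueError("rate matrix must be 2-D (neurons x frequencies)")
        if not np.all(np.isfinite(R)):
            raise ValueError("rate matrix must be finite")
        n, f = R.shape
        k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if self.sampling not in ("empirical", "binned"):
            raise ValueError("sampling must be 'empirical' or 'binned'")
        u, s, vt = np.linalg.svd(R, full_matrices=False)
        tol = s.max(initial=0.0) * max(n, f) * np.finfo(float).eps
        rank = int(np.sum(s > tol))
        if k > min(n, f):
            raise ValueError(f"n_components={k} exceeds min(N, F)={min(n, f)}")
        if k > rank:
            raise ValueError(f"n_components={k} exceeds the effective rank {rank}")
        # orient each basis vector so its largest-magnitude entry is positive
        signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
        signs[signs == 0] = 1.0
        vt = vt * signs[:, None]
        u = u * signs[None, :]

        self.singular_values_ = s
        self.rank_ = rank
        self.n_features_in_ = f
        self.basis_ = vt[:k]
        self.smoothed_basis_ = moving_average(self.basis_, self.smooth_window)
        if self.coefficients_from_smoothed:
            # least-squares projection onto the (non-orthogonal) smoothed basis
            self.coefficients_ = np.linalg.lstsq(
                self.smoothed_basis_.T, R.T, rcond=None
            )[0].T
        else:
            self.coefficients_ = u[:, :k] * s[:k]
        total = float(np.sum(s**2))
        self.explained_variance_ratio_ = s**2 / total if total > 0 else np.zeros_like(s)
        return self

    # -- diagnostics ----------------------------------------------------

    def explained_variance(self, k: int | None = None) -> float:
        """Fraction of summed squared singular values captured by the top k."""
        check_is_fitted(self, "singular_values_")
        k = self.n_components if k is None else int(k)
        return float(np.sum(self.explained_variance_ratio_[:k]))

    def explained_variance_curve(self) -> np.ndarray:
        check_is_fitted(self, "singular_values_")
        return np.cumsum(self.explained_variance_ratio_)

    # -- transform / reconstruct ---------------------------------------

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project rate curves onto the raw basis, returning coefficients."""
        check_is_fitted(self, "basis_")
        R = np.asarray(X, dtype=float)
        return R @ self.basis_.T

    def inverse_transform(self, A: np.ndarray, smoothed: bool = True) -> np.ndarray:
        """Assemble rate curves from coefficients (smoothed basis by default)."""
        check_is_fitted(self, "basis_")
        basis = self.smoothed_basis_ if smoothed else self.basis_
        return np.asarray(A, dtype=float) @ basis

    def reconstruct(self, smoothed: bool = False) -> np.ndarray:
        """Reconstruct the observed neurons from their fitted coefficients.

        With ``smoothed=False`` this is exactly the rank-K SVD projection of
        the fitted matrix.
        """
        check_is_fitted(self, "coefficients_")
        return self.inverse_transform(self.coefficients_, smoothed=smoothed)

    # -- generation -----------------------------------------------------

    def sample(self, n: int, seed: int = 0) -> ModelNeuronEnsemble:
        """Generate n model neurons by factorized coefficient resampling."""
        check_is_fitted(self, "coefficients_")
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        obs = self.coefficients_
        k = obs.shape[1]
        a = np.empty((n, k))
        for l in range(k):
            col = obs[:, l]
            if self.sampling == "binned":
                a[:, l] = _sample_binned(col, n, rng)
            else:
                a[:, l] = rng.choice(col, size=n, replace=True)
        curves = self.inverse_transform(a, smoothed=True)
        n_floored = int(np.sum(curves < 0))
        return ModelNeuronEnsemble(
            rate_curves=np.clip(curves, 0.0, None),
            model_id=f"ibf_k{k}",
            seed=seed,
            n_floored=n_floored,
            coefficients=a,
        )

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "coefficients_")
        payload = {
            "params": self.get_params(),
            "basis": self.basis_.tolist(),
            "smoothed_basis": self.smoothed_basis_.tolist(),
            "coefficients": self.coefficients_.tolist(),
            "singular_values": self.singular_values_.tolist(),
            "rank": self.rank_,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IndependentBasisModel":
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.basis_ = np.asarray(payload["basis"])
        model.smoothed_basis_ = np.asarray(payload["smoothed_basis"])
        model.coefficients_ = np.asarray(payload["coefficients"])
        model.singular_values_ = np.asarray(payload["singular_values"])
        model.rank_ = int(payload["rank"])
        total = float(np.sum(model.singular_values_**2))
        model.explained_variance_ratio_ = (
            model.singular_values_**2 / total if total > 0
            else np.zeros_like(model.singular_values_)
        )
        model.n_features_in_ = model.basis_.shape[1]
        return model


def _sample_binned(values: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Histogram sampling with Freedman–Diaconis bins and within-bin jitter."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        return np.full(n, v[0])
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    width = 2 * iqr / np.cbrt(v.size) if iqr > 0 else np.ptp(v) / 10
    n_bins = max(1, int(np.ceil(np.ptp(v) / width)))
    hist, edges = np.histogram(v, bins=n_bins)
    probs = hist / hist.sum()
    which = rng.choice(n_bins, size=n, p=probs)
    return rng.uniform(edges[which], edges[which + 1])


def fit_ibf(rate_matrix: np.ndarray, k: int = 6, **kwargs) -> IndependentBasisModel:
    """Convenience wrapper: fit an :class:`IndependentBasisModel` of order k."""
    return IndependentBasisModel(n_components=k, **kwargs).fit(rate_matrix)


@dataclass
class SelectKResult:
    k_star: int
    k_candidates: np.ndarray
    test_mse: np.ndarray  # mean over splits, one entry per candidate
    explained_variance: np.ndarray  # cumulative EV at each candidate (full data)
    n_splits: int


def select_k(
    trial_counts: np.ndarray,
    k_candidates=range(1, 15),
    n_splits: int = 25,
    test_fraction: float = 0.2,
    seed: int = 0,
    smooth_window: int = 3,
) -> SelectKResult:
    """Model-order selection by trial-split cross-validation.

    For each random 80/20 split of trials, the model is fitted on the
    train-trial mean rates and its reconstruction is scored (mean squared
    error) against the test-trial mean rates, for every candidate K.  The
    returned K* minimizes mean test MSE (ties to the smaller K); the test
    error typically shows a broad minimum once K reaches the true complexity
    of the ensemble, while the in-sample explained variance keeps rising.
    """
    counts = np.asarray(trial_counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("trial_counts must be (neurons, frequencies, trials)")
    n, f, t = counts.shape
    if t < 2:
        raise ValueError("need at least 2 trials per condition to split")
    ks = np.array(sorted(set(int(k) for k in k_candidates)))
    if ks.min() < 1 or ks.max() > min(n, f):
        raise ValueError(f"candidates must lie in [1, {min(n, f)}]")
    n_test = max(1, int(round(t * test_fraction)))
    if n_test >= t:
        n_test = t - 1
    rng = np.random.default_rng(seed)
    mse = np.zeros((n_splits, ks.size))
    for split in range(n_splits):
        perm = rng.permutation(t)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        train_mean = counts[:, :, train_idx].mean(axis=2)
        test_mean = counts[:, :, test_idx].mean(axis=2)
        # same decomposition the estimator performs, but keeping all modes so
        # candidates above the train-matrix rank degrade gracefully
        u, s, vt = np.linalg.svd(train_mean, full_matrices=False)
        smoothed = moving_average(vt, smooth_window)
        coeff = u * s
        for j, k in enumerate(ks):
            kk = min(int(k), s.size)
            recon = coeff[:, :kk] @ smoothed[:kk]
            mse[split, j] = float(np.mean((recon - test_mean) ** 2))
    mean_mse = mse.mean(axis=0)
    k_star = int(ks[np.argmin(mean_mse)])  # argmin takes the first (smaller K) on ties
    full_model = IndependentBasisModel(n_components=1).fit(counts.mean(axis=2))
    ev_curve = np.cumsum(full_model.explained_variance_ratio_)
    ev = np.array([ev_curve[min(k, ev_curve.size) - 1] for k in ks])
    return SelectKResult(
        k_star=k_star, k_candidates=ks, test_mse=mean_mse,
        explained_variance=ev, n_splits=n_splits,
    )


def rates_at(
    ensemble: ModelNeuronEnsemble, grid_log2_axis: np.ndarray, x_octave: float
) -> np.ndarray:
    """Per-neuron expected counts at an octave coordinate (linear interpolation)."""
    x_axis = np.asarray(grid_log2_axis, dtype=float)
    if not (x_axis[0] <= x_octave <= x_axis[-1]):
        raise ValueError("frequency outside the model grid")
    return np.array(
        [np.interp(x_octave, x_axis, curve) for curve in ensemble.rate_curves]
    )


def simulate_trials(
    rates: np.ndarray, n_trials: int, seed: int = 0
) -> np.ndarray:
    """Independent Poisson counts, shape (n_trials, n_neurons)."""
    lam = np.asarray(rates, dtype=float)
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.poisson(lam[None, :], size=(n_trials, lam.size))
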