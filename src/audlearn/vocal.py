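"""Vocalization-response analysis: sparseness, similarity, Fano, decoding.

Lifetime sparseness of a neuron over the n syllables of a call,

    S = (1 - [(sum r_i / n)^2 / sum(r_i^2 / n)]) / (1 - 1/n),

ranges from 0% (all syllables driven equally, a dense code) to 100% (one
syllable only, a maximally sparse code).  Population sparseness is 100 minus
the percentage of neurons responding significantly to a syllable.  Response
similarity between call variants is the Pearson correlation of per-syllable
evoked rates (or of 1-ms PSTHs), averaged over neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .synthetic.vocal import SyllableResponseSet
from .tuning import responsiveness_test


def lifetime_sparseness(responses: np.ndarray) -> float:
    """Lifetime sparseness S (%) of one neuron's per-syllable mean rates.

    Returns NaN (flagged undefined) when every response is zero.
    """
    r = np.asarray(responses, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need a 1-D vector of at least 2 responses")
    if np.any(r < 0):
        raise ValueError("responses must be non-negative")
    n = r.size
    if np.all(r == 0):
        return float("nan")
    num = (r.sum() / n) ** 2 / np.sum(r**2 / n)
    return float(100.0 * (1.0 - num) / (1.0 - 1.0 / n))


def population_sparseness(significant: np.ndarray) -> np.ndarray:
    """Per-syllable population sparseness (%) from a neurons x syllables mask."""
    m = np.asarray(significant, dtype=bool)
    if m.ndim != 2:
        raise ValueError("significance matrix must be 2-D (neurons x syllables)")
    if m.shape[0] == 0:
        raise ValueError("need at least one neuron")
    return 100.0 - 100.0 * m.mean(axis=0)


def syllable_significance(
    srs: SyllableResponseSet, variant: float = 1.0, alpha: float = 0.05
) -> np.ndarray:
    """Boolean (neurons x syllables) mask of significant syllable responses.

    Per (neuron, syllable), evoked counts for the chosen variant are compared
    with the matched spontaneous counts by two-sample t-test.
    """
    vi = srs.variant_index(variant)
    n, s = srs.n_neurons, srs.n_syllables
    mask = np.zeros((n, s), dtype=bool)
    for i in range(n):
        for j in range(s):
            _, sig = responsiveness_test(
                srs.responses[i, vi, j], srs.spont_counts[i, vi, j], alpha=alpha
            )
            mask[i, j] = sig
    return mask


def sparseness_report(srs: SyllableResponseSet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-neuron lifetime sparseness for the original call (variant s=1)."""
    vi = srs.variant_index(1.0)
    rates = srs.responses[:, vi].mean(axis=2)  # (N, S) trial-mean counts
    values = [lifetime_sparseness(r) for r in rates]
    return pd.DataFrame(
        {
            "neuron_id": srs.neuron_ids or list(range(srs.n_neurons)),
            "group": srs.group_label,
            "lifetime_sparseness_pct": values,
            "mean_evoked_rate": rates.mean(axis=1),
        }
    )


@dataclass(frozen=True)
class SimilarityMatrix:
    speeding_factors: tuple[float, ...]
    matrix: np.ndarray  # (V, V) across-neuron mean Pearson r
    per_neuron: np.ndarray  # (N, V, V), NaN where excluded
    n_excluded: np.ndarray  # (V, V) zero-variance neurons dropped per pair

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    def mean_offdiagonal(self) -> float:
        v = self.matrix.shape[0]
        mask = ~np.eye(v, dtype=bool)
        return float(np.nanmean(self.matrix[mask]))


def similarity_matrix(srs: SyllableResponseSet, mode: str = "rates") -> SimilarityMatrix:
    """Across-variant response similarity, averaged over neurons.

    mode="rates": per neuron, Pearson r between the per-syllable trial-mean
    rate vectors of each variant pair.  mode="psth": Pearson r between 1-ms
    PSTHs (requires the response set to carry spike times).  Zero-variance
    neurons are excluded from a pair's mean, and the exclusion count kept.
    """
    v = len(srs.speeding_factors)
    if v < 2:
        raise ValueError("need at least 2 stimulus variants")
    if mode == "rates":
        vectors = srs.syllable_rates()  # (N, V, S)
    elif mode == "psth":
        if srs.spike_times is None:
            raise ValueError("psth mode requires spike times in the response set")
        vectors = _psth_vectors(srs)
    else:
        raise ValueError("mode must be 'rates' or 'psth'")
    n = vectors.shape[0]
    per = np.full((n, v, v), np.nan)
    excluded = np.zeros((v, v), dtype=int)
    for i in range(n):
        for a in range(v):
            per[i, a, a] = 1.0
            for b in range(a + 1, v):
                xa, xb = vectors[i, a], vectors[i, b]
                if xa.std() == 0 or xb.std() == 0:
                    excluded[a, b] += 1
                    excluded[b, a] += 1
                    continue
                r = float(stats.pearsonr(xa, xb).statistic)
                per[i, a, b] = per[i, b, a] = r
    with np.errstate(invalid="ignore"):
        matrix = np.nanmean(per, axis=0)
    return SimilarityMatrix(
        speeding_factors=srs.speeding_factors,
        matrix=matrix, per_neuron=per, n_excluded=excluded,
    )


def _psth_vectors(srs: SyllableResponseSet, bin_ms: float = 1.0) -> np.ndarray:
    """1-ms PSTHs over the concatenated syllable windows, shape (N, V, B)."""
    windows = srs.syllable_windows_ms
    edges_list = [np.arange(w0, w1 + bin_ms, bin_ms) for w0, w1 in windows]
    n, v = srs.n_neurons, len(srs.speeding_factors)
    out = []
    for i in range(n):
        per_variant = []
        for a in range(v):
            segs = []
            for j, edges in enumerate(edges_list):
                counts = np.zeros(edges.size - 1)
                for trial in srs.spike_times[i][a][j]:
                    counts += np.histogram(trial, bins=edges)[0]
                segs.append(counts / srs.n_trials)
            per_variant.append(np.concatenate(segs))
        out.append(per_variant)
    return np.asarray(out)


def fano_factor(counts: np.ndarray) -> float:
    """Trial-to-trial variance/mean of spike counts (unbiased variance).

    Returns NaN (flagged undefined) when the mean count is zero.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValueError("need at least 2 trials")
    m = c.mean()
    if m == 0:
        return float("nan")
    return float(c.var(ddof=1) / m)


def fano_report(srs: SyllableResponseSet) -> pd.DataFrame:
    """Fano factors per (neuron, variant, syllable) plus per-neuron means.

    Both per-condition values and their across-condition mean are reported,
    since reliability may be summarized either way.
    """
    rows = []
    for i in range(srs.n_neurons):
        ffs = []
        for a in range(len(srs.speeding_factors)):
            for j in range(srs.n_syllables):
                ff = fano_factor(srs.responses[i, a, j])
                ffs.append(ff)
                rows.append(
                    dict(
                        neuron=i, speeding_factor=srs.speeding_factors[a],
                        syllable=j, fano=ff,
                    )
                )
        rows.append(
            dict(neuron=i, speeding_factor=np.nan, syllable=-1,
                 fano=float(np.nanmean(ffs)))
        )
    return pd.DataFrame(rows)


def decode_vocal_pair(
    srs: SyllableResponseSet,
    variant_a: float,
    variant_b: float,
    n_neurons: int = 37,
    k_values=None,
    n_iterations: int = 1000,
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cumulative-syllable population decoding of two call variants.

    For each cumulative syllable count k, single-trial feature vectors are
    the per-neuron spike counts in syllables 1..k (concatenated).  A linear
    soft-margin SVM is scored by leave-one-out cross-validation: each
    iteration holds out one trial per class, trains on the remaining 15 (for
    the standard 16 repetitions), and tests the two held-out vectors.

    Note that leave-one-out on a fixed sample is pessimistically biased at
    chance (holding a trial out shifts its class's training mean away from
    it), so indistinguishable stimuli score somewhat *below* 0.5; the bias
    is shared by any two conditions being compared.
    """
    va, vb = srs.variant_index(variant_a), srs.variant_index(variant_b)
    if n_neurons > srs.n_neurons:
        raise ValueError(
            f"requested {n_neurons} neurons but the set has {srs.n_neurons}"
        )
    ks = list(k_values) if k_values is not None else list(range(1, srs.n_syllables + 1))
    rng = np.random.default_rng(seed)
    idx = rng.choice(srs.n_neurons, size=n_neurons, replace=False)
    t = srs.n_trials
    # (T, N, S) per class
    xa = srs.responses[idx, va].transpose(2, 0, 1).astype(float)
    xb = srs.responses[idx, vb].transpose(2, 0, 1).astype(float)
    rows = []
    for k in ks:
        fa = xa[:, :, :k].reshape(t, -1)
        fb = xb[:, :, :k].reshape(t, -1)
        correct = 0
        total = 0
        for _ in range(n_iterations):
            held = int(rng.integers(t))
            train_mask = np.ones(t, dtype=bool)
            train_mask[held] = False
            x_train = np.vstack([fa[train_mask], fb[train_mask]])
            y_train = np.repeat([0, 1], t - 1)
            mu, sd = x_train.mean(axis=0), x_train.std(axis=0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="linear", C=C)
            clf.fit((x_train - mu) / sd, y_train)
            pred = clf.predict((np.vstack([fa[held], fb[held]]) - mu) / sd)
            correct += int(pred[0] == 0) + int(pred[1] == 1)
            total += 2
        rows.append(dict(k_syllables=int(k), accuracy=correct / total,
                         n_neurons=n_neurons, n_iterations=n_iterations))
    return pd.DataFrame(rows)
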