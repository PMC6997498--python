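"""CSV serialization of ensembles, behavior logs and vocal response sets.

All tables are plain RFC-4180 CSV written through pandas; spike-time lists
are semicolon-joined strings.  The spike table carries one row per
(cell, stimulus, trial) with both the evoked-window and the matched
pre-stimulus count, which is everything the tuning analyses need.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import StimulusGrid
from .synthetic.behavior import BehaviorLog
from .synthetic.tuning import TuningEnsemble
from .synthetic.vocal import SyllableResponseSet


def stimuli_frame(grid: StimulusGrid) -> pd.DataFrame:
    rows = [
        dict(stim_id=f"f{fi:02d}_l{li}", freq_khz=f, level_db=l)
        for fi, f in enumerate(grid.frequencies_khz)
        for li, l in enumerate(grid.levels_db)
    ]
    return pd.DataFrame(rows)


def spikes_frame(ensemble: TuningEnsemble) -> pd.DataFrame:
    n, f, l, t = ensemble.counts.shape
    ni, fi, li, ti = np.unravel_index(np.arange(n * f * l * t), (n, f, l, t))
    meta = ensemble.neurons
    return pd.DataFrame(
        {
            "cell_id": meta.neuron_id.to_numpy()[ni],
            "group": meta.group.to_numpy()[ni],
            "cell_class": meta.cell_class.to_numpy()[ni],
            "site": meta.site.to_numpy()[ni],
            "stim_id": [f"f{a:02d}_l{b}" for a, b in zip(fi, li)],
            "trial": ti,
            "count": ensemble.counts[ni, fi, li, ti],
            "spont_count": ensemble.spont_counts[ni, fi, li, ti],
            "spike_times_ms": "",
        }
    )


def write_ensemble(ensemble: TuningEnsemble, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes_frame(ensemble).to_csv(out / "spikes.csv", index=False)
    stimuli_frame(ensemble.grid).to_csv(out / "stimuli.csv", index=False)


def read_ensemble(in_dir: str | Path) -> TuningEnsemble:
    """Rebuild an ensemble from spikes.csv + stimuli.csv.

    The true rate curves are not stored, so the reconstructed ensemble
    carries the measured (trial- and level-averaged) curves in their place.
    """
    in_dir = Path(in_dir)
    spikes = pd.read_csv(in_dir / "spikes.csv")
    stimuli = pd.read_csv(in_dir / "stimuli.csv")
    freqs = np.sort(stimuli.freq_khz.unique())
    levels = np.sort(stimuli.level_db.unique())
    grid = StimulusGrid(frequencies_khz=freqs, levels_db=levels)
    cells = spikes.drop_duplicates("cell_id")[
        ["cell_id", "group", "cell_class", "site"]
    ].reset_index(drop=True)
    cell_idx = {c: i for i, c in enumerate(cells.cell_id)}
    stim = stimuli.set_index("stim_id")
    f_idx = {s: int(np.searchsorted(freqs, stim.loc[s, "freq_khz"])) for s in stim.index}
    l_idx = {s: int(np.searchsorted(levels, stim.loc[s, "level_db"])) for s in stim.index}
    n_trials = int(spikes.trial.max()) + 1
    shape = (len(cells), grid.n_frequencies, grid.n_levels, n_trials)
    counts = np.zeros(shape, dtype=np.int64)
    spont = np.zeros(shape, dtype=np.int64)
    ni = spikes.cell_id.map(cell_idx).to_numpy()
    fi = spikes.stim_id.map(f_idx).to_numpy()
    li = spikes.stim_id.map(l_idx).to_numpy()
    ti = spikes.trial.to_numpy()
    counts[ni, fi, li, ti] = spikes["count"].to_numpy()
    spont[ni, fi, li, ti] = spikes.spont_count.to_numpy()
    neurons = cells.rename(columns={"cell_id": "neuron_id"})
    neurons["bf_true_khz"] = np.nan
    return TuningEnsemble(
        grid=grid,
        neurons=neurons,
        rate_curves=counts.mean(axis=(2, 3)),
        counts=counts,
        spont_counts=spont,
        level_gains=np.ones(grid.n_levels),
        group_label=str(cells.group.iloc[0]) if len(cells) else "naive",
    )


def write_behavior_log(log: BehaviorLog, path: str | Path) -> None:
    log.trials.to_csv(path, index=False)


def read_behavior_log(path: str | Path) -> BehaviorLog:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["licked"] = df.licked.astype(str).str.lower().isin(["true", "1"])
    df["lick_times_ms"] = df.lick_times_ms.astype(str).replace("nan", "")
    return BehaviorLog(trials=df)


def write_vocal_set(srs: SyllableResponseSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, v, s, t = srs.responses.shape
    ni, vi, si, ti = np.unravel_index(np.arange(n * v * s * t), (n, v, s, t))
    ids = srs.neuron_ids or [str(i) for i in range(n)]
    pd.DataFrame(
        {
            "cell_id": np.asarray(ids)[ni],
            "group": srs.group_label,
            "speeding_factor": np.asarray(srs.speeding_factors)[vi],
            "syllable": si,
            "trial": ti,
            "count": srs.responses[ni, vi, si, ti],
            "spont_count": srs.spont_counts[ni, vi, si, ti],
        }
    ).to_csv(out / "vocal_spikes.csv", index=False)
    pd.DataFrame(
        {
            "syllable": np.arange(s),
            "onset_ms": srs.syllable_windows_ms[:, 0],
            "offset_ms": srs.syllable_windows_ms[:, 1],
        }
    ).to_csv(out / "syllables.csv", index=False)


def read_vocal_set(in_dir: str | Path) -> SyllableResponseSet:
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "vocal_spikes.csv")
    syl = pd.read_csv(in_dir / "syllables.csv").sort_values("syllable")
    ids = list(dict.fromkeys(df.cell_id))
    factors = sorted(df.speeding_factor.unique(), reverse=True)
    n, v = len(ids), len(factors)
    s = int(df.syllable.max()) + 1
    t = int(df.trial.max()) + 1
    resp = np.zeros((n, v, s, t), dtype=np.int64)
    spont = np.zeros((n, v, s, t), dtype=np.int64)
    cell_idx = {c: i for i, c in enumerate(ids)}
    var_idx = {f: i for i, f in enumerate(factors)}
    ni = df.cell_id.map(cell_idx).to_numpy()
    vi = df.speeding_factor.map(var_idx).to_numpy()
    resp[ni, vi, df.syllable, df.trial] = df["count"].to_numpy()
    spont[ni, vi, df.syllable, df.trial] = df.spont_count.to_numpy()
    return SyllableResponseSet(
        speeding_factors=tuple(float(f) for f in factors),
        syllable_windows_ms=syl[["onset_ms", "offset_ms"]].to_numpy(),
        responses=resp,
        spont_counts=spont,
        mean_rates=resp.mean(axis=3),
        group_label=str(df.group.iloc[0]) if len(df) else "naive",
        neuron_ids=[str(i) for i in ids],
    )


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2, default=_json_default) + "\n"
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
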