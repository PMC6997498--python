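"""End-to-end study orchestration: synthesize, analyze, report.

Two entry points mirror the two experiments: :func:`run_tone_study` chains
behavior metrics, tuning summaries, the generative basis model, Fisher
information and pairwise decoding; :func:`run_vocal_study` chains sparseness,
similarity and cumulative-syllable decoding.  Both write per-stage output
files plus a JSON summary with naive-vs-expert rank-sum comparisons
(Holm–Bonferroni adjusted) and a manifest recording seeds, parameters and
file hashes.  All randomness derives from the single config seed, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import behavior as bhv
from . import ibf, io, popcode, tuning, vocal
from .grids import StimulusGrid, TRAINING_BAND_KHZ
from .synthetic.behavior import default_training_stages, generate_behavior_log
from .synthetic.tuning import expert_tone_spec, generate_tuning_ensemble, naive_tone_spec
from .synthetic.vocal import expert_vocal_spec, generate_vocal_responses, naive_vocal_spec

log = logging.getLogger("audlearn.pipeline")


class ToneStudyConfig(BaseModel):
    out_dir: str
    seed: int  # required: every stochastic stage derives its seed from this
    n_neurons: int = Field(100, ge=1)
    n_model_neurons: int = Field(200, ge=1)
    k: int = Field(6, ge=1)
    training_band_khz: tuple[float, float] = TRAINING_BAND_KHZ
    decode_iterations: int = Field(50, ge=1)
    n_mice: int = Field(3, ge=1)
    catch_rate: float = Field(0.06, ge=0, lt=1)


class VocalStudyConfig(BaseModel):
    out_dir: str
    seed: int
    n_neurons: int = Field(60, ge=1)
    decoder_neurons: int = Field(37, ge=1)
    decode_iterations: int = Field(100, ge=1)
    decode_pair: tuple[float, float] = (1.0, 0.9)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _rank_sum_table(metrics: dict[str, tuple[np.ndarray, np.ndarray]]) -> list[dict]:
    """Rank-sum naive-vs-expert comparisons with Holm–Bonferroni adjustment."""
    rows = []
    pvals = []
    for name, (a, b) in metrics.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        res = stats.ranksums(a, b)
        rows.append(
            dict(metric=name, naive_median=float(np.median(a)),
                 expert_median=float(np.median(b)), p_raw=float(res.pvalue))
        )
        pvals.append(res.pvalue)
    reject, p_adj, _, _ = multipletests(pvals, alpha=0.05, method="holm")
    for row, p, rej in zip(rows, p_adj, reject):
        row["p_holm"] = float(p)
        row["significant"] = bool(rej)
    return rows


def _manifest(out: Path, config: BaseModel, seeds: list[int]) -> None:
    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    hashes = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest() for name in files
    }
    io.dump_json(
        dict(config=config.model_dump(), stage_seeds=seeds, file_hashes=hashes),
        out / "manifest.json",
    )


def run_tone_study(config: ToneStudyConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)
    grid = StimulusGrid.default()
    summary: dict = {"study": "tone", "seed": config.seed}

    # -- behavior ------------------------------------------------------
    log.info("tone study: simulating %d behavior logs", config.n_mice)
    stages = default_training_stages()
    logs = [
        generate_behavior_log(
            stages, mouse_id=f"m{mi:03d}", seed=seeds[0] + mi,
            catch_rate=config.catch_rate,
        )
        for mi in range(config.n_mice)
    ]
    io.write_behavior_log(logs[0], out / "trials.csv")
    stage_tables = [bhv.stage_dprime(lg) for lg in logs]
    summary["behavior"] = {
        "stage_dprime_mean": [
            float(np.mean([t.dprime.iloc[i] for t in stage_tables]))
            for i in range(len(stages))
        ],
        "stage_separation_pct_octave": [
            float(100 * abs(np.log2(s.target_khz / s.nontarget_khz))) for s in stages
        ],
    }
    catch = logs[0].trials[logs[0].trials.stimulus_kind == "catch"]
    if len(catch) >= 20:
        fit = bhv.fit_psychometric(catch.stimulus_khz.to_numpy(), catch.licked.to_numpy())
        summary["behavior"]["decision_boundary_khz"] = fit.decision_boundary_khz
        summary["behavior"]["psychometric_degenerate"] = fit.degenerate

    # -- tuning ensembles ----------------------------------------------
    log.info("tone study: generating ensembles and summaries")
    ens = {
        "naive": generate_tuning_ensemble(
            naive_tone_spec(config.n_neurons, seed=seeds[1]), grid
        ),
        "expert": generate_tuning_ensemble(
            expert_tone_spec(config.n_neurons, seed=seeds[2]), grid
        ),
    }
    summaries = pd.concat(
        [tuning.ensemble_summaries(e, config.training_band_khz) for e in ens.values()],
        ignore_index=True,
    )
    summaries.to_csv(out / "neuron_summaries.csv", index=False)
    sc = {
        g: tuning.pairwise_signal_correlations(e) for g, e in ens.items()
    }
    pd.concat(
        [df.assign(group=g) for g, df in sc.items()], ignore_index=True
    ).to_csv(out / "signal_correlations.csv", index=False)

    band_lo, band_hi = config.training_band_khz
    by_group = {g: summaries[summaries.group == g] for g in ens}
    summary["tuning"] = {
        g: {
            "n_responsive": int(df.is_responsive.sum()),
            "bf_in_band_fraction": float(
                ((df.bf_khz >= band_lo) & (df.bf_khz <= band_hi)).mean()
            ),
            "mean_signal_correlation": float(np.nanmean(sc[g].r)) if len(sc[g]) else None,
        }
        for g, df in by_group.items()
    }

    # -- generative model, FI, decoding --------------------------------
    log.info("tone study: fitting basis models and decoding")
    fi_rows, decode_rows = [], []
    models = {}
    for gi, (g, e) in enumerate(ens.items()):
        model = ibf.fit_ibf(e.mean_curves(), k=config.k)
        models[g] = model
        (out / f"model_{g}.json").write_text(model.to_json())
        sample = model.sample(config.n_model_neurons, seed=seeds[3] + gi)
        # sampled curves may be floored at exactly 0; a physiological floor
        # (0.05 counts/window) keeps r'^2/r finite at silent-region edges
        fi = popcode.fisher_information(
            sample.rate_curves, grid.log2_axis, floor_eps=0.05
        )
        fi_rows.append(
            pd.DataFrame(
                dict(group=g, freq_khz=grid.frequencies_khz,
                     x_octave=grid.log2_axis, total_fi=fi.total)
            )
        )
        band_mask = grid.band_mask(config.training_band_khz)
        in_band = int(np.flatnonzero(band_mask)[0])
        flank = min(grid.n_frequencies - 2, int(np.flatnonzero(band_mask)[-1]) + 1)
        for label, i1 in (("in_band", in_band), ("flank", flank)):
            res = popcode.decode_pair(
                sample.rate_curves[:, i1], sample.rate_curves[:, i1 + 1],
                f1=grid.frequencies_khz[i1], f2=grid.frequencies_khz[i1 + 1],
                max_iter=config.decode_iterations, seed=seeds[4] + gi,
            )
            decode_rows.append(
                dict(group=g, pair=label, f1_khz=res.f1, f2_khz=res.f2,
                     accuracy=res.accuracy, dprime=res.dprime,
                     n_iterations=res.n_iterations)
            )
        summary.setdefault("model", {})[g] = {
            "k": config.k,
            "explained_variance": model.explained_variance(),
            "fi_total_mean": float(fi.total.mean()),
        }
    pd.concat(fi_rows, ignore_index=True).to_csv(out / "fi_profile.csv", index=False)
    pd.DataFrame(decode_rows).to_csv(out / "decoding.csv", index=False)
    summary["decoding"] = decode_rows

    # -- group comparisons ---------------------------------------------
    nv, ex = by_group["naive"], by_group["expert"]
    center = np.log2(np.sqrt(band_lo * band_hi))
    summary["group_comparisons"] = _rank_sum_table(
        {
            "selectivity_pct": (nv.selectivity_pct, ex.selectivity_pct),
            "spontaneous_hz": (nv.spontaneous_hz, ex.spontaneous_hz),
            "rate_training_band_hz": (nv.rate_training_band_hz, ex.rate_training_band_hz),
            "bf_distance_to_band_octave": (
                np.abs(np.log2(nv.bf_khz) - center),
                np.abs(np.log2(ex.bf_khz) - center),
            ),
        }
    )
    io.dump_json(summary, out / "summary.json")
    _manifest(out, config, seeds)
    return summary


def run_vocal_study(config: VocalStudyConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    summary: dict = {"study": "vocal", "seed": config.seed}

    log.info("vocal study: generating response sets")
    sets = {
        "naive": generate_vocal_responses(
            naive_vocal_spec(config.n_neurons, seed=seeds[0])
        ),
        "expert": generate_vocal_responses(
            expert_vocal_spec(config.n_neurons, seed=seeds[1])
        ),
    }
    sparse_tables, sim = {}, {}
    rows_sparse, rows_sim, rows_decode = [], [], []
    for gi, (g, srs) in enumerate(sets.items()):
        sp = vocal.sparseness_report(srs)
        sparse_tables[g] = sp
        rows_sparse.append(sp)
        sig = vocal.syllable_significance(srs)
        pop = vocal.population_sparseness(sig)
        sm = vocal.similarity_matrix(srs)
        sim[g] = sm
        for a in range(len(srs.speeding_factors)):
            for b in range(len(srs.speeding_factors)):
                rows_sim.append(
                    dict(group=g, s_a=srs.speeding_factors[a],
                         s_b=srs.speeding_factors[b], r=sm.matrix[a, b])
                )
        curve = vocal.decode_vocal_pair(
            srs, *config.decode_pair, n_neurons=config.decoder_neurons,
            n_iterations=config.decode_iterations, seed=seeds[2] + gi,
        )
        rows_decode.append(curve.assign(group=g))
        summary.setdefault("groups", {})[g] = {
            "lifetime_sparseness_mean_pct": float(
                np.nanmean(sp.lifetime_sparseness_pct)
            ),
            "population_sparseness_mean_pct": float(np.mean(pop)),
            "similarity_offdiagonal_mean": sm.mean_offdiagonal(),
            "decoding_accuracy_final": float(curve.accuracy.iloc[-1]),
        }
    pd.concat(rows_sparse, ignore_index=True).to_csv(out / "sparseness.csv", index=False)
    pd.DataFrame(rows_sim).to_csv(out / "similarity.csv", index=False)
    pd.concat(rows_decode, ignore_index=True).to_csv(
        out / "decoding_curve.csv", index=False
    )
    summary["group_comparisons"] = _rank_sum_table(
        {
            "lifetime_sparseness_pct": (
                sparse_tables["naive"].lifetime_sparseness_pct,
                sparse_tables["expert"].lifetime_sparseness_pct,
            ),
            "mean_evoked_rate": (
                sparse_tables["naive"].mean_evoked_rate,
                sparse_tables["expert"].mean_evoked_rate,
            ),
        }
    )
    io.dump_json(summary, out / "summary.json")
    _manifest(out, config, seeds)
    return summary
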