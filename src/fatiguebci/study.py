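"""End-to-end simulated study: pre-rest, calibration, game, post-rest for
every participant and session, followed by the full statistical analysis.

For each simulated participant the three-session crossover (MI-BCI, P300-BCI,
video control; Latin-square order) is played out on synthetic EEG: the
resting-state alpha biomarker is measured before and after the task, BCI
sessions train their decoder and play game trials, and the per-session rows
are assembled into the cohort table consumed by the statistics layer
(mixed models, repeated-measures correlation, reliability).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarker, pipelines, simulate, stats
from .io import StudyConfig

logger = logging.getLogger(__name__)

__all__ = ["run_study", "records_to_long"]


def _participant_config(config: StudyConfig, p: int) -> simulate.SimulationConfig:
    seed = int(np.random.SeedSequence([config.seed, 1000 + p]).generate_state(1)[0] % 2**31)
    return dataclasses.replace(config.simulation, seed=seed)


def records_to_long(records: pd.DataFrame) -> pd.DataFrame:
    """Reshape the per-session table to one row per session x time (pre/post)."""
    rows = []
    for _, r in records.iterrows():
        for time in ("pre", "post"):
            rows.append({
                "participant": r["participant"],
                "session": r["session"],
                "order": r["order"],
                "time": time,
                "vasf": r[f"vasf_{time}"],
                "alpha": r[f"alpha_{time}"],
            })
    return pd.DataFrame(rows)


def _session_alpha(
    pcfg: simulate.SimulationConfig,
    config: StudyConfig,
    stream: tuple[int, ...],
    target_pre: float,
    target_post: float,
) -> tuple[float | None, float | None]:
    """Measured pre/post alpha power from synthetic resting EEG.

    The alpha source amplitude is scaled so that the session's band power
    lands near the cohort-model draw (``target_pre``/``target_post``), which
    carries the participant random intercept and the post-task shift; band
    power goes as amplitude squared, hence the square-root scaling."""
    out = []
    for phase, target in (("pre", target_pre), ("post", target_post)):
        scale = float(np.sqrt(max(target, 0.5) / pcfg.alpha_pre_mean))
        rec = simulate.gen_resting(pcfg, 120.0, alpha_scale=scale,
                                   stream=(*stream, 0 if phase == "pre" else 1))
        res = biomarker.resting_alpha(rec, phase=phase,
                                      aggregation=config.alpha_aggregation)
        out.append(None if res.excluded else res.aggregate)
    return tuple(out)


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Run the full simulated protocol and analysis.

    Returns a results bundle with the per-session ``records`` table, the
    decoder ``metrics`` table, and the statistical outputs (mixed models for
    both primary outcomes, the fatigue/alpha repeated-measures correlation,
    and SEM/MDC reliability).  Deterministic under ``config.seed``; if
    ``out_dir`` is given, the tables are flushed there as CSV even when a
    later stage fails.
    """
    cohort = simulate.gen_cohort(config.simulation)
    records = cohort.copy()
    records["alpha_pre"] = np.nan
    records["alpha_post"] = np.nan
    records["performance"] = np.nan
    metric_rows = []
    participants = sorted(cohort["participant"].unique())

    stage = "simulation"
    try:
        for p_idx, participant in enumerate(participants):
            pcfg = _participant_config(config, p_idx)
            for s_idx, session in enumerate(simulate.SESSIONS):
                mask = (records["participant"] == participant) & (
                    records["session"] == session
                )
                row = cohort[mask]
                a_pre, a_post = _session_alpha(
                    pcfg, config, (50, s_idx),
                    float(row["alpha_pre"].iloc[0]),
                    float(row["alpha_post"].iloc[0]),
                )
                records.loc[mask, "alpha_pre"] = a_pre
                records.loc[mask, "alpha_post"] = a_post
                if session == "MI":
                    rec, events = simulate.gen_mi_session(pcfg)
                    decoder = pipelines.train_mi(rec, events, k=config.k_folds,
                                                 seed=config.seed, feedback_trace=False)
                    outcomes = pipelines.play_mi_game(
                        decoder, pcfg, n_trials=config.n_game_trials_mi,
                        max_steps=config.mi_timeout_windows,
                    )
                elif session == "P300":
                    rec, events = simulate.gen_p300_session(pcfg)
                    decoder = pipelines.train_p300(
                        rec, events, k=config.k_folds, seed=config.seed,
                        n_filters=config.n_xdawn_filters, shrinkage=config.shrinkage,
                    )
                    outcomes = pipelines.play_p300_game(
                        decoder, pcfg, n_trials=config.n_game_trials_p300,
                    )
                else:
                    continue
                perf = pipelines.game_performance(outcomes)
                records.loc[mask, "performance"] = perf
                m = decoder.training_metrics_
                metric_rows.append({
                    "participant": participant,
                    "session": session,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "game_performance": perf,
                })
        metrics = pd.DataFrame(metric_rows)

        stage = "statistics"
        long = records_to_long(records)
        lmm_vasf = stats.fit_lmm(long, "vasf", ("session", "time"))
        lmm_alpha = stats.fit_lmm(long, "alpha", ("session", "time"))
        d = records.dropna(subset=["alpha_pre", "alpha_post"]).copy()
        d["d_vasf"] = d["vasf_post"] - d["vasf_pre"]
        d["d_alpha"] = d["alpha_post"] - d["alpha_pre"]
        rm = stats.rmcorr(d, "d_vasf", "d_alpha")
        # test-retest reliability across the first two visits (pre-task values)
        rel = {}
        wide = records.pivot_table(index="participant", columns="order",
                                   values=["vasf_pre", "alpha_pre"])
        for outcome in ("vasf_pre", "alpha_pre"):
            pair = wide[outcome][[1, 2]].dropna()
            rel[outcome.replace("_pre", "")] = stats.sem_from_pairs(
                pair[1].to_numpy(), pair[2].to_numpy()
            )
        results = {
            "records": records,
            "metrics": metrics,
            "lmm_vasf": lmm_vasf,
            "lmm_alpha": lmm_alpha,
            "rmcorr_fatigue_alpha": rm,
            "reliability": rel,
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest()[:12],
        }
    except Exception as err:
        if out_dir is not None:
            _flush(records, pd.DataFrame(metric_rows), Path(out_dir))
        raise RuntimeError(f"study failed during stage '{stage}': {err}") from err

    logger.info("study complete: seed=%d config=%s participants=%d",
                config.seed, results["config_hash"], len(participants))
    if out_dir is not None:
        _flush(records, metrics, Path(out_dir), results)
    return results


def _flush(records: pd.DataFrame, metrics: pd.DataFrame, out_dir: Path,
           results: dict | None = None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    records.to_csv(out_dir / "session_records.csv", index=False)
    metrics.to_csv(out_dir / "decoder_metrics.csv", index=False)
    if results is not None:
        eff_rows = []
        for name, lmm in (("vasf", results["lmm_vasf"]), ("alpha", results["lmm_alpha"])):
            for term, t in lmm.fixed_effects.items():
                eff_rows.append({"outcome": name, "term": term, **t, "aic": lmm.aic})
        pd.DataFrame(eff_rows).to_csv(out_dir / "fixed_effects.csv", index=False)
        rel_rows = [
            {"outcome": k, "sem": v.sem, "mdc95": v.mdc95}
            for k, v in results["reliability"].items()
        ]
        pd.DataFrame(rel_rows).to_csv(out_dir / "reliability.csv", index=False)
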