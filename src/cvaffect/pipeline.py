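"""End-to-end orchestration: simulate -> featurize -> train -> evaluate ->
interpret -> coder curves, with a deterministic CSV report set.

Every report CSV starts with a ``# config_hash=...`` comment line so any
artifact can be traced back to the exact resolved configuration; two runs with
the same configuration and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import simulate as sim
from .agreement import agreement_report, condition_wise_evaluation, within_participant_performance
from .coder import fit_per_coder, subsample_importance_curve
from .interpret import partial_dependence, pd_importance, pd_interaction_importance
from .model import (ModelSpec, average_coder_ratings, predict_ratings,
                    repeated_split_evaluation, split_by_participant,
                    train_rating_model)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cvaffect")

VALENCES = ("positive", "negative")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    simulation: sim.SimulationConfig | None = field(default_factory=sim.SimulationConfig)
    timeseries_csv: str | None = None     # used instead of simulation if set
    ratings_csv: str | None = None
    gap_threshold: float = 1.0
    participant_threshold: float = 0.5
    n_trees: int = 500
    m_try: int | None = None
    train_fraction: float = 0.66
    run_conditions: bool = True
    run_importance: bool = True
    run_coder_curves: bool = False
    n_splits: int = 0                      # repeated-split sensitivity (0 = off)
    grid_points: int = 25
    importance_subsample: int = 1000
    interaction_grid_points: int = 10
    interaction_subsample: int = 300
    subsample_n_grid: tuple[int, ...] | None = None
    subsample_iterations: int = 30

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = sim.SimulationConfig.from_dict(raw["simulation"])
        if raw.get("subsample_n_grid"):
            raw["subsample_n_grid"] = tuple(raw["subsample_n_grid"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    def hash(self) -> str:
        payload = yaml.safe_dump(self.resolved(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every enabled stage, writing reports under ``out_dir``.

    Returns a summary dict of the headline numbers.  Any stage failure aborts
    with the stage name attached to the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": h, **config.resolved()}, fh, sort_keys=True)

    root = np.random.SeedSequence(config.seed)
    (split_ss, model_ss, cond_ss, sens_ss, coder_ss) = root.spawn(5)
    spec = ModelSpec(n_trees=config.n_trees, m_try=config.m_try)
    summary: dict = {"config_hash": h}

    stage = "simulate"
    try:
        if config.timeseries_csv:
            recordings = feat.read_au_timeseries(config.timeseries_csv)
            ratings = pd.read_csv(config.ratings_csv)
        else:
            simcfg = config.simulation or sim.SimulationConfig()
            recordings, truth, ratings = sim.simulate_study(simcfg)
        log.info("simulate: %d recordings", len(recordings))

        stage = "featurize"
        matrix, report = feat.featurize_recordings(
            recordings, config.gap_threshold, config.participant_threshold)
        _write_csv(report.excluded_recordings, out / "exclusions.csv", h)
        _write_csv(report.excluded_participants, out / "excluded_participants.csv", h)
        _write_csv(matrix, out / "features.csv", h, index=True)
        _write_csv(ratings, out / "ratings.csv", h)
        summary["n_retained"] = report.n_retained
        summary["n_excluded"] = report.n_input - report.n_retained
        log.info("featurize: retained %d of %d recordings",
                 report.n_retained, report.n_input)

        for vi, valence in enumerate(VALENCES):
            stage = f"train/{valence}"
            outcome = average_coder_ratings(ratings, valence).loc[matrix.index]
            seed_split = int(split_ss.spawn(vi + 1)[vi].generate_state(1)[0] % 2**31)
            seed_model = int(model_ss.spawn(vi + 1)[vi].generate_state(1)[0] % 2**31)
            plan = split_by_participant(matrix, config.train_fraction, seed_split)
            model = train_rating_model(matrix.loc[plan.train_ids],
                                       outcome.loc[plan.train_ids], spec, seed_model)

            stage = f"evaluate/{valence}"
            pred_test = predict_ratings(model, matrix.loc[plan.test_ids])
            pred_train = predict_ratings(model, matrix.loc[plan.train_ids])
            rep_test = agreement_report(pred_test, outcome.loc[plan.test_ids])
            rep_train = agreement_report(pred_train, outcome.loc[plan.train_ids])
            overall = pd.DataFrame([
                {"valence": valence, "set": "train", "pearson_r": rep_train.pearson_r,
                 "r_ci_low": rep_train.r_ci[0], "r_ci_high": rep_train.r_ci[1],
                 "icc1": rep_train.icc_value, "n": len(plan.train_ids)},
                {"valence": valence, "set": "test", "pearson_r": rep_test.pearson_r,
                 "r_ci_low": rep_test.r_ci[0], "r_ci_high": rep_test.r_ci[1],
                 "icc1": rep_test.icc_value, "n": len(plan.test_ids)},
            ])
            _write_csv(overall, out / f"agreement_overall_{valence}.csv", h)
            summary[f"test_r_{valence}"] = rep_test.pearson_r
            summary[f"test_icc1_{valence}"] = rep_test.icc_value
            log.info("%s: test r=%.3f icc1=%.3f", valence,
                     rep_test.pearson_r, rep_test.icc_value)

            wp, medians = within_participant_performance(
                pred_test, outcome.loc[plan.test_ids],
                matrix.loc[plan.test_ids, "participant_id"])
            _write_csv(wp, out / f"within_participant_{valence}.csv", h)
            summary[f"median_within_r_{valence}"] = medians["median_r"]

            if config.run_conditions:
                stage = f"conditions/{valence}"
                seed_cond = int(cond_ss.spawn(vi + 1)[vi].generate_state(1)[0] % 2**31)
                table = condition_wise_evaluation(matrix, outcome, spec, seed_cond,
                                                  config.train_fraction)
                _write_csv(table, out / f"agreement_by_condition_{valence}.csv", h)

            if config.run_importance:
                stage = f"interpret/{valence}"
                full_model = train_rating_model(matrix, outcome, spec, seed_model)
                profile = pd_importance(full_model, matrix,
                                        grid_points=config.grid_points,
                                        subsample=config.importance_subsample,
                                        seed=config.seed)
                imp = profile.normalize().values.rename("share").to_frame()
                imp.insert(0, "importance", profile.values)
                imp.index.name = "au"
                _write_csv(imp, out / f"importance_{valence}.csv", h, index=True)
                inter = pd_interaction_importance(
                    full_model, matrix, grid_points=config.interaction_grid_points,
                    subsample=config.interaction_subsample, seed=config.seed)
                _write_csv(inter.table, out / f"interactions_{valence}.csv", h)
                curves = []
                for au in profile.top(5):
                    c = partial_dependence(full_model, matrix, au,
                                           grid_points=config.grid_points)
                    curves.append(pd.DataFrame(
                        {"au": au, "grid": c.grid, "pd": c.values}))
                _write_csv(pd.concat(curves, ignore_index=True),
                           out / f"pd_curves_{valence}.csv", h)
                summary[f"top_aus_{valence}"] = profile.top(3)

            if config.n_splits > 0:
                stage = f"split_sensitivity/{valence}"
                seed_sens = int(sens_ss.spawn(vi + 1)[vi].generate_state(1)[0] % 2**31)
                sens = repeated_split_evaluation(matrix, outcome, config.n_splits,
                                                 spec, seed_sens, config.train_fraction)
                _write_csv(sens, out / f"split_sensitivity_{valence}.csv", h)
                summary[f"split_r_mean_{valence}"] = float(sens["pearson_r"].mean())
                summary[f"split_r_sd_{valence}"] = float(sens["pearson_r"].std(ddof=1))

        if config.run_coder_curves:
            stage = "coder_curves"
            n_grid = config.subsample_n_grid
            if n_grid is None:
                from .coder import DEFAULT_N_GRID
                n_grid = DEFAULT_N_GRID
            coders = sorted(ratings["coder_id"].unique())
            seeds = coder_ss.spawn(len(coders) * 2)
            k = 0
            for coder in coders:
                sub = ratings[ratings["coder_id"] == coder].set_index("recording_id")
                for valence in VALENCES:
                    y = sub.loc[matrix.index, f"{valence}_rating"].astype(float)
                    curve = subsample_importance_curve(
                        matrix, y, n_grid=n_grid,
                        iterations=config.subsample_iterations,
                        seed=int(seeds[k].generate_state(1)[0] % 2**31),
                        spec=spec, coder_id=coder, valence=valence)
                    _write_csv(curve.table,
                               out / f"coder_curve_{coder}_{valence}.csv", h)
                    k += 1
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(_plain(summary), fh, sort_keys=True)
    return summary


def _plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out
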