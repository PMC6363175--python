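"""Per-coder model fits and the subsampling reliability (randomization) test.

For each coder, a forest is fit to that coder's own ratings (not the panel
average) and a PD importance profile extracted.  The randomization test then
asks how many rated recordings are needed to recover that coder's profile:
for each subsample size n, draw n recordings without replacement, refit, and
compute the ICC(2, average) between the subsample profile and the full-data
profile; repeat for several iterations and trace the mean curve.  An
ICC(2) of .75 is the conventional "excellent" reference level, reported via
:func:`crossing_n` rather than hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import icc
from .interpret import ImportanceProfile, pd_importance, importance_agreement
from .model import ModelSpec, train_rating_model

__all__ = [
    "DEFAULT_N_GRID",
    "SubsampleCurve",
    "fit_per_coder",
    "subsample_importance_curve",
    "crossing_n",
]

#: Subsample sizes used by the full-scale randomization test.
DEFAULT_N_GRID: tuple[int, ...] = (
    10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95,
    100, 105, 115, 125, 135, 150, 200, 250, 300, 350, 400, 450, 500, 550,
    600, 650, 700, 750, 800, 850, 900, 950, 1000, 1200, 1400, 1600, 1800,
    2000, 2500, 3000,
)


@dataclass
class SubsampleCurve:
    """Mean ICC(2, average) vs subsample size for one coder and valence."""

    table: pd.DataFrame          # columns: n, mean_icc2, se_icc2, iterations
    coder_id: int | str
    valence: str

    @property
    def n_grid(self) -> np.ndarray:
        return self.table["n"].to_numpy()


def fit_per_coder(features: pd.DataFrame, ratings: pd.DataFrame,
                  spec: ModelSpec = ModelSpec(), seed: int = 0,
                  valences: tuple[str, ...] = ("positive", "negative"),
                  importance_kwargs: dict | None = None,
                  ) -> dict[tuple[int, str], tuple[object, ImportanceProfile]]:
    """Fit one forest + importance profile per coder per valence.

    ``ratings`` is the long coder table (recording_id, coder_id,
    positive_rating, negative_rating); each model's outcome is the individual
    coder's rating aligned to the feature matrix rows.
    """
    for col in ("recording_id", "coder_id"):
        if col not in ratings.columns:
            raise ValueError(f"ratings table lacks column {col!r}")
    ikw = dict(importance_kwargs or {})
    root = np.random.SeedSequence(seed)
    coders = sorted(ratings["coder_id"].unique())
    out: dict[tuple[int, str], tuple[object, ImportanceProfile]] = {}
    seeds = iter(root.spawn(len(coders) * len(valences)))
    for coder in coders:
        sub = ratings[ratings["coder_id"] == coder].set_index("recording_id")
        for valence in valences:
            col = f"{valence}_rating"
            if col not in ratings.columns:
                raise ValueError(f"ratings table lacks column {col!r}")
            y = sub.loc[features.index, col].astype(float)
            ss = next(seeds)
            model_seed = int(ss.generate_state(1)[0] % (2**31))
            model = train_rating_model(features, y, spec, seed=model_seed)
            profile = pd_importance(model, features, **ikw)
            out[(coder, valence)] = (model, profile)
    return out


def subsample_importance_curve(features: pd.DataFrame, coder_ratings: pd.Series,
                               n_grid=DEFAULT_N_GRID, iterations: int = 30,
                               seed: int = 0, spec: ModelSpec = ModelSpec(),
                               coder_id: int | str = 0, valence: str = "positive",
                               model_seed: int | None = None,
                               importance_kwargs: dict | None = None,
                               full_profile: ImportanceProfile | None = None,
                               ) -> SubsampleCurve:
    """Randomization test: profile recovery as a function of sample size.

    For each n in ``n_grid`` (sizes above the available recording count are
    skipped with a warning) and each of ``iterations`` repetitions: sample n
    recordings without replacement, refit the forest, extract the PD
    importance profile, and score its ICC(2, average) against the full-data
    profile.  Each iteration uses its own random sub-stream for both the
    subsample and (unless ``model_seed`` is pinned) the forest, so sampling
    and forest variability are pooled, as in the study design.  Sampled row
    indices are sorted, so the n = N subsample is the full data set itself.
    """
    if iterations < 2:
        raise ValueError("need at least 2 iterations to estimate a standard error")
    ikw = dict(importance_kwargs or {})
    y = coder_ratings.loc[features.index].astype(float)
    n_total = len(features)
    root = np.random.SeedSequence(seed)

    if full_profile is None:
        full_seed = model_seed if model_seed is not None else int(
            root.generate_state(1)[0] % (2**31))
        full_model = train_rating_model(features, y, spec, seed=full_seed)
        full_profile = pd_importance(full_model, features, **ikw)

    usable = [n for n in n_grid if n <= n_total]
    skipped = [n for n in n_grid if n > n_total]
    if skipped:
        warnings.warn(f"skipping subsample sizes beyond the {n_total} available "
                      f"recordings: {skipped}")

    rows = []
    grid_seeds = root.spawn(len(usable))
    for n, nss in zip(usable, grid_seeds):
        iccs = []
        for it_ss in nss.spawn(iterations):
            sample_seed, fit_seed = [int(s.generate_state(1)[0] % (2**31))
                                     for s in it_ss.spawn(2)]
            rng = np.random.default_rng(sample_seed)
            rows_idx = np.sort(rng.choice(n_total, size=n, replace=False))
            sub = features.iloc[rows_idx]
            sub_y = y.iloc[rows_idx]
            fit_seed = model_seed if model_seed is not None else fit_seed
            model = train_rating_model(sub, sub_y, spec, seed=fit_seed)
            profile = pd_importance(model, sub, **ikw)
            rep = importance_agreement(profile, full_profile,
                                       icc_model=2, icc_unit="average")
            iccs.append(rep.icc_value)
        iccs = np.asarray(iccs)
        rows.append({"n": n, "mean_icc2": float(iccs.mean()),
                     "se_icc2": float(iccs.std(ddof=1) / np.sqrt(len(iccs))),
                     "iterations": len(iccs)})
    return SubsampleCurve(table=pd.DataFrame(rows), coder_id=coder_id,
                          valence=valence)


def crossing_n(curve: SubsampleCurve, threshold: float = 0.75) -> int | None:
    """Smallest subsample size whose mean ICC(2) reaches ``threshold``."""
    hit = curve.table[curve.table["mean_icc2"] >= threshold]
    return int(hit["n"].iloc[0]) if len(hit) else None
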