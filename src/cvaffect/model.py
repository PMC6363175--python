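"""Random-forest affect-intensity regression with the study's split design.

The outcome for the main models is the arithmetic mean of the coder panel's
ratings per recording; per-coder models use an individual coder's ratings.
Forests use 500 trees and mtry = floor(p/3) candidate predictors per split
(p = number of AU predictors, so 6 for the standard 20-AU set), with bootstrap
resampling per tree.  Train/test splits are stratified *within* participant:
66% of each participant's recordings train the model, the rest test it, so
every participant contributes to both sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .agreement import agreement_report, AgreementReport
from .features import au_columns

__all__ = [
    "ModelSpec",
    "AffectIntensityForest",
    "SplitPlan",
    "split_by_participant",
    "average_coder_ratings",
    "train_rating_model",
    "predict_ratings",
    "repeated_split_evaluation",
]


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one affect-intensity forest."""

    n_trees: int = 500
    m_try: int | None = None          # None -> floor(p / 3), at least 1
    valence_target: str = "positive"

    def resolve_m_try(self, p: int) -> int:
        m = self.m_try if self.m_try is not None else max(1, p // 3)
        if not 1 <= m <= p:
            raise ValueError(f"m_try={m} outside [1, {p}]")
        return m


class AffectIntensityForest(RegressorMixin, BaseEstimator):
    """Random-forest regressor mapping AU point estimates to affect intensity.

    A thin scikit-learn estimator around :class:`RandomForestRegressor` that
    resolves ``m_try`` from the number of predictors at fit time, records the
    training feature ranges and outcome range, and validates feature alignment
    at predict time.  Because a forest averages training outcomes, predictions
    are always bounded by the training outcome range; no clipping to the 1-7
    rating scale is applied.

    Parameters
    ----------
    n_trees : int, default 500
        Trees in the forest.
    m_try : int or None, default None
        Candidate predictors per split; None resolves to ``floor(p/3)``.
    random_state : int or None
        Seed for bootstrap resampling and split sampling.
    """

    def __init__(self, n_trees: int = 500, m_try: int | None = None,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.m_try = m_try
        self.random_state = random_state

    def fit(self, X, y):
        X_arr, names = _as_matrix(X)
        y_arr = np.asarray(y, float).ravel()
        if len(y_arr) != len(X_arr):
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(X_arr)) or not np.all(np.isfinite(y_arr)):
            raise ValueError("non-finite values in features or outcome")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        p = X_arr.shape[1]
        self.m_try_ = ModelSpec(self.n_trees, self.m_try).resolve_m_try(p)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees, max_features=self.m_try_,
            bootstrap=True, random_state=self.random_state, n_jobs=1,
        ).fit(X_arr, y_arr)
        self.y_range_ = (float(y_arr.min()), float(y_arr.max()))
        self.feature_range_ = pd.DataFrame(
            {"min": X_arr.min(axis=0), "max": X_arr.max(axis=0)}, index=names)
        return self

    def predict(self, X) -> np.ndarray:
        X_arr = self._check_features(X)
        return self.forest_.predict(X_arr)

    def _check_features(self, X) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise ValueError("estimator is not fitted")
        X_arr, names = _as_matrix(X)
        if isinstance(X, pd.DataFrame):
            if list(names) != list(self.feature_names_in_):
                raise ValueError(
                    "feature columns do not match training columns: "
                    f"{list(names)[:3]}... vs {list(self.feature_names_in_)[:3]}...")
        elif X_arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got {X_arr.shape[1]}")
        return X_arr


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Coerce a feature table to (array, column names), dropping metadata."""
    if isinstance(X, pd.DataFrame):
        aus = au_columns(X)
        cols = aus if aus else list(X.columns)
        return X[cols].to_numpy(float), cols
    arr = np.asarray(X, float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


@dataclass
class SplitPlan:
    """Per-recording train/test assignment from a participant-stratified split."""

    assignment: pd.Series            # recording_id -> 'train' | 'test'
    train_fraction: float
    seed: int

    @property
    def train_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "train"]

    @property
    def test_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "test"]


def split_by_participant(table: pd.DataFrame, train_fraction: float = 0.66,
                         seed: int = 0, participant_disjoint: bool = False,
                         ) -> SplitPlan:
    """Randomly assign round(train_fraction * n_i) of each participant's
    recordings to the training set (round-half-up), remainder to test.

    The count is clamped to [1, n_i - 1] for participants with >= 2 recordings
    so that everyone appears in both sets; a participant with a single
    recording triggers a warning and goes to the training set.

    With ``participant_disjoint=True`` the alternative folding scheme is used
    instead: whole participants are shuffled into the training set until it
    holds at least ``train_fraction`` of all recordings, so no participant
    appears in both sets.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if "participant_id" not in table.columns:
        raise ValueError("table must carry a participant_id column")
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=table.index, dtype=object)
    if participant_disjoint:
        pids = table["participant_id"].unique()
        rng.shuffle(pids)
        target = train_fraction * len(table)
        sizes = table["participant_id"].value_counts()
        taken = 0
        train_pids = set()
        for pid in pids:
            if taken >= target:
                break
            train_pids.add(pid)
            taken += int(sizes[pid])
        if len(train_pids) == len(pids):  # keep the test set non-empty
            train_pids.discard(pids[-1])
        is_train = table["participant_id"].isin(train_pids)
        assignment.loc[is_train] = "train"
        assignment.loc[~is_train] = "test"
        return SplitPlan(assignment=assignment, train_fraction=train_fraction,
                         seed=seed)
    for pid, g in table.groupby("participant_id", sort=True):
        n = len(g)
        if n == 1:
            warnings.warn(f"participant {pid} has a single recording; assigned to train")
            assignment.loc[g.index] = "train"
            continue
        n_train = int(np.floor(train_fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        train_pos = rng.choice(n, size=n_train, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[train_pos] = True
        assignment.loc[g.index[mask]] = "train"
        assignment.loc[g.index[~mask]] = "test"
    return SplitPlan(assignment=assignment, train_fraction=train_fraction, seed=seed)


def average_coder_ratings(ratings: pd.DataFrame, valence: str) -> pd.Series:
    """Arithmetic mean over coders of one valence's ratings, per recording."""
    col = f"{valence}_rating"
    if col not in ratings.columns:
        raise ValueError(f"ratings table lacks column {col!r}")
    return ratings.groupby("recording_id")[col].mean().rename(f"{valence}_mean")


def train_rating_model(features: pd.DataFrame, outcome: pd.Series,
                       spec: ModelSpec = ModelSpec(), seed: int | None = None,
                       ) -> AffectIntensityForest:
    """Fit an affect-intensity forest; rows of features and outcome aligned."""
    outcome = outcome.loc[features.index] if isinstance(outcome, pd.Series) else outcome
    est = AffectIntensityForest(n_trees=spec.n_trees, m_try=spec.m_try,
                                random_state=seed)
    return est.fit(features, outcome)


def predict_ratings(model: AffectIntensityForest, features) -> np.ndarray:
    """Model-generated ratings (real-valued, rating units, unclipped)."""
    return model.predict(features)


def repeated_split_evaluation(features: pd.DataFrame, outcome: pd.Series,
                              n_splits: int = 1000,
                              spec: ModelSpec = ModelSpec(),
                              seed: int = 0,
                              train_fraction: float = 0.66) -> pd.DataFrame:
    """Sensitivity of test-set performance to the train/test split.

    Repeats (split, fit, evaluate) ``n_splits`` times; each repetition draws
    its split seed and forest seed from an independent sub-stream of ``seed``,
    so repetitions are independent and the whole analysis is reproducible.
    Returns one row per split with test-set Pearson r and ICC(1, single).
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for i, ss in enumerate(root.spawn(n_splits)):
        split_seed, model_seed = [int(s.generate_state(1)[0] % (2**31))
                                  for s in ss.spawn(2)]
        plan = split_by_participant(features, train_fraction=train_fraction,
                                    seed=split_seed)
        model = train_rating_model(features.loc[plan.train_ids],
                                   outcome.loc[plan.train_ids], spec, seed=model_seed)
        pred = predict_ratings(model, features.loc[plan.test_ids])
        rep: AgreementReport = agreement_report(
            pred, outcome.loc[plan.test_ids].to_numpy(), icc_model=1, icc_unit="single")
        rows.append({"split": i, "pearson_r": rep.pearson_r, "icc1": rep.icc_value,
                     "n_train": len(plan.train_ids), "n_test": len(plan.test_ids)})
    return pd.DataFrame(rows)
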