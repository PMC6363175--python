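"""Partial-dependence interpretation of fitted affect-intensity forests.

Partial dependence (PD) of a feature is the model's expected prediction as a
function of that feature, averaging over the observed values of all others:
PD(v) = mean_i f(x_i with x_s := v).  The importance of a feature is the
standard deviation of its PD curve over a quantile grid — for a linear
predictor f(x) = beta * x this reduces to |beta| * SD(grid), which ties the
measure back to regression beta weights.  Pairwise interaction importance uses
the two-direction conditional-SD statistic on the 2-D PD surface: the SD
across one axis is computed at each value of the other axis, the variability
of those conditional SDs is taken, and the two directions are averaged.

Two computation paths give identical results (up to float summation order):
a naive row-substitution loop ("brute") and an exact single-traversal tree
kernel ("tree") that makes scanning all p(p-1)/2 AU pairs tractable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _pdtree
from .agreement import (AgreementReport, UndefinedCorrelationError, icc,
                        pearson_ci)
from .features import au_columns

__all__ = [
    "PDCurve",
    "PDSurface",
    "ImportanceProfile",
    "InteractionMatrix",
    "quantile_grid",
    "partial_dependence",
    "pd_importance",
    "pd_interaction_importance",
    "importance_agreement",
]


@dataclass
class PDCurve:
    feature: str
    grid: np.ndarray
    values: np.ndarray          # predicted outcome, rating units

    def importance(self) -> float:
        """SD of the PD values over the grid (sample SD, ddof=1)."""
        return float(np.std(self.values, ddof=1))


@dataclass
class PDSurface:
    feature_i: str
    feature_j: str
    grid_i: np.ndarray
    grid_j: np.ndarray
    values: np.ndarray          # shape (len(grid_i), len(grid_j))

    def interaction_importance(self) -> float:
        """Two-direction conditional-SD (Greenwell-style) statistic."""
        sd_i_given_j = np.std(self.values, axis=0, ddof=1)
        sd_j_given_i = np.std(self.values, axis=1, ddof=1)
        return float((np.std(sd_i_given_j, ddof=1) + np.std(sd_j_given_i, ddof=1)) / 2)


@dataclass
class ImportanceProfile:
    """Per-AU PD importance for one fitted model."""

    values: pd.Series            # index: feature names; nonnegative
    normalized: bool = False

    def normalize(self) -> "ImportanceProfile":
        total = self.values.sum()
        if total == 0:
            return ImportanceProfile(self.values.copy(), normalized=True)
        return ImportanceProfile(self.values / total, normalized=True)

    def top(self, k: int) -> list[str]:
        return list(self.values.sort_values(ascending=False).index[:k])


@dataclass
class InteractionMatrix:
    """Pairwise PD interaction importance over all unordered feature pairs."""

    table: pd.DataFrame          # columns: feature_i, feature_j, score, share

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def top(self, k: int) -> pd.DataFrame:
        return self.table.sort_values("score", ascending=False).head(k)

    def matrix(self) -> pd.DataFrame:
        feats = sorted(set(self.table["feature_i"]) | set(self.table["feature_j"]))
        m = pd.DataFrame(np.nan, index=feats, columns=feats)
        for _, row in self.table.iterrows():
            m.loc[row["feature_i"], row["feature_j"]] = row["score"]
            m.loc[row["feature_j"], row["feature_i"]] = row["score"]
        return m


def quantile_grid(x, n_points: int = 25, lo: float = 0.025, hi: float = 0.975,
                  ) -> np.ndarray:
    """Equally spaced empirical quantiles of a feature's distribution.

    Quantile grids keep the PD evaluation inside the data's bulk instead of
    letting outliers stretch the range.
    """
    if n_points < 2:
        raise ValueError("a PD grid needs at least 2 points")
    return np.quantile(np.asarray(x, float), np.linspace(lo, hi, n_points))


def _resolve(model, data):
    """Feature matrix (rows x model features), names, and the raw forest."""
    names = list(getattr(model, "feature_names_in_", []))
    if isinstance(data, pd.DataFrame):
        cols = names if names else au_columns(data)
        X = data[cols].to_numpy(float)
        names = cols
    else:
        X = np.asarray(data, float)
        if not names:
            names = [f"x{i}" for i in range(X.shape[1])]
    forest = getattr(model, "forest_", None)
    if forest is None and hasattr(model, "estimators_"):
        forest = model
    return X, names, forest


def _feature_name(feature, names) -> str:
    if isinstance(feature, (int, np.integer)):
        label = f"AU{int(feature):02d}"
        if label in names:
            return label
        return names[int(feature)]
    if feature not in names:
        raise ValueError(f"{feature!r} is not among the model's features")
    return str(feature)


def _check_range(model, name, grid):
    fr = getattr(model, "feature_range_", None)
    if fr is not None and name in fr.index:
        if grid.min() < fr.loc[name, "min"] or grid.max() > fr.loc[name, "max"]:
            warnings.warn(f"PD grid for {name} extends outside the training range "
                          "(extrapolation)")


def _brute_pd(model, X, col_idx, grid) -> np.ndarray:
    out = np.empty(len(grid))
    work = X.copy()
    for g, v in enumerate(grid):
        work[:, col_idx] = v
        out[g] = float(np.mean(model.predict(work)))
        work[:, col_idx] = X[:, col_idx]
    return out


def _brute_pd2(model, X, ci, cj, grid_i, grid_j) -> np.ndarray:
    out = np.empty((len(grid_i), len(grid_j)))
    work = X.copy()
    for a, vi in enumerate(grid_i):
        for b, vj in enumerate(grid_j):
            work[:, ci] = vi
            work[:, cj] = vj
            out[a, b] = float(np.mean(model.predict(work)))
    return out


def partial_dependence(model, data, features, grid=None, grid_points: int = 25,
                       method: str = "auto"):
    """PD curve (one feature) or surface (a pair) by exact averaging.

    ``method``: 'brute' substitutes grid values row by row through
    ``model.predict``; 'tree' uses the exact single-traversal kernel (tree
    ensembles only); 'auto' picks 'tree' when available.  Grids default to
    25 equally spaced 2.5%-97.5% quantiles of each feature in ``data``.
    """
    X, names, forest = _resolve(model, data)
    if X.shape[0] == 0:
        raise ValueError("data is empty")
    single = isinstance(features, (str, int, np.integer))
    feats = [features] if single else list(features)
    cols = [_feature_name(f, names) for f in feats]
    idx = [names.index(c) for c in cols]

    if grid is None:
        grids = [quantile_grid(X[:, i], n_points=grid_points) for i in idx]
    else:
        grids = [np.asarray(grid, float)] if single else [np.asarray(g, float) for g in grid]
    grids = [np.sort(g) for g in grids]
    for c, g in zip(cols, grids):
        _check_range(model, c, g)

    use_tree = method == "tree" or (method == "auto" and forest is not None)
    if use_tree and forest is None:
        raise ValueError("method='tree' requires a tree-ensemble model")

    # sklearn trees compare float32-cast inputs against float64 thresholds;
    # replicate exactly so the traversal matches brute-force substitution
    X32 = X.astype(np.float32)
    grids32 = [g.astype(np.float32) for g in grids]

    if single:
        if use_tree:
            packed = _packed(forest)
            vals = _pdtree.pd_grid_1d(*packed, X32, idx[0], grids32[0])
        else:
            vals = _brute_pd(model, X, idx[0], grids[0])
        return PDCurve(feature=cols[0], grid=grids[0], values=vals)

    if len(cols) != 2:
        raise ValueError("features must be a single feature or a pair")
    if use_tree:
        packed = _packed(forest)
        vals = _pdtree.pd_grid_2d(*packed, X32, idx[0], idx[1],
                                  grids32[0], grids32[1])
    else:
        vals = _brute_pd2(model, X, idx[0], idx[1], grids[0], grids[1])
    return PDSurface(feature_i=cols[0], feature_j=cols[1],
                     grid_i=grids[0], grid_j=grids[1], values=vals)


def _packed(forest):
    key = "_cvaffect_packed"
    cached = getattr(forest, key, None)
    if cached is None:
        cached = _pdtree.pack_forest(forest)
        try:
            setattr(forest, key, cached)
        except AttributeError:  # pragma: no cover
            pass
    return cached


def _subsample(X: np.ndarray, cap: int | None, seed: int) -> np.ndarray:
    if cap is None or len(X) <= cap:
        return X
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(len(X), size=cap, replace=False))
    return X[rows]


def pd_importance(model, data, grid_points: int = 25, subsample: int | None = 1000,
                  seed: int = 0, normalize: bool = False,
                  method: str = "auto") -> ImportanceProfile:
    """PD-based importance of every model feature.

    importance(feature) = SD over the grid of its PD curve.  Rows are
    subsampled (fixed seed) beyond ``subsample`` for tractability; grids are
    always computed from the full ``data``.
    """
    if grid_points < 2:
        raise ValueError("importance needs a grid of at least 2 points")
    X, names, _ = _resolve(model, data)
    Xs = _subsample(X, subsample, seed)
    values = {}
    for i, name in enumerate(names):
        grid = quantile_grid(X[:, i], n_points=grid_points)
        curve = partial_dependence(model, Xs, name, grid=grid, method=method)
        values[name] = curve.importance()
    profile = ImportanceProfile(pd.Series(values, name="importance"))
    return profile.normalize() if normalize else profile


def pd_interaction_importance(model, data, grid_points: int = 10,
                              subsample: int | None = 300, seed: int = 0,
                              normalize: bool = False,
                              method: str = "auto") -> InteractionMatrix:
    """Two-direction conditional-SD interaction importance for all pairs.

    Enumerates every unordered pair of model features (p(p-1)/2 pairs; 190
    for the standard 20-AU set).  ``share`` is each pair's fraction of the
    summed interaction scores.
    """
    if grid_points < 3:
        raise ValueError("interaction grids need at least 3 points per axis")
    X, names, _ = _resolve(model, data)
    if len(names) < 2:
        raise ValueError("interaction analysis needs at least 2 features")
    Xs = _subsample(X, subsample, seed)
    grids = {i: quantile_grid(X[:, i], n_points=grid_points)
             for i in range(X.shape[1])}
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        surf = partial_dependence(model, Xs, (names[i], names[j]),
                                  grid=(grids[i], grids[j]), method=method)
        rows.append({"feature_i": names[i], "feature_j": names[j],
                     "score": surf.interaction_importance()})
    table = pd.DataFrame(rows)
    total = table["score"].sum()
    table["share"] = table["score"] / total if total > 0 else 0.0
    if normalize and total > 0:
        table["score"] = table["score"] / total
    return InteractionMatrix(table=table)


def importance_agreement(profile_a: ImportanceProfile, profile_b: ImportanceProfile,
                         icc_model: int = 3, icc_unit: str = "average",
                         ) -> AgreementReport:
    """ICC between two importance profiles (AUs as items, profiles as raters)."""
    a, b = profile_a.values, profile_b.values
    if set(a.index) != set(b.index):
        raise ValueError("importance profiles cover different AU sets")
    b = b.reindex(a.index)
    rep = icc(np.column_stack([a.to_numpy(), b.to_numpy()]),
              model=icc_model, unit=icc_unit)
    try:
        rep.pearson_r, rep.r_ci = pearson_ci(a.to_numpy(), b.to_numpy())
    except (UndefinedCorrelationError, ValueError):
        pass
    return rep
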