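"""Correlation and intraclass-correlation (ICC) agreement machinery.

ICCs follow the McGraw & Wong mean-squares estimators.  With n items rated by
k raters, let MSB/MSW be the one-way between/within-item mean squares and
MSR/MSC/MSE the two-way item, rater, and residual mean squares:

=====================  =====================================================
ICC(1, single)         (MSB - MSW) / (MSB + (k-1) MSW)
ICC(1, average)        (MSB - MSW) / MSB
ICC(2, single)         (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
ICC(2, average)        (MSR - MSE) / (MSR + (MSC - MSE) / n)
ICC(3, single)         (MSR - MSE) / (MSR + (k-1) MSE)
ICC(3, average)        (MSR - MSE) / MSR
=====================  =====================================================

Negative ICCs are reported as computed (never truncated at zero): columns that
disagree more within items than between items legitimately yield ICC < 0.

Model-vs-human item agreement throughout the package uses ICC(1, single)
(one-way random, absolute agreement regardless of condition/participant);
coder-panel and importance-profile agreement use ICC(3, average); the
subsampling reliability analysis uses ICC(2, average).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "UndefinedCorrelationError",
    "InsufficientDataError",
    "pearson_ci",
    "icc",
    "within_participant_performance",
    "variance_performance_association",
    "condition_wise_evaluation",
]


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance in one of the vectors)."""


class InsufficientDataError(ValueError):
    """Too few valid observations for the requested statistic."""


@dataclass
class AgreementReport:
    """Pearson r (with 95% CI) and an ICC comparing two or more rating sets."""

    pearson_r: float | None
    r_ci: tuple[float, float] | None
    icc_value: float
    icc_model: int
    icc_unit: str
    n_items: int
    k_raters: int


def pearson_ci(x, y, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Product-moment correlation with a Fisher-z confidence interval.

    CI: tanh(atanh(r) +/- z_crit / sqrt(n - 3)).  Raises
    :class:`UndefinedCorrelationError` if either vector has zero variance —
    an undefined correlation is signalled, never silently reported as 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise InsufficientDataError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r = float(stats.pearsonr(x, y).statistic)
    zcrit = stats.norm.ppf(0.5 + confidence / 2)
    if abs(r) >= 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(len(x) - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _mean_squares(m: np.ndarray) -> dict[str, float]:
    n, k = m.shape
    grand = m.mean()
    item_means = m.mean(axis=1)
    rater_means = m.mean(axis=0)
    ss_items = k * np.sum((item_means - grand) ** 2)
    ss_raters = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_within = np.sum((m - item_means[:, None]) ** 2)
    ss_error = ss_total - ss_items - ss_raters
    return {
        "MSB": ss_items / (n - 1),
        "MSW": ss_within / (n * (k - 1)),
        "MSR": ss_items / (n - 1),
        "MSC": ss_raters / (k - 1),
        "MSE": ss_error / ((n - 1) * (k - 1)),
    }


def icc(ratings, model: int = 1, unit: str = "single") -> AgreementReport:
    """McGraw-Wong intraclass correlation from an items x raters matrix.

    ``model``: 1 (one-way random), 2 (two-way random, absolute agreement),
    3 (two-way mixed, consistency).  ``unit``: 'single' or 'average'.
    Missing cells are a data error (no imputation is attempted).
    """
    m = np.asarray(ratings, float)
    if isinstance(ratings, pd.DataFrame):
        m = ratings.to_numpy(float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters matrix")
    n, k = m.shape
    if n < 2:
        raise ValueError("need at least 2 items")
    if k < 2:
        raise ValueError("need at least 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings contain missing or non-finite cells")
    if unit not in ("single", "average"):
        raise ValueError(f"unknown unit {unit!r}")
    ms = _mean_squares(m)
    msb, msw = ms["MSB"], ms["MSW"]
    msr, msc, mse = ms["MSR"], ms["MSC"], ms["MSE"]
    if model == 1:
        denom = msb + (k - 1) * msw if unit == "single" else msb
        num = msb - msw
    elif model == 2:
        num = msr - mse
        denom = (msr + (k - 1) * mse + k * (msc - mse) / n if unit == "single"
                 else msr + (msc - mse) / n)
    elif model == 3:
        num = msr - mse
        denom = msr + (k - 1) * mse if unit == "single" else msr
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    value = 1.0 if denom == 0 and num == 0 else float(num / denom)
    return AgreementReport(pearson_r=None, r_ci=None, icc_value=value,
                           icc_model=model, icc_unit=unit, n_items=n, k_raters=k)


def agreement_report(x, y, icc_model: int = 1, icc_unit: str = "single",
                     ) -> AgreementReport:
    """Pearson r (95% CI) plus an ICC between two aligned rating vectors."""
    r, ci = pearson_ci(x, y)
    rep = icc(np.column_stack([np.asarray(x, float), np.asarray(y, float)]),
              model=icc_model, unit=icc_unit)
    rep.pearson_r = r
    rep.r_ci = ci
    return rep


def within_participant_performance(predictions, ratings, participant_ids,
                                   ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-participant model-vs-human agreement.

    Returns a table (participant_id, n, pearson_r, icc1) and the medians over
    participants.  Participants whose human ratings (or predictions) have zero
    variance get NaN and are excluded from the medians, mirroring the
    treatment of undefined correlations.
    """
    df = pd.DataFrame({
        "participant_id": np.asarray(participant_ids),
        "pred": np.asarray(predictions, float),
        "rating": np.asarray(ratings, float),
    })
    rows = []
    for pid, g in df.groupby("participant_id", sort=True):
        row = {"participant_id": pid, "n": len(g)}
        try:
            row["pearson_r"], _ = pearson_ci(g["pred"], g["rating"])
        except (UndefinedCorrelationError, InsufficientDataError):
            row["pearson_r"] = np.nan
        if len(g) >= 2:
            row["icc1"] = icc(g[["rating", "pred"]].to_numpy(),
                              model=1, unit="single").icc_value
        else:
            row["icc1"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    medians = {
        "median_r": float(table["pearson_r"].median(skipna=True)),
        "median_icc1": float(table["icc1"].median(skipna=True)),
    }
    return table, medians


def variance_performance_association(per_participant_r: pd.Series,
                                     rating_sd: pd.Series,
                                     ) -> tuple[float, tuple[float, float]]:
    """Correlation of per-participant accuracy with log rating SD.

    Participants with undefined accuracy or zero rating SD are excluded.
    Raises :class:`InsufficientDataError` with < 4 valid participants.
    """
    df = pd.DataFrame({"r": per_participant_r, "sd": rating_sd}).dropna()
    df = df[df["sd"] > 0]
    if len(df) < 4:
        raise InsufficientDataError(
            f"only {len(df)} participants with defined accuracy and positive SD")
    return pearson_ci(df["r"].to_numpy(), np.log(df["sd"].to_numpy()))


def condition_wise_evaluation(feature_matrix: pd.DataFrame,
                              outcome: pd.Series,
                              spec,
                              seed: int,
                              train_fraction: float = 0.66,
                              ) -> pd.DataFrame:
    """Split/fit/evaluate independently within each task-instruction condition.

    Each condition's recordings get their own participant-stratified split and
    a fresh forest with the identical model spec; the report has one row per
    condition (r, CI, ICC(1, single), train/test counts).  Conditions with too
    few recordings to split are reported with NaN metrics and skipped.
    """
    from .model import split_by_participant, train_rating_model, predict_ratings

    root = np.random.SeedSequence(seed)
    rows = []
    conditions = list(pd.unique(feature_matrix["condition"]))
    seeds = root.spawn(len(conditions))
    for cond, ss in zip(conditions, seeds):
        mask = feature_matrix["condition"] == cond
        sub = feature_matrix.loc[mask]
        y = outcome.loc[sub.index]
        row = {"condition": cond, "n_recordings": int(mask.sum())}
        split_seed, model_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        try:
            plan = split_by_participant(sub, train_fraction=train_fraction,
                                        seed=split_seed)
            model = train_rating_model(sub.loc[plan.train_ids], y.loc[plan.train_ids],
                                       spec, seed=model_seed)
            pred = predict_ratings(model, sub.loc[plan.test_ids])
            rep = agreement_report(pred, y.loc[plan.test_ids].to_numpy(),
                                   icc_model=1, icc_unit="single")
            row.update({"pearson_r": rep.pearson_r, "r_ci_low": rep.r_ci[0],
                        "r_ci_high": rep.r_ci[1], "icc1": rep.icc_value,
                        "n_train": len(plan.train_ids), "n_test": len(plan.test_ids)})
        except (ValueError, UndefinedCorrelationError) as err:
            row.update({"pearson_r": np.nan, "r_ci_low": np.nan, "r_ci_high": np.nan,
                        "icc1": np.nan, "n_train": 0, "n_test": 0,
                        "note": str(err)})
        rows.append(row)
    return pd.DataFrame(rows)
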