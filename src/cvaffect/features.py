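"""AU evidence time-series handling and normalized-AUC featurization.

A recording's per-frame AU evidence series is reduced to one point estimate
per AU: the area under the evidence curve (trapezoid rule over maximal runs of
consecutive face-detected frames) divided by the total face-detected time — a
time-weighted average of signed evidence that is unbiased by detection gaps.
Recordings in which the face is undetected for 1 s or more are excluded, and a
participant with >= 50% of recordings excluded loses all recordings.

The evidence point estimate is kept signed (detector evidence spans roughly
[-16, 16]); no probability transform and no per-subject baseline correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AUTimeSeries",
    "ExclusionReport",
    "FormatError",
    "DataError",
    "UndetectableFaceError",
    "read_au_timeseries",
    "normalized_auc",
    "filter_recordings",
    "build_feature_matrix",
    "featurize_recordings",
]


class FormatError(ValueError):
    """A required column is missing or a file dialect is unrecognised."""


class DataError(ValueError):
    """Structurally valid input with inconsistent content."""


class UndetectableFaceError(DataError):
    """Fewer than 2 face-detected frames: the recording is unusable."""


@dataclass(frozen=True)
class AUTimeSeries:
    """One recording's per-frame AU evidence matrix with detection flags."""

    recording_id: str
    participant_id: str
    condition: str
    block_valence: str
    timestamps: np.ndarray          # seconds, strictly increasing
    face_detected: np.ndarray       # bool per frame
    evidence: np.ndarray            # frames x n_AUs
    au_labels: tuple[int, ...]

    def __post_init__(self):
        t = np.asarray(self.timestamps, float)
        if len(t) != len(self.face_detected) or len(t) != len(self.evidence):
            raise DataError(
                f"{self.recording_id}: timestamps, flags and evidence lengths differ")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DataError(f"{self.recording_id}: timestamps not strictly increasing")
        if self.evidence.shape[1] != len(self.au_labels):
            raise DataError(f"{self.recording_id}: evidence columns != AU labels")
        det = np.asarray(self.face_detected, bool)
        if not np.all(np.isfinite(np.asarray(self.evidence)[det])):
            raise DataError(f"{self.recording_id}: non-finite evidence at detected frames")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def detected_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive detected frames as [start, stop) pairs."""
        return _runs(np.asarray(self.face_detected, bool))

    def longest_undetected_gap(self) -> float:
        """Duration in seconds of the longest contiguous undetected span.

        Each frame occupies the interval from its timestamp to the next
        frame's timestamp; the terminal frame is assigned the median
        inter-frame interval.  A k-frame gap in a uniformly sampled recording
        therefore lasts exactly k / frame_rate seconds.
        """
        det = np.asarray(self.face_detected, bool)
        if det.all():
            return 0.0
        t = np.asarray(self.timestamps, float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        edges = np.append(t, t[-1] + dt)
        longest = 0.0
        for start, stop in _runs(~det):
            longest = max(longest, edges[stop] - edges[start])
        return longest


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


@dataclass
class ExclusionReport:
    """Outcome of the quality filter: who was dropped and why."""

    excluded_recordings: pd.DataFrame   # recording_id, participant_id, reason, longest_gap_s
    excluded_participants: pd.DataFrame  # participant_id, n_recordings, n_excluded, fraction
    n_input: int
    n_retained: int

    def __post_init__(self):
        assert self.n_retained + len(self.excluded_recordings) == self.n_input


# ---------------------------------------------------------------------------
# Reading

_FACET_AU = re.compile(r"^AU(\d+)$")
_OPENFACE_AU = re.compile(r"^\s?AU(\d+)_r$")

_META_DEFAULTS = {"participant_id": None, "condition": "unknown",
                  "block_valence": "unknown"}


def read_au_timeseries(path) -> list[AUTimeSeries]:
    """Read a per-frame AU evidence CSV into one AUTimeSeries per recording.

    Accepts the native dialect written by :mod:`cvaffect.simulate`
    (``recording_id, timestamp_s, face_detected, AU01..``) and an
    OpenFace-style dialect (``timestamp, success, AU01_r..``).  Raises
    :class:`FormatError` naming the missing column, :class:`DataError` on
    non-monotone timestamps.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]

    au_cols: list[tuple[int, str]] = []
    for col in df.columns:
        m = _FACET_AU.match(col) or _OPENFACE_AU.match(col)
        if m:
            au_cols.append((int(m.group(1)), col))
    if not au_cols:
        raise FormatError("no AU evidence columns found (expected AUxx or AUxx_r)")
    au_cols.sort(key=lambda kv: kv[0])

    ts_col = next((c for c in ("timestamp_s", "timestamp") if c in df.columns), None)
    if ts_col is None:
        raise FormatError("missing timestamp column ('timestamp_s' or 'timestamp')")
    face_col = next((c for c in ("face_detected", "success") if c in df.columns), None)
    if face_col is None:
        raise FormatError("missing face-detected column ('face_detected' or 'success')")

    if "recording_id" not in df.columns:
        df = df.assign(recording_id="recording_1")
    meta = {k: (df[k] if k in df.columns else None) for k in _META_DEFAULTS}

    out = []
    labels = tuple(a for a, _ in au_cols)
    cols = [c for _, c in au_cols]
    for rec_id, g in df.groupby("recording_id", sort=False):
        t = g[ts_col].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise DataError(f"{rec_id}: non-monotone timestamps")
        out.append(AUTimeSeries(
            recording_id=str(rec_id),
            participant_id=str(g["participant_id"].iloc[0]) if meta["participant_id"] is not None else str(rec_id),
            condition=str(g["condition"].iloc[0]) if meta["condition"] is not None else "unknown",
            block_valence=str(g["block_valence"].iloc[0]) if meta["block_valence"] is not None else "unknown",
            timestamps=t,
            face_detected=g[face_col].to_numpy().astype(bool),
            evidence=g[cols].to_numpy(float),
            au_labels=labels,
        ))
    return out


# ---------------------------------------------------------------------------
# Featurization

def normalized_auc(ts: AUTimeSeries) -> pd.Series:
    """Normalized-AUC point estimate per AU for one recording.

    Trapezoidal integral of evidence over each maximal run of consecutive
    detected frames, summed across runs, divided by the total detected time
    (sum of run durations).  Runs of a single frame span zero time and are
    dropped from both numerator and denominator.  The result is a
    time-weighted average of signed evidence, so it always lies within the
    [min, max] of the detected-frame evidence.
    """
    t = np.asarray(ts.timestamps, float)
    ev = np.asarray(ts.evidence, float)
    auc = np.zeros(ev.shape[1])
    total_time = 0.0
    for start, stop in ts.detected_runs():
        if stop - start < 2:
            continue  # a single detected frame carries no duration
        auc += np.trapezoid(ev[start:stop], x=t[start:stop], axis=0)
        total_time += t[stop - 1] - t[start]
    if total_time == 0.0:
        raise UndetectableFaceError(
            f"{ts.recording_id}: fewer than 2 consecutive detected frames")
    values = auc / total_time
    return pd.Series(values, index=[f"AU{a:02d}" for a in ts.au_labels],
                     name=ts.recording_id)


def filter_recordings(recordings: Sequence[AUTimeSeries],
                      gap_threshold: float = 1.0,
                      participant_threshold: float = 0.5,
                      ) -> tuple[list[AUTimeSeries], ExclusionReport]:
    """Apply the occlusion quality filter.

    A recording is excluded iff its longest contiguous face-undetected span
    lasts ``gap_threshold`` seconds *or more*; if the excluded fraction of a
    participant's recordings reaches ``participant_threshold`` (>=), all of
    that participant's recordings are excluded.
    """
    if len(recordings) == 0:
        raise DataError("empty recording collection")
    gaps = {r.recording_id: r.longest_undetected_gap() for r in recordings}
    # small tolerance so an exactly-1-s gap is excluded despite float
    # timestamp arithmetic (">= 1 s" ties count as exclusions)
    gap_excluded = {rid for rid, g in gaps.items() if g >= gap_threshold - 1e-9}

    by_participant: dict[str, list[AUTimeSeries]] = {}
    for r in recordings:
        by_participant.setdefault(r.participant_id, []).append(r)

    excluded_rows = []
    part_rows = []
    cascade: set[str] = set()
    for pid, recs in by_participant.items():
        n_exc = sum(1 for r in recs if r.recording_id in gap_excluded)
        frac = n_exc / len(recs)
        if frac >= participant_threshold:
            cascade.add(pid)
            part_rows.append({"participant_id": pid, "n_recordings": len(recs),
                              "n_excluded": n_exc, "excluded_fraction": frac})

    retained = []
    for r in recordings:
        if r.recording_id in gap_excluded:
            excluded_rows.append({
                "recording_id": r.recording_id, "participant_id": r.participant_id,
                "reason": "long_gap", "longest_gap_s": gaps[r.recording_id]})
        elif r.participant_id in cascade:
            excluded_rows.append({
                "recording_id": r.recording_id, "participant_id": r.participant_id,
                "reason": "participant_cascade", "longest_gap_s": gaps[r.recording_id]})
        else:
            retained.append(r)

    report = ExclusionReport(
        excluded_recordings=pd.DataFrame(
            excluded_rows, columns=["recording_id", "participant_id", "reason",
                                    "longest_gap_s"]),
        excluded_participants=pd.DataFrame(
            part_rows, columns=["participant_id", "n_recordings", "n_excluded",
                                "excluded_fraction"]),
        n_input=len(recordings),
        n_retained=len(retained),
    )
    return retained, report


def build_feature_matrix(recordings: Sequence[AUTimeSeries]) -> pd.DataFrame:
    """Featurize retained recordings into a recordings x AUs matrix.

    Columns: participant_id, condition, block_valence metadata followed by the
    AU point estimates in label order; index is recording_id.  No baseline
    correction is applied.
    """
    ids = [r.recording_id for r in recordings]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate recording_id in collection")
    rows = []
    meta = []
    for r in recordings:
        rows.append(normalized_auc(r))
        meta.append({"participant_id": r.participant_id, "condition": r.condition,
                     "block_valence": r.block_valence})
    features = pd.DataFrame(rows)
    features.index.name = "recording_id"
    meta_df = pd.DataFrame(meta, index=features.index)
    return pd.concat([meta_df, features], axis=1)


METADATA_COLUMNS = ("participant_id", "condition", "block_valence")


def au_columns(feature_matrix: pd.DataFrame) -> list[str]:
    """The AU predictor columns of a feature matrix, in stored order."""
    return [c for c in feature_matrix.columns if _FACET_AU.match(c)]


def featurize_recordings(recordings: Sequence[AUTimeSeries],
                         gap_threshold: float = 1.0,
                         participant_threshold: float = 0.5,
                         ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Filter then featurize: the standard preprocessing entry point."""
    retained, report = filter_recordings(recordings, gap_threshold,
                                         participant_threshold)
    usable = []
    extra_rows = []
    for r in retained:
        try:
            normalized_auc(r)  # cheap validity probe happens inside build below
        except UndetectableFaceError:
            extra_rows.append({
                "recording_id": r.recording_id, "participant_id": r.participant_id,
                "reason": "undetectable_face",
                "longest_gap_s": r.longest_undetected_gap()})
            continue
        usable.append(r)
    if extra_rows:
        report = ExclusionReport(
            excluded_recordings=pd.concat(
                [report.excluded_recordings, pd.DataFrame(extra_rows)],
                ignore_index=True),
            excluded_participants=report.excluded_participants,
            n_input=report.n_input,
            n_retained=len(usable),
        )
    return build_feature_matrix(usable), report
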