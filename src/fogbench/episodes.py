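"""Episode extraction and the gold-standard per-subject FOG outcomes.

Three outcomes summarize FOG severity per subject: percent time frozen
(%TF = 100 x frozen time / evaluated time), number of FOG episodes, and
total FOG duration.  Episodes are maximal runs of true samples in a binary
per-sample series (a label channel, or thresholded detector decisions).

Post-processing knobs ``merge_gap_s`` (merge runs separated by short gaps)
and ``min_duration_s`` (drop very short runs) default to 0/off: the
outcomes are well-defined without post-processing, and the knobs exist for
sensitivity analyses of episode splitting/lumping.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import Episode
from .errors import UndefinedMetricError, ValidationError

SPLITS = ("train", "public_test", "private_test")
EVENT_CLASSES = ("start_hesitation", "turn", "walking", "notype")


def extract_episodes(binary: np.ndarray, sampling_rate: float,
                     min_duration_s: float = 0.0, merge_gap_s: float = 0.0,
                     fog_class: str = "any") -> list[Episode]:
    """Runs of true samples -> sorted non-overlapping episodes.

    Runs separated by gaps of at most ``merge_gap_s`` are merged first;
    episodes strictly shorter than ``min_duration_s`` are then dropped.
    """
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be positive")
    b = np.asarray(binary).astype(bool)
    if b.ndim != 1:
        raise ValidationError("binary series must be 1-D")
    edges = np.diff(np.r_[0, b.astype(np.int8), 0])
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if merge_gap_s > 0 and len(starts) > 1:
        gap_samples = starts[1:] - ends[:-1]
        keep = gap_samples > merge_gap_s * sampling_rate
        starts = starts[np.r_[True, keep]]
        ends = ends[np.r_[keep, True]]
    episodes = [Episode(fog_class, int(a), int(b_), sampling_rate)
                for a, b_ in zip(starts, ends)]
    if min_duration_s > 0:
        episodes = [e for e in episodes if e.duration_s >= min_duration_s]
    return episodes


@dataclass
class SubjectSummary:
    """The three gold-standard outcomes for one subject/session set."""

    subject_id: str
    percent_time_frozen: float
    n_episodes: int
    total_duration_s: float


def subject_summary(episodes: Sequence[Episode], mask: np.ndarray,
                    sampling_rate: float, subject_id: str = "") -> SubjectSummary:
    """%TF, episode count and total duration over masked time only."""
    mask = np.asarray(mask).astype(bool)
    masked_samples = int(mask.sum())
    if masked_samples == 0:
        raise UndefinedMetricError("%TF undefined: zero masked observation time")
    frozen_samples = 0
    n_episodes = 0
    for ep in episodes:
        if ep.end > len(mask):
            raise ValidationError("episode extends past the mask")
        in_mask = int(mask[ep.start:ep.end].sum())
        if in_mask:
            n_episodes += 1
            frozen_samples += in_mask
    total_s = frozen_samples / sampling_rate
    return SubjectSummary(
        subject_id=subject_id,
        percent_time_frozen=100.0 * frozen_samples / masked_samples,
        n_episodes=n_episodes,
        total_duration_s=total_s,
    )


def class_time_shares(class_decisions: dict[str, np.ndarray]) -> dict[str, float]:
    """Share (%) of total FOG time per class; classes must be mutually exclusive."""
    keys = list(class_decisions)
    stacked = np.vstack([np.asarray(class_decisions[k]).astype(bool) for k in keys])
    if stacked.sum(axis=0).max(initial=0) > 1:
        raise ValidationError("class decision channels must be mutually exclusive")
    counts = stacked.sum(axis=1).astype(float)
    total = counts.sum()
    if total == 0:
        raise UndefinedMetricError("class shares undefined: zero FOG time")
    return {k: 100.0 * c / total for k, c in zip(keys, counts)}


@dataclass
class EventSummaryTotals:
    """Aggregates of a per-class x per-split event count/duration table."""

    counts: pd.DataFrame        # class x split
    durations_min: pd.DataFrame
    class_totals_counts: pd.Series
    class_totals_durations: pd.Series
    split_totals_counts: pd.Series
    split_totals_durations: pd.Series
    grand_total_events: int
    grand_total_duration_min: float


def dataset_summary(counts: pd.DataFrame, durations_min: pd.DataFrame) -> EventSummaryTotals:
    """Row, column and grand totals of an event-frequency/duration table.

    ``counts`` and ``durations_min`` are class x split tables; absent cells
    (e.g. notype outside the training split) are 0.
    """
    counts = counts.fillna(0.0)
    durations_min = durations_min.fillna(0.0)
    for df, what in ((counts, "counts"), (durations_min, "durations")):
        if (df.to_numpy(dtype=float) < 0).any():
            raise ValidationError(f"negative entry in event {what}")
    return EventSummaryTotals(
        counts=counts,
        durations_min=durations_min,
        class_totals_counts=counts.sum(axis=1),
        class_totals_durations=durations_min.sum(axis=1),
        split_totals_counts=counts.sum(axis=0),
        split_totals_durations=durations_min.sum(axis=0),
        grand_total_events=int(counts.to_numpy(dtype=float).sum()),
        grand_total_duration_min=float(durations_min.to_numpy(dtype=float).sum()),
    )


def load_event_summary() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged per-class, per-split event table of the benchmark dataset.

    Counts and durations (minutes) of expert-annotated FOG events in the
    TLVMC FOG-prediction competition dataset, by class and train/test split.
    Returns (counts, durations_min), both class x split DataFrames.
    """
    with resources.files("fogbench").joinpath("data/event_summary.csv").open() as fh:
        df = pd.read_csv(fh)
    counts = df.pivot(index="fog_class", columns="split", values="n_events")
    durations = df.pivot(index="fog_class", columns="split", values="duration_min")
    counts = counts.reindex(index=EVENT_CLASSES, columns=SPLITS)
    durations = durations.reindex(index=EVENT_CLASSES, columns=SPLITS)
    return counts, durations
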