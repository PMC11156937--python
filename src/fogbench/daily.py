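"""Daily-living (24/7) %TF analysis and its statistical machinery.

FOG in daily life is assumed to occur only during or adjacent to walking,
so all 24/7 analyses are restricted to walking bouts padded by 5 s on each
side.  Hourly %TF is total freezing time divided by total walking-bout
time in that clock hour; daily %TF is the same ratio at day granularity.
An hour with zero bout time has no defined %TF (propagated as NaN, never
imputed).  Group contrasts (freezer vs. non-freezer per hour) use
two-tailed Mann-Whitney U tests; within-freezer daytime-vs-night contrasts
use a Friedman test with per-hour Wilcoxon post-hocs against the subject's
median night %TF.  All multiplicity correction uses the two-stage linear
step-up FDR procedure of Benjamini, Krieger and Yekutieli (BKY).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import WalkingBouts
from .errors import (AlignmentError, InsufficientDataError,
                     UndefinedMetricError, ValidationError)

logger = logging.getLogger(__name__)

DAYTIME_HOURS = tuple(range(7, 23))   # 07:00-22:59 inclusive
NIGHT_HOURS = tuple(h % 24 for h in range(23, 31))  # 23:00-06:59


# ---------------------------------------------------------------------------
# Bout masking and profiles
# ---------------------------------------------------------------------------


def expand_bouts(bouts: WalkingBouts, pad_s: float, n: int,
                 sampling_rate: float) -> np.ndarray:
    """Boolean mask covering each bout padded by ``pad_s`` on both sides.

    Padded intervals are clipped to [0, n) and overlaps merged (a union of
    intervals is just the OR of their memberships).
    """
    pad = int(round(pad_s * sampling_rate))
    mask = np.zeros(n, dtype=bool)
    for a, b in bouts.intervals:
        mask[max(0, a - pad):min(n, b + pad)] = True
    return mask


def ensemble_or(decisions: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise OR of member decision series: FOG if any model says FOG."""
    if not decisions:
        raise ValidationError("ensemble needs at least one member")
    out = np.asarray(decisions[0]).astype(bool).copy()
    for d in decisions[1:]:
        d = np.asarray(d).astype(bool)
        if d.shape != out.shape:
            raise AlignmentError("ensemble member length mismatch")
        out |= d
    return out


@dataclass
class HourlyProfile:
    """Per-day 24-bin %TF restricted to walking-bout time.

    ``tf`` holds NaN where the hour had no bout time; ``bout_seconds`` is
    the denominator per bin.
    """

    subject_id: str
    day: int
    tf: np.ndarray
    bout_seconds: np.ndarray


def _bin_indices(n: int, start_clock: datetime, sampling_rate: float):
    """Hour-of-day and day index for each sample (attributed by midpoint)."""
    start_s = (start_clock.hour * 3600 + start_clock.minute * 60
               + start_clock.second)
    t = start_s + (np.arange(n) + 0.5) / sampling_rate
    hour = (t // 3600).astype(np.int64) % 24
    day = (t // 86400).astype(np.int64)
    return hour, day


def hourly_tf(decisions: np.ndarray, bout_mask: np.ndarray,
              start_clock: datetime, sampling_rate: float,
              subject_id: str = "") -> tuple[list[HourlyProfile], np.ndarray]:
    """Per-day hourly %TF profiles plus the week-averaged 24-vector.

    The week average of a bin uses only days where that bin is defined
    (bout time > 0); a bin undefined on every day stays NaN.
    """
    decisions = np.asarray(decisions).astype(bool)
    bout_mask = np.asarray(bout_mask).astype(bool)
    if decisions.shape != bout_mask.shape:
        raise AlignmentError("decisions and bout mask length mismatch")
    n = len(decisions)
    hour, day = _bin_indices(n, start_clock, sampling_rate)
    n_days = int(day.max()) + 1 if n else 0
    flat = day * 24 + hour
    bout_counts = np.bincount(flat[bout_mask], minlength=n_days * 24)
    fog_counts = np.bincount(flat[bout_mask & decisions], minlength=n_days * 24)
    profiles = []
    for d in range(n_days):
        bsec = bout_counts[d * 24:(d + 1) * 24] / sampling_rate
        fsec = fog_counts[d * 24:(d + 1) * 24] / sampling_rate
        with np.errstate(invalid="ignore", divide="ignore"):
            tf = np.where(bsec > 0, 100.0 * fsec / np.where(bsec > 0, bsec, 1.0), np.nan)
        profiles.append(HourlyProfile(subject_id, d, tf, bsec))
    return profiles, week_average(profiles)


def week_average(profiles: Sequence[HourlyProfile]) -> np.ndarray:
    """Mean over days of each defined hourly bin (NaN if never defined)."""
    if not profiles:
        return np.full(24, np.nan)
    stacked = np.vstack([p.tf for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        return np.nanmean(stacked, axis=0)


def daily_tf(decisions: np.ndarray, bout_mask: np.ndarray,
             start_clock: datetime, sampling_rate: float) -> np.ndarray:
    """%TF per calendar day: freezing time / bout time on that day (NaN if none)."""
    decisions = np.asarray(decisions).astype(bool)
    bout_mask = np.asarray(bout_mask).astype(bool)
    if decisions.shape != bout_mask.shape:
        raise AlignmentError("decisions and bout mask length mismatch")
    _, day = _bin_indices(len(decisions), start_clock, sampling_rate)
    n_days = int(day.max()) + 1 if len(decisions) else 0
    bout = np.bincount(day[bout_mask], minlength=n_days).astype(float)
    fog = np.bincount(day[bout_mask & decisions], minlength=n_days).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(bout > 0, 100.0 * fog / np.where(bout > 0, bout, 1.0), np.nan)


def night_reference(week_avg: np.ndarray,
                    night_hours: Sequence[int] = NIGHT_HOURS) -> float:
    """Median of the defined night-hour %TF bins (the nocturnal reference)."""
    vals = np.asarray(week_avg, dtype=float)[list(night_hours)]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise UndefinedMetricError("night reference undefined: no defined night bins")
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# BKY two-stage FDR
# ---------------------------------------------------------------------------


def _bh_reject(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejections at the given level."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresh = level * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, dtype=bool)
    if len(passed):
        reject[order[:passed[-1] + 1]] = True
    return reject


def _bky_reject_at(p: np.ndarray, q: float) -> np.ndarray:
    """Two-stage linear step-up rejection set at FDR level q."""
    m = len(p)
    q1 = q / (1.0 + q)
    stage1 = _bh_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return _bh_reject(p, q1 * m / (m - r1))


def bky_fdr(p_values: Sequence[float], q: float = 0.05
            ) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage Benjamini-Krieger-Yekutieli FDR control.

    Stage 1 runs the linear step-up procedure at q' = q/(1+q) to estimate
    the number of true nulls; stage 2 reruns it at q' * m/(m - r1).
    Returns (rejections at level q, adjusted p-values), where the adjusted
    p-value of a hypothesis is the smallest q at which it is rejected
    (found by bisection; the rejection set grows monotonically with q).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-D")
    if len(p) == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = np.ones(len(p))
    for i in range(len(p)):
        if p[i] == 0:
            adjusted[i] = 0.0
            continue
        lo, hi = 0.0, 1.0
        if not _bky_reject_at(p, 1.0)[i]:
            adjusted[i] = 1.0
            continue
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if _bky_reject_at(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        adjusted[i] = hi
    return _bky_reject_at(p, q), adjusted


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U; exact null for small tie-free samples.

    Exact enumeration when the combined sample has at most 10 observations
    and no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("Mann-Whitney needs n >= 2 per group")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    tie_free = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed paired signed-rank p; all-zero differences -> p = 1 (flagged)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError("paired samples must have equal length")
    d = a - b
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        logger.warning("signed-rank test: all paired differences are zero; p = 1")
        return 1.0
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox",
                         method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparisonReport:
    """Per-hour freezer vs. non-freezer contrast with BKY adjustment."""

    hours: list[int]
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    medians_a: np.ndarray
    medians_b: np.ndarray
    skipped_hours: list[int] = field(default_factory=list)
    q: float = 0.05


def compare_groups_hourly(profiles_a: Sequence[np.ndarray],
                          profiles_b: Sequence[np.ndarray],
                          q: float = 0.05,
                          hours: Sequence[int] = tuple(range(24)),
                          ) -> GroupComparisonReport:
    """Mann-Whitney per clock hour on subjects' week-averaged hourly %TF.

    ``profiles_*`` are per-subject 24-vectors (NaN = undefined bin).  Hours
    where either group has fewer than 2 defined subjects are skipped and
    reported; BKY adjustment runs across the tested hours.
    """
    a = np.vstack(list(profiles_a))
    b = np.vstack(list(profiles_b))
    tested, raw, med_a, med_b, skipped = [], [], [], [], []
    for h in hours:
        va = a[:, h][~np.isnan(a[:, h])]
        vb = b[:, h][~np.isnan(b[:, h])]
        if len(va) < 2 or len(vb) < 2:
            skipped.append(h)
            continue
        _, p = mann_whitney_u(va, vb)
        tested.append(h)
        raw.append(p)
        med_a.append(np.median(va))
        med_b.append(np.median(vb))
    if not tested:
        raise InsufficientDataError("no hour had enough defined subjects in both groups")
    rejected, adj = bky_fdr(raw, q=q)
    return GroupComparisonReport(hours=tested, raw_p=np.asarray(raw),
                                 adjusted_p=adj, rejected=rejected,
                                 medians_a=np.asarray(med_a),
                                 medians_b=np.asarray(med_b),
                                 skipped_hours=skipped, q=q)


@dataclass
class DaytimeNightReport:
    friedman_statistic: float
    friedman_p: float
    daytime_hours: list[int]
    posthoc_raw_p: np.ndarray
    posthoc_adjusted_p: np.ndarray
    posthoc_rejected: np.ndarray
    n_subjects: int
    excluded_subjects: list[str] = field(default_factory=list)


def daytime_vs_night(week_profiles: Sequence[np.ndarray],
                     subject_ids: Optional[Sequence[str]] = None,
                     daytime_hours: Sequence[int] = DAYTIME_HOURS,
                     night_hours: Sequence[int] = NIGHT_HOURS,
                     q: float = 0.05) -> DaytimeNightReport:
    """Friedman test of daytime hourly %TF against the night reference.

    Blocks are subjects; treatments are the daytime hour columns plus one
    column holding each subject's median night %TF.  Post-hoc: per daytime
    hour, paired Wilcoxon signed-rank against the night reference, BKY
    adjusted.  Subjects missing any daytime bin or the night reference are
    excluded with a logged warning.
    """
    ids = list(subject_ids) if subject_ids is not None else [
        str(i) for i in range(len(list(week_profiles)))]
    rows, excluded = [], []
    for sid, prof in zip(ids, week_profiles):
        prof = np.asarray(prof, dtype=float)
        day_vals = prof[list(daytime_hours)]
        try:
            ref = night_reference(prof, night_hours)
        except UndefinedMetricError:
            excluded.append(sid)
            continue
        if np.isnan(day_vals).any():
            excluded.append(sid)
            continue
        rows.append(np.r_[day_vals, ref])
    if excluded:
        logger.warning("daytime-vs-night: excluded %d subject(s) with undefined bins", len(excluded))
    if len(rows) < 3:
        raise InsufficientDataError("Friedman test needs >= 3 complete subjects")
    table = np.vstack(rows)
    if np.allclose(table, table[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*table.T)
    raw = [wilcoxon_signed_rank(table[:, j], table[:, -1])
           for j in range(len(daytime_hours))]
    rejected, adj = bky_fdr(raw, q=q)
    return DaytimeNightReport(float(stat), float(p), list(daytime_hours),
                              np.asarray(raw), adj, rejected,
                              n_subjects=len(rows), excluded_subjects=excluded)


def severity_split(manifest, score_column: str = "nfogq",
                   cutoff: Optional[float] = None) -> dict[str, list[str]]:
    """Split freezers into moderate (score <= cutoff) vs. severe (> cutoff).

    ``manifest`` is a DataFrame with columns subject_id, group and a FOG
    severity questionnaire score; the default cutoff is the freezer-cohort
    median.  Freezers with a missing score are excluded and logged.
    """
    freezers = manifest[manifest["group"] == "freezer"]
    missing = freezers[freezers[score_column].isna()]
    for sid in missing["subject_id"]:
        logger.warning("severity split: subject %s has no severity score; excluded", sid)
    freezers = freezers.dropna(subset=[score_column])
    if len(freezers) == 0:
        raise InsufficientDataError("no freezer has a severity score")
    if cutoff is None:
        cutoff = float(freezers[score_column].median())
    moderate = freezers.loc[freezers[score_column] <= cutoff, "subject_id"]
    severe = freezers.loc[freezers[score_column] > cutoff, "subject_id"]
    return {"moderate": list(moderate), "severe": list(severe),
            "cutoff": cutoff}


@dataclass
class SeverityComparisonReport:
    friedman_statistic: float
    friedman_p: float
    pairs: list[tuple[str, str]]
    dunn_z: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray


def severity_comparison(group_profiles: dict[str, Sequence[np.ndarray]],
                        daytime_hours: Sequence[int] = DAYTIME_HOURS,
                        q: float = 0.05) -> SeverityComparisonReport:
    """Omnibus + pairwise contrast of group daytime %TF, hours as blocks.

    Each group's per-subject week profiles are reduced to the group mean
    %TF per daytime hour; the resulting hours x groups table is tested
    with a Friedman test, followed by pairwise Dunn mean-rank comparisons
    (z = (Rbar_i - Rbar_j) / sqrt(k(k+1)/(6 n_blocks))), BKY adjusted.
    """
    names = list(group_profiles)
    if len(names) < 3:
        raise InsufficientDataError("severity comparison expects >= 3 groups")
    cols = []
    for name in names:
        stacked = np.vstack(list(group_profiles[name]))[:, list(daytime_hours)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cols.append(np.nanmean(stacked, axis=0))
    table = np.column_stack(cols)          # hours x groups
    if np.isnan(table).any():
        raise InsufficientDataError("a group has an all-undefined daytime hour")
    if np.allclose(table, table[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*table.T)
    nb, k = table.shape
    ranks = stats.rankdata(table, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * nb))
    pairs, zs, raw = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((names[i], names[j]))
            zs.append(z)
            raw.append(2 * stats.norm.sf(abs(z)))
    rejected, adj = bky_fdr(raw, q=q)
    return SeverityComparisonReport(float(stat), float(p), pairs,
                                    np.asarray(zs), np.asarray(raw), adj, rejected)


def class_distribution_comparison(shares_protocol, shares_daily) -> dict[str, float]:
    """Per-class paired Wilcoxon p comparing class %TF shares across settings.

    ``shares_*`` are DataFrames (subjects x classes) of per-subject class
    time shares during FOG-provoking protocols vs. daily living.  P-values
    are two-tailed and deliberately unadjusted (reported per class).
    """
    out = {}
    for col in shares_protocol.columns:
        out[col] = wilcoxon_signed_rank(shares_protocol[col].to_numpy(float),
                                        shares_daily[col].to_numpy(float))
    return out
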