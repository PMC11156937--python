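"""The two orchestrated pipelines: test-set evaluation and daily living.

``run_eval_pipeline`` reproduces the post-competition measurement chain on
a labeled session set plus a submission: competition mAP, PR/ROC curves,
operating-point metric table, per-subject gold-standard outcomes (truth
vs. estimate) and their ICC(2,1) agreement.

``run_daily_pipeline`` runs the 24/7 chain on a cohort: padded-bout
masking, hourly/daily %TF profiles, freezer vs. non-freezer hourly
contrasts, daytime-vs-night Friedman analysis, severity-split comparison,
day-to-day ICC(A,k) stability and the freezer/non-freezer effect size.

Every report carries a provenance block (package version, seed, config
hash) and is bit-reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from datetime import datetime
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import cohens_d, icc_2_1, icc_a_k
from .core_io import LabelSeries, Recording, ScoreSeries, WalkingBouts, make_mask
from .daily import (DAYTIME_HOURS, compare_groups_hourly, daily_tf,
                    daytime_vs_night, expand_bouts, hourly_tf,
                    severity_comparison, severity_split)
from .episodes import extract_episodes, subject_summary
from .errors import FogbenchError, InsufficientDataError
from .operating_point import binarize_all_fog, operating_point_table, select_threshold
from .scoring import mean_average_precision, pr_curve, roc_curve


def _provenance(seed: Optional[int], config: Mapping) -> dict:
    blob = json.dumps({k: str(v) for k, v in sorted(config.items())}).encode()
    return {"package": "fogbench", "version": __version__, "seed": seed,
            "config_sha256": hashlib.sha256(blob).hexdigest()[:16]}


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [None if (isinstance(v, float) and np.isnan(v)) else v
                for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        v = obj.item()
        return None if isinstance(v, float) and np.isnan(v) else v
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_eval_pipeline(sessions: Sequence[tuple[Recording, LabelSeries]],
                      submission: Mapping[str, ScoreSeries],
                      seed: Optional[int] = None,
                      out_dir=None) -> dict:
    """Evaluate a submission against labeled sessions; see module docstring."""
    triples = []
    for rec, labels in sessions:
        if rec.session_id not in submission:
            raise FogbenchError(
                f"stage scoring failed: submission missing session {rec.session_id!r}")
        scores = submission[rec.session_id]
        if len(scores) != len(labels):
            raise FogbenchError(
                f"stage scoring failed: session {rec.session_id!r} length mismatch")
        triples.append((rec, labels, scores, make_mask(labels)))

    map_report = mean_average_precision([(l, s, m) for _, l, s, m in triples])

    # pooled curves + operating table on the concatenated session set
    pooled_labels = LabelSeries(
        **{ch: np.concatenate([getattr(l, ch) for _, l, _, _ in triples])
           for ch in ("start_hesitation", "turn", "walking", "notype", "valid", "task")})
    pooled_scores = ScoreSeries(
        **{ch: np.concatenate([getattr(s, ch) for _, _, s, _ in triples])
           for ch in ("start_hesitation", "turn", "walking")})
    pooled_mask = np.concatenate([m for _, _, _, m in triples])
    table = operating_point_table(pooled_labels, pooled_scores, pooled_mask)

    y_all, s_all = binarize_all_fog(pooled_labels, pooled_scores)
    curves = {"pr_all_fog": pr_curve(y_all, s_all, pooled_mask, "all_fog"),
              "roc_all_fog": roc_curve(y_all, s_all, pooled_mask, "all_fog")}
    thr_all = table["all_fog"].threshold

    # per-subject gold-standard outcomes, truth vs. estimate
    subjects: dict[str, dict] = {}
    for rec, labels, scores, mask in triples:
        sub = subjects.setdefault(rec.subject_id,
                                  {"truth": [], "est": [], "mask": [], "fs": rec.sampling_rate})
        y, s = binarize_all_fog(labels, scores)
        sub["truth"].append(y)
        sub["est"].append(s >= thr_all)
        sub["mask"].append(mask)
    rows = []
    for sid, d in sorted(subjects.items()):
        fs = d["fs"]
        mask = np.concatenate(d["mask"])
        truth = np.concatenate(d["truth"]) & mask
        est = np.concatenate(d["est"]) & mask
        t = subject_summary(extract_episodes(truth, fs), mask, fs, sid)
        e = subject_summary(extract_episodes(est, fs), mask, fs, sid)
        rows.append({"subject_id": sid,
                     "tf_true": t.percent_time_frozen, "tf_est": e.percent_time_frozen,
                     "n_true": t.n_episodes, "n_est": e.n_episodes,
                     "dur_true": t.total_duration_s, "dur_est": e.total_duration_s})
    outcomes = pd.DataFrame(rows)

    icc = {}
    if len(outcomes) >= 3:
        for name, (a, b) in {"percent_time_frozen": ("tf_true", "tf_est"),
                             "n_episodes": ("n_true", "n_est"),
                             "total_duration": ("dur_true", "dur_est")}.items():
            icc[name] = icc_2_1(outcomes[[a, b]].to_numpy(float))

    report = {"provenance": _provenance(seed, {"n_sessions": len(triples)}),
              "scoring": map_report,
              "operating_point": {k: v.as_dict() for k, v in table.items()},
              "curves": curves, "subject_outcomes": outcomes, "icc": icc}
    if out_dir is not None:
        _write_report(report, out_dir, "eval")
    return report


def run_daily_pipeline(manifest: pd.DataFrame,
                       subject_data: Mapping[str, tuple[np.ndarray, WalkingBouts,
                                                        datetime, float]],
                       pad_s: float = 5.0, seed: Optional[int] = None,
                       out_dir=None, q: float = 0.05) -> dict:
    """Daily-living analysis over a cohort of week-long decision series.

    ``subject_data`` maps subject_id -> (binary decision series, walking
    bouts, start clock, sampling rate).  Single-subject cohorts yield
    profiles only; group statistics are skipped with a warning entry.
    """
    week_profiles: dict[str, np.ndarray] = {}
    daily: dict[str, np.ndarray] = {}
    for sid, (decisions, bouts, start_clock, fs) in subject_data.items():
        bout_mask = expand_bouts(bouts, pad_s=pad_s, n=len(decisions), sampling_rate=fs)
        _, week_avg = hourly_tf(decisions, bout_mask, start_clock, fs, sid)
        week_profiles[sid] = week_avg
        daily[sid] = daily_tf(decisions, bout_mask, start_clock, fs)

    groups = {g: [s for s in df["subject_id"] if s in week_profiles]
              for g, df in manifest.groupby("group")}
    freezers = groups.get("freezer", [])
    non_freezers = groups.get("non_freezer", [])

    report: dict = {"provenance": _provenance(seed, {"pad_s": pad_s, "q": q}),
                    "week_profiles": week_profiles, "daily_tf": daily,
                    "warnings": []}

    if len(freezers) >= 2 and len(non_freezers) >= 2:
        report["group_hourly"] = compare_groups_hourly(
            [week_profiles[s] for s in freezers],
            [week_profiles[s] for s in non_freezers], q=q)
        fd = np.array([np.nanmean(daily[s]) for s in freezers])
        nd = np.array([np.nanmean(daily[s]) for s in non_freezers])
        report["daily_tf_cohens_d"] = cohens_d(fd, nd)
    else:
        report["warnings"].append("group statistics skipped: need >= 2 subjects per group")

    if len(freezers) >= 3:
        try:
            report["daytime_vs_night"] = daytime_vs_night(
                [week_profiles[s] for s in freezers], freezers, q=q)
        except InsufficientDataError as exc:
            report["warnings"].append(f"daytime-vs-night skipped: {exc}")
        # day-to-day stability of daily %TF over the first 6 complete days
        panel = [daily[s][:6] for s in freezers
                 if len(daily[s]) >= 6 and not np.isnan(daily[s][:6]).any()]
        if len(panel) >= 3:
            report["icc_daily_tf"] = icc_a_k(np.vstack(panel))
        sev = severity_split(manifest)
        grp_profiles = {"non_freezer": [week_profiles[s] for s in non_freezers],
                        "moderate": [week_profiles[s] for s in sev["moderate"]
                                     if s in week_profiles],
                        "severe": [week_profiles[s] for s in sev["severe"]
                                   if s in week_profiles]}
        if all(len(v) >= 1 for v in grp_profiles.values()):
            try:
                report["severity"] = severity_comparison(grp_profiles, q=q)
                report["severity_cutoff"] = sev["cutoff"]
            except InsufficientDataError as exc:
                report["warnings"].append(f"severity comparison skipped: {exc}")

    if out_dir is not None:
        _write_report(report, out_dir, "daily")
    return report


def _write_report(report: dict, out_dir, stem: str) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {}
    for k, v in report.items():
        if isinstance(v, pd.DataFrame):
            v.to_csv(out / f"{stem}_{k}.csv", index=False)
            payload[k] = f"{stem}_{k}.csv"
        else:
            payload[k] = _jsonable(v)
    with open(out / f"{stem}_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
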