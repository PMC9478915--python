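"""Trace curation and conflict-based performance evaluation.

Curation provides the programmatic equivalents of manual post-processing:
connecting, cutting, and deleting identity traces or single detections,
always preserving the partition invariant (every detection in at most one
trace, at most one detection per trace per time step).

Evaluation quantifies how well the signal features separate true from false
connections.  A *tracking conflict* is a detection alpha whose
threshold-passing forward partners belong to at least two different
ground-truth identities; for each conflict the closest same-identity
partner (true connection) and the closest other-identity partner (false
connection) are recorded with their feature values (frequency difference,
field difference, frequency error, field error, combined distance).  Per
feature we report the fraction of conflicts in which the true connection
scores strictly smaller than the false one, and the ROC area under the
curve of the pooled true-vs-false distributions (smaller value = predicted
true; ties count one half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .distance import (
    DistanceConfig,
    ErrorCalibration,
    field_difference,
    field_error,
    frequency_difference,
    frequency_error,
    signal_distance,
    spatial_profile,
)
from .spectral import Detection
from .tracker import IdentityTrace

__all__ = [
    "ConflictRecord",
    "EvalSummary",
    "FEATURES",
    "extract_conflicts",
    "evaluate",
    "assignment_accuracy",
    "connect_traces",
    "cut_trace",
    "delete_trace",
    "delete_detection",
]

#: feature names evaluated for conflict separation
FEATURES = ("df", "dS", "ef", "eS", "eps")


@dataclass
class ConflictRecord:
    """One tracking conflict: a detection with competing identity partners."""

    alpha: Detection
    true_partner: Detection
    false_partner: Detection
    true_features: dict[str, float]
    false_features: dict[str, float]


@dataclass
class EvalSummary:
    """Separation performance of each feature, in percent."""

    n_conflicts: int
    fraction_correct: dict[str, float]
    auc: dict[str, float]


def _features(a: Detection, b: Detection, cal: ErrorCalibration,
              cfg: DistanceConfig) -> dict[str, float]:
    df = frequency_difference(a.eodf, b.eodf)
    ds = field_difference(spatial_profile(a.powers), spatial_profile(b.powers))
    ef = frequency_error(df, cfg)
    es = field_error(ds, cal)
    return {
        "df": df,
        "dS": ds,
        "ef": ef,
        "eS": es,
        "eps": signal_distance(ef, es, cfg),
    }


def extract_conflicts(detections: list[Detection],
                      labels: np.ndarray,
                      cal: ErrorCalibration,
                      cfg: DistanceConfig = DistanceConfig()) -> list[ConflictRecord]:
    """Find all tracking conflicts among a recording's detections.

    ``labels`` gives the ground-truth identity of every detection (from the
    simulator or curated traces); a negative label means unknown and raises
    an error when such a detection enters a conflict.  For every detection
    alpha whose forward threshold-passing candidates span at least two
    identities, one record pairs the minimum-distance candidate of alpha's
    own identity (true) with the minimum-distance candidate of any other
    identity (false); alphas whose candidates all agree are the easy cases
    and are skipped, as are conflicts without a same-identity candidate.
    """
    labels = np.asarray(labels)
    if len(labels) != len(detections):
        raise ValueError("one ground-truth label per detection required")
    order = sorted(range(len(detections)),
                   key=lambda i: (detections[i].time, detections[i].eodf))
    times = np.array([detections[i].time for i in order])

    records: list[ConflictRecord] = []
    for pos, ai in enumerate(order):
        da = detections[ai]
        hi = np.searchsorted(times, da.time + cfg.dt_thresh, side="right")
        cand = []
        for qos in range(pos + 1, hi):
            bi = order[qos]
            db = detections[bi]
            if db.time <= da.time:
                continue
            if abs(db.eodf - da.eodf) > cfg.df_thresh:
                continue
            cand.append(bi)
        if not cand:
            continue
        cand_labels = {int(labels[bi]) for bi in cand}
        if len(cand_labels) < 2:
            continue
        if min(cand_labels) < 0 or labels[ai] < 0:
            raise ValueError("ground-truth label missing for a conflict participant")
        feats = {bi: _features(da, detections[bi], cal, cfg) for bi in cand}
        same = [bi for bi in cand if labels[bi] == labels[ai]]
        other = [bi for bi in cand if labels[bi] != labels[ai]]
        if not same or not other:
            continue
        best_true = min(same, key=lambda bi: feats[bi]["eps"])
        best_false = min(other, key=lambda bi: feats[bi]["eps"])
        records.append(ConflictRecord(
            alpha=da,
            true_partner=detections[best_true],
            false_partner=detections[best_false],
            true_features=feats[best_true],
            false_features=feats[best_false],
        ))
    return records


def _auc_smaller_is_positive(true_vals: np.ndarray, false_vals: np.ndarray) -> float:
    """ROC AUC with smaller values predicting the positive (true) class.

    Mann-Whitney closed form on pooled ranks; ties contribute one half.
    """
    pooled = np.concatenate([true_vals, false_vals])
    ranks = rankdata(pooled)
    n_t, n_f = len(true_vals), len(false_vals)
    rank_sum_true = ranks[:n_t].sum()
    # P(true < false) + 0.5 P(true == false)
    return (n_t * n_f + n_t * (n_t + 1) / 2.0 - rank_sum_true) / (n_t * n_f)


def evaluate(conflicts: list[ConflictRecord]) -> EvalSummary:
    """Summarize feature separation over a set of conflicts (percent)."""
    if not conflicts:
        raise ValueError("at least one conflict is required for evaluation")
    fraction = {}
    auc = {}
    for feat in FEATURES:
        tv = np.array([c.true_features[feat] for c in conflicts])
        fv = np.array([c.false_features[feat] for c in conflicts])
        fraction[feat] = 100.0 * float(np.mean(tv < fv))
        auc[feat] = 100.0 * _auc_smaller_is_positive(tv, fv)
    return EvalSummary(len(conflicts), fraction, auc)


def assignment_accuracy(traces: list[IdentityTrace], detections: list[Detection],
                        labels: np.ndarray) -> float:
    """Percent of tracked detections assigned to the correct fish.

    Each identity trace is mapped to the ground-truth fish that contributes
    most of its detections (majority vote); a detection counts as correct if
    its trace maps to its own label.  Detections with unknown label
    (negative) are excluded from the count.
    """
    by_key = {(d.time_index, d.eodf): int(lab) for d, lab in zip(detections, labels)}
    total = correct = 0
    for tr in traces:
        labs = [by_key[(d.time_index, d.eodf)] for d in tr.detections]
        labs = [l for l in labs if l >= 0]
        if not labs:
            continue
        vals, counts = np.unique(labs, return_counts=True)
        majority = int(vals[np.argmax(counts)])
        total += len(labs)
        correct += sum(1 for l in labs if l == majority)
    if total == 0:
        raise ValueError("no labeled detections to score")
    return 100.0 * correct / total


def connect_traces(a: IdentityTrace, b: IdentityTrace) -> IdentityTrace:
    """Merge two traces into one (keeps the first trace's id).

    Fails if any time step is occupied in both traces.
    """
    if not a.time_steps().isdisjoint(b.time_steps()):
        raise ValueError("cannot connect traces with overlapping time steps")
    merged = sorted(zip(a.indices + b.indices, a.detections + b.detections),
                    key=lambda p: p[1].time)
    return IdentityTrace(a.identity_id,
                         [d for _, d in merged],
                         [i for i, _ in merged])


def cut_trace(a: IdentityTrace, t: float) -> tuple[IdentityTrace, IdentityTrace]:
    """Split a trace at time ``t`` (first part < t, second part >= t)."""
    if not (a.start_time < t <= a.end_time):
        raise ValueError("cut time must lie strictly inside the trace's span")
    first = [(i, d) for i, d in zip(a.indices, a.detections) if d.time < t]
    second = [(i, d) for i, d in zip(a.indices, a.detections) if d.time >= t]
    if not first or not second:
        raise ValueError("cut must leave both parts nonempty")
    return (
        IdentityTrace(a.identity_id, [d for _, d in first], [i for i, _ in first]),
        IdentityTrace(a.identity_id + 1, [d for _, d in second], [i for i, _ in second]),
    )


def delete_trace(traces: list[IdentityTrace], identity_id: int) -> list[IdentityTrace]:
    """Remove a whole identity (e.g., a non-fish artifact trace)."""
    if identity_id not in {t.identity_id for t in traces}:
        raise KeyError(f"unknown identity id {identity_id}")
    return [t for t in traces if t.identity_id != identity_id]


def delete_detection(traces: list[IdentityTrace], identity_id: int,
                     time_index: int) -> list[IdentityTrace]:
    """Remove one detection from one trace (no automatic splitting).

    Traces emptied by the deletion are dropped from the returned set.
    """
    out = []
    found = False
    for tr in traces:
        if tr.identity_id != identity_id:
            out.append(tr)
            continue
        keep = [(i, d) for i, d in zip(tr.indices, tr.detections)
                if d.time_index != time_index]
        if len(keep) == len(tr.detections):
            raise KeyError(
                f"identity {identity_id} has no detection at time step {time_index}"
            )
        found = True
        if keep:
            out.append(IdentityTrace(tr.identity_id,
                                     [d for _, d in keep],
                                     [i for i, _ in keep]))
    if not found:
        raise KeyError(f"unknown identity id {identity_id}")
    return out
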