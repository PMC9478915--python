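"""Identity tracking: cluster detections into per-fish traces.

The tracker processes a recording in overlapping 30 s windows shifted by
10 s.  Within each window all threshold-passing detection pairs (forward in
time, at most 10 s and 2.5 Hz apart) are stored with their combined signal
distance in a :class:`DistanceCube` and traversed in ascending distance:
the cheapest pairs form identities first, later pairs extend or merge
identities unless that would put two detections of one fish at the same
time step (temporal conflict -> pair ignored).

Only the central third of each window is validated — detections there have
had all their potential partners considered.  Validated window-local traces
are then appended to established identities from earlier windows, again in
ascending order of the distance between trace-end and trace-start signals.
The window then slides on by 10 s.

This window-based, distance-ordered strategy (rather than connecting
detections strictly in temporal order) is what makes the tracking robust
against detection dropouts and crossing EOD frequency traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import (
    DistanceConfig,
    ErrorCalibration,
    calibrate_field_error,
    detection_distance,
    select_calibration_window,
)
from .spectral import Detection

__all__ = [
    "TrackingConfig",
    "DistanceCube",
    "IdentityTrace",
    "build_distance_cube",
    "cluster_window",
    "assemble_windows",
    "track",
]


@dataclass
class TrackingConfig:
    """Window layout of the tracker plus the embedded distance parameters.

    Defaults implement the canonical layout: 30 s tracking windows whose
    central 10 s is validated, sliding by 10 s.
    """

    window_length: float = 30.0
    central_length: float = 10.0
    window_shift: float = 10.0
    distance: DistanceConfig = field(default_factory=DistanceConfig)

    def __post_init__(self) -> None:
        if min(self.window_length, self.central_length, self.window_shift) <= 0:
            raise ValueError("window parameters must be positive")
        if self.window_shift > self.central_length:
            raise ValueError("window_shift must not exceed central_length")
        if self.window_length < 2 * self.central_length:
            raise ValueError("window_length must cover at least two central lengths")


@dataclass
class DistanceCube:
    """Layered store of pairwise distances within one tracking window.

    ``layers`` maps a time step index ``i`` to the detections alpha observed
    at ``i``; each alpha maps to its forward partners ``(beta, eps)`` with
    ``t_beta > t_alpha``, both thresholds satisfied.  Every window detection
    owns exactly one alpha row (possibly empty).  Indices refer to one
    shared detection list.
    """

    layers: dict[int, dict[int, list[tuple[int, float]]]] = field(default_factory=dict)

    def detection_indices(self) -> list[int]:
        out = [a for layer in self.layers.values() for a in layer]
        return sorted(out)

    def iter_pairs(self):
        """Yield all (alpha_index, beta_index, eps) entries."""
        for step in sorted(self.layers):
            for alpha, entries in self.layers[step].items():
                for beta, eps in entries:
                    yield alpha, beta, eps


@dataclass
class IdentityTrace:
    """Time-ordered detections attributed to one fish.

    Holds at most one detection per time step.  ``indices`` are the
    positions of the detections in the originating detection list (parallel
    to ``detections``), kept for table round-trips.
    """

    identity_id: int
    detections: list[Detection] = field(default_factory=list)
    indices: list[int] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([d.time for d in self.detections])

    @property
    def start_time(self) -> float:
        return self.detections[0].time

    @property
    def end_time(self) -> float:
        return self.detections[-1].time

    def time_steps(self) -> set[int]:
        return {d.time_index for d in self.detections}


def build_distance_cube(detections: list[Detection],
                        cal: ErrorCalibration,
                        cfg: TrackingConfig = TrackingConfig(),
                        indices: list[int] | None = None,
                        cache: dict[tuple[int, int], float] | None = None) -> DistanceCube:
    """Compute the distance cube over a set of detections.

    Stores exactly the forward pairs (``t_beta > t_alpha``) with time
    difference at most ``dt_thresh`` and frequency difference at most
    ``df_thresh``; the distance is the combined frequency/field error.

    ``indices`` restricts the cube to a subset of ``detections`` (defaults
    to all); ``cache`` optionally memoizes pair distances across overlapping
    windows.
    """
    if cal is None:
        raise ValueError("an ErrorCalibration is required to build the distance cube")
    dcfg = cfg.distance
    if indices is None:
        indices = list(range(len(detections)))
    order = sorted(indices, key=lambda i: (detections[i].time, detections[i].eodf))
    cube = DistanceCube()
    for i in order:
        cube.layers.setdefault(detections[i].time_index, {})[i] = []
    for pos, a in enumerate(order):
        da = detections[a]
        row = cube.layers[da.time_index][a]
        for b in order[pos + 1:]:
            db = detections[b]
            if db.time - da.time > dcfg.dt_thresh:
                break
            if db.time <= da.time:
                continue
            if abs(db.eodf - da.eodf) > dcfg.df_thresh:
                continue
            if cache is not None and (a, b) in cache:
                eps = cache[(a, b)]
            else:
                eps = detection_distance(da, db, cal, dcfg)
                if cache is not None:
                    cache[(a, b)] = eps
            row.append((b, eps))
    return cube


def _pair_sort_key(detections):
    def key(entry):
        a, b, eps = entry
        da, db = detections[a], detections[b]
        return (eps, da.time, da.eodf, db.time, db.eodf)
    return key


def cluster_window(cube: DistanceCube, detections: list[Detection]) -> list[IdentityTrace]:
    """Cluster the detections of one window by ascending pair distance.

    Pairs are traversed cheapest first (ties broken by alpha time, alpha
    frequency, beta time, beta frequency).  A pair founds a new identity if
    neither end is assigned, extends an identity if exactly one end is, and
    merges two identities otherwise — each action only if no time step would
    end up holding two detections; conflicting pairs are skipped.  Leftover
    detections become singleton identities.  Window-local labels are
    assigned in order of first detection (time, then frequency).
    """
    members = cube.detection_indices()
    pairs = sorted(cube.iter_pairs(), key=_pair_sort_key(detections))

    assign: dict[int, int] = {}
    groups: dict[int, dict] = {}
    next_gid = 0
    for a, b, _eps in pairs:
        ga, gb = assign.get(a), assign.get(b)
        if ga is None and gb is None:
            groups[next_gid] = {
                "members": [a, b],
                "steps": {detections[a].time_index, detections[b].time_index},
            }
            assign[a] = assign[b] = next_gid
            next_gid += 1
        elif ga is not None and gb is None:
            if detections[b].time_index not in groups[ga]["steps"]:
                groups[ga]["members"].append(b)
                groups[ga]["steps"].add(detections[b].time_index)
                assign[b] = ga
        elif ga is None and gb is not None:
            if detections[a].time_index not in groups[gb]["steps"]:
                groups[gb]["members"].append(a)
                groups[gb]["steps"].add(detections[a].time_index)
                assign[a] = gb
        elif ga != gb:
            if groups[ga]["steps"].isdisjoint(groups[gb]["steps"]):
                for m in groups[gb]["members"]:
                    assign[m] = ga
                groups[ga]["members"].extend(groups[gb]["members"])
                groups[ga]["steps"] |= groups[gb]["steps"]
                del groups[gb]
    for m in members:
        if m not in assign:
            groups[next_gid] = {"members": [m], "steps": {detections[m].time_index}}
            assign[m] = next_gid
            next_gid += 1

    traces = []
    for g in groups.values():
        idx = sorted(g["members"], key=lambda i: detections[i].time)
        traces.append(IdentityTrace(0, [detections[i] for i in idx], idx))
    traces.sort(key=lambda t: (t.start_time, t.detections[0].eodf))
    for label, trace in enumerate(traces):
        trace.identity_id = label
    return traces


def assemble_windows(established: list[IdentityTrace],
                     window_traces: list[IdentityTrace],
                     cfg: TrackingConfig,
                     cal: ErrorCalibration,
                     window_start: float,
                     detections: list[Detection] | None = None,
                     cache: dict[tuple[int, int], float] | None = None) -> list[IdentityTrace]:
    """Append validated window-local traces to established identities.

    Candidate connections run from signals alpha of established identities
    within the leading ``central_length`` of the current window (its first
    third) to signals beta of the new traces (already truncated to the
    validated central third), subject to the usual time and frequency
    thresholds.  Connections are made in ascending distance; per pass each
    new trace joins at most one established identity and vice versa, and
    only without temporal conflict.  Unmatched new traces become new
    identities.
    """
    dcfg = cfg.distance
    if not established:
        return list(window_traces)

    lead_lo = window_start
    lead_hi = window_start + cfg.central_length
    candidates = []
    for ei, etr in enumerate(established):
        for pa, a in enumerate(etr.indices):
            da = etr.detections[pa]
            if not (lead_lo <= da.time < lead_hi):
                continue
            for wi, wtr in enumerate(window_traces):
                for pb, b in enumerate(wtr.indices):
                    db = wtr.detections[pb]
                    if db.time <= da.time or db.time - da.time > dcfg.dt_thresh:
                        continue
                    if abs(db.eodf - da.eodf) > dcfg.df_thresh:
                        continue
                    if cache is not None and (a, b) in cache:
                        eps = cache[(a, b)]
                    else:
                        eps = detection_distance(da, db, cal, dcfg)
                        if cache is not None:
                            cache[(a, b)] = eps
                    candidates.append((eps, da.time, da.eodf, db.time, db.eodf, ei, wi))

    candidates.sort()
    used_estab: set[int] = set()
    used_new: set[int] = set()
    for eps, *_rest, ei, wi in candidates:
        if ei in used_estab or wi in used_new:
            continue
        etr, wtr = established[ei], window_traces[wi]
        if not etr.time_steps().isdisjoint(wtr.time_steps()):
            continue
        merged = sorted(
            zip(etr.indices + wtr.indices, etr.detections + wtr.detections),
            key=lambda p: p[1].time,
        )
        etr.indices = [i for i, _ in merged]
        etr.detections = [d for _, d in merged]
        used_estab.add(ei)
        used_new.add(wi)

    out = list(established)
    for wi, wtr in enumerate(window_traces):
        if wi not in used_new:
            out.append(wtr)
    return out


def track(detections: list[Detection],
          cfg: TrackingConfig = TrackingConfig(),
          cal: ErrorCalibration | None = None,
          calibration_window_start: float | None = None) -> list[IdentityTrace]:
    """Track a full recording's detections into fish identities.

    Slides 30 s windows in 10 s steps over the detections.  Each window is
    clustered by ascending distance; its validated span (normally the
    central third, extended to the leading third for the first window and
    the trailing third for the last) contributes traces that are appended to
    the established identities.  If no calibration is given, the field-error
    CDF is calibrated once on the busiest 30 s window (or the one starting
    at ``calibration_window_start``).

    Returns disjoint identities covering every detection, labeled by order
    of first appearance.
    """
    if not detections:
        return []
    order = sorted(range(len(detections)),
                   key=lambda i: (detections[i].time, detections[i].eodf))
    if cal is None:
        if calibration_window_start is None:
            calibration_window_start = select_calibration_window(detections, cfg.distance)
        cal = calibrate_field_error(detections, calibration_window_start, cfg.distance)

    times = np.array([detections[i].time for i in order])
    t0 = float(times[0])
    t_last = float(times[-1])
    cache: dict[tuple[int, int], float] = {}
    established: list[IdentityTrace] = []
    validated_up_to = -np.inf
    k = 0
    while True:
        w = t0 + k * cfg.window_shift
        is_last = t_last < w + cfg.window_length
        lo_i, hi_i = np.searchsorted(times, [w, w + cfg.window_length])
        window_idx = [order[i] for i in range(lo_i, hi_i)]
        if window_idx:
            cube = build_distance_cube(detections, cal, cfg, window_idx, cache)
            traces = cluster_window(cube, detections)
            v_lo = max(w + cfg.central_length, validated_up_to) if k > 0 else -np.inf
            v_hi = np.inf if is_last else w + 2 * cfg.central_length
            validated = []
            for tr in traces:
                keep = [p for p, d in enumerate(tr.detections) if v_lo <= d.time < v_hi]
                if keep:
                    validated.append(IdentityTrace(
                        tr.identity_id,
                        [tr.detections[p] for p in keep],
                        [tr.indices[p] for p in keep],
                    ))
            established = assemble_windows(
                established, validated, cfg, cal, w, detections, cache
            )
            validated_up_to = v_hi
        if is_last:
            break
        k += 1

    established.sort(key=lambda t: (t.start_time, t.detections[0].eodf))
    for label, trace in enumerate(established):
        trace.identity_id = label
    return established
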