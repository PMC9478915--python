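"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literally as possible (plain loops,
math-module arithmetic) and stays independent of the library code paths it
checks.
"""

from __future__ import annotations

import math


def logistic_frequency_error(df: float, f0: float = 0.35, slope: float = 0.08) -> float:
    return 1.0 / (1.0 + math.exp(-(df - f0) / slope))


def spatial_profile_ref(powers):
    lo = min(powers)
    hi = max(powers)
    if hi == lo:
        return [0.0] * len(powers)
    return [(p - lo) / (hi - lo) for p in powers]


def field_difference_ref(sa, sb):
    total = 0.0
    for x, y in zip(sa, sb):
        total += (x - y) ** 2
    return math.sqrt(total)


def field_error_ref(ds: float, sorted_vals) -> float:
    """Piecewise-linear CDF through (v_k, k/(m-1)), clamped to [0, 1]."""
    v = list(sorted_vals)
    m = len(v)
    if m == 1:
        return 1.0 if (ds >= v[0] and ds > 0) else 0.0
    if ds <= v[0]:
        return 0.0
    if ds >= v[-1]:
        return 1.0
    for k in range(m - 1):
        if v[k] <= ds <= v[k + 1]:
            y0 = k / (m - 1)
            y1 = (k + 1) / (m - 1)
            if v[k + 1] == v[k]:
                return y1
            return y0 + (y1 - y0) * (ds - v[k]) / (v[k + 1] - v[k])
    raise AssertionError("unreachable")


def pair_distances_ref(detections, sorted_cal, dt_thresh=10.0, df_thresh=2.5,
                       f0=0.35, slope=0.08, wf=1.0 / 3.0, ws=2.0 / 3.0):
    """All forward threshold-passing pairs with their combined distance.

    ``detections`` is a list of objects with .time, .time_index, .eodf,
    .powers.  Returns a list of (i, j, eps) over index pairs of the list.
    """
    pairs = []
    for i, a in enumerate(detections):
        for j, b in enumerate(detections):
            if b.time <= a.time:
                continue
            if b.time - a.time > dt_thresh:
                continue
            if abs(a.eodf - b.eodf) > df_thresh:
                continue
            ef = logistic_frequency_error(abs(a.eodf - b.eodf), f0, slope)
            ds = field_difference_ref(spatial_profile_ref(list(a.powers)),
                                      spatial_profile_ref(list(b.powers)))
            es = field_error_ref(ds, sorted_cal)
            pairs.append((i, j, wf * ef + ws * es))
    return pairs


def cluster_replay_ref(detections, pairs):
    """Literal replay of the ascending-distance clustering rules.

    Sorts ALL pairs by (distance, alpha time, alpha frequency, beta time,
    beta frequency) and maintains a plain list of member sets.  Returns the
    partition as a set of frozensets of detection indices.
    """
    order = sorted(
        pairs,
        key=lambda p: (p[2], detections[p[0]].time, detections[p[0]].eodf,
                       detections[p[1]].time, detections[p[1]].eodf),
    )
    clusters: list[set[int]] = []

    def find(i):
        for c in clusters:
            if i in c:
                return c
        return None

    def steps(c):
        return {detections[i].time_index for i in c}

    for i, j, _eps in order:
        ci, cj = find(i), find(j)
        if ci is None and cj is None:
            clusters.append({i, j})
        elif ci is not None and cj is None:
            if detections[j].time_index not in steps(ci):
                ci.add(j)
        elif ci is None and cj is not None:
            if detections[i].time_index not in steps(cj):
                cj.add(i)
        elif ci is not cj:
            if not (steps(ci) & steps(cj)):
                ci |= cj
                clusters.remove(cj)
    for i in range(len(detections)):
        if find(i) is None:
            clusters.append({i})
    return {frozenset(c) for c in clusters}


def peaks_with_prominence_ref(values, threshold):
    """Textbook local-maximum + prominence detection.

    A sample is a local maximum if strictly higher than both neighbors.  Its
    prominence is its height above the higher of the two key saddles: on
    each side walk until a strictly higher sample (or the edge) and take the
    minimum along the way.  Returns indices with prominence > threshold.
    """
    out = []
    n = len(values)
    for i in range(1, n - 1):
        if not (values[i] > values[i - 1] and values[i] > values[i + 1]):
            continue
        left_min = values[i]
        k = i - 1
        while k >= 0 and values[k] <= values[i]:
            left_min = min(left_min, values[k])
            k -= 1
        right_min = values[i]
        k = i + 1
        while k < n and values[k] <= values[i]:
            right_min = min(right_min, values[k])
            k += 1
        prominence = values[i] - max(left_min, right_min)
        if prominence > threshold:
            out.append(i)
    return out


def harmonic_groups_ref(peaks, band, tol_fraction, bin_width, max_harmonics):
    """Naive greedy harmonic grouping over (freq, level) peaks.

    Candidate fundamentals inside ``band`` are tried strongest first (ties:
    lower frequency); each claims, per harmonic order, the unused peak
    closest to the integer multiple within tolerance.  Groups with fewer
    than three members are abandoned.  Returns a list of sorted fundamental
    frequencies with their member frequency lists.
    """
    used = [False] * len(peaks)
    cand = [i for i, (f, _l) in enumerate(peaks) if band[0] <= f <= band[1]]
    cand.sort(key=lambda i: (-peaks[i][1], peaks[i][0]))
    groups = []
    for ci in cand:
        if used[ci]:
            continue
        f1 = peaks[ci][0]
        tol = tol_fraction * f1 + bin_width
        members = []
        for k in range(1, max_harmonics + 1):
            best, best_err = -1, tol
            for j, (fj, _lj) in enumerate(peaks):
                if used[j] or j in members:
                    continue
                if abs(fj - k * f1) <= best_err:
                    best, best_err = j, abs(fj - k * f1)
            if best >= 0:
                members.append(best)
        if len(members) >= 3:
            for m in members:
                used[m] = True
            groups.append((f1, sorted(peaks[m][0] for m in members)))
    groups.sort()
    return groups


def evaluate_ref(true_vals, false_vals):
    """Brute-force fraction-correct and AUC (smaller = positive), percent."""
    n = len(true_vals)
    frac = 100.0 * sum(1 for t, f in zip(true_vals, false_vals) if t < f) / n
    wins = 0.0
    for t in true_vals:
        for f in false_vals:
            if t < f:
                wins += 1.0
            elif t == f:
                wins += 0.5
    auc = 100.0 * wins / (len(true_vals) * len(false_vals))
    return frac, auc
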