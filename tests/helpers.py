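"""Independent oracles and matching utilities shared across tests.

The brute-force detector re-implements the peak acceptance rules with
plain Python loops, straight from their written definition, so it can
serve as an independent oracle for the vectorised implementation.
"""

from __future__ import annotations

import numpy as np

from mcca.detection import DetectionParams

MIN_SPAN = 5  # shortest trusted baseline span, in frames


def brute_force_detect(
    y: np.ndarray,
    params: DetectionParams,
    sampling_rate_hz: float,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Literal loop implementation of the three peak criteria.

    A sample is a candidate when the first difference crosses zero from
    positive to non-positive and the second difference is negative; it is
    accepted when its value exceeds the local baseline mean plus
    ``amplitude_sd_multiple`` noise SDs, with the baseline window chosen as
    the nearest preceding activity-free span (activity marked by a
    provisional global-statistics pass).
    """
    y = np.asarray(y, dtype=float)
    noise = y if noise is None else np.asarray(noise, dtype=float)
    n = y.size
    k = params.amplitude_sd_multiple

    cand = [
        i
        for i in range(1, n - 1)
        if (y[i] - y[i - 1]) > 0
        and (y[i + 1] - y[i]) <= 0
        and (y[i + 1] - 2 * y[i] + y[i - 1]) < 0
    ]

    sd_g = float(np.std(np.diff(noise)) / np.sqrt(2))
    mean_g = float(np.mean(y))
    med_g = float(np.median(y))
    edge = params.edge_sd_multiple * sd_g

    active = np.zeros(n, dtype=bool)
    for p in cand:
        if y[p] > mean_g + k * sd_g:
            f = p
            while f > 0:
                f -= 1
                if abs(y[f] - med_g) <= edge:
                    break
            t = p
            while t < n - 1:
                t += 1
                if abs(y[t] - med_g) <= edge:
                    break
            active[f : t + 1] = True

    clean = ~active
    run = [0] * n
    acc = 0
    for i in range(n):
        acc = acc + 1 if clean[i] else 0
        run[i] = acc

    width = max(2, int(round(params.baseline_window_s * sampling_rate_hz)))

    gbest = None
    best_len = 0
    for i in range(n):
        if run[i] >= MIN_SPAN and run[i] >= best_len:
            best_len = run[i]
            gbest = (i - run[i] + 1, i)

    accepted = []
    for c in cand:
        j = c - 1
        win = None
        if j >= 0:
            for e in range(j, -1, -1):
                if run[e] >= width:
                    win = (e - width + 1, e)
                    break
            if win is None:
                bl = 0
                for e in range(j + 1):
                    if run[e] >= MIN_SPAN and run[e] >= bl:
                        bl = run[e]
                        win = (e - run[e] + 1, e)
        if win is None:
            win = gbest
        if win is None:
            m, s = mean_g, sd_g
        else:
            f, e = win
            m = float(np.mean(y[f : e + 1]))
            s = float(np.std(np.diff(noise[f : e + 1])) / np.sqrt(2))
        if y[c] > m + k * s:
            accepted.append(c)
    return np.asarray(accepted, dtype=int)


def match_events(
    detected_times: np.ndarray,
    true_times: np.ndarray,
    tolerance_s: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy nearest-first one-to-one matching.

    Returns (true positives, false positives, false negatives).
    """
    det = np.asarray(detected_times, dtype=float)
    tru = np.asarray(true_times, dtype=float)
    used: set[int] = set()
    tp = 0
    for t in tru:
        if det.size == 0:
            break
        order = np.argsort(np.abs(det - t))
        for j in order:
            if abs(det[j] - t) <= tolerance_s and int(j) not in used:
                used.add(int(j))
                tp += 1
                break
    return tp, det.size - tp, tru.size - tp
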