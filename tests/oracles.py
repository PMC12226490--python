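"""Independent brute-force reference implementations used only by tests.

Every function here is a deliberately naive per-frame / per-element loop,
kept free of any code path shared with the package, so that agreement with
the vectorized implementations is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np

from socialdist.trajectory_io import BODY_PARTS

SUBSET_PARTS = {
    "all": list(BODY_PARTS),
    "no_tail": ["nose", "left_ear", "right_ear"],
    "ears_only": ["left_ear", "right_ear"],
}


def centroids_bruteforce(track, part_subset="all", min_parts=1):
    """Per-frame per-animal centroid by explicit python loops."""
    names = SUBSET_PARTS[part_subset]
    idx = [BODY_PARTS.index(p) for p in names]
    F = track.n_frames
    out = np.full((F, 2, 2), np.nan)
    n_used = np.zeros((F, 2), dtype=int)
    for f in range(F):
        for a in range(2):
            pts = [
                track.xy[f, a, p]
                for p in idx
                if track.accepted[f, a, p]
            ]
            n_used[f, a] = len(pts)
            if len(pts) >= min_parts:
                out[f, a, 0] = sum(q[0] for q in pts) / len(pts)
                out[f, a, 1] = sum(q[1] for q in pts) / len(pts)
    return out, n_used


def epoch_stats_bruteforce(dist, frames_per_epoch):
    """Per-epoch mean/median over valid frames by explicit slicing."""
    n_epochs = len(dist) // frames_per_epoch
    means, medians, ns = [], [], []
    for e in range(n_epochs):
        chunk = [
            d
            for d in dist[e * frames_per_epoch : (e + 1) * frames_per_epoch]
            if math.isfinite(d)
        ]
        ns.append(len(chunk))
        if chunk:
            means.append(sum(chunk) / len(chunk))
            medians.append(float(np.median(chunk)))
        else:
            means.append(float("nan"))
            medians.append(float("nan"))
    return np.array(means), np.array(medians), np.array(ns)


def hbt_cells_bruteforce(regions1, regions2):
    """3x3 mean inter-region distance by per-frame loops."""
    S = np.zeros((3, 3))
    n = np.zeros((3, 3), dtype=int)
    for i in range(3):
        for j in range(3):
            acc = []
            for f in range(regions1.shape[0]):
                p, q = regions1[f, i], regions2[f, j]
                if np.all(np.isfinite(p)) and np.all(np.isfinite(q)):
                    acc.append(math.hypot(p[0] - q[0], p[1] - q[1]))
            n[i, j] = len(acc)
            S[i, j] = sum(acc) / len(acc) if acc else float("nan")
    return S, n


def frobenius_bruteforce(M):
    return math.sqrt(sum(M[i, j] ** 2 for i in range(M.shape[0]) for j in range(M.shape[1])))


def fan_triangulation_area(vertices):
    """Polygon area as a fan of signed triangle areas from vertex 0."""
    v = np.asarray(vertices, dtype=float)
    total = 0.0
    for i in range(1, len(v) - 1):
        ax, ay = v[i] - v[0]
        bx, by = v[i + 1] - v[0]
        total += 0.5 * (ax * by - ay * bx)
    return abs(total)


def rejection_pct_bruteforce(track):
    """Per-animal per-part rejected-frame percentages by counting loops."""
    F = track.n_frames
    out = np.zeros((2, len(BODY_PARTS)))
    for a in range(2):
        for p in range(len(BODY_PARTS)):
            rejected = sum(1 for f in range(F) if not track.accepted[f, a, p])
            out[a, p] = 100.0 * rejected / F
    return out


def pearson_hand(x, y):
    """Pearson r from the raw covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def sem_two_pass(values):
    """SEM via an explicit two-pass sample variance."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var) / math.sqrt(n)
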