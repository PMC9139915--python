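"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops over voxels, pairs
and thresholds — and shares no code with the package's vectorized builders.
"""

from __future__ import annotations

import numpy as np

ALL_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def glcm_brute(bins: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Double loop over every in-mask voxel and its 26 neighbors."""
    G = int(bins[mask].max())
    counts = np.zeros((G, G))
    shape = bins.shape
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in ALL_26:
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]:
                        if mask[z2, y2, x2]:
                            counts[bins[z, y, x] - 1, bins[z2, y2, x2] - 1] += 1
    return counts / counts.sum()


def glrlm_brute(bins: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Walk every maximal line in each of the 13 positive directions."""
    G = int(bins[mask].max())
    shape = bins.shape
    directions = [d for d in ALL_26 if d > (0, 0, 0)]
    runs = []
    for d in directions:
        visited = np.zeros(shape, dtype=bool)
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if not mask[z, y, x] or visited[z, y, x]:
                        continue
                    pz, py, px = z - d[0], y - d[1], x - d[2]
                    prev_same = (
                        0 <= pz < shape[0]
                        and 0 <= py < shape[1]
                        and 0 <= px < shape[2]
                        and mask[pz, py, px]
                        and bins[pz, py, px] == bins[z, y, x]
                    )
                    if prev_same:
                        continue  # not a run start
                    length = 0
                    cz, cy, cx = z, y, x
                    while (
                        0 <= cz < shape[0]
                        and 0 <= cy < shape[1]
                        and 0 <= cx < shape[2]
                        and mask[cz, cy, cx]
                        and bins[cz, cy, cx] == bins[z, y, x]
                    ):
                        visited[cz, cy, cx] = True
                        length += 1
                        cz, cy, cx = cz + d[0], cy + d[1], cx + d[2]
                    runs.append((bins[z, y, x], length))
        visited[:] = False
    max_len = max(l for _, l in runs)
    mat = np.zeros((G, max_len))
    for lev, ln in runs:
        mat[lev - 1, ln - 1] += 1
    return mat


def glszm_brute(bins: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flood-fill connected equal-level zones with an explicit stack."""
    G = int(bins[mask].max())
    shape = bins.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                level = bins[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in ALL_26:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= nz < shape[0]
                            and 0 <= ny < shape[1]
                            and 0 <= nx < shape[2]
                            and mask[nz, ny, nx]
                            and not seen[nz, ny, nx]
                            and bins[nz, ny, nx] == level
                        ):
                            seen[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                zones.append((level, size))
    max_size = max(s for _, s in zones)
    mat = np.zeros((G, max_size))
    for lev, s in zones:
        mat[lev - 1, s - 1] += 1
    return mat


def ngtdm_brute(bins: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel neighborhood means with explicit loops."""
    G = int(bins[mask].max())
    shape = bins.shape
    mat = np.zeros((G, 2))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                nb = []
                for dz, dy, dx in ALL_26:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if (
                        0 <= nz < shape[0]
                        and 0 <= ny < shape[1]
                        and 0 <= nx < shape[2]
                        and mask[nz, ny, nx]
                    ):
                        nb.append(bins[nz, ny, nx])
                if not nb:
                    continue
                lev = bins[z, y, x]
                mat[lev - 1, 0] += 1
                mat[lev - 1, 1] += abs(lev - float(np.mean(nb)))
    return mat


def ap_brute(labels, scores) -> float:
    """Step-summed AP over descending unique-score thresholds."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    thresholds = sorted(set(scores.tolist()), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = scores >= t
        tp = int((labels[pred] == 1).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def auc_brute(labels, scores) -> float:
    """Pairwise rank statistic U/(n1 n0) with half-credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson_brute(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
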