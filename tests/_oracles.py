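"""Independent brute-force oracles used only by the tests.

Everything here is written as naively as possible (explicit python loops,
flood fills, exhaustive threshold enumeration) and never shares code with
the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def glcm_bruteforce(levels: np.ndarray, ng: int, offset: tuple[int, ...],
                    symmetric: bool = True) -> np.ndarray:
    """Co-occurrence counts by explicit per-voxel neighbor enumeration."""
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for idx in np.ndindex(shape):
        i = levels[idx]
        if i == 0:
            continue
        nbr = tuple(a + o for a, o in zip(idx, offset))
        if all(0 <= n < s for n, s in zip(nbr, shape)):
            j = levels[nbr]
            if j > 0:
                counts[i - 1, j - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def glrlm_bruteforce(levels: np.ndarray, ng: int, direction: tuple[int, ...]) -> dict:
    """Run-length counts {(level, length): n} by walking every maximal line."""
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    starts = []
    for idx in np.ndindex(shape):
        prev = tuple(a - o for a, o in zip(idx, direction))
        if not all(0 <= p < s for p, s in zip(prev, shape)):
            starts.append(idx)
    for start in starts:
        seq = []
        pos = start
        while all(0 <= p < s for p, s in zip(pos, shape)):
            seq.append(int(levels[pos]))
            pos = tuple(a + o for a, o in zip(pos, direction))
        k = 0
        while k < len(seq):
            if seq[k] == 0:
                k += 1
                continue
            length = 1
            while k + length < len(seq) and seq[k + length] == seq[k]:
                length += 1
            runs[(seq[k], length)] = runs.get((seq[k], length), 0) + 1
            k += length
    return runs


def glszm_bruteforce(levels: np.ndarray) -> dict:
    """Zone counts {(level, size): n} by BFS flood fill with infinity-norm
    (8/26-) connectivity."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    offsets = [o for o in np.ndindex(*([3] * levels.ndim))
               if any(v != 1 for v in o)]
    offsets = [tuple(v - 1 for v in o) for o in offsets]
    zones: dict[tuple[int, int], int] = {}
    for idx in np.ndindex(shape):
        if visited[idx] or levels[idx] == 0:
            continue
        level = int(levels[idx])
        stack, size = [idx], 0
        visited[idx] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nbr = tuple(a + o for a, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nbr, shape)) and \
                        not visited[nbr] and levels[nbr] == level:
                    visited[nbr] = True
                    stack.append(nbr)
        zones[(level, size)] = zones.get((level, size), 0) + 1
    return zones


def median_filter_bruteforce(plane: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window median with reflect padding, nested loops."""
    half = window // 2
    padded = np.pad(plane, half, mode="reflect")
    out = np.empty_like(plane, dtype=float)
    for r in range(plane.shape[0]):
        for c in range(plane.shape[1]):
            out[r, c] = np.median(padded[r : r + window, c : c + window])
    return out


def ap_threshold_enumeration(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision as the per-positive mean of interpolated precision.

    Enumerate every threshold, collect (recall, precision) points, then for
    each of the n_pos recall levels k/n_pos take the maximum precision among
    points with recall >= that level.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    points = []
    for t in np.unique(scores):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        if tp + fp == 0:
            continue
        points.append((tp / n_pos, tp / (tp + fp)))
    total = 0.0
    for k in range(1, n_pos + 1):
        level = k / n_pos
        best = max((p for r, p in points if r >= level - 1e-12), default=0.0)
        total += best
    return total / n_pos


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise win probability with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
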