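"""Independent brute-force oracles: direct-definition implementations used
only to cross-check the package, sharing no code with it."""

from __future__ import annotations

import itertools

import numpy as np


def glrlm_oracle(levels: np.ndarray, mask: np.ndarray, directions) -> dict[str, float]:
    """Run-length features by explicit voxel walking per direction."""
    lv = np.asarray(levels)
    m = np.asarray(mask) > 0
    shape = m.shape
    runs: list[tuple[int, int]] = []  # (level, length)

    def inside(p):
        return all(0 <= c < s for c, s in zip(p, shape))

    for d in directions:
        for p in itertools.product(*(range(s) for s in shape)):
            if not m[p]:
                continue
            prev = tuple(a - b for a, b in zip(p, d))
            if inside(prev) and m[prev] and lv[prev] == lv[p]:
                continue  # not a run start
            length = 1
            q = tuple(a + b for a, b in zip(p, d))
            while inside(q) and m[q] and lv[q] == lv[p]:
                length += 1
                q = tuple(a + b for a, b in zip(q, d))
            runs.append((int(lv[p]), length))

    n_runs = len(runs)
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for lev, ln in runs:
        by_level[lev] = by_level.get(lev, 0) + 1
        by_length[ln] = by_length.get(ln, 0) + 1
    gln = sum(v**2 for v in by_level.values()) / n_runs
    rln = sum(v**2 for v in by_length.values()) / n_runs
    return {"GLN": gln, "RLN": rln, "n_runs": n_runs,
            "voxel_runs_per_direction": sum(ln for _, ln in runs) / len(directions)}


def ngtdm_oracle(levels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """NGTDM features from per-voxel neighbourhood means computed directly."""
    lv = np.asarray(levels)
    m = np.asarray(mask) > 0
    shape = m.shape
    entries: list[tuple[int, float]] = []  # (level, |i - Abar|)
    for p in itertools.product(*(range(s) for s in shape)):
        if not m[p]:
            continue
        nbrs = []
        for off in itertools.product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            q = tuple(a + b for a, b in zip(p, off))
            if all(0 <= c < s for c, s in zip(q, shape)) and m[q]:
                nbrs.append(lv[q])
        if nbrs:
            entries.append((int(lv[p]), abs(lv[p] - float(np.mean(nbrs)))))

    total = len(entries)
    levels_present = sorted({e[0] for e in entries})
    n = {i: sum(1 for l, _ in entries if l == i) for i in levels_present}
    s = {i: sum(d for l, d in entries if l == i) for i in levels_present}
    p_ = {i: n[i] / total for i in levels_present}
    ngp = len(levels_present)

    sum_ps = sum(p_[i] * s[i] for i in levels_present)
    sum_s = sum(s.values())

    coarseness = 1e6 if sum_ps == 0 else min(1.0 / sum_ps, 1e6)
    contrast = 0.0
    if ngp > 1:
        acc = sum(p_[i] * p_[j] * (i - j) ** 2 for i in levels_present for j in levels_present)
        contrast = acc / (ngp * (ngp - 1)) * (sum_s / total)
    busy_den = sum(abs(i * p_[i] - j * p_[j]) for i in levels_present for j in levels_present)
    busyness = 0.0 if busy_den == 0 else sum_ps / busy_den
    complexity = 0.0
    if ngp > 1:
        complexity = sum(
            abs(i - j) * (p_[i] * s[i] + p_[j] * s[j]) / (p_[i] + p_[j])
            for i in levels_present for j in levels_present
        ) / total
    strength = 0.0
    if sum_s > 0:
        strength = sum(
            (p_[i] + p_[j]) * (i - j) ** 2 for i in levels_present for j in levels_present
        ) / sum_s
    return {
        "busyness": busyness, "coarseness": coarseness, "complexity": complexity,
        "contrast": contrast, "strength": strength,
    }


def auc_pair_oracle(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC by exhaustive positive/negative pair counting (ties 0.5)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = wins = 0.0
    for a in pos:
        for b in neg:
            total += 1
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / total


def cindex_pair_oracle(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell c by exhaustive pair enumeration."""
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j or not event[i]:
                continue
            if time[i] < time[j] or (time[i] == time[j] and not event[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den if den else float("nan")
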