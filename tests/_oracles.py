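"""Independent brute-force oracles for the evaluation metrics.

Deliberately naive: instances become Python sets of pixel coordinates
and every quantity is computed by exhaustive enumeration, sharing no
code with the library implementations they cross-check.
"""

from __future__ import annotations

import numpy as np


def _instance_sets(m: np.ndarray) -> dict[int, set]:
    out = {}
    for label in np.unique(m):
        if label == 0:
            continue
        ys, xs = np.nonzero(m == label)
        out[int(label)] = set(zip(ys.tolist(), xs.tolist()))
    return out


def dice_oracle(x: np.ndarray, y: np.ndarray) -> float:
    xs = set(zip(*np.nonzero(np.asarray(x) > 0)))
    ys = set(zip(*np.nonzero(np.asarray(y) > 0)))
    if not xs and not ys:
        return 1.0
    return 2.0 * len(xs & ys) / (len(xs) + len(ys))


def aji_oracle(gt: np.ndarray, pred: np.ndarray) -> float:
    gts = _instance_sets(gt)
    preds = _instance_sets(pred)
    if not gts:
        return 1.0 if not preds else 0.0
    used: set[int] = set()
    inter_total = 0
    union_total = 0
    for g_label in sorted(gts):
        g = gts[g_label]
        best, best_j = None, -1.0
        for p_label in sorted(preds):
            if p_label in used:
                continue
            p = preds[p_label]
            inter = len(g & p)
            if inter == 0:
                continue
            j = inter / len(g | p)
            if j > best_j:
                best, best_j = p_label, j
        if best is None:
            union_total += len(g)
            continue
        used.add(best)
        inter_total += len(g & preds[best])
        union_total += len(g | preds[best])
    for p_label, p in preds.items():
        if p_label not in used:
            union_total += len(p)
    if union_total == 0:
        return 1.0
    return inter_total / union_total


def pq_oracle(gt: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    gts = _instance_sets(gt)
    preds = _instance_sets(pred)
    matches = []
    for g_label, g in gts.items():
        for p_label, p in preds.items():
            iou = len(g & p) / len(g | p)
            if iou > 0.5:
                matches.append((g_label, p_label, iou))
    tp = len(matches)
    fp = len(preds) - tp
    fn = len(gts) - tp
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0
    dq = tp / (tp + 0.5 * fp + 0.5 * fn)
    sq = sum(m[2] for m in matches) / tp if tp else 0.0
    return dq, sq, dq * sq


def random_instance_map(rng: np.random.Generator, size: int = 48,
                        max_instances: int = 6) -> np.ndarray:
    """Random blobby instance map: a few rectangles and discs, later
    ones overwriting earlier ones."""
    m = np.zeros((size, size), dtype=np.int32)
    n = int(rng.integers(0, max_instances + 1))
    for label in range(1, n + 1):
        if rng.random() < 0.5:
            y, x = rng.integers(0, size, 2)
            h, w = rng.integers(3, size // 2, 2)
            m[y:y + h, x:x + w] = label
        else:
            cy, cx = rng.integers(0, size, 2)
            r = int(rng.integers(2, size // 4))
            yy, xx = np.ogrid[:size, :size]
            m[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = label
    # relabel to consecutive labels, dropping overwritten instances
    out = np.zeros_like(m)
    for new, old in enumerate(np.unique(m[m > 0]), start=1):
        out[m == old] = new
    return out
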