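"""Independent brute-force oracles used to validate the pipeline primitives.

Everything here is written as plain Python loops / direct definitions, kept
deliberately separate from the implementations under test.
"""

from __future__ import annotations

import numpy as np


def motion_image_oracle(a, b, c, erosion_size=3, dilation_size=5, threshold=15.0):
    """Pixel-loop evaluation of the double-difference + morphology formula.

    Out-of-bounds pixels are treated as background (0) for both operators.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    h, w = a.shape
    dif = np.abs(a - b) - np.abs(b - c)
    binary = np.zeros((h, w), bool)
    for y in range(h):
        for x in range(w):
            v = dif[y, x]
            if v < 0:
                v = 0.0
            binary[y, x] = v >= threshold

    def erode(img, k):
        r = k // 2
        out = np.zeros_like(img)
        for y in range(h):
            for x in range(w):
                ok = True
                for dy in range(-r, k - r):
                    for dx in range(-r, k - r):
                        yy, xx = y + dy, x + dx
                        if yy < 0 or yy >= h or xx < 0 or xx >= w or not img[yy, xx]:
                            ok = False
                            break
                    if not ok:
                        break
                out[y, x] = ok
        return out

    def dilate(img, k):
        r = k // 2
        out = np.zeros_like(img)
        for y in range(h):
            for x in range(w):
                hit = False
                for dy in range(-r, k - r):
                    for dx in range(-r, k - r):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and img[yy, xx]:
                            hit = True
                            break
                    if hit:
                        break
                out[y, x] = hit
        return out

    if erosion_size > 1:
        binary = erode(binary, erosion_size)
    if dilation_size > 1:
        binary = dilate(binary, dilation_size)
    return binary


def winding_number_inside(p, vertices, eps=1e-9):
    """Winding-number point-in-polygon test; edge points count inside."""
    px, py = float(p[0]), float(p[1])
    n = len(vertices)
    wn = 0
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
        if abs(cross) <= eps * max(1.0, abs(x1 - x0) + abs(y1 - y0)):
            if (
                min(x0, x1) - eps <= px <= max(x0, x1) + eps
                and min(y0, y1) - eps <= py <= max(y0, y1) + eps
            ):
                return True
        if y0 <= py:
            if y1 > py and cross > 0:
                wn += 1
        else:
            if y1 <= py and cross < 0:
                wn -= 1
    return wn != 0


def counting_box_oracle(features, search_x, search_y, search_w, search_h, box_w, box_h):
    """Exhaustive argmax over all counting-box placements.

    Returns (best_x, best_y, best_count) with ties broken by smallest
    (y, then x) of the box origin; (None, None, 0) if no features.
    """
    features = np.asarray(features, bool)
    sub = features[search_y : search_y + search_h, search_x : search_x + search_w]
    if not sub.any():
        return None, None, 0
    best = (-1, None, None)
    for by in range(search_h - box_h + 1):
        for bx in range(search_w - box_w + 1):
            cnt = int(sub[by : by + box_h, bx : bx + box_w].sum())
            if cnt > best[0]:
                best = (cnt, bx, by)
    return best[1] + search_x, best[2] + search_y, best[0]


def scanline_fill(vertices, shape):
    """Per-pixel polygon rasterization by individual membership tests."""
    h, w = shape
    out = np.zeros((h, w), bool)
    for y in range(h):
        for x in range(w):
            out[y, x] = winding_number_inside((x, y), vertices)
    return out


def windowed_mean_oracle(values, valid, t):
    """Centered-window mean over valid entries; None where no valid entry."""
    n = len(values)
    half = t // 2
    out = []
    for i in range(n):
        acc = [
            values[j]
            for j in range(max(0, i - half), min(n, i + half + 1))
            if valid[j]
        ]
        out.append(sum(acc) / len(acc) if acc else None)
    return out


def windowed_vote_oracle(labels, window, tie_keeps_current=True):
    """Centered-window majority vote over labels with deterministic ties."""
    n = len(labels)
    half = window // 2
    out = []
    for i in range(n):
        votes = {}
        for j in range(max(0, i - half), min(n, i + half + 1)):
            votes[labels[j]] = votes.get(labels[j], 0) + 1
        best = max(votes.values())
        winners = [k for k, v in votes.items() if v == best]
        if labels[i] in winners and tie_keeps_current:
            out.append(labels[i])
        else:
            out.append(sorted(winners)[0])
    return out
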