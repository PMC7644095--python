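"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive and shares no code path with the
package: run-length encoding by explicit iteration, per-minute membership
counting, dense polyline resampling with bracketed root refinement, an
exhaustive left-edge-anchored cone search, and textbook t / F formulas.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


# ---------------------------------------------------------------------------
# sleep scoring

def rle_bouts(counts, threshold: int) -> list[tuple[int, int]]:
    """Sleep bouts by explicit run-length encoding of the zero pattern."""
    bouts = []
    start = None
    for i, c in enumerate(list(counts) + [1]):  # sentinel closes a trailing run
        if c == 0:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= threshold:
                bouts.append((start, i))
            start = None
    return bouts


def per_minute_totals(intervals, window: tuple[int, int]) -> tuple[int, int]:
    """(total minutes, bout count) by testing every minute's membership."""
    a, b = window
    total = 0
    n = 0
    for s, e in intervals:
        overlap = sum(1 for m in range(a, b) if s <= m < e)
        total += overlap
        if overlap > 0:
            n += 1
    return total, n


# ---------------------------------------------------------------------------
# Sholl geometry

def dense_crossings(skel, radii, step: float = 0.01):
    """Ring crossings by dense resampling and sign-change bracketing.

    Each branch is resampled at ``step`` um arclength (original vertices
    included, so every bracket lies on a single original segment); a sign
    change of (distance - r) between consecutive samples brackets one
    transversal crossing, whose angle is refined by root bracketing on the
    exact radial distance along the polyline.

    Returns (counts_per_ring, angles_deg).
    """
    counts = np.zeros(len(radii), dtype=int)
    angles: list[float] = []
    root = np.asarray(skel.root, dtype=float)
    for branch in skel.branches:
        pts = np.asarray(branch, dtype=float) - root
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        dense_s = np.unique(np.concatenate([np.arange(0.0, cum[-1], step), cum]))

        def pos(s):
            x = np.interp(s, cum, pts[:, 0])
            y = np.interp(s, cum, pts[:, 1])
            return np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])

        d = np.linalg.norm(pos(dense_s), axis=1)
        for k, r in enumerate(radii):
            f = d - r
            sign_change = f[:-1] * f[1:] < 0
            for i in np.flatnonzero(sign_change):
                s_star = brentq(
                    lambda s: float(np.linalg.norm(pos(s)[0]) - r),
                    dense_s[i], dense_s[i + 1], xtol=1e-12,
                )
                p = pos(s_star)[0]
                counts[k] += 1
                angles.append(float(np.degrees(np.arctan2(p[1], p[0]))) % 360.0)
    return counts, np.asarray(angles)


def anchored_cone_max(angles, full_angle_deg: float) -> int:
    """Maximum crossings inside a cone, by exhaustive left-edge anchoring.

    A maximal cone can be rotated clockwise until its left (lower-angle)
    edge touches a crossing, so trying every crossing angle as the left edge
    is exhaustive.  Membership in [a, a + w] is evaluated with explicit
    wraparound, a different arithmetic path from the implementation.
    """
    angles = sorted(float(a) % 360.0 for a in angles)
    if not angles:
        raise ValueError("no angles")
    w = full_angle_deg
    tol = 1e-9
    best = 0
    for a in angles:
        count = 0
        for b in angles:
            delta = (b - a) % 360.0
            if delta <= w + tol or delta >= 360.0 - tol:
                count += 1
        best = max(best, count)
    return best


# ---------------------------------------------------------------------------
# statistics

def student_t(a, b) -> float:
    """Pooled-variance two-sample t statistic from the textbook formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def oneway_f(*samples) -> float:
    """One-way ANOVA F from between/within mean squares, written out."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    allv = np.concatenate(samples)
    grand = allv.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_between = len(samples) - 1
    df_within = len(allv) - len(samples)
    return float((ss_between / df_between) / (ss_within / df_within))
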