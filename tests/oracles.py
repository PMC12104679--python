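"""Independent brute-force oracles for the morphometric features.

Deliberately naive: convex hull by monotone chain on pixel corners, shoelace
area, edge-counting perimeter, O(n^2) chord search.  These stay independent of
the implementations they check.
"""

import numpy as np


def brute_area(mask):
    return sum(1 for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c])


def brute_extents(mask):
    rows = [r for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    cols = [c for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    return max(cols) - min(cols) + 1, max(rows) - min(rows) + 1


def brute_com(mask):
    pts = [(c, r) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    return (
        sum(p[0] for p in pts) / len(pts),
        sum(p[1] for p in pts) / len(pts),
    )


def brute_perimeter(mask):
    h, w = mask.shape
    edges = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    edges += 1
    return float(edges)


def corner_points(mask):
    pts = set()
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                pts.update({(c, r), (c + 1, r), (c, r + 1), (c + 1, r + 1)})
    return sorted(pts)


def monotone_chain(points):
    """Convex hull (counter-clockwise in y-up convention) of 2D points."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) == 1:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def shoelace(verts):
    a = 0.0
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        a += x0 * y1 - x1 * y0
    return abs(a) / 2.0


def brute_hull(mask):
    """(area, n_vertices, vertices) of the corner-lattice convex hull."""
    verts = monotone_chain(corner_points(mask))
    return shoelace(verts), len(verts), verts


def _seg_dist(p, a, b):
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(p - a)))
    t = min(1.0, max(0.0, float((p - a) @ ab) / denom))
    return float(np.hypot(*(p - (a + t * ab))))


def brute_longest_path(mask, eps=0.75):
    """Longest hull-vertex chord passing within eps of the centroid.

    Same fallback convention as the implementation: twice the max
    centroid-to-vertex distance when no chord qualifies.
    """
    _, _, verts = brute_hull(mask)
    com = brute_com(mask)
    best = -1.0
    for i in range(len(verts)):
        for j in range(i + 1, len(verts)):
            if _seg_dist(com, verts[i], verts[j]) <= eps:
                d = float(np.hypot(verts[i][0] - verts[j][0], verts[i][1] - verts[j][1]))
                best = max(best, d)
    if best >= 0:
        return best
    return 2.0 * max(
        float(np.hypot(v[0] - com[0], v[1] - com[1])) for v in verts
    )
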