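"""Body-ellipse geometry for arena-tracked animals.

Each animal is an ellipse with semi-major axis ``a`` along its heading
``theta`` and semi-minor axis ``b``.  The "nose" is the front tip of the
ellipse.  Two quantities drive the interaction definition downstream:

* the Euclidean distance from a focal animal's nose to the closest point
  of another animal's body ellipse (zero if the nose is inside it), and
* the total angle of the focal animal's field of view occluded by the
  other animal's body, measured from the nose.

All functions are vectorized over numpy arrays and broadcast like ufuncs.
Angles are radians; positions are millimetres, arena-centered.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "nose_position",
    "point_to_ellipse_distance",
    "nose_to_ellipse_distance",
    "angle_subtended",
]

TWO_PI = 2.0 * np.pi


def wrap_angle(angle):
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(angle, dtype=float), TWO_PI)


def nose_position(x, y, theta, a):
    """Front tip of the body ellipse: ``(x + a cos(theta), y + a sin(theta))``."""
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    a = np.asarray(a, dtype=float)
    return x + a * np.cos(theta), np.asarray(y, dtype=float) + a * np.sin(theta)


def _to_ellipse_frame(px, py, cx, cy, theta):
    """Rotate/translate points into the frame whose x-axis is the ellipse's major axis."""
    dx = np.asarray(px, dtype=float) - np.asarray(cx, dtype=float)
    dy = np.asarray(py, dtype=float) - np.asarray(cy, dtype=float)
    ct, st = np.cos(theta), np.sin(theta)
    return ct * dx + st * dy, -st * dx + ct * dy


def point_to_ellipse_distance(px, py, cx, cy, theta, a, b,
                              n_grid: int = 96, n_refine: int = 48):
    """Distance from points to ellipses (0 if a point is inside its ellipse).

    The boundary is parametrized as ``(a cos t, b sin t)``; the squared
    distance is minimized by a coarse grid scan (which isolates the basin of
    the global minimum) followed by ternary refinement.  With the default
    settings the parameter is located to ~1e-9 rad, far below the 1e-4 mm
    accuracy the interaction pipeline requires.
    """
    u, v = _to_ellipse_frame(px, py, cx, cy, theta)
    u, v, a, b = np.broadcast_arrays(u, v, np.asarray(a, dtype=float),
                                     np.asarray(b, dtype=float))
    u = np.abs(u)  # exploit 4-fold symmetry
    v = np.abs(v)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    # coarse scan over the first quadrant of the boundary
    ts = np.linspace(0.0, np.pi / 2.0, n_grid)
    best_d2 = np.full(u.shape, np.inf)
    best_t = np.zeros(u.shape)
    for t in ts:
        d2 = (u - a * np.cos(t)) ** 2 + (v - b * np.sin(t)) ** 2
        better = d2 < best_d2
        best_d2 = np.where(better, d2, best_d2)
        best_t = np.where(better, t, best_t)

    h = (np.pi / 2.0) / (n_grid - 1)
    lo = np.clip(best_t - h, 0.0, np.pi / 2.0)
    hi = np.clip(best_t + h, 0.0, np.pi / 2.0)

    def d2_at(t):
        return (u - a * np.cos(t)) ** 2 + (v - b * np.sin(t)) ** 2

    for _ in range(n_refine):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        left = d2_at(m1) < d2_at(m2)
        hi = np.where(left, m2, hi)
        lo = np.where(left, lo, m1)

    t = 0.5 * (lo + hi)
    dist = np.sqrt(d2_at(t))
    return np.where(inside, 0.0, dist)


def nose_to_ellipse_distance(xi, yi, thetai, ai, xj, yj, thetaj, aj, bj, **kw):
    """Distance from animal i's nose to the closest point of animal j's ellipse."""
    nx, ny = nose_position(xi, yi, thetai, ai)
    return point_to_ellipse_distance(nx, ny, xj, yj, thetaj, aj, bj, **kw)


def _arc_overlap(arc_start, arc_width, win_start, win_width):
    """Length of the overlap between two circular arcs (start, width)."""
    s = np.mod(arc_start - win_start, TWO_PI)
    end = s + arc_width
    ov = np.clip(np.minimum(end, win_width) - s, 0.0, None)
    ov = ov + np.clip(np.minimum(end - TWO_PI, win_width), 0.0, None)
    return ov


def angle_subtended(xi, yi, thetai, ai, xj, yj, thetaj, aj, bj, fov=TWO_PI):
    """Angle of i's field of view (cone of width ``fov`` about its heading,
    apex at its nose) occluded by j's body ellipse.

    Computed in closed form from the two tangent lines drawn from the nose
    to the ellipse: mapping j's ellipse to the unit circle turns tangency
    into circle tangency, and mapping the tangent points back gives the
    exact angular extent of the occluded arc, which is then intersected
    with the field-of-view arc.  A nose inside j's body sees only j,
    so the whole field of view is returned.
    """
    nx, ny = nose_position(xi, yi, thetai, ai)
    u, v = _to_ellipse_frame(nx, ny, xj, yj, thetaj)
    aj = np.asarray(aj, dtype=float)
    bj = np.asarray(bj, dtype=float)
    qx, qy = u / aj, v / bj
    d2 = qx ** 2 + qy ** 2
    inside = d2 <= 1.0
    d2 = np.where(inside, 4.0, d2)  # dummy external value; result overwritten below
    s = np.sqrt(np.clip(d2 - 1.0, 0.0, None))

    # tangent points on the unit circle seen from (qx, qy)
    t1x = (qx + s * qy) / d2
    t1y = (qy - s * qx) / d2
    t2x = (qx - s * qy) / d2
    t2y = (qy + s * qx) / d2

    # map back to world coordinates
    ct, st = np.cos(thetaj), np.sin(thetaj)

    def back(tx, ty):
        ex, ey = aj * tx, bj * ty
        return xj + ct * ex - st * ey, yj + st * ex + ct * ey

    w1x, w1y = back(t1x, t1y)
    w2x, w2y = back(t2x, t2y)
    d1 = np.arctan2(w1y - ny, w1x - nx)
    d2ang = np.arctan2(w2y - ny, w2x - nx)
    dc = np.arctan2(np.asarray(yj, dtype=float) - ny,
                    np.asarray(xj, dtype=float) - nx)

    # occluded arc: the one between the tangent directions containing the
    # direction to the ellipse center
    w_ccw = np.mod(d2ang - d1, TWO_PI)
    contains = np.mod(dc - d1, TWO_PI) <= w_ccw
    arc_start = np.where(contains, d1, d2ang)
    arc_width = np.where(contains, w_ccw, TWO_PI - w_ccw)

    fov = np.asarray(fov, dtype=float)
    win_start = np.asarray(thetai, dtype=float) - fov / 2.0
    out = _arc_overlap(arc_start, arc_width, win_start, fov)
    return np.where(inside, np.broadcast_to(fov, out.shape), out)
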