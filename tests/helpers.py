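"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) they verify: flood-fill labeling by explicit BFS, hole filling
by border flood, point-in-polygon by ray casting, and ellipse perimeter
by numeric quadrature of the arc-length integral.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.integrate import quad


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label 8-connected components by BFS, raster-scan seed order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nrows, ncols = mask.shape
    current = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = current
                while queue:
                    r, c = queue.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < nrows
                                and 0 <= cc < ncols
                                and mask[rr, cc]
                                and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = current
                                queue.append((rr, cc))
    return labels, current


def fill_holes_by_border_flood(mask: np.ndarray) -> np.ndarray:
    """Definition-based hole filling: background stays background only if
    4-connected to the image border."""
    mask = np.asarray(mask, dtype=bool)
    nrows, ncols = mask.shape
    reach = np.zeros(mask.shape, dtype=bool)
    queue = deque()
    for r in range(nrows):
        for c in (0, ncols - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    for c in range(ncols):
        for r in (0, nrows - 1):
            if not mask[r, c] and not reach[r, c]:
                reach[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and not mask[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                queue.append((rr, cc))
    return mask | ~reach


def ray_cast_inside(x: float, y: float, vertices) -> bool:
    """Point-in-polygon by ray casting; points on an edge count as inside."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-edge check (closed region): collinear and within the segment box
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and min(y1, y2) - 1e-12 <= y <= max(
                y1, y2
            ) + 1e-12:
                return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


def ellipse_perimeter_quadrature(a: float, b: float) -> float:
    """Perimeter of an ellipse by numeric quadrature of the arc length:
    integral over theta of sqrt(a^2 sin^2 + b^2 cos^2)."""
    integrand = lambda th: np.sqrt(a**2 * np.sin(th) ** 2 + b**2 * np.cos(th) ** 2)
    val, _ = quad(integrand, 0.0, 2.0 * np.pi, limit=200)
    return float(val)


def er_from_quantities(S: float, p: float, l_minor: float, l_major: float) -> float:
    """The extensibility-ratio formula applied directly to raw quantities."""
    return abs(1.0 - (4.0 * np.pi * S / p**2) * (l_minor / l_major))
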