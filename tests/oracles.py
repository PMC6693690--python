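"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration (per-cell loops,
heap-based shortest paths, dense point-in-polygon rasterization), sharing no
code path with the implementation it checks.
"""

from __future__ import annotations

import heapq
import math

import numpy as np
import shapely

SQRT2 = math.sqrt(2.0)


def nearest_source_fill_oracle(values, covered, fine_rects, coarse_rects,
                               origin_x, origin_y, cell_size, nodata=-9999.0):
    """Brute-force two-pass sealed nearest-source fill.

    ``fine_rects``/``coarse_rects`` are lists of (c0, r0, c1, r1) cell-index
    rectangles (half-open), in unit_id order.  Cell membership, nearest
    source search (ties by smallest row-major index), the fine pass, and the
    coarse pass for units with zero covered cells are all enumerated
    directly, per cell.
    """
    nrow, ncol = values.shape
    out = np.full((nrow, ncol), nodata, dtype=float)
    out[covered] = values[covered]

    def center(r, c):
        return (origin_x + (c + 0.5) * cell_size,
                origin_y - (r + 0.5) * cell_size)

    def cells_in(rect):
        c0, r0, c1, r1 = rect
        return [(r, c) for r in range(r0, r1) for c in range(c0, c1)]

    def fill(targets, sources, src_values):
        for (r, c) in targets:
            x, y = center(r, c)
            best = None
            best_d = None
            for (rs, cs) in sources:  # row-major order -> first min wins
                xs, ys = center(rs, cs)
                d = (x - xs) ** 2 + (y - ys) ** 2
                if best_d is None or d < best_d:
                    best_d = d
                    best = (rs, cs)
            if best is not None:
                out[r, c] = src_values[best]

    # Pass 1
    for rect in fine_rects:
        cells = cells_in(rect)
        sources = [(r, c) for (r, c) in cells if covered[r, c]]
        if not sources:
            continue
        targets = [(r, c) for (r, c) in cells if not covered[r, c]]
        fill(targets, sources, {s: values[s] for s in sources})

    # Pass 2
    pass1 = out.copy()
    bearing = [(r, c) for r in range(nrow) for c in range(ncol)
               if pass1[r, c] != nodata]
    for rect in coarse_rects:
        cells = cells_in(rect)
        if any(covered[r, c] for (r, c) in cells):
            continue
        inside = [(r, c) for (r, c) in cells if pass1[r, c] != nodata]
        sources = inside if inside else bearing
        targets = [(r, c) for (r, c) in cells if pass1[r, c] == nodata]
        fill(targets, sources, {s: pass1[s] for s in sources})
    return out


def barrier_idw_oracle(barrier, samples, origin_x, origin_y, cell_size,
                       power=2.0, k=8, nodata=-9999.0):
    """Heap-based single-source shortest paths per sample over the
    8-connected grid (no corner cutting through diagonal barrier pairs),
    then the IDW formula per free cell."""
    nrow, ncol = barrier.shape
    n_s = len(samples)
    dist = np.full((n_s, nrow, ncol), np.inf)

    def neighbors(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrow and 0 <= cc < ncol):
                    continue
                if barrier[rr, cc]:
                    continue
                if dr != 0 and dc != 0:
                    if barrier[r + dr, c] and barrier[r, c + dc]:
                        continue
                    yield rr, cc, SQRT2 * cell_size
                else:
                    yield rr, cc, cell_size

    cells_of = []
    vals = []
    for si, (sr, sc, sval) in enumerate(samples):
        cells_of.append((sr, sc))
        vals.append(sval)
        d = dist[si]
        d[sr, sc] = 0.0
        heap = [(0.0, sr, sc)]
        while heap:
            dd, r, c = heapq.heappop(heap)
            if dd > d[r, c]:
                continue
            for rr, cc, w in neighbors(r, c):
                nd = dd + w
                if nd < d[rr, cc]:
                    d[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))

    out = np.full((nrow, ncol), nodata, dtype=float)
    for r in range(nrow):
        for c in range(ncol):
            if barrier[r, c]:
                continue
            ds = dist[:, r, c]
            if not np.isfinite(ds).any():
                continue
            order = np.argsort(ds, kind="stable")[:min(k, n_s)]
            dk = ds[order]
            if (dk == 0).any():
                out[r, c] = float(np.mean([vals[i] for i in order[dk == 0]]))
                continue
            finite = np.isfinite(dk)
            w = np.zeros_like(dk)
            w[finite] = 1.0 / dk[finite] ** power
            if w.sum() == 0:
                continue
            out[r, c] = float(np.sum(w * np.array(vals)[order]) / w.sum())
    return out


def rasterized_area(geom, bounds, res=1.0):
    """Area of a geometry by counting res×res sample cells whose centers
    fall inside, over the given (minx, miny, maxx, maxy) window."""
    minx, miny, maxx, maxy = bounds
    xs = np.arange(minx + res / 2, maxx, res)
    ys = np.arange(miny + res / 2, maxy, res)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel())
    return float(inside.sum()) * res * res


def densified_station_oracle(coords, point, step=1.0):
    """Arc-length position of the nearest densified vertex to ``point``."""
    px, py = point
    best_d = np.inf
    best_s = 0.0
    s = 0.0
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        seg = math.hypot(x1 - x0, y1 - y0)
        n = max(int(math.ceil(seg / step)), 1)
        for i in range(n + 1):
            t = i / n
            x = x0 + t * (x1 - x0)
            y = y0 + t * (y1 - y0)
            d = math.hypot(x - px, y - py)
            if d < best_d:
                best_d = d
                best_s = s + t * seg
        s += seg
    return best_s
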