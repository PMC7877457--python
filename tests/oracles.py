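"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain Python loops over pixels
(or exhaustive enumeration), separate from the vectorized implementations
in the package, so each measurement definition is checked by two
independent code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

SQ2 = math.sqrt(2.0)

# Crofton intercept weights per 2x2 configuration, written out explicitly
# (code = br + 2*tr + 4*bl + 8*tl)
_CROFTON_LUT = {
    1: math.pi / 4 * (1 + 1 / SQ2),
    2: math.pi / (4 * SQ2),
    3: math.pi / (2 * SQ2),
    5: math.pi / 4 * (1 + 1 / SQ2),
    7: math.pi / (4 * SQ2),
    8: math.pi / 4,
    9: math.pi / 2,
    10: math.pi / (4 * SQ2),
    11: math.pi / (4 * SQ2),
    12: math.pi / 4,
    13: math.pi / 2,
}


def crofton_perimeter_loop(mask: np.ndarray) -> float:
    m = np.pad(np.asarray(mask, bool), 1)
    total = 0.0
    for i in range(m.shape[0] - 1):
        for j in range(m.shape[1] - 1):
            tl, tr = int(m[i, j]), int(m[i, j + 1])
            bl, br = int(m[i + 1, j]), int(m[i + 1, j + 1])
            code = br + 2 * tr + 4 * bl + 8 * tl
            total += _CROFTON_LUT.get(code, 0.0)
    return total


def _hull_edges(points: list[tuple[float, float]]):
    """All edges of the convex hull by the brute-force all-pairs test."""
    edges = []
    n = len(points)
    for a, b in itertools.combinations(range(n), 2):
        ax, ay = points[a]
        bx, by = points[b]
        nx, ny = by - ay, ax - bx  # normal of the segment
        if nx == 0 and ny == 0:
            continue
        side_pos = side_neg = False
        for k in range(n):
            if k in (a, b):
                continue
            s = nx * (points[k][0] - ax) + ny * (points[k][1] - ay)
            if s > 1e-12:
                side_pos = True
            elif s < -1e-12:
                side_neg = True
        if not (side_pos and side_neg):
            edges.append((a, b, nx, ny, side_pos))
    return edges


def convex_hull_area_px_loop(rows, cols) -> int:
    """Hull pixel count: half-plane membership from a brute-force hull."""
    pts = [(float(r), float(c)) for r, c in zip(rows, cols)]
    unique = sorted(set(pts))
    if len(unique) < 3:
        return len(pts)
    # collinearity check
    (x0, y0), (x1, y1) = unique[0], unique[1]
    if all(
        abs((x1 - x0) * (y - y0) - (y1 - y0) * (x - x0)) < 1e-12 for x, y in unique
    ):
        return len(pts)
    edges = _hull_edges(unique)
    count = 0
    for r in range(int(min(rows)), int(max(rows)) + 1):
        for c in range(int(min(cols)), int(max(cols)) + 1):
            ok = True
            for a, b, nx, ny, side_pos in edges:
                ax, ay = unique[a]
                s = nx * (r - ax) + ny * (c - ay)
                # interior lies on the side where the other points are
                if side_pos and s < -1e-9:
                    ok = False
                elif not side_pos and s > 1e-9:
                    ok = False
                if not ok:
                    break
            if ok:
                count += 1
    return count


def euler_number_loop(mask: np.ndarray) -> int:
    """Components (8-connected) minus holes (4-connected background)."""

    def flood_count(grid, connectivity8):
        seen = np.zeros_like(grid, dtype=bool)
        n = 0
        offs = (
            [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
            if connectivity8
            else [(-1, 0), (1, 0), (0, -1), (0, 1)]
        )
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                if grid[i, j] and not seen[i, j]:
                    n += 1
                    stack = [(i, j)]
                    seen[i, j] = True
                    while stack:
                        x, y = stack.pop()
                        for dx, dy in offs:
                            u, v = x + dx, y + dy
                            if (
                                0 <= u < grid.shape[0]
                                and 0 <= v < grid.shape[1]
                                and grid[u, v]
                                and not seen[u, v]
                            ):
                                seen[u, v] = True
                                stack.append((u, v))
        return n

    mask = np.asarray(mask, bool)
    components = flood_count(mask, connectivity8=True)
    padded_bg = ~np.pad(mask, 1)
    bg_regions = flood_count(padded_bg, connectivity8=False)
    holes = bg_regions - 1  # outer background is one region
    return components - holes


def shape_features_loop(rows, cols) -> dict:
    """The whole shape battery via explicit loops."""
    rows = [int(r) for r in rows]
    cols = [int(c) for c in cols]
    n = len(rows)
    area = n
    rbar = sum(rows) / n
    cbar = sum(cols) / n
    mu_rr = sum((r - rbar) ** 2 for r in rows) / n + 1 / 12
    mu_cc = sum((c - cbar) ** 2 for c in cols) / n + 1 / 12
    mu_rc = sum((r - rbar) * (c - cbar) for r, c in zip(rows, cols)) / n
    common = math.sqrt((mu_rr - mu_cc) ** 2 + 4 * mu_rc**2)
    l1 = (mu_rr + mu_cc + common) / 2
    l2 = (mu_rr + mu_cc - common) / 2
    r0, r1 = min(rows), max(rows)
    c0, c1 = min(cols), max(cols)
    mask = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=bool)
    for r, c in zip(rows, cols):
        mask[r - r0 + 1, c - c0 + 1] = True
    perim = crofton_perimeter_loop(mask)
    member = set(zip(rows, cols))
    # radius: distance to the nearest non-member pixel (image border counts
    # as background via the padded mask)
    radii = []
    bg = [
        (i + r0 - 1, j + c0 - 1)
        for i in range(mask.shape[0])
        for j in range(mask.shape[1])
        if not mask[i, j]
    ]
    for r, c in zip(rows, cols):
        radii.append(min(math.hypot(r - br, c - bc) for br, bc in bg))
    msd = sum((r - rbar) ** 2 + (c - cbar) ** 2 for r, c in zip(rows, cols)) / n
    orientation = 0.5 * math.atan2(2 * mu_rc, mu_rr - mu_cc)
    if orientation <= -math.pi / 2 + 1e-9:
        orientation += math.pi
    return {
        "area": area,
        "equivalent_diameter": 2 * math.sqrt(area / math.pi),
        "compactness": msd / (area / (2 * math.pi)),
        "eccentricity": math.sqrt(max(0.0, 1 - l2 / l1)),
        "euler_number": euler_number_loop(mask),
        "extent": area / ((r1 - r0 + 1) * (c1 - c0 + 1)),
        "form_factor": 4 * math.pi * area / perim**2,
        "major_axis_length": 4 * math.sqrt(l1),
        "minor_axis_length": 4 * math.sqrt(l2),
        "maximum_radius": max(radii),
        "mean_radius": sum(radii) / n,
        "orientation": orientation,
        "perimeter": perim,
        "solidity": area / convex_hull_area_px_loop(rows, cols),
    }


def _median_loop(vals):
    vals = sorted(vals)
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2


def _percentile_loop(vals, q):
    """Linear interpolation between order statistics (inclusive method)."""
    vals = sorted(vals)
    n = len(vals)
    pos = (n - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return vals[lo] * (1 - frac) + vals[hi] * frac


def intensity_features_loop(rows, cols, image) -> dict:
    member = set(zip(rows, cols))
    vals = [float(image[r, c]) for r, c in zip(rows, cols)]
    n = len(vals)
    edge_vals = []
    for r, c in zip(rows, cols):
        if any(
            (r + dr, c + dc) not in member
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
        ):
            edge_vals.append(float(image[r, c]))
    total = sum(vals)
    mean_r = sum(rows) / n
    mean_c = sum(cols) / n
    if total > 0:
        wr = sum(r * float(image[r, c]) for r, c in zip(rows, cols)) / total
        wc = sum(c * float(image[r, c]) for r, c in zip(rows, cols)) / total
        md = math.hypot(wr - mean_r, wc - mean_c)
    else:
        md = 0.0
    mean = total / n
    var = sum((v - mean) ** 2 for v in vals) / n
    med = _median_loop(vals)
    if edge_vals:
        emean = sum(edge_vals) / len(edge_vals)
        evar = sum((v - emean) ** 2 for v in edge_vals) / len(edge_vals)
    else:
        evar = 0.0
    return {
        "integrated_intensity": total,
        "integrated_intensity_edge": sum(edge_vals),
        "min_intensity": min(vals),
        "max_intensity": max(vals),
        "min_intensity_edge": min(edge_vals) if edge_vals else 0.0,
        "std_intensity": math.sqrt(var),
        "std_intensity_edge": math.sqrt(evar),
        "mad_intensity": _median_loop([abs(v - med) for v in vals]),
        "lower_quartile_intensity": _percentile_loop(vals, 25),
        "upper_quartile_intensity": _percentile_loop(vals, 75),
        "mass_displacement": md,
    }


def permutation_p_exhaustive(a, b) -> float:
    """Two-tailed permutation p by full enumeration of relabelings."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)
    observed = sum(a) / n1 - sum(b) / len(b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diff = sum(ga) / len(ga) - sum(gb) / len(gb)
        total += 1
        if abs(diff) >= abs(observed) - 1e-12:
            count += 1
    return count / total


def power_t2n_quadrature(d, n1, n2, alpha=0.05) -> float:
    """Two-sample t power by numerical integration over the chi-square
    denominator (independent of any noncentral-t CDF implementation)."""
    from scipy import integrate
    from scipy.stats import chi2, norm
    from scipy.stats import t as t_dist

    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = t_dist.ppf(1 - alpha / 2, df)

    def integrand(v):
        s = math.sqrt(v / df)
        hit = norm.sf(tcrit * s - ncp) + norm.cdf(-tcrit * s - ncp)
        return chi2.pdf(v, df) * hit

    val, _ = integrate.quad(integrand, 0, chi2.ppf(1 - 1e-12, df), limit=200)
    return val


def find_correlation_loop(df, cutoff):
    """caret-style findCorrelation re-applied with an exhaustive re-check."""
    cols = [c for c in df.columns]
    dropped = []
    # constant columns first
    for c in list(cols):
        if df[c].nunique(dropna=True) <= 1:
            dropped.append(c)
            cols.remove(c)
    while True:
        best = None
        corr = df[cols].corr().abs()
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = corr.iloc[i, j]
                if best is None or r > best[0]:
                    best = (r, i, j)
        if best is None or not best[0] > cutoff:
            break
        _, i, j = best
        mean_i = corr.iloc[i].drop(corr.index[i]).mean()
        mean_j = corr.iloc[j].drop(corr.index[j]).mean()
        victim = cols[j] if mean_j >= mean_i else cols[i]
        dropped.append(victim)
        cols.remove(victim)
    return cols, dropped
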