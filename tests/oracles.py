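"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (loops, full enumeration, all-pairs
distances) and shares no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int
                          ) -> list[set[tuple[int, int]]]:
    """Connected components of a 2D boolean mask by explicit flood fill."""
    nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        nbrs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for i, j in zip(*np.nonzero(mask)):
        if seen[i, j]:
            continue
        stack, comp = [(i, j)], set()
        seen[i, j] = True
        while stack:
            a, b = stack.pop()
            comp.add((a, b))
            for da, db in nbrs:
                x, y = a + da, b + db
                if (0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                        and mask[x, y] and not seen[x, y]):
                    seen[x, y] = True
                    stack.append((x, y))
        comps.append(comp)
    return comps


def brute_surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a face-adjacent background neighbour (loops);
    out-of-lattice counts as background."""
    pts = []
    shape = np.array(mask.shape)
    for idx in np.argwhere(mask):
        for ax in range(mask.ndim):
            hit = False
            for d in (-1, 1):
                n = idx.copy()
                n[ax] += d
                if (n < 0).any() or (n >= shape).any() or not mask[tuple(n)]:
                    pts.append(tuple(idx))
                    hit = True
                    break
            if hit:
                break
    return np.array(pts, dtype=float).reshape(-1, mask.ndim)


def brute_surface_distances(pred: np.ndarray, ref: np.ndarray,
                            spacing) -> tuple[np.ndarray, np.ndarray]:
    """Directed surface distances by exhaustive all-pairs search."""
    spacing = np.asarray(spacing, dtype=float)
    sa = brute_surface_voxels(pred) * spacing
    sb = brute_surface_voxels(ref) * spacing
    d = np.linalg.norm(sa[:, None, :] - sb[None, :, :], axis=2)
    return d.min(axis=1), d.min(axis=0)


def brute_percentile_95(values: np.ndarray) -> float:
    """95th percentile with linear interpolation between order statistics,
    computed by explicit sort-and-index."""
    v = np.sort(np.asarray(values, dtype=float))
    h = 0.95 * (len(v) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def brute_inscribed_thickness(mask2d: np.ndarray, spacing2d) -> float:
    """Inscribed-disk diameter: 2x the largest distance from any mask pixel
    center to the nearest background pixel center, in mm."""
    spacing2d = np.asarray(spacing2d, dtype=float)
    fg = np.argwhere(mask2d) * spacing2d
    bg = np.argwhere(~mask2d) * spacing2d
    d = np.linalg.norm(fg[:, None, :] - bg[None, :, :], axis=2)
    return 2.0 * float(d.min(axis=1).max())


def brute_max_perpendicular(points_mm: np.ndarray, p0, p1) -> float:
    """Max perpendicular distance from points to the line through p0, p1."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    best = 0.0
    for pt in points_mm:
        rel = pt - p0
        best = max(best, abs(d[0] * rel[1] - d[1] * rel[0])
                   / np.linalg.norm(d))
    return best


def anova_icc21(table: np.ndarray) -> float:
    """ICC(2,1) from explicit loop-based sums of squares."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = sum(table[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(table[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(table[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i, j] - grand) ** 2
                 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def wilcoxon_exact_enumeration(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    # midranks of |d|
    order = np.argsort(np.abs(d), kind="stable")
    absd = np.abs(d)[order]
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[j + 1] == absd[i]:
            j += 1
        ranks[i:j + 1] = (i + j) / 2 + 1
        i = j + 1
    rank_of = np.empty(n)
    rank_of[order] = ranks
    w_obs = rank_of[d > 0].sum()
    ws = [sum(r for r, s in zip(rank_of, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def random_blob(rng: np.random.Generator, shape: tuple[int, ...],
                n_seeds: int = 3, r_max: float = 5.0) -> np.ndarray:
    """Union of random balls: a connected-ish test mask with a smooth-ish
    surface (random uniform masks are almost all surface)."""
    mask = np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    for _ in range(n_seeds):
        c = [rng.uniform(0, n - 1) for n in shape]
        r = rng.uniform(1.5, r_max)
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        mask |= d2 <= r ** 2
    return mask
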