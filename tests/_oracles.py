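"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written from the defining formula or by exhaustive
enumeration, deliberately avoiding the code paths (and, where practical,
the libraries) used by the package itself.
"""

from __future__ import annotations

import heapq
import itertools
import math

import numpy as np
from scipy import stats


def otsu_threshold_exhaustive(values: np.ndarray) -> float:
    """Threshold maximising inter-class variance by trying every level."""
    values = np.asarray(values).ravel()
    candidates = np.unique(values)
    best_t, best_var = candidates[0], -1.0
    for t in candidates[:-1]:
        lo = values[values <= t]
        hi = values[values > t]
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def flood_fill_fragments(
    psyn_mask: np.ndarray,
    tubulin_mask: np.ndarray,
    *,
    pixel_size: float,
    min_area_um2: float,
    coloc_fraction: float,
    dilation_radius_px: int,
    connectivity: int = 8,
) -> set[frozenset]:
    """Kept components as pixel sets, via explicit BFS flood fill."""
    h, w = psyn_mask.shape
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    # chessboard-dilated tubulin is wrong: use Euclidean disk like skimage's
    dil = np.zeros_like(tubulin_mask, dtype=bool)
    r = dilation_radius_px
    offs = [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    ] or [(0, 0)]
    for rr, cc in zip(*np.nonzero(tubulin_mask)):
        for dr, dc in offs:
            if 0 <= rr + dr < h and 0 <= cc + dc < w:
                dil[rr + dr, cc + dc] = True

    seen = np.zeros_like(psyn_mask, dtype=bool)
    min_px = math.ceil(min_area_um2 / pixel_size**2 - 1e-9)
    kept: set[frozenset] = set()
    for r0, c0 in zip(*np.nonzero(psyn_mask)):
        if seen[r0, c0]:
            continue
        comp = []
        stack = [(r0, c0)]
        seen[r0, c0] = True
        while stack:
            rr, cc = stack.pop()
            comp.append((rr, cc))
            for dr, dc in nbrs:
                nr, nc = rr + dr, cc + dc
                if 0 <= nr < h and 0 <= nc < w and psyn_mask[nr, nc] and not seen[nr, nc]:
                    seen[nr, nc] = True
                    stack.append((nr, nc))
        frac = sum(dil[rr, cc] for rr, cc in comp) / len(comp)
        if len(comp) >= min_px and frac >= coloc_fraction - 1e-12:
            kept.add(frozenset(comp))
    return kept


def geodesic_length_dijkstra(skeleton_pixels, pixel_size: float) -> float:
    """Largest pairwise shortest-path over skeleton pixels (√2 diagonals)."""
    pts = [tuple(p) for p in skeleton_pixels]
    if len(pts) <= 1:
        return 0.0
    pset = set(pts)
    best = 0.0
    for src in pts:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, (r, c) = heapq.heappop(heap)
            if d > dist.get((r, c), np.inf):
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    nb = (r + dr, c + dc)
                    if nb not in pset:
                        continue
                    nd = d + (math.sqrt(2.0) if dr and dc else 1.0)
                    if nd < dist.get(nb, np.inf):
                        dist[nb] = nd
                        heapq.heappush(heap, (nd, nb))
        best = max(best, max(dist.values()))
    return best * pixel_size


def grubbs_exclusions_direct(
    values, alpha: float = 0.05, min_keep: int = 7
) -> list[int]:
    """Iterative two-sided Grubbs exclusions straight from the formula."""
    vals = list(map(float, values))
    active = list(range(len(vals)))
    out: list[int] = []
    while len(active) >= max(3, min_keep):
        x = np.array([vals[i] for i in active])
        n = len(x)
        s = x.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(x - x.mean())
        k = int(np.argmax(dev))
        g = dev[k] / s
        t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
        g_crit = ((n - 1) / math.sqrt(n)) * math.sqrt(t2 / (n - 2 + t2))
        if g > g_crit:
            out.append(active.pop(k))
        else:
            break
    return sorted(out)


def mann_whitney_exact_enumeration(a, b) -> tuple[float, float]:
    """(U of group A, two-sided p) by enumerating all group assignments."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    ranks = {}
    i = 0
    while i < len(pooled):  # midranks
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        for k in range(i, j):
            ranks.setdefault(pooled[i], (i + j + 1) / 2)
        i = j

    def u_of(sample, n_other):
        r = sum(ranks[v] for v in sample)
        return r - len(sample) * (len(sample) + 1) / 2

    n1, n2 = len(a), len(b)
    u_obs = u_of(a, n2)
    u_min = min(u_obs, n1 * n2 - u_obs)
    all_vals = a + b
    idx = range(len(all_vals))
    total = 0
    extreme = 0
    for comb in itertools.combinations(idx, n1):
        grp = [all_vals[i] for i in comb]
        u = u_of(grp, n2)
        total += 1
        if u <= u_min + 1e-9 or u >= n1 * n2 - u_min - 1e-9:
            extreme += 1
    return u_obs, extreme / total
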