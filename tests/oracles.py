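"""Independent brute-force oracles for the texture features.

Everything here is written as plain nested loops over pixels, structured
differently from the library implementation, so agreement between the two is
a meaningful check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _pop_skew_kurt(values):
    n = len(values)
    m = sum(values) / n
    v = sum((x - m) ** 2 for x in values) / n
    if v == 0:
        return 0.0, 0.0
    skew = sum((x - m) ** 3 for x in values) / n / v ** 1.5
    kurt = sum((x - m) ** 4 for x in values) / n / v ** 2
    return skew, kurt


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_oracle(levels, mask, n_levels, distance=1, directions=DIRECTIONS):
    """Five GLCM features by exhaustive pair enumeration, averaged over directions."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    nrow, ncol = levels.shape
    per_dir = []
    for (dr, dc) in directions:
        counts = {}
        for r in range(nrow):
            for c in range(ncol):
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < nrow and 0 <= c2 < ncol and mask[r, c] and mask[r2, c2]:
                    i, j = int(levels[r, c]), int(levels[r2, c2])
                    counts[(i, j)] = counts.get((i, j), 0) + 1
                    counts[(j, i)] = counts.get((j, i), 0) + 1  # symmetrize
        total = sum(counts.values())
        if total == 0:
            continue
        p = {k: v / total for k, v in counts.items()}
        contrast = sum(pij * (i - j) ** 2 for (i, j), pij in p.items())
        energy = sum(pij ** 2 for pij in p.values())
        homog = sum(pij / (1 + (i - j) ** 2) for (i, j), pij in p.items())
        entropy = -sum(pij * math.log2(pij) for pij in p.values() if pij > 0)
        pi = [0.0] * n_levels
        for (i, j), pij in p.items():
            pi[i] += pij
        mu = sum(i * pi[i] for i in range(n_levels))
        var = sum((i - mu) ** 2 * pi[i] for i in range(n_levels))
        if var > 0:
            corr = sum(pij * (i - mu) * (j - mu) for (i, j), pij in p.items()) / var
        else:
            corr = 0.0
        per_dir.append({"contrast": contrast, "correlation": corr,
                        "energy": energy, "homogeneity": homog,
                        "entropy": entropy})
    keys = per_dir[0].keys()
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in keys}


# ---------------------------------------------------------------------------
# GLRL
# ---------------------------------------------------------------------------

def _runs_along(levels, mask, direction):
    """All maximal in-mask constant runs along one direction, as (level, length)."""
    nrow, ncol = levels.shape
    dr, dc = direction
    runs = []
    seen = set()
    for r0 in range(nrow):
        for c0 in range(ncol):
            # walk backwards to find the start of this voxel's line segment
            if (r0, c0) in seen:
                continue
            # start a traversal from every cell with no predecessor on its line
            rp, cp = r0 - dr, c0 - dc
            if 0 <= rp < nrow and 0 <= cp < ncol:
                continue  # not a line start
            r, c = r0, c0
            cur_level, cur_len = None, 0
            while 0 <= r < nrow and 0 <= c < ncol:
                seen.add((r, c))
                if mask[r, c]:
                    lev = int(levels[r, c])
                    if lev == cur_level:
                        cur_len += 1
                    else:
                        if cur_level is not None:
                            runs.append((cur_level, cur_len))
                        cur_level, cur_len = lev, 1
                else:
                    if cur_level is not None:
                        runs.append((cur_level, cur_len))
                    cur_level, cur_len = None, 0
                r, c = r + dr, c + dc
            if cur_level is not None:
                runs.append((cur_level, cur_len))
    return runs


def glrl_oracle(levels, mask, n_levels, directions=DIRECTIONS):
    """Eleven run-length features via direct run enumeration, averaged."""
    levels = np.asarray(levels)
    mask = np.asarray(mask, bool)
    n_pixels = int(mask.sum())
    per_dir = []
    for d in directions:
        runs = _runs_along(levels, mask, d)
        nr = len(runs)
        feats = {
            "SRE": sum(1.0 / L ** 2 for _, L in runs) / nr,
            "LRE": sum(float(L ** 2) for _, L in runs) / nr,
            "RP": nr / n_pixels,
            "LGRE": sum(1.0 / (g + 1) ** 2 for g, _ in runs) / nr,
            "HGRE": sum(float((g + 1) ** 2) for g, _ in runs) / nr,
            "SRLGE": sum(1.0 / ((g + 1) ** 2 * L ** 2) for g, L in runs) / nr,
            "SRHGE": sum((g + 1) ** 2 / L ** 2 for g, L in runs) / nr,
            "LRLGE": sum(L ** 2 / (g + 1) ** 2 for g, L in runs) / nr,
            "LRHGE": sum(float(((g + 1) * L) ** 2) for g, L in runs) / nr,
        }
        by_level = {}
        by_length = {}
        for g, L in runs:
            by_level[g] = by_level.get(g, 0) + 1
            by_length[L] = by_length.get(L, 0) + 1
        feats["GLN"] = sum(v ** 2 for v in by_level.values()) / nr
        feats["RLN"] = sum(v ** 2 for v in by_length.values()) / nr
        per_dir.append(feats)
    keys = per_dir[0].keys()
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in keys}


# ---------------------------------------------------------------------------
# GLGM
# ---------------------------------------------------------------------------

def glgm_oracle(image, mask, spacing=(1.0, 1.0)):
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    dy, dx = spacing
    nrow, ncol = image.shape
    grads = []
    for r in range(nrow):
        for c in range(ncol):
            if not mask[r, c]:
                continue
            if not (0 < r < nrow - 1 and 0 < c < ncol - 1):
                continue
            if not (mask[r - 1, c] and mask[r + 1, c] and mask[r, c - 1] and mask[r, c + 1]):
                continue
            gx = (image[r, c + 1] - image[r, c - 1]) / (2 * dx)
            gy = (image[r + 1, c] - image[r - 1, c]) / (2 * dy)
            grads.append(math.sqrt(gx * gx + gy * gy))
    if not grads:
        return None
    n = len(grads)
    mgr = sum(grads) / n
    vgr = sum((g - mgr) ** 2 for g in grads) / n
    skew, kurt = _pop_skew_kurt(grads)
    return {"MGR": mgr, "VGR": vgr, "skewness": skew, "kurtosis": kurt}


# ---------------------------------------------------------------------------
# Laws
# ---------------------------------------------------------------------------

_VECS = {"L": [1.0, 2.0, 1.0], "E": [-1.0, 0.0, 1.0], "S": [-1.0, 2.0, -1.0]}


def laws_oracle(image, mask):
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    nrow, ncol = image.shape
    roi_mean = image[mask].mean()
    centered = [[(image[r, c] - roi_mean) if mask[r, c] else 0.0
                 for c in range(ncol)] for r in range(nrow)]
    out = {}
    for a in "LES":
        for b in "LES":
            responses = []
            for r in range(nrow):
                for c in range(ncol):
                    if not (0 < r < nrow - 1 and 0 < c < ncol - 1):
                        continue
                    if not all(mask[r + u, c + v]
                               for u in (-1, 0, 1) for v in (-1, 0, 1)):
                        continue
                    resp = sum(
                        _VECS[a][u + 1] * _VECS[b][v + 1] * centered[r + u][c + v]
                        for u in (-1, 0, 1) for v in (-1, 0, 1)
                    )
                    responses.append(abs(resp))
            if responses:
                out[f"{a}3{b}3"] = sum(responses) / len(responses)
            else:
                out[f"{a}3{b}3"] = None
    return out


def random_test_images(n, rng, max_size=6, max_levels=4):
    """Random small (levels, mask) instances whose masks admit all families."""
    out = []
    while len(out) < n:
        nrow = rng.integers(4, max_size + 1)
        ncol = rng.integers(4, max_size + 1)
        levels = rng.integers(0, max_levels, size=(nrow, ncol))
        mask = rng.random((nrow, ncol)) < 0.85
        # need an interior voxel with full 3x3 support for GLGM/Laws
        if glgm_oracle(levels.astype(float), mask) is None:
            continue
        if any(v is None for v in laws_oracle(levels.astype(float), mask).values()):
            continue
        out.append((levels, mask))
    return out
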