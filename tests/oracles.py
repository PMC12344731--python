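"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — pure-Python flood fill, exhaustive
per-voxel scans, O(n²) pairwise loops — and shares no code path with the
package.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def neighbors(idx, shape, connectivity):
    """Yield in-bounds neighbors of a voxel under 6/18/26 connectivity."""
    x, y, z = idx
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                    yield (nx, ny, nz)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected foreground components by BFS flood fill; list of voxel sets."""
    mask = np.asarray(mask) != 0
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for idx in map(tuple, np.argwhere(mask)):
        if seen[idx]:
            continue
        comp = set()
        queue = deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for nb in neighbors(cur, mask.shape, connectivity):
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(comp)
    return comps


def erosion_difference_shell(mask: np.ndarray) -> np.ndarray:
    """Boundary shell: foreground voxels with a 6-neighbor outside the
    foreground, volume-edge voxels included."""
    mask = np.asarray(mask) != 0
    shell = np.zeros(mask.shape, dtype=bool)
    for idx in map(tuple, np.argwhere(mask)):
        on_edge = any(i == 0 or i == s - 1 for i, s in zip(idx, mask.shape))
        if on_edge or any(not mask[nb] for nb in neighbors(idx, mask.shape, 6)):
            shell[idx] = True
    return shell


def brute_force_adjacency(lesion_voxels, shell: np.ndarray) -> bool:
    """Any lesion voxel on or 26-adjacent to a shell voxel? O(n) voxel scan."""
    shell = np.asarray(shell) != 0
    for idx in map(tuple, np.asarray(lesion_voxels)):
        if shell[idx]:
            return True
        for nb in neighbors(idx, shell.shape, 26):
            if shell[nb]:
                return True
    return False


def brute_force_cells(boundaries, lung_bbox_lower, lung_bbox_upper, divisions, voxels):
    """Per-voxel grid-cell assignment by linear scan over the boundary lists."""
    cells = set()
    for vox in map(tuple, np.asarray(voxels)):
        cell = []
        outside = False
        for ax, v in enumerate(vox):
            if not (lung_bbox_lower[ax] <= v < lung_bbox_upper[ax]):
                outside = True
                break
            b = boundaries[ax]
            chosen = divisions - 1
            for i in range(divisions):
                hi_closed = i == divisions - 1
                if b[i] <= v < b[i + 1] or (hi_closed and b[i] <= v <= b[i + 1]):
                    chosen = i
                    break
            cell.append(chosen)
        if not outside:
            cells.add(tuple(cell))
    return cells


def counting_dsc_avd_rvd(g: np.ndarray, s: np.ndarray, voxel_volume_cm3: float):
    """DSC/AVD/RVD by explicit voxel counting loops."""
    g = np.asarray(g) != 0
    s = np.asarray(s) != 0
    ng = ns = ninter = 0
    for idx in itertools.product(*(range(d) for d in g.shape)):
        if g[idx]:
            ng += 1
        if s[idx]:
            ns += 1
        if g[idx] and s[idx]:
            ninter += 1
    d = 1.0 if ng + ns == 0 else 2.0 * ninter / (ng + ns)
    a = voxel_volume_cm3 * abs(ng - ns)
    r = None if ng == 0 else abs(ng - ns) / ng
    return d, a, r


def all_pairs_overlap_matching(gt_sets: list[set], inf_sets: list[set]):
    """Exhaustive overlap matrix: for each GT set, indices of inference sets
    sharing ≥1 voxel; plus false-positive inference indices."""
    matches = {i: [j for j, s in enumerate(inf_sets) if gt & s] for i, gt in enumerate(gt_sets)}
    matched = {j for lst in matches.values() for j in lst}
    fps = [j for j in range(len(inf_sets)) if j not in matched]
    return matches, fps


def exact_rank_sum_p(a, b):
    """Two-sided exact rank-sum p by full enumeration of group relabelings."""
    a, b = list(map(float, a)), list(map(float, b))
    pooled = a + b
    n_a = len(a)

    def u_of(sel):
        grp_a = [pooled[i] for i in sel]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u = 0.0
        for x in grp_a:
            for y in grp_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    center = n_a * len(b) / 2.0
    obs = u_of(tuple(range(n_a)))
    dev = abs(obs - center)
    total = extreme = 0
    for sel in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(set(sel)) - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def all_pairs_axes(voxels_xy, dx, dy):
    """Major/minor axes of one slice by O(n²) loops over voxel centers.

    Tie-break convention (shared with the implementation contract): points
    lexicographically sorted, first max-distance pair in i<j scan order.
    """
    pts = sorted((x * dx, y * dy) for x, y in voxels_xy)
    n = len(pts)
    if n < 2:
        return 0.0, 0.0
    major = max(math.dist(pts[i], pts[j]) for i in range(n) for j in range(i + 1, n))
    if major == 0.0:
        return 0.0, 0.0
    pair = None
    for i in range(n):
        for j in range(i + 1, n):
            if abs(math.dist(pts[i], pts[j]) - major) <= 1e-9 * max(1.0, major):
                pair = (i, j)
                break
        if pair:
            break
    (x0, y0), (x1, y1) = pts[pair[0]], pts[pair[1]]
    ux, uy = x1 - x0, y1 - y0
    norm = math.hypot(ux, uy)
    px, py = -uy / norm, ux / norm
    projs = [x * px + y * py for x, y in pts]
    return major, max(projs) - min(projs)
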