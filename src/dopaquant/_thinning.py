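"""Homotopic 3D thinning by sequential simple-point deletion.

Reduces a binary volume to a one-voxel-wide curve skeleton while preserving
topology: a voxel is deleted only if it is a *simple point* — its removal
changes neither the number of 26-connected object components nor the number
of 6-connected background components in its neighborhood (the standard
Bertrand/Malandain characterization) — and not a curve endpoint (a voxel with
exactly one object neighbor). Deletion proceeds in six directional
subiterations (up/down/north/south/east/west border voxels) and voxels are
re-checked at deletion time, which keeps the result homotopic regardless of
order effects within a pass.

The simple-point test depends only on the 26-voxel neighborhood pattern, so
results are memoized on the 26-bit pattern; tubular masks hit only a few
hundred distinct patterns, making the thinning fast in pure Python.
"""

from __future__ import annotations

import numpy as np

__all__ = ["homotopic_thin_3d"]

# fixed neighborhood enumeration: all offsets in {-1,0,1}^3 minus the center
_OFFSETS26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
_INDEX_OF = {off: i for i, off in enumerate(_OFFSETS26)}

# adjacency among the 26 neighbor positions (26-connectivity, object side)
_ADJ26 = [
    [
        j
        for j, q in enumerate(_OFFSETS26)
        if j != i and max(abs(q[0] - p[0]), abs(q[1] - p[1]), abs(q[2] - p[2])) == 1
    ]
    for i, p in enumerate(_OFFSETS26)
]

# 18-neighborhood positions (face + edge neighbors) and their 6-adjacency
_N18 = [i for i, p in enumerate(_OFFSETS26) if abs(p[0]) + abs(p[1]) + abs(p[2]) <= 2]
_N18_SET = set(_N18)
_ADJ6_N18 = {
    i: [
        j
        for j in _N18
        if j != i
        and abs(_OFFSETS26[j][0] - _OFFSETS26[i][0])
        + abs(_OFFSETS26[j][1] - _OFFSETS26[i][1])
        + abs(_OFFSETS26[j][2] - _OFFSETS26[i][2])
        == 1
    ]
    for i in _N18
}
_FACES = [i for i, p in enumerate(_OFFSETS26) if abs(p[0]) + abs(p[1]) + abs(p[2]) == 1]

_simple_cache: dict[int, bool] = {}


def _is_simple_pattern(pattern: int) -> bool:
    """Simple-point test on a 26-bit neighborhood occupancy pattern."""
    cached = _simple_cache.get(pattern)
    if cached is not None:
        return cached

    obj = [i for i in range(26) if pattern >> i & 1]
    result: bool
    if not obj:
        result = False  # isolated voxel: deletion removes a component
    else:
        # C*: 26-connected components of object voxels in N26 must equal 1
        seen: set[int] = set()
        comps = 0
        for start in obj:
            if start in seen:
                continue
            comps += 1
            if comps > 1:
                break
            stack = [start]
            seen.add(start)
            while stack:
                v = stack.pop()
                for w in _ADJ26[v]:
                    if (pattern >> w & 1) and w not in seen:
                        seen.add(w)
                        stack.append(w)
        if comps != 1:
            result = False
        else:
            # C_bar: 6-connected components of background voxels in N18 that
            # touch a face neighbor of the center must equal 1
            bg_faces = [i for i in _FACES if not pattern >> i & 1]
            if not bg_faces:
                result = False  # interior voxel
            else:
                seen_b: set[int] = set()
                comps_b = 0
                for start in bg_faces:
                    if start in seen_b:
                        continue
                    comps_b += 1
                    if comps_b > 1:
                        break
                    stack = [start]
                    seen_b.add(start)
                    while stack:
                        v = stack.pop()
                        for w in _ADJ6_N18[v]:
                            if not (pattern >> w & 1) and w not in seen_b:
                                seen_b.add(w)
                                stack.append(w)
                result = comps_b == 1
    _simple_cache[pattern] = result
    return result


def _pattern_at(mask: np.ndarray, z: int, y: int, x: int) -> int:
    pat = 0
    for i, (dz, dy, dx) in enumerate(_OFFSETS26):
        if mask[z + dz, y + dy, x + dx]:
            pat |= 1 << i
    return pat


def homotopic_thin_3d(mask: np.ndarray) -> np.ndarray:
    """Thin a 3D boolean mask to a curve skeleton, preserving topology.

    Returns a boolean array of the same shape. Curve endpoints (voxels with a
    single object neighbor) are never deleted, so line-like structures keep
    their full extent.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3-D mask")
    if not mask.any():
        return mask.copy()

    # pad so neighborhood lookups never go out of bounds
    work = np.pad(mask, 1)
    directions = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]

    changed = True
    while changed:
        changed = False
        for dz, dy, dx in directions:
            # border voxels whose (dz,dy,dx) face-neighbor is background and
            # whose opposite neighbor is object: deletion moves the surface
            # inward along d and cannot melt a 1-voxel-thick structure
            # lengthwise (which would destroy, not thin, a line or ribbon)
            ahead = np.roll(work, (-dz, -dy, -dx), axis=(0, 1, 2))
            behind = np.roll(work, (dz, dy, dx), axis=(0, 1, 2))
            candidates = np.argwhere(work & ~ahead & behind)
            for z, y, x in candidates:
                if not work[z, y, x]:
                    continue  # removed earlier in this subiteration
                if not work[z - dz, y - dy, x - dx]:
                    continue  # opposite support vanished during this pass
                pat = _pattern_at(work, z, y, x)
                n_obj = bin(pat).count("1")
                if n_obj <= 1:
                    continue  # endpoint or isolated: keep
                if _is_simple_pattern(pat):
                    work[z, y, x] = False
                    changed = True
    return work[1:-1, 1:-1, 1:-1]
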