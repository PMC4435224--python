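"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: O(n^2) scans straight from the
defining formulas, with no shared code with the package under test.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def brute_lof(points: np.ndarray, k: int, variant: str = "mk") -> dict:
    """Brute-force k-distance / mk-distance LOF on raw (unstandardized) points.

    Returns per-point dicts of k_distance, N_k, mk_distance, N_mk, lrd, lof,
    computed by exhaustive scans over all pairwise distances.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    D = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)

    out = {}
    for s in range(n):
        d = np.array([D[s, o] for o in range(n) if o != s])
        others = np.array([o for o in range(n) if o != s])
        # smallest radius with >= k inside (<=) and <= k-1 strictly inside
        kdist = None
        for r in sorted(set(d)):
            if np.sum(d <= r) >= k and np.sum(d < r) <= k - 1:
                kdist = r
                break
        assert kdist is not None
        nk = set(int(o) for o, dd in zip(others, d) if dd <= kdist)
        mk = float(np.mean([D[s, o] for o in nk]))
        nmk = set(int(o) for o in nk if D[s, o] <= mk)
        out[s] = {"k_distance": float(kdist), "N_k": nk,
                  "mk_distance": mk, "N_mk": nmk}

    def radius(o):
        return out[o]["mk_distance"] if variant == "mk" else out[o]["k_distance"]

    def hood(o):
        return out[o]["N_mk"] if variant == "mk" else out[o]["N_k"]

    for s in range(n):
        reach = [max(radius(o), D[s, o]) for o in hood(s)]
        out[s]["lrd"] = 1.0 / max(float(np.mean(reach)), EPS)
    for s in range(n):
        out[s]["lof"] = float(np.mean([out[o]["lrd"] for o in hood(s)]) / out[s]["lrd"])
    return out


def brute_first_level(points: np.ndarray, kdists: np.ndarray, p: np.ndarray) -> set[int]:
    """All x with d(x, p) <= k_distance(x), by direct scan."""
    d = np.linalg.norm(points - p, axis=1)
    return {int(i) for i in np.flatnonzero(d <= kdists)}


def brute_second_level(points: np.ndarray, radii: np.ndarray,
                       f1_wo_p: set[int], f1_all: set[int]) -> set[int]:
    """All y outside F1 with some x in F1\\{p} within y's own radius."""
    out = set()
    for y in range(len(points)):
        if y in f1_all:
            continue
        for x in f1_wo_p:
            if np.linalg.norm(points[y] - points[x]) <= radii[y]:
                out.add(y)
                break
    return out


def brute_third_level(points: np.ndarray, radii: np.ndarray,
                      f1: set[int], f2: set[int]) -> set[int]:
    """All z outside F1|F2 with some y in F2 within z's own radius."""
    out = set()
    for z in range(len(points)):
        if z in f1 or z in f2:
            continue
        for y in f2:
            if np.linalg.norm(points[z] - points[y]) <= radii[z]:
                out.add(z)
                break
    return out
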