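"""Batch and incremental mean-k-distance local outlier factor (D-LOF).

The detector scores each multivariate reading vector by a density-ratio
local outlier factor in which the classical k-distance neighbourhood is
replaced by the *mk-distance* neighbourhood: the mean distance from a point
to its k nearest neighbours.  Because the mean is never larger than the
k-th neighbour distance, the neighbourhood shrinks and the score becomes
more sensitive to isolated points.

Quantities cached per point:

* ``k_distance``   -- distance to the k-th nearest neighbour (tie-inclusive:
  the smallest radius containing at least k other points while at most k-1
  lie strictly inside).
* ``N_k``          -- every point within ``k_distance`` (may exceed k under ties).
* ``mk_distance``  -- mean distance to the members of ``N_k``.
* ``N_mk``         -- every point within ``mk_distance`` (a subset of ``N_k``).
* ``lrd``          -- reciprocal mean reachability distance over ``N_mk``,
  where reach(s, o) = max(mk_distance(o), d(s, o)).
* ``lof``          -- mean of lrd(o)/lrd(s) over o in ``N_mk(s)``.

Points whose LOF exceeds a threshold (default 2.0) are flagged outlying.

Insertion of a new point refreshes caches only for the three tiers of
influenced points:

* F1 -- points x with d(x, p) <= k_distance(x) (plus p itself); their
  neighbourhoods, mk-distance, lrd and LOF all change.
* F2 -- points y outside F1 whose mk-neighbourhood contains a member of
  F1 \\ {p}; their lrd and LOF change.
* F3 -- points z outside F1 and F2 whose mk-neighbourhood contains a member
  of F2; only their LOF changes.

This truncation is exact: a point whose mk-neighbourhood contains no
influenced member keeps bit-identical lrd and LOF, which the test suite
verifies against full batch recomputation.

The ``variant`` switch selects between the mk-distance neighbourhood
("mk", the default) and the classical k-distance neighbourhood
("original") so the two scores can be compared on the same data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PointRecord",
    "KnowledgeBase",
    "InfluenceSets",
    "InsertResult",
    "batch_fit",
]

#: Floor applied to a mean reachability distance of exactly zero (coincident
#: duplicates) so lrd stays finite.
EPSILON_REACH = 1e-12

#: Default LOF cutoff above which a point is flagged outlying.
DEFAULT_THRESHOLD = 2.0


@dataclass
class PointRecord:
    """Cached neighbourhood quantities for one point in the knowledge base."""

    point: np.ndarray            # standardized coordinates
    k_distance: float = np.nan
    k_neighborhood: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mk_distance: float = np.nan
    mk_neighborhood: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    lrd: float = np.nan
    lof: float = np.nan


@dataclass
class InfluenceSets:
    """The three pairwise-disjoint tiers of points influenced by an insertion."""

    f1: set[int]
    f2: set[int]
    f3: set[int]

    @property
    def all(self) -> set[int]:
        return self.f1 | self.f2 | self.f3


@dataclass
class InsertResult:
    """Outcome of inserting one point: its id, LOF, flag, and influence tiers."""

    point_id: int
    lof: float
    flagged: bool
    influence: InfluenceSets
    undo: dict | None = None


class KnowledgeBase:
    """Point set with cached k-distance / mk-distance LOF quantities.

    Parameters
    ----------
    k : int
        Neighbourhood size of the k-distance.
    threshold : float
        LOF cutoff above which a point is flagged outlying.
    variant : {"mk", "original"}
        "mk" uses the mean-k-distance neighbourhood for reachability, lrd
        and LOF; "original" uses the classical k-distance neighbourhood.
    standardize : bool
        Standardize each coordinate (subtract mean, divide by std) before
        computing Euclidean distances.  The standardization parameters are
        frozen at fit time and reused for all subsequent inserts.
    """

    def __init__(self, k: int, threshold: float = DEFAULT_THRESHOLD,
                 variant: str = "mk", standardize: bool = True):
        if k < 1:
            raise ValueError("k must be a positive integer")
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        if variant not in ("mk", "original"):
            raise ValueError(f"unknown variant {variant!r}")
        self.k = int(k)
        self.threshold = float(threshold)
        self.variant = variant
        self.standardize = bool(standardize)
        self._mean: np.ndarray | None = None
        self._std: np.ndarray | None = None
        self.records: dict[int, PointRecord] = {}
        self._next_id = 0
        self._fitted = False

    # ------------------------------------------------------------------ #
    # construction

    def fit(self, points: np.ndarray, ids: np.ndarray | None = None) -> "KnowledgeBase":
        """Batch-fit all cached quantities for ``points`` (rows = points)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        if n < self.k + 1:
            raise ValueError(
                f"need at least k+1 = {self.k + 1} points, got {n}")
        if ids is None:
            ids = np.arange(n, dtype=np.int64)
        else:
            ids = np.asarray(ids, dtype=np.int64)
            if len(np.unique(ids)) != n:
                raise ValueError("ids must be unique")
        if self.standardize:
            self._mean = points.mean(axis=0)
            std = points.std(axis=0)
            std[std == 0] = 1.0
            self._std = std
        else:
            self._mean = np.zeros(points.shape[1])
            self._std = np.ones(points.shape[1])
        Z = (points - self._mean) / self._std
        self.records = {int(i): PointRecord(point=Z[j]) for j, i in enumerate(ids)}
        self._next_id = int(ids.max()) + 1
        self._ids = ids.copy()
        self._recompute_all()
        self._fitted = True
        return self

    def _rebuild_arrays(self) -> None:
        """Rebuild the contiguous coordinate/radius arrays from the records."""
        ids = np.fromiter(self.records.keys(), dtype=np.int64)
        Z = np.vstack([self.records[int(i)].point for i in ids])
        self._ids_arr = ids
        self._Zarr = Z
        self._kd_arr = np.array([self.records[int(i)].k_distance for i in ids])
        self._mk_arr = np.array([self.records[int(i)].mk_distance for i in ids])
        self._row = {int(i): r for r, i in enumerate(ids)}

    def _append_row(self, i: int) -> None:
        rec = self.records[i]
        self._ids_arr = np.append(self._ids_arr, i)
        self._Zarr = np.vstack([self._Zarr, rec.point[None, :]])
        self._kd_arr = np.append(self._kd_arr, rec.k_distance)
        self._mk_arr = np.append(self._mk_arr, rec.mk_distance)
        self._row[i] = len(self._ids_arr) - 1

    def _drop_last_row(self, i: int) -> None:
        assert self._ids_arr[-1] == i
        self._ids_arr = self._ids_arr[:-1]
        self._Zarr = self._Zarr[:-1]
        self._kd_arr = self._kd_arr[:-1]
        self._mk_arr = self._mk_arr[:-1]
        del self._row[i]

    def _sync_row(self, i: int) -> None:
        rec = self.records[i]
        r = self._row[i]
        self._kd_arr[r] = rec.k_distance
        self._mk_arr[r] = rec.mk_distance

    def _recompute_all(self) -> None:
        """Recompute every cached quantity from scratch (exact k-NN)."""
        ids = np.fromiter(self.records.keys(), dtype=np.int64)
        Z = np.vstack([self.records[int(i)].point for i in ids])
        n = len(ids)
        # exact k-NN with a buffer to resolve ties at the k-distance radius
        n_query = min(n, self.k + 2)
        nn = NearestNeighbors(n_neighbors=n_query, algorithm="auto")
        nn.fit(Z)
        dist, idx = nn.kneighbors(Z)
        # column 0 is the point itself (distance 0); drop it
        dist, idx = dist[:, 1:], idx[:, 1:]
        for row in range(n):
            s = int(ids[row])
            kdist = dist[row, self.k - 1]
            if n_query - 1 > self.k and dist[row, self.k] <= kdist:
                # tie spills past the buffer: fall back to a full scan
                d_all = np.linalg.norm(Z - Z[row], axis=1)
                d_all[row] = np.inf
                order = np.argsort(d_all, kind="stable")
                kdist = d_all[order[self.k - 1]]
                members = np.flatnonzero(d_all <= kdist)
                nbr_ids = ids[members]
                nbr_d = d_all[members]
            else:
                within = dist[row] <= kdist
                nbr_ids = ids[idx[row][within]]
                nbr_d = dist[row][within]
            rec = self.records[s]
            rec.k_distance = float(kdist)
            rec.k_neighborhood = nbr_ids.astype(np.int64)
            rec.mk_distance = float(nbr_d.mean())
            rec.mk_neighborhood = nbr_ids[nbr_d <= rec.mk_distance].astype(np.int64)
        self._rebuild_arrays()
        for s in self.records:
            self._recompute_lrd(s)
        for s in self.records:
            self._recompute_lof(s)

    # ------------------------------------------------------------------ #
    # cached-quantity helpers

    def _radius(self, rec: PointRecord) -> float:
        """Neighbourhood radius of the active variant."""
        return rec.mk_distance if self.variant == "mk" else rec.k_distance

    def _nbrs(self, rec: PointRecord) -> np.ndarray:
        """Neighbourhood of the active variant."""
        return rec.mk_neighborhood if self.variant == "mk" else rec.k_neighborhood

    def _dist(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.records[a].point - self.records[b].point))

    def _recompute_lrd(self, s: int) -> None:
        rec = self.records[s]
        nbrs = self._nbrs(rec)
        if len(nbrs) == 0:
            raise ValueError(f"point {s} has an empty neighbourhood")
        reach = [max(self._radius(self.records[int(o)]), self._dist(s, int(o)))
                 for o in nbrs]
        mean_reach = max(float(np.mean(reach)), EPSILON_REACH)
        rec.lrd = 1.0 / mean_reach

    def _recompute_lof(self, s: int) -> None:
        rec = self.records[s]
        nbrs = self._nbrs(rec)
        lrds = [self.records[int(o)].lrd for o in nbrs]
        rec.lof = float(np.mean(lrds) / rec.lrd)

    # ------------------------------------------------------------------ #
    # public single-point accessors

    def k_distance(self, s: int) -> tuple[float, set[int]]:
        """k-distance and tie-inclusive k-neighbourhood of point ``s``."""
        rec = self.records[s]
        return rec.k_distance, set(int(i) for i in rec.k_neighborhood)

    def mk_distance(self, s: int) -> float:
        """Mean distance from ``s`` to the members of its k-neighbourhood."""
        return self.records[s].mk_distance

    def reach_dist(self, s: int, o: int) -> float:
        """Reachability distance max(radius(o), d(s, o)) of ``s`` w.r.t. ``o``."""
        return max(self._radius(self.records[o]), self._dist(s, o))

    def lrd(self, s: int) -> float:
        """Local reachability density of point ``s``."""
        return self.records[s].lrd

    def lof(self, s: int) -> float:
        """Local outlier factor of point ``s``."""
        return self.records[s].lof

    def lofs(self) -> dict[int, float]:
        """LOF of every point, keyed by id."""
        return {s: rec.lof for s, rec in self.records.items()}

    def outliers(self, threshold: float | None = None) -> set[int]:
        """Ids of points whose LOF exceeds ``threshold`` (default: the kb's)."""
        t = self.threshold if threshold is None else threshold
        return {s for s, rec in self.records.items() if rec.lof > t}

    # ------------------------------------------------------------------ #
    # influence tiers

    def _standardize_point(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float).ravel()
        dim = len(self._mean)
        if p.shape != (dim,):
            raise ValueError(f"expected a point of dimension {dim}, got shape {p.shape}")
        return (p - self._mean) / self._std

    def _all_ids_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self._ids_arr, self._Zarr

    def _radius_arr(self) -> np.ndarray:
        return self._mk_arr if self.variant == "mk" else self._kd_arr

    def find_first_level(self, z: np.ndarray, exclude: int | None = None) -> set[int]:
        """Points x with d(x, p) <= k_distance(x) for a standardized point ``z``."""
        d = np.linalg.norm(self._Zarr - z, axis=1)
        hit = self._ids_arr[d <= self._kd_arr]
        out = {int(i) for i in hit}
        if exclude is not None:
            out.discard(exclude)
        return out

    def _reverse_radius_hits(self, sources: list[int],
                             excluded: set[int]) -> set[int]:
        """Candidates outside ``excluded`` with a source inside their own
        variant radius."""
        if not sources:
            return set()
        ids, Z = self._ids_arr, self._Zarr
        mask = ~np.isin(ids, list(excluded))
        cand_idx = np.flatnonzero(mask)
        if len(cand_idx) == 0:
            return set()
        X = np.vstack([self.records[int(x)].point for x in sources])
        radii = self._radius_arr()[cand_idx]
        hits = np.zeros(len(cand_idx), dtype=bool)
        # one pass per source point keeps memory O(n) even for large bases
        for src in X:
            d = np.linalg.norm(Z[cand_idx] - src, axis=1)
            hits |= d <= radii
        return {int(i) for i in ids[cand_idx[hits]]}

    def find_second_level(self, f1: set[int], p_id: int) -> set[int]:
        """Points y outside F1 whose mk-neighbourhood contains some x in F1\\{p}."""
        return self._reverse_radius_hits([x for x in f1 if x != p_id], f1)

    def find_third_level(self, f1: set[int], f2: set[int]) -> set[int]:
        """Points z outside F1|F2 whose mk-neighbourhood contains some y in F2."""
        return self._reverse_radius_hits(sorted(f2), f1 | f2)

    # ------------------------------------------------------------------ #
    # incremental insertion

    def insert(self, p: np.ndarray, keep_undo: bool = False) -> InsertResult:
        """Insert one point, refreshing caches over the three influence tiers.

        Neighbourhood updates cover the three insertion situations: p on the
        k-distance circle (append), p strictly inside with ties holding the
        radius (append), and p strictly inside with exactly k-1 interior
        points (the boundary neighbours are evicted and k-distance shrinks).
        All are realized exactly by re-deriving N_k(x) from the old
        neighbourhood plus p, since no point outside the old N_k can enter.

        With ``keep_undo`` the result carries a snapshot allowing
        :meth:`rollback`, used when an outlying vector must not join the
        knowledge base.
        """
        if not self._fitted:
            raise RuntimeError("knowledge base must be fitted before insert()")
        z = self._standardize_point(p)
        p_id = self._next_id
        self._next_id += 1

        f1_others = self.find_first_level(z)
        f1 = set(f1_others) | {p_id}

        undo: dict | None = None
        if keep_undo:
            undo = {"p_id": p_id, "records": {}}

        def snapshot(i: int) -> None:
            if undo is not None and i != p_id and i not in undo["records"]:
                r = self.records[i]
                undo["records"][i] = (r.k_distance, r.k_neighborhood.copy(),
                                      r.mk_distance, r.mk_neighborhood.copy(),
                                      r.lrd, r.lof)

        # update N_k / k-distance / mk-distance / N_mk of first-level points
        for x in f1_others:
            snapshot(x)
            rec = self.records[x]
            old_rows = [self._row[int(i)] for i in rec.k_neighborhood]
            old_d = np.linalg.norm(self._Zarr[old_rows] - rec.point, axis=1)
            cand_ids = np.append(rec.k_neighborhood, p_id)
            cand_d = np.append(old_d, np.linalg.norm(rec.point - z))
            order = np.argsort(cand_d, kind="stable")
            kdist = cand_d[order[self.k - 1]] if len(cand_d) >= self.k \
                else cand_d[order[-1]]
            within = cand_d <= kdist
            rec.k_distance = float(kdist)
            rec.k_neighborhood = cand_ids[within].astype(np.int64)
            nbr_d = cand_d[within]
            rec.mk_distance = float(nbr_d.mean())
            rec.mk_neighborhood = rec.k_neighborhood[nbr_d <= rec.mk_distance]
            self._sync_row(x)

        # p's own caches from scratch against the updated kb
        self.records[p_id] = PointRecord(point=z)
        self._init_record(p_id)
        self._append_row(p_id)

        f2 = self.find_second_level(f1, p_id)
        f3 = self.find_third_level(f1, f2)

        for s in sorted(f2):
            snapshot(s)
        for s in sorted(f3):
            snapshot(s)
        for s in sorted(f1 | f2):
            self._recompute_lrd(s)
        for s in sorted(f1 | f2 | f3):
            self._recompute_lof(s)

        lof_p = self.records[p_id].lof
        return InsertResult(point_id=p_id, lof=lof_p,
                            flagged=bool(lof_p > self.threshold),
                            influence=InfluenceSets(f1=f1, f2=f2, f3=f3),
                            undo=undo)

    def _init_record(self, s: int) -> None:
        """Compute neighbourhood caches of a newly inserted point from
        scratch against every other point (``s`` is not yet in the arrays)."""
        rec = self.records[s]
        ids, Z = self._all_ids_points()
        d = np.linalg.norm(Z - rec.point, axis=1)
        order = np.argsort(d, kind="stable")
        kdist = float(d[order[min(self.k, len(order)) - 1]])
        within = d <= kdist
        rec.k_distance = kdist
        rec.k_neighborhood = ids[within].astype(np.int64)
        nbr_d = d[within]
        rec.mk_distance = float(nbr_d.mean())
        rec.mk_neighborhood = rec.k_neighborhood[nbr_d <= rec.mk_distance]

    def rollback(self, result: InsertResult) -> None:
        """Undo an insert made with ``keep_undo=True``."""
        if result.undo is None:
            raise ValueError("insert was not made with keep_undo=True")
        p_id = result.undo["p_id"]
        del self.records[p_id]
        self._drop_last_row(p_id)
        for i, (kd, nk, mkd, nmk, lrd, lof) in result.undo["records"].items():
            r = self.records[i]
            r.k_distance, r.k_neighborhood = kd, nk
            r.mk_distance, r.mk_neighborhood = mkd, nmk
            r.lrd, r.lof = lrd, lof
            self._sync_row(i)

    # ------------------------------------------------------------------ #
    # maintenance & serialization

    def refresh(self, max_size: int | None = None) -> None:
        """Full batch recomputation, optionally retiring oldest points first."""
        if max_size is not None and len(self.records) > max_size:
            for i in sorted(self.records)[: len(self.records) - max_size]:
                del self.records[i]
        self._recompute_all()

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self, path: str) -> None:
        ids, Z = self._all_ids_points()
        raw = Z * self._std + self._mean
        payload = {
            "k": self.k, "threshold": self.threshold, "variant": self.variant,
            "standardize": self.standardize,
            "mean": self._mean.tolist(), "std": self._std.tolist(),
            "ids": ids.tolist(), "points": raw.tolist(),
            "lof": [self.records[int(i)].lof for i in ids],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "KnowledgeBase":
        with open(path) as fh:
            payload = json.load(fh)
        kb = cls(k=payload["k"], threshold=payload["threshold"],
                 variant=payload["variant"], standardize=payload["standardize"])
        kb.fit(np.asarray(payload["points"], dtype=float),
               ids=np.asarray(payload["ids"], dtype=np.int64))
        return kb


def batch_fit(points: np.ndarray, k: int, threshold: float = DEFAULT_THRESHOLD,
              variant: str = "mk", standardize: bool = True) -> KnowledgeBase:
    """Fit a :class:`KnowledgeBase` on ``points`` and return it."""
    return KnowledgeBase(k=k, threshold=threshold, variant=variant,
                         standardize=standardize).fit(points)
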