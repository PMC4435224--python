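"""Synthetic physiological streams, fault injection, and LOF benchmarks.

The vitals generator emulates a monitored patient: heart rate (HR) cycles
inside 40-140 bpm; respiration rate (RR) sits near 20 breaths/min and is an
affine function of HR; body temperature (BT) is stable around 37 degC; SpO2
fluctuates in 90-100 with rare dips below 90; blood glucose (GLU) and
systolic blood pressure (BP) cycle gently around their norms.  A +1 degC
body-temperature excursion raises HR by a configurable coupling gain
(default 12 bpm/degC, physiological range 10-15).  Illness episodes shift
the attributes *out of sync*: HR reacts immediately, RR one instant later,
BT only after several instants, so no single instant shows a coherent
all-attribute anomaly.

Fault injection plants sensor failures (stuck-at, offset, spike, drift) into
chosen cells and returns ground-truth labels computed as the exact cell-wise
difference mask between input and output.

The clustered point-set generator builds planted-outlier benchmarks for the
LOF detector: Gaussian clusters plus gross outliers placed in annular shells
at least ten cluster radii from every cluster centre and mutually separated
so each planted point is an isolated outlier rather than a member of an
outlying clump (density-ratio detectors are not designed to find outlying
clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ATTRIBUTES",
    "VitalsConfig",
    "IllnessEpisode",
    "FaultModel",
    "FaultLabels",
    "ReadingMatrix",
    "generate_vitals",
    "inject_faults",
    "generate_cluster_dataset",
    "generate_regression_samples",
]

log = logging.getLogger(__name__)

#: Supported attributes, their baselines, cyclical amplitudes and noise SDs.
ATTRIBUTES = {
    #        baseline  amplitude  noise   phase
    "HR":   (85.0,     20.0,      3.0,    0.0),
    "RR":   (20.0,     0.0,       1.0,    0.0),   # derived from HR
    "BT":   (37.0,     0.2,       0.05,   0.7),
    "SpO2": (97.0,     1.5,       0.5,    1.4),
    "GLU":  (5.5,      1.0,       0.2,    2.1),
    "BP":   (115.0,    8.0,       3.0,    2.8),
}

#: RR as an affine function of HR: RR = 20 + RR_SLOPE * (HR - 85).
RR_SLOPE = 0.2

#: Hard physical ranges used for clipping (clipping is logged).
PHYSICAL_RANGE = {
    "HR": (40.0, 140.0), "RR": (5.0, 60.0), "BT": (34.0, 42.0),
    "SpO2": (70.0, 100.0), "GLU": (2.0, 25.0), "BP": (60.0, 220.0),
}

#: Illness response: per-attribute onset lag (instants) and full-magnitude
#: shift.  HR reacts at once; RR follows; BT drifts up only minutes later.
ILLNESS_LAG = {"HR": 0, "RR": 1, "BT": 5, "SpO2": 3, "GLU": 4, "BP": 2}
ILLNESS_SHIFT = {"HR": 30.0, "RR": 8.0, "BT": 1.5, "SpO2": -7.0,
                 "GLU": 2.5, "BP": 20.0}

#: Probability per instant of a rare genuine SpO2 dip below 90.
SPO2_DIP_RATE = 0.005


@dataclass
class IllnessEpisode:
    """One illness excursion: onset instant, plateau length, severity scale."""

    start: int
    duration: int = 20
    magnitude: float = 1.0
    ramp: int = 5


@dataclass
class VitalsConfig:
    """Configuration of the vitals simulator."""

    attributes: tuple[str, ...] = ("HR", "RR", "BT", "SpO2", "GLU", "BP")
    duration: int = 500
    period: int = 100
    coupling: float = 12.0          # bpm per degC, physiological range 10-15
    illness_episodes: list[IllnessEpisode] = field(default_factory=list)
    noise: dict[str, float] | None = None
    spo2_dip_rate: float = SPO2_DIP_RATE
    seed: int = 0

    def __post_init__(self):
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        unknown = set(self.attributes) - set(ATTRIBUTES)
        if unknown:
            raise ValueError(f"unknown attributes: {sorted(unknown)}")
        if not 0 <= self.coupling <= 20:
            raise ValueError("coupling must lie in [0, 20] bpm/degC")
        if self.noise:
            if any(v < 0 for v in self.noise.values()):
                raise ValueError("noise SDs must be nonnegative")

    def noise_sd(self, attr: str) -> float:
        if self.noise is not None and attr in self.noise:
            return self.noise[attr]
        return ATTRIBUTES[attr][2]


@dataclass
class FaultModel:
    """One family of injected sensor failures."""

    kind: str = "spike"             # stuck_at | offset | spike | drift
    rate: float = 0.05              # fraction of instants affected per sensor
    magnitude: float = 6.0          # in units of the attribute's stream SD
    target_sensors: tuple[str, ...] | None = None
    run_length: int = 5             # instants per stuck_at/drift episode
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("stuck_at", "offset", "spike", "drift"):
            raise ValueError(f"unknown fault kind {self.kind!r}")
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must lie in [0, 1]")


@dataclass
class FaultLabels:
    """Ground truth: injected-fault cells and genuine-illness instants."""

    fault: np.ndarray               # (duration, n) bool, injected cells
    illness: np.ndarray             # (duration,) bool, genuine excursions

    @classmethod
    def empty(cls, duration: int, n: int) -> "FaultLabels":
        return cls(fault=np.zeros((duration, n), dtype=bool),
                   illness=np.zeros(duration, dtype=bool))


@dataclass
class ReadingMatrix:
    """Timestamped multivariate readings X = (X_ji)."""

    times: np.ndarray
    values: np.ndarray              # (duration, n)
    attributes: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.attributes))
        df.insert(0, "time", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadingMatrix":
        cols = [c for c in df.columns if c != "time"]
        times = df["time"].to_numpy() if "time" in df else np.arange(len(df))
        return cls(times=times, values=df[cols].to_numpy(dtype=float),
                   attributes=tuple(cols))


# ---------------------------------------------------------------------- #
# vitals


def _episode_profile(cfg: VitalsConfig, ep: IllnessEpisode, lag: int) -> np.ndarray:
    """Ramp-plateau-ramp activation (0..1) of one episode for one attribute."""
    t = np.arange(cfg.duration, dtype=float)
    start = ep.start + lag
    up = np.clip((t - start) / max(ep.ramp, 1), 0.0, 1.0)
    down = np.clip((start + ep.duration + ep.ramp - t) / max(ep.ramp, 1), 0.0, 1.0)
    return np.minimum(up, down).clip(0.0, 1.0)


def generate_vitals(cfg: VitalsConfig) -> tuple[ReadingMatrix, FaultLabels]:
    """Simulate the configured vitals stream; labels carry illness flags only."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.duration, dtype=float)
    omega = 2 * np.pi / cfg.period
    n = len(cfg.attributes)
    values = np.empty((cfg.duration, n))

    # deterministic episode shifts per attribute (lagged, ramped)
    shift = {}
    for attr in cfg.attributes:
        s = np.zeros(cfg.duration)
        for ep in cfg.illness_episodes:
            s += (ep.magnitude * ILLNESS_SHIFT[attr]
                  * _episode_profile(cfg, ep, ILLNESS_LAG[attr]))
        shift[attr] = s

    # BT first (drives the HR coupling), then HR, then RR from realized HR
    series = {}
    for attr in cfg.attributes:
        base, amp, _, phase = ATTRIBUTES[attr]
        sd = cfg.noise_sd(attr)
        if attr == "RR":
            continue
        x = base + amp * np.sin(omega * t + phase) + shift[attr]
        if attr == "HR":
            x = x + cfg.coupling * shift.get("BT", np.zeros(cfg.duration))
        x = x + rng.normal(0.0, sd, cfg.duration)
        if attr == "SpO2":
            dips = rng.random(cfg.duration) < cfg.spo2_dip_rate
            x = np.where(dips, 90.0 - rng.uniform(1.0, 4.0, cfg.duration), x)
            x = np.minimum(x, 100.0)
        series[attr] = x
    if "RR" in cfg.attributes:
        hr = series.get("HR")
        if hr is None:
            raise ValueError("RR requires HR among the attributes")
        series["RR"] = (20.0 + RR_SLOPE * (hr - 85.0) + shift["RR"]
                        + rng.normal(0.0, cfg.noise_sd("RR"), cfg.duration))

    for j, attr in enumerate(cfg.attributes):
        lo, hi = PHYSICAL_RANGE[attr]
        x = series[attr]
        n_clip = int(np.sum((x < lo) | (x > hi)))
        if n_clip:
            log.info("clipping %d %s readings to [%g, %g]", n_clip, attr, lo, hi)
        values[:, j] = np.clip(x, lo, hi)

    illness = np.zeros(cfg.duration, dtype=bool)
    for ep in cfg.illness_episodes:
        lo = ep.start
        hi = min(ep.start + ep.duration + ep.ramp + max(ILLNESS_LAG.values()),
                 cfg.duration)
        illness[lo:hi] = True

    matrix = ReadingMatrix(times=t, values=values, attributes=cfg.attributes)
    labels = FaultLabels(fault=np.zeros((cfg.duration, n), dtype=bool),
                         illness=illness)
    return matrix, labels


# ---------------------------------------------------------------------- #
# fault injection


def inject_faults(matrix: ReadingMatrix,
                  models: list[FaultModel]) -> tuple[ReadingMatrix, FaultLabels]:
    """Plant sensor failures; labels are the exact input/output diff mask."""
    values = matrix.values.copy()
    duration, n = values.shape
    col = {a: j for j, a in enumerate(matrix.attributes)}
    sds = values.std(axis=0)
    sds[sds == 0] = 1.0

    for model in models:
        rng = np.random.default_rng(model.seed)
        targets = model.target_sensors or matrix.attributes
        for attr in targets:
            j = col[attr]
            mag = model.magnitude * sds[j]
            if model.kind == "spike":
                hit = np.flatnonzero(rng.random(duration) < model.rate)
                signs = rng.choice([-1.0, 1.0], size=len(hit))
                values[hit, j] += signs * mag
            elif model.kind == "offset":
                hit = np.flatnonzero(rng.random(duration) < model.rate)
                values[hit, j] += mag
            elif model.kind in ("stuck_at", "drift"):
                L = max(model.run_length, 1)
                n_runs = int(round(model.rate * duration / L))
                starts = rng.choice(np.arange(1, max(duration - L, 2)),
                                    size=min(n_runs, duration - L - 1),
                                    replace=False) if n_runs > 0 else []
                for s in starts:
                    idx = np.arange(s, min(s + L, duration))
                    if model.kind == "stuck_at":
                        values[idx, j] = values[s - 1, j]
                    else:
                        values[idx, j] += mag * (np.arange(len(idx)) + 1) / L

    fault = values != matrix.values
    if not fault.any():
        log.warning("fault injection modified no cells")
    out = ReadingMatrix(times=matrix.times.copy(), values=values,
                        attributes=matrix.attributes)
    return out, FaultLabels(fault=fault, illness=np.zeros(duration, dtype=bool))


# ---------------------------------------------------------------------- #
# planted-outlier point sets


def generate_cluster_dataset(size: int, n_outliers: int, dim: int = 2,
                             seed: int = 0, n_clusters: int | None = None,
                             cluster_sd: float = 1.0,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian clusters plus isolated gross outliers; returns (points, ids).

    Inliers are drawn from compact spherical Gaussian clusters on a jittered
    grid of centres.  Each outlier is placed uniformly in an annular shell
    10-25 cluster radii (radius = maximum inlier distance to its centre)
    around one of the centres, and planted points are kept mutually
    separated by at least 27 cluster radii so each one is an isolated
    outlier, never part of an outlying clump.  Outliers occupy the last
    ``n_outliers`` rows; their row indices are returned.
    """
    if n_outliers >= size:
        raise ValueError("n_outliers must be smaller than size")
    rng = np.random.default_rng(seed)
    n_in = size - n_outliers
    if n_clusters is None:
        # enough centres that the shells can host all outliers in isolation
        n_clusters = max(3, int(np.ceil(n_outliers / 3)))
    n_clusters = min(n_clusters, max(n_in // 20, 1))

    # jittered grid of cluster centres, spaced far apart relative to sd
    spacing = 400.0 * cluster_sd
    g = int(np.ceil(n_clusters ** (1.0 / dim)))
    cells = np.stack(np.meshgrid(*[np.arange(g)] * dim, indexing="ij"),
                     axis=-1).reshape(-1, dim)[:n_clusters]
    centers = cells * spacing + rng.uniform(-40, 40, size=(n_clusters, dim)) \
        * cluster_sd

    counts = np.full(n_clusters, n_in // n_clusters)
    counts[: n_in % n_clusters] += 1
    inliers, assign = [], []
    for c in range(n_clusters):
        inliers.append(rng.normal(centers[c], cluster_sd, size=(counts[c], dim)))
        assign.extend([c] * counts[c])
    inliers = np.vstack(inliers)
    assign = np.asarray(assign)
    rmax = float(np.max(np.linalg.norm(inliers - centers[assign], axis=1)))

    shell_lo, shell_hi, sep = 10.0 * rmax, 25.0 * rmax, 27.0 * rmax
    placed: list[np.ndarray] = []
    for i in range(n_outliers):
        c = centers[i % n_clusters]
        ok = False
        min_sep = sep
        for attempt in range(5000):
            direction = rng.normal(size=dim)
            direction /= np.linalg.norm(direction)
            radius = (shell_lo ** dim
                      + rng.random() * (shell_hi ** dim - shell_lo ** dim)) \
                ** (1.0 / dim)
            cand = c + radius * direction
            far_from_centers = np.min(
                np.linalg.norm(centers - cand, axis=1)) >= shell_lo
            far_from_outliers = (not placed or np.min(
                np.linalg.norm(np.asarray(placed) - cand, axis=1)) >= min_sep)
            if far_from_centers and far_from_outliers:
                ok = True
                break
            if attempt and attempt % 500 == 0:
                min_sep *= 0.95   # relax slowly if the shell is crowded
        if not ok:
            raise RuntimeError("could not place isolated outliers; "
                               "increase n_clusters or reduce n_outliers")
        placed.append(cand)

    points = np.vstack([inliers, np.asarray(placed)]) if n_outliers else inliers
    outlier_ids = np.arange(n_in, size, dtype=np.int64)
    return points, outlier_ids


# ---------------------------------------------------------------------- #
# regression benchmark data


def generate_regression_samples(u: int = 20, m: int = 5, seed: int = 0,
                                slope: float = 2.0, intercept: float = 1.0,
                                noise_scale: float = 0.04,
                                skew: float = 2.0) -> "pd.DataFrame":
    """Sample-group table for the fuzzy-regression benchmarks (long format).

    Outputs follow y = slope*x + intercept with multiplicative noise drawn
    from an asymmetric trapezoidal distribution (right spread ``skew`` times
    the left), emulating readings whose uncertainty is genuinely
    trapezoidal.  ``noise_scale`` = 0 gives noiseless crisp data.  Columns:
    group (1..m, m most recent), instant (1..u), y, x_1.
    """
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(2.0, 10.0, size=u))
    core = slope * x + intercept
    rows = []
    for h in range(1, m + 1):
        if noise_scale > 0:
            # support [-noise_scale, skew*noise_scale], flat core in the middle
            total = (1 + skew) * noise_scale
            noise = stats.trapezoid.rvs(0.3, 0.6, loc=-noise_scale,
                                        scale=total, size=u, random_state=rng)
        else:
            noise = np.zeros(u)
        y = core * (1.0 + noise)
        for j in range(u):
            rows.append({"group": h, "instant": j + 1, "y": y[j], "x_1": x[j]})
    return pd.DataFrame(rows)
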