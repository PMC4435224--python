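"""Three-step fault-detection pipeline, evaluation metrics, and benchmarks.

Per streamed reading vector:

1. The vector is scored by the incremental mean-k-distance LOF against the
   knowledge base of vectors previously deemed normal.  Non-outlying
   vectors join the knowledge base and every sensor is good this round.
2. An outlying vector's readings are split into physiologically normal and
   abnormal sets by the per-attribute normal intervals.  If every reading
   falls on one side, no sensor is blamed: the excursion is coherent and is
   attributed to a change of the patient's state.  Otherwise the larger set
   is taken as reliable regressors and each reading in the smaller set is
   suspected.
3. Each suspected reading is predicted by a trapezoidal fuzzy regression
   fitted on sample groups drawn from the same within-period instants of
   the most recent periods, and judged good / fault / undecided from the
   relative position of the fuzzy prediction, the normal interval, and the
   actual reading.  Undecided verdicts persisting over consecutive rounds
   are promoted to fault.

Outlying vectors are rolled back out of the knowledge base after judgment,
so the base keeps only vectors considered normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dlof import KnowledgeBase
from .fuzzy_regression import FitConfig, GAConfig, SampleGroups, fit
from .judgment import (FAULT, GOOD, UNDECIDED, JudgmentConfig, NormalInterval,
                       judge, resolve_undecided)
from .synth import (FaultLabels, FaultModel, IllnessEpisode, ReadingMatrix,
                    VitalsConfig, generate_cluster_dataset, generate_vitals,
                    inject_faults)

__all__ = [
    "DEFAULT_INTERVALS",
    "DetectorConfig",
    "DetectionReport",
    "partition_readings",
    "dfd_m_step",
    "run_detection",
    "evaluate",
    "alarm_filter",
    "benchmark_planted_outliers",
    "benchmark_end_to_end",
]

log = logging.getLogger(__name__)

PATIENT_STATE_CHANGE = "patient_state_change"
WARMUP = "warmup"

#: Default physiological normal intervals (adult resting ranges).
DEFAULT_INTERVALS = {
    "HR": NormalInterval(50.0, 130.0, "HR"),
    "RR": NormalInterval(10.0, 30.0, "RR"),
    "BT": NormalInterval(36.0, 38.5, "BT"),
    "SpO2": NormalInterval(89.0, 100.5, "SpO2"),
    "GLU": NormalInterval(3.9, 7.8, "GLU"),
    "BP": NormalInterval(90.0, 140.0, "BP"),
}


@dataclass
class DetectorConfig:
    """Full configuration of the three-step detector."""

    k: int = 10
    lof_threshold: float = 2.0
    intervals: dict[str, NormalInterval] = field(
        default_factory=lambda: dict(DEFAULT_INTERVALS))
    regression: FitConfig = field(default_factory=lambda: FitConfig(
        ga=GAConfig(population=40, generations=60, polish=False)))
    judgment: JudgmentConfig = field(default_factory=JudgmentConfig)
    u: int = 20                  # instants per sample group
    m: int = 5                   # sample groups (periods of history)
    period: int = 100            # cycle length of the stream
    warmup: int | None = None    # instants fitted as the initial base
    kb_max_size: int | None = None
    ga_seed: int = 42

    def resolved_warmup(self) -> int:
        w = self.warmup if self.warmup is not None else self.m * self.period + self.u
        return max(w, self.k + 2)


@dataclass
class DetectionReport:
    """Per-instant, per-sensor outcome of a detection run."""

    attributes: tuple[str, ...]
    states: np.ndarray             # (duration, n) of state strings
    vector_outlier: np.ndarray     # (duration,) bool
    evaluated: np.ndarray          # (duration,) bool; False during warmup
    lof: np.ndarray                # (duration,) float, NaN during warmup
    case_ids: np.ndarray           # (duration, n) int, 0 where not judged
    #: one row per judged reading: instant, sensor, y, the evaluated
    #: breakpoints (a-l, a_lambda, b_lambda, b+r, low, high), case, state
    trace: list[dict] = field(default_factory=list)


def partition_readings(vector: np.ndarray, attributes: tuple[str, ...],
                       intervals: dict[str, NormalInterval],
                       ) -> tuple[list[str], list[str]]:
    """Split one reading vector into normal and abnormal attribute sets."""
    normal, abnormal = [], []
    for j, attr in enumerate(attributes):
        if attr not in intervals:
            raise KeyError(f"no normal interval configured for {attr!r}")
        (normal if intervals[attr].contains(float(vector[j])) else
         abnormal).append(attr)
    return normal, abnormal


def _sample_groups(history: np.ndarray, t: int, cols_x: list[int], col_y: int,
                   u: int, m: int, period: int) -> SampleGroups | None:
    """Assemble u-by-m sample groups from the same within-period instants.

    Group h covers the u instants ending one-to-m periods before ``t``; the
    most recent group supplies the crisp regressors.
    """
    first = t - m * period - u + 1
    if first < 0:
        return None
    y = np.empty((u, m))
    for h in range(1, m + 1):           # h = m is the most recent group
        g = m + 1 - h
        idx = np.arange(t - g * period - u + 1, t - g * period + 1)
        y[:, h - 1] = history[idx, col_y]
    idx_m = np.arange(t - period - u + 1, t - period + 1)
    x = history[np.ix_(idx_m, cols_x)]
    return SampleGroups(x=x, y=y)


def dfd_m_step(vector: np.ndarray, history: np.ndarray, kb: KnowledgeBase,
               cfg: DetectorConfig, attributes: tuple[str, ...],
               trace: list[dict] | None = None,
               ) -> tuple[dict[str, str], dict[str, int], float, bool]:
    """One detection round: returns (per-sensor states, case ids, LOF, kept).

    ``history`` holds all previously streamed rows (raw readings); the
    current ``vector`` is inserted into the knowledge base and rolled back
    if it scores outlying.  ``kept`` reports whether it stayed.
    """
    t = len(history)
    res = kb.insert(vector, keep_undo=True)
    states: dict[str, str] = {}
    cases: dict[str, int] = {}
    if not res.flagged:
        kb_kept = True
        for attr in attributes:
            states[attr] = GOOD
        return states, cases, res.lof, kb_kept

    kb.rollback(res)
    normal, abnormal = partition_readings(vector, attributes, cfg.intervals)
    if not normal or not abnormal:
        log.debug("t=%d outlying but coherent (|A'|=%d, |B'|=%d): patient "
                  "state change", t, len(normal), len(abnormal))
        for attr in attributes:
            states[attr] = PATIENT_STATE_CHANGE
        return states, cases, res.lof, False

    # the larger set is reliable; ties favour the physiologically normal set
    if len(normal) >= len(abnormal):
        reliable, suspected = normal, abnormal
    else:
        reliable, suspected = abnormal, normal
    col = {a: j for j, a in enumerate(attributes)}
    cols_x = [col[a] for a in reliable]
    x_now = np.array([vector[col[a]] for a in reliable])

    for attr in attributes:
        states[attr] = GOOD
    for attr in suspected:
        samples = _sample_groups(history, t, cols_x, col[attr],
                                 cfg.u, cfg.m, cfg.period)
        if samples is None or np.any(samples.y_recent == 0):
            log.debug("t=%d %s: insufficient or degenerate history, "
                      "deferring", t, attr)
            states[attr] = UNDECIDED
            continue
        from dataclasses import replace

        reg_cfg = FitConfig(
            lambda_start=cfg.regression.lambda_start,
            lambda_end=cfg.regression.lambda_end,
            ga=replace(cfg.regression.ga,
                       seed=(cfg.ga_seed * 1000003 + t * 31 + col[attr])
                       % (2 ** 31)),
            spread_floor=cfg.regression.spread_floor)
        model = fit(samples, reg_cfg)
        pred = model.predict(x_now)
        verdict = judge(pred, float(vector[col[attr]]),
                        cfg.intervals[attr], cfg.judgment)
        states[attr] = verdict.state
        cases[attr] = verdict.case_id
        if trace is not None:
            trace.append({"instant": t, "sensor": attr,
                          "y": float(vector[col[attr]]),
                          **verdict.breakpoints,
                          "case_id": verdict.case_id,
                          "state": verdict.state})
        log.debug("t=%d %s: y=%.3f pred=%s case=%d -> %s", t, attr,
                  vector[col[attr]], pred.as_tuple(), verdict.case_id,
                  verdict.state)
    return states, cases, res.lof, False


def run_detection(matrix: ReadingMatrix, cfg: DetectorConfig,
                  ) -> DetectionReport:
    """Run the three-step detector over a full reading matrix.

    The first ``cfg.warmup`` instants form the initial knowledge base (all
    considered normal) and are not judged.  Per-sensor undecided streaks are
    resolved with the configured persistence as the stream advances.
    """
    values = matrix.values
    duration, n = values.shape
    attributes = matrix.attributes
    warmup = cfg.resolved_warmup()
    if duration <= warmup:
        raise ValueError(f"stream of {duration} instants is shorter than the "
                         f"warmup of {warmup}")

    kb = KnowledgeBase(k=cfg.k, threshold=cfg.lof_threshold).fit(
        values[:warmup])
    states = np.full((duration, n), WARMUP, dtype=object)
    case_ids = np.zeros((duration, n), dtype=int)
    vector_outlier = np.zeros(duration, dtype=bool)
    evaluated = np.zeros(duration, dtype=bool)
    lof_trace = np.full(duration, np.nan)
    sensor_hist: dict[str, list[str]] = {a: [] for a in attributes}
    trace: list[dict] = []

    for t in range(warmup, duration):
        raw_states, cases, lof_t, kept = dfd_m_step(
            values[t], values[:t], kb, cfg, attributes, trace=trace)
        lof_trace[t] = lof_t
        vector_outlier[t] = not kept
        evaluated[t] = True
        for j, attr in enumerate(attributes):
            s = raw_states[attr]
            # streak bookkeeping: patient-state changes do not implicate the
            # sensor, so they reset the undecided streak like a good round
            sensor_hist[attr].append(GOOD if s == PATIENT_STATE_CHANGE else s)
            if s == UNDECIDED:
                resolved = resolve_undecided(sensor_hist[attr], cfg.judgment)
                states[t, j] = resolved
            else:
                states[t, j] = s
            case_ids[t, j] = cases.get(attr, 0)
        if cfg.kb_max_size is not None and len(kb) > cfg.kb_max_size:
            kb.refresh(max_size=cfg.kb_max_size)

    return DetectionReport(attributes=attributes, states=states,
                           vector_outlier=vector_outlier, evaluated=evaluated,
                           lof=lof_trace, case_ids=case_ids, trace=trace)


# ---------------------------------------------------------------------- #
# metrics


def evaluate(report: DetectionReport, truth: FaultLabels) -> dict:
    """Cell-level detection metrics against ground-truth fault labels.

    detection_accuracy: fraction of evaluated cells whose fault/not-fault
    classification is correct.  false_alarm_rate: fraction of genuinely
    correct readings misjudged as faulty, over all evaluated readings.
    Both are also reported per attribute.
    """
    if truth.fault.shape != report.states.shape:
        raise ValueError("truth labels and report have different shapes")
    mask = report.evaluated
    pred_fault = report.states == FAULT
    pf, tf = pred_fault[mask], truth.fault[mask]
    total = pf.size
    correct = np.sum(pf == tf)
    false_alarms = np.sum(pf & ~tf)
    missed = np.sum(~pf & tf)
    per_attr = {}
    for j, attr in enumerate(report.attributes):
        pa, ta = pred_fault[mask, j], truth.fault[mask, j]
        per_attr[attr] = {
            "detection_accuracy": float(np.mean(pa == ta)) if len(pa) else np.nan,
            "false_alarm_rate": float(np.mean(pa & ~ta)) if len(pa) else np.nan,
        }
    n_faults = int(np.sum(tf))
    return {
        "detection_accuracy": float(correct / total) if total else np.nan,
        "false_alarm_rate": float(false_alarms / total) if total else np.nan,
        "fault_recall": float((n_faults - missed) / n_faults) if n_faults else np.nan,
        "n_cells": int(total),
        "n_faults": n_faults,
        "per_attribute": per_attr,
    }


def alarm_filter(matrix: ReadingMatrix, report: DetectionReport,
                 intervals: dict[str, NormalInterval],
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Alarm instants before and after fault filtering.

    ``before``: evaluated instants where any reading exits its interval.
    ``after``: those instants minus the ones where every offending reading's
    sensor is classified faulty (pure data-fault alarms are suppressed).
    """
    duration, n = matrix.values.shape
    out_of_range = np.zeros((duration, n), dtype=bool)
    for j, attr in enumerate(matrix.attributes):
        iv = intervals[attr]
        v = matrix.values[:, j]
        out_of_range[:, j] = (v < iv.low) | (v > iv.high)
    before = np.flatnonzero(out_of_range.any(axis=1) & report.evaluated)
    keep = []
    for t in before:
        offending = np.flatnonzero(out_of_range[t])
        if not all(report.states[t, j] == FAULT for j in offending):
            keep.append(t)
    return before, np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------- #
# benchmarks


def benchmark_planted_outliers(size: int, n_outliers: int, k: int,
                               seeds: range | list[int],
                               threshold: float = 2.0, dim: int = 2,
                               variant: str = "mk",
                               incremental_frac: float = 0.0) -> np.ndarray:
    """Per-seed detected fraction of planted outliers.

    With ``incremental_frac`` > 0 that fraction of the points (chosen at
    random) is withheld from the batch fit and inserted one by one through
    the incremental update, emulating a growing stream.
    """
    rates = []
    for seed in seeds:
        points, outlier_ids = generate_cluster_dataset(
            size=size, n_outliers=n_outliers, dim=dim, seed=seed)
        kb = KnowledgeBase(k=k, threshold=threshold, variant=variant,
                           standardize=False)
        if incremental_frac > 0:
            rng = np.random.default_rng(seed + 1)
            perm = rng.permutation(size)
            n_init = int(round((1 - incremental_frac) * size))
            init, stream = perm[:n_init], perm[n_init:]
            kb.fit(points[init], ids=init)
            # inserted points receive fresh sequential ids; remember them
            stream_ids = {int(row): kb.insert(points[row]).point_id
                          for row in stream}
            flagged = kb.outliers()
            detected = sum(
                1 for o in outlier_ids
                if stream_ids.get(int(o), int(o)) in flagged)
            rates.append(detected / n_outliers)
        else:
            kb.fit(points)
            flagged = kb.outliers()
            rates.append(len(flagged & {int(i) for i in outlier_ids})
                         / n_outliers)
    return np.asarray(rates)


def benchmark_end_to_end(seeds: range | list[int], duration: int = 520,
                         period: int = 50, u: int = 8, m: int = 4,
                         fault_rate: float = 0.05,
                         fault_magnitude: float = 6.0,
                         k: int = 10,
                         ga_population: int = 40, ga_generations: int = 60,
                         attributes: tuple[str, ...] = ("HR", "RR", "BT",
                                                        "SpO2", "GLU", "BP"),
                         ) -> dict:
    """Full-pipeline benchmark on synthetic vitals with planted faults.

    Per seed: generate a vitals stream with out-of-sync illness episodes,
    inject spike faults at ``fault_rate`` per cell into the streamed (post
    warmup) portion, run the detector, and score cell-level accuracy and
    false alarm rate.  Returns per-seed arrays plus means in percent.
    """
    warmup = m * period + u
    if duration <= warmup + period:
        raise ValueError("duration too short for the configured warmup")
    accs, fars, recalls = [], [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        ep_start = int(rng.integers(warmup + 20, duration - 60))
        cfg_v = VitalsConfig(
            attributes=attributes, duration=duration, period=period,
            coupling=float(rng.uniform(10, 15)),
            illness_episodes=[IllnessEpisode(start=ep_start, duration=25)],
            seed=seed)
        clean, labels = generate_vitals(cfg_v)
        # plant faults only into the streamed portion; the initial knowledge
        # base is taken to be clean, as the detector assumes
        post = ReadingMatrix(times=clean.times[warmup:],
                             values=clean.values[warmup:].copy(),
                             attributes=attributes)
        post_faulty, post_labels = inject_faults(
            post, [FaultModel(kind="spike", rate=fault_rate,
                              magnitude=fault_magnitude, seed=seed + 10_000)])
        values = clean.values.copy()
        values[warmup:] = post_faulty.values
        matrix = ReadingMatrix(times=clean.times, values=values,
                               attributes=attributes)
        truth = FaultLabels.empty(duration, len(attributes))
        truth.fault[warmup:] = post_labels.fault
        truth.illness = labels.illness

        det_cfg = DetectorConfig(
            k=k, u=u, m=m, period=period, warmup=warmup,
            regression=FitConfig(ga=GAConfig(population=ga_population,
                                             generations=ga_generations,
                                             polish=False)),
            ga_seed=seed)
        report = run_detection(matrix, det_cfg)
        metrics = evaluate(report, truth)
        accs.append(metrics["detection_accuracy"])
        fars.append(metrics["false_alarm_rate"])
        recalls.append(metrics["fault_recall"])
    accs, fars = np.asarray(accs), np.asarray(fars)
    return {
        "accuracy_per_seed": accs,
        "false_alarm_per_seed": fars,
        "fault_recall_per_seed": np.asarray(recalls),
        "mean_accuracy_pct": float(100 * accs.mean()),
        "mean_false_alarm_pct": float(100 * fars.mean()),
        "n_seeds": len(accs),
    }
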