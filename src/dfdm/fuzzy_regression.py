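"""Trapezoidal fuzzy linear regression fitted by a penalty-method GA.

Model
-----
A fuzzy linear function with trapezoidal fuzzy coefficients

    Y~_j = A~_0 + A~_1 x_j1 + ... + A~_n x_jn,     A~_i = (a_i, b_i, l_i, r_i)

predicts for each regressor vector a trapezoidal fuzzy number whose core is
[y_a, y_b] and whose support is [y_a - y_l, y_b + y_r]:

    y_a = sum a_i x_i + a_0         y_b = sum b_i x_i + b_0
    y_l = sum l_i |x_i| + l_0       y_r = sum r_i |x_i| + r_0

The training data are u within-period instants observed over m historical
periods ("sample groups").  Per instant, the observed outputs across the
groups are fuzzified: the core bounds are the minimum and maximum of the m
group values, and the spreads are left to the optimizer.  The fit minimizes
the expectation-based relative error

    R = sum_j ((E[Y~_jm] - Y_jm) / Y_jm)^2,     E[(a,b,l,r)] = (2a+2b-l+r)/4

subject to the core matching the fuzzified bounds (equality residuals
h_1..h_4) and the prediction containing the observation with membership at
least the fitting degree lambda_j (inequality constraints g_1, g_2).  The
constrained program is folded into the exact-penalty objective

    R + sum |h_i| + sum |min(0, g_i)|

and minimized by a seeded real-coded genetic algorithm (the objective is
non-smooth, so gradient methods are not attractive).

Two baselines are provided: a triangular-fuzzy-number regression
(``model="triangle"``: the core collapses to a point, b_i = a_i) and a crisp
ordinary-least-squares line (:func:`fit_slr`), both scored with the same
relative-error statistic so the three can be compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "TrapezoidalFuzzyNumber",
    "SampleGroups",
    "FitConfig",
    "GAConfig",
    "FuzzyModel",
    "fuzzify_outputs",
    "objective_R",
    "penalty_objective",
    "fit",
    "grid_search_fit",
    "fit_slr",
]

#: strict-positivity floor for the spread parameters l, r
SPREAD_FLOOR = 1e-6


# ---------------------------------------------------------------------- #
# fuzzy numbers


@dataclass(frozen=True)
class TrapezoidalFuzzyNumber:
    """Trapezoidal fuzzy number (a, b, l, r): core [a, b], support [a-l, b+r]."""

    a: float
    b: float
    l: float
    r: float

    def __post_init__(self):
        if self.a > self.b + 1e-12:
            raise ValueError(f"core bounds inverted: a={self.a} > b={self.b}")
        if self.l <= 0 or self.r <= 0:
            raise ValueError("spreads l, r must be strictly positive")

    @property
    def support(self) -> tuple[float, float]:
        return (self.a - self.l, self.b + self.r)

    def membership(self, y: float) -> float:
        """Piecewise-linear membership: rising shoulder, core, falling shoulder."""
        if self.a - self.l < y < self.a:
            return (y - self.a + self.l) / self.l
        if self.a <= y <= self.b:
            return 1.0
        if self.b < y <= self.b + self.r:
            return (self.b + self.r - y) / self.r
        return 0.0

    def expectation(self) -> float:
        """Crisp expectation (2a + 2b - l + r) / 4."""
        return (2 * self.a + 2 * self.b - self.l + self.r) / 4.0

    def level_cut(self, lam: float) -> tuple[float, float]:
        """Reading values whose membership equals ``lam`` on each shoulder."""
        return (self.a - (1 - lam) * self.l, self.b + (1 - lam) * self.r)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.l, self.r)


# ---------------------------------------------------------------------- #
# training data


@dataclass
class SampleGroups:
    """u within-period instants observed over m sample groups.

    ``x`` is the u-by-n regressor matrix of the most recent group (the
    precise inputs used for fitting); ``y`` is the u-by-m matrix of observed
    outputs, one column per group, with column m-1 the most recent.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have one row per instant")
        if self.x.shape[0] < 2:
            raise ValueError("need at least u = 2 instants")
        if self.x.shape[1] < 1:
            raise ValueError("need at least one regressor")

    @property
    def u(self) -> int:
        return self.x.shape[0]

    @property
    def n(self) -> int:
        return self.x.shape[1]

    @property
    def m(self) -> int:
        return self.y.shape[1]

    @property
    def y_recent(self) -> np.ndarray:
        """Crisp outputs of the most recent group (used in the R statistic)."""
        return self.y[:, -1]


def fuzzify_outputs(samples: SampleGroups) -> tuple[np.ndarray, np.ndarray]:
    """Per-instant fuzzified core bounds: (min over groups, max over groups)."""
    y = samples.y
    return y.min(axis=1), y.max(axis=1)


# ---------------------------------------------------------------------- #
# configuration


@dataclass
class GAConfig:
    """Hyperparameters of the real-coded genetic algorithm."""

    population: int = 100
    generations: int = 300
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.1        # initial step, fraction of bound width
    mutation_sigma_final: float = 1e-4  # annealed to this by the last generation
    polish: bool = True                # local refinement of the winner(s)
    polish_starts: int = 4             # GA winner, two survivors, heuristic
    polish_maxfev: int = 8000          # objective-evaluation budget per start
    seed: int = 42


@dataclass
class FitConfig:
    """Fitting degrees, GA settings and numerical floors for one fit."""

    lambdas: np.ndarray | None = None   # per-instant, nondecreasing toward now
    lambda_start: float = 0.5
    lambda_end: float = 0.9
    ga: GAConfig = field(default_factory=GAConfig)
    spread_floor: float = SPREAD_FLOOR
    #: weight of the spread-parsimony tie-break inside the search objective.
    #: The error statistic depends on the spreads only through r - l, so
    #: symmetrically inflating both spreads is otherwise free; following the
    #: possibilistic-regression convention the search prefers the smallest
    #: spreads compatible with the containment constraints.  The reported
    #: penalty value excludes this term.
    spread_parsimony: float = 1e-3

    def resolve_lambdas(self, u: int) -> np.ndarray:
        if self.lambdas is not None:
            lam = np.asarray(self.lambdas, dtype=float)
            if lam.shape != (u,):
                raise ValueError(f"lambdas must have length u={u}")
        else:
            lam = np.linspace(self.lambda_start, self.lambda_end, u)
        if np.any(lam < 0) or np.any(lam > 1):
            raise ValueError("fitting degrees must lie in [0, 1]")
        return lam


@dataclass
class FuzzyModel:
    """Fitted fuzzy regression: n+1 trapezoidal coefficients (intercept first)."""

    coefficients: list[TrapezoidalFuzzyNumber]
    fit_R: float = np.nan
    fit_penalty: float = np.nan
    feasibility_report: dict = field(default_factory=dict)
    model: str = "trapezoid"

    @property
    def n(self) -> int:
        return len(self.coefficients) - 1

    def predict(self, x: np.ndarray) -> TrapezoidalFuzzyNumber:
        """Fuzzy prediction for one regressor vector (spreads use |x_i|)."""
        x = np.asarray(x, dtype=float).ravel()
        if x.shape != (self.n,):
            raise ValueError(f"expected {self.n} regressors, got {x.shape}")
        C = np.array([c.as_tuple() for c in self.coefficients])  # (n+1, 4)
        a = C[0, 0] + C[1:, 0] @ x
        b = C[0, 1] + C[1:, 1] @ x
        l = C[0, 2] + C[1:, 2] @ np.abs(x)
        r = C[0, 3] + C[1:, 3] @ np.abs(x)
        if a > b:  # possible under negative regressors; repair by swapping
            a, b = b, a
        return TrapezoidalFuzzyNumber(a, b, max(l, SPREAD_FLOOR),
                                      max(r, SPREAD_FLOOR))

    def params(self) -> np.ndarray:
        return np.array([c.as_tuple() for c in self.coefficients]).ravel()

    def to_json(self, path: str) -> None:
        payload = {"model": self.model, "fit_R": self.fit_R,
                   "fit_penalty": self.fit_penalty,
                   "feasibility_report": self.feasibility_report,
                   "coefficients": [c.as_tuple() for c in self.coefficients]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FuzzyModel":
        with open(path) as fh:
            payload = json.load(fh)
        coeffs = [TrapezoidalFuzzyNumber(*c) for c in payload["coefficients"]]
        return cls(coefficients=coeffs, fit_R=payload["fit_R"],
                   fit_penalty=payload.get("fit_penalty", np.nan),
                   feasibility_report=payload.get("feasibility_report", {}),
                   model=payload.get("model", "trapezoid"))


# ---------------------------------------------------------------------- #
# objectives

def _decode(params: np.ndarray, n: int, model: str,
            spread_floor: float) -> np.ndarray:
    """Reshape a flat parameter vector to (n+1, 4) and repair invariants.

    Repairs: a_i <= b_i by swapping, spreads floored at ``spread_floor``;
    for the triangular degeneration the core collapses to b_i = a_i.
    Accepts a batch of vectors (P, 4(n+1)) and returns (P, n+1, 4).
    """
    P = np.atleast_2d(np.asarray(params, dtype=float))
    C = P.reshape(P.shape[0], n + 1, 4).copy()
    a = np.minimum(C[:, :, 0], C[:, :, 1])
    b = np.maximum(C[:, :, 0], C[:, :, 1])
    C[:, :, 0], C[:, :, 1] = a, b
    if model == "triangle":
        C[:, :, 1] = C[:, :, 0]
    C[:, :, 2:] = np.maximum(C[:, :, 2:], spread_floor)
    return C


def _batch_components(C: np.ndarray, samples: SampleGroups,
                      lambdas: np.ndarray):
    """Per-candidate R, equality residuals and hinge violations.

    ``C`` has shape (P, n+1, 4).  Returns arrays of shape (P,).
    """
    X1 = np.hstack([np.ones((samples.u, 1)), samples.x])          # (u, n+1)
    Xa = np.hstack([np.ones((samples.u, 1)), np.abs(samples.x)])  # (u, n+1)
    ya_pred = X1 @ C[:, :, 0].T   # (u, P)
    yb_pred = X1 @ C[:, :, 1].T
    yl_pred = Xa @ C[:, :, 2].T
    yr_pred = Xa @ C[:, :, 3].T

    ym = samples.y_recent[:, None]           # crisp outputs, most recent group
    E = (2 * ya_pred + 2 * yb_pred - yl_pred + yr_pred) / 4.0
    R = np.sum(((E - ym) / ym) ** 2, axis=0)

    ya_obs, yb_obs = fuzzify_outputs(samples)
    h = (np.abs(ya_obs[:, None] - ya_pred).sum(axis=0)
         + np.abs(yb_obs[:, None] - yb_pred).sum(axis=0))

    lam = lambdas[:, None]
    g1 = ym - (ya_pred - (1 - lam) * yl_pred)   # lower containment
    g2 = (yb_pred + (1 - lam) * yr_pred) - ym   # upper containment
    g = (np.maximum(0.0, -g1).sum(axis=0) + np.maximum(0.0, -g2).sum(axis=0))
    # mean spread relative to the output scale (parsimony tie-break)
    S = (yl_pred + yr_pred).mean(axis=0) / np.abs(ym).mean()
    return R, h, g, S


def objective_R(model: FuzzyModel, samples: SampleGroups) -> float:
    """Expectation-based relative error R of a fitted model on ``samples``."""
    ym = samples.y_recent
    if np.any(ym == 0):
        raise ValueError(
            "observed outputs contain zeros; shift or rescale the attribute "
            "before fitting (R is a relative-error statistic)")
    C = np.array([c.as_tuple() for c in model.coefficients])[None, :, :]
    R, _, _, _ = _batch_components(C, samples, np.zeros(samples.u))
    return float(R[0])


def penalty_objective(params: np.ndarray, samples: SampleGroups,
                      config: FitConfig) -> float:
    """Exact-penalty objective R + sum|h_i| + sum|min(0, g_i)| for one vector."""
    ym = samples.y_recent
    if np.any(ym == 0):
        raise ValueError(
            "observed outputs contain zeros; shift or rescale the attribute")
    lam = config.resolve_lambdas(samples.u)
    C = _decode(params, samples.n, "trapezoid", config.spread_floor)
    R, h, g, _ = _batch_components(C, samples, lam)
    return float(R[0] + h[0] + g[0])


# ---------------------------------------------------------------------- #
# bounds

def _parameter_bounds(samples: SampleGroups,
                      spread_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Data-driven box bounds for the flat parameter vector.

    Core coefficients are centred on the crisp OLS solution with a halfwidth
    of three residual standard deviations (scaled by the regressor spread);
    spread coefficients range from the positivity floor up to twice the
    output spread on the same scale.
    """
    X1 = np.hstack([np.ones((samples.u, 1)), samples.x])
    ym = samples.y_recent
    beta, *_ = np.linalg.lstsq(X1, ym, rcond=None)
    resid = ym - X1 @ beta
    sig = max(float(np.std(resid)), 1e-3 * max(float(np.std(ym)), 1.0))
    span = float(ym.max() - ym.min()) + sig
    xscale = np.concatenate([[1.0], np.maximum(np.std(samples.x, axis=0), 1e-6)])
    half = 3.0 * (sig + span) / xscale
    lo = np.empty((samples.n + 1, 4))
    hi = np.empty((samples.n + 1, 4))
    lo[:, 0] = lo[:, 1] = beta - half
    hi[:, 0] = hi[:, 1] = beta + half
    lo[:, 2] = lo[:, 3] = spread_floor
    # each spread term contributes at most ~2*span at a typical regressor
    # magnitude, so the total support width stays on the data scale
    xmag = np.concatenate([[1.0],
                           np.maximum(np.mean(np.abs(samples.x), axis=0),
                                      1e-6)])
    hi[:, 2] = hi[:, 3] = 2.0 * span / ((samples.n + 1) * xmag)
    return lo.ravel(), hi.ravel()


# ---------------------------------------------------------------------- #
# genetic algorithm

def _heuristic_seeds(samples: SampleGroups, spread_floor: float) -> np.ndarray:
    """Informed individuals for the initial population.

    The equality residuals want the core lines through the fuzzified min and
    max envelopes, so least-squares fits of those envelopes (with spreads at
    the floor or sized to the residual scale) start the search in the right
    basin.
    """
    X1 = np.hstack([np.ones((samples.u, 1)), samples.x])
    ya_obs, yb_obs = fuzzify_outputs(samples)
    beta_a, *_ = np.linalg.lstsq(X1, ya_obs, rcond=None)
    beta_b, *_ = np.linalg.lstsq(X1, yb_obs, rcond=None)
    resid = max(float(np.std(ya_obs - X1 @ beta_a)),
                float(np.std(yb_obs - X1 @ beta_b)), spread_floor)
    seeds = []
    for spread0 in (spread_floor, resid, 4 * resid):
        C = np.zeros((samples.n + 1, 4))
        C[:, 0], C[:, 1] = beta_a, beta_b
        C[0, 2] = C[0, 3] = spread0
        C[1:, 2] = C[1:, 3] = spread_floor
        seeds.append(C.ravel())
    beta_m = (beta_a + beta_b) / 2
    C = np.zeros((samples.n + 1, 4))
    C[:, 0] = C[:, 1] = beta_m
    C[0, 2] = C[0, 3] = 2 * resid
    C[1:, 2] = C[1:, 3] = spread_floor
    seeds.append(C.ravel())
    return np.asarray(seeds)

def fit(samples: SampleGroups, config: FitConfig | None = None,
        model: str = "trapezoid",
        bounds: tuple[np.ndarray, np.ndarray] | None = None) -> FuzzyModel:
    """Fit the fuzzy regression by minimizing the penalty objective with a GA.

    The GA is real-coded and fully vectorized: tournament selection, blend
    crossover, Gaussian mutation, one elite.  Deterministic for a fixed
    ``config.ga.seed``.
    """
    if model not in ("trapezoid", "triangle"):
        raise ValueError(f"unknown model {model!r}")
    config = config or FitConfig()
    ym = samples.y_recent
    if np.any(ym == 0):
        raise ValueError(
            "observed outputs contain zeros; shift or rescale the attribute")
    lam = config.resolve_lambdas(samples.u)
    lo, hi = bounds if bounds is not None else _parameter_bounds(
        samples, config.spread_floor)
    if np.any(hi <= lo):
        raise ValueError("parameter bounds are empty on at least one axis")

    ga = config.ga
    rng = np.random.default_rng(ga.seed)
    dim = 4 * (samples.n + 1)
    P = ga.population
    pop = rng.uniform(lo, hi, size=(P, dim))
    pop[: min(4, P)] = np.clip(
        _heuristic_seeds(samples, config.spread_floor), lo, hi)

    def evaluate(pop_arr: np.ndarray) -> np.ndarray:
        """Search objective: exact penalty plus the spread-parsimony term."""
        C = _decode(pop_arr, samples.n, model, config.spread_floor)
        R, h, g, S = _batch_components(C, samples, lam)
        return R + h + g + config.spread_parsimony * S

    fitness = evaluate(pop)
    best_i = int(np.argmin(fitness))
    best_x, best_f = pop[best_i].copy(), float(fitness[best_i])
    width = hi - lo

    decay = (ga.mutation_sigma_final / ga.mutation_sigma) \
        ** (1.0 / max(ga.generations - 1, 1))
    sigma = ga.mutation_sigma
    for _ in range(ga.generations):
        # tournament selection (vectorized)
        contenders = rng.integers(0, P, size=(2 * P, ga.tournament))
        winners = contenders[np.arange(2 * P),
                             np.argmin(fitness[contenders], axis=1)]
        p1, p2 = pop[winners[:P]], pop[winners[P:]]
        # blend crossover (mild extrapolation keeps variance up)
        do_cx = rng.random(P) < ga.crossover_rate
        alpha = rng.uniform(-0.25, 1.25, size=(P, dim))
        children = np.where(do_cx[:, None], alpha * p1 + (1 - alpha) * p2, p1)
        # Gaussian mutation with annealed step size
        do_mut = rng.random((P, dim)) < ga.mutation_rate
        children = children + do_mut * rng.normal(0, sigma, size=(P, dim)) * width
        sigma *= decay
        np.clip(children, lo, hi, out=children)
        child_fit = evaluate(children)
        # elitism: preserve the incumbent
        worst = int(np.argmax(child_fit))
        children[worst], child_fit[worst] = best_x, best_f
        pop, fitness = children, child_fit
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f:
            best_x, best_f = pop[gen_best].copy(), float(fitness[gen_best])

    if ga.polish:
        # memetic step: refine the winner and the two best survivors with a
        # bounded direction-set search on the same (non-smooth) objective;
        # polishing several basins guards against premature convergence
        order = np.argsort(fitness)
        starts = [best_x] + [pop[i] for i in order[:2]] \
            + [np.clip(_heuristic_seeds(samples, config.spread_floor)[1],
                       lo, hi)]
        starts = starts[: max(ga.polish_starts, 1)]

        def scalar(v):
            return float(evaluate(np.clip(v, lo, hi)[None])[0])

        for x0 in starts:
            res = optimize.minimize(
                scalar, x0, method="Powell", bounds=list(zip(lo, hi)),
                options={"maxfev": ga.polish_maxfev, "xtol": 1e-10,
                         "ftol": 1e-12})
            # a simplex pass recovers where direction-set search stalls on
            # the non-smooth l1 ridges
            res2 = optimize.minimize(
                scalar, res.x, method="Nelder-Mead",
                options={"maxfev": ga.polish_maxfev // 2, "xatol": 1e-10,
                         "fatol": 1e-12, "adaptive": True})
            for cand in (res, res2):
                if cand.fun < best_f:
                    best_x = np.clip(cand.x, lo, hi)
                    best_f = float(cand.fun)

    C = _decode(best_x, samples.n, model, config.spread_floor)[0]
    coeffs = [TrapezoidalFuzzyNumber(*row) for row in C]
    R, h, g, _ = _batch_components(C[None], samples, lam)
    fm = FuzzyModel(coefficients=coeffs, fit_R=float(R[0]),
                    fit_penalty=float(R[0] + h[0] + g[0]), model=model,
                    feasibility_report={"sum_abs_h": float(h[0]),
                                        "sum_hinge_g": float(g[0])})
    return fm


def grid_search_fit(samples: SampleGroups, config: FitConfig | None = None,
                    levels: int = 5, polish: bool = True) -> FuzzyModel:
    """Brute-force reference solver for tiny instances (n = 1, small u).

    Evaluates the penalty objective on a full Cartesian grid over the
    parameter box and optionally polishes the best grid point with a
    bounded Powell search.  Exponential in the parameter count -- intended
    only as an independent oracle for the GA on n=1 problems.
    """
    if samples.n > 1:
        raise ValueError("grid search oracle is limited to n = 1")
    config = config or FitConfig()
    lam = config.resolve_lambdas(samples.u)
    lo, hi = _parameter_bounds(samples, config.spread_floor)
    dim = len(lo)
    axes = [np.linspace(lo[d], hi[d], levels) for d in range(dim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)

    def evaluate(pop_arr):
        C = _decode(pop_arr, samples.n, "trapezoid", config.spread_floor)
        R, h, g, S = _batch_components(C, samples, lam)
        return R + h + g + config.spread_parsimony * S

    # evaluate in chunks to bound memory; keep the few best grid points
    top_f: list[float] = []
    top_x: list[np.ndarray] = []
    for start in range(0, len(grid), 200_000):
        chunk = grid[start:start + 200_000]
        f = evaluate(chunk)
        order = np.argsort(f)[:3]
        top_f.extend(float(v) for v in f[order])
        top_x.extend(chunk[i].copy() for i in order)
    order = np.argsort(top_f)[:3]
    best_f, best_x = top_f[order[0]], top_x[order[0]]

    if polish:
        for i in order:
            res = optimize.minimize(
                lambda v: float(evaluate(v[None])[0]), top_x[i],
                method="Powell", bounds=list(zip(lo, hi)),
                options={"maxiter": 20000, "xtol": 1e-10, "ftol": 1e-12})
            if res.fun < best_f:
                best_f, best_x = float(res.fun), res.x

    C = _decode(best_x, samples.n, "trapezoid", config.spread_floor)[0]
    R, h, g, _ = _batch_components(C[None], samples, lam)
    return FuzzyModel(coefficients=[TrapezoidalFuzzyNumber(*row) for row in C],
                      fit_R=float(R[0]), fit_penalty=float(R[0] + h[0] + g[0]),
                      feasibility_report={"sum_abs_h": float(h[0]),
                                          "sum_hinge_g": float(g[0])},
                      model="trapezoid")


# ---------------------------------------------------------------------- #
# crisp baseline

def fit_slr(samples: SampleGroups) -> tuple[np.ndarray, float]:
    """Ordinary least squares on the most recent group's crisp outputs.

    Returns the coefficient vector (intercept first) and the same
    relative-error statistic R used for the fuzzy models.
    """
    X1 = np.hstack([np.ones((samples.u, 1)), samples.x])
    ym = samples.y_recent
    beta, *_ = np.linalg.lstsq(X1, ym, rcond=None)
    pred = X1 @ beta
    R = float(np.sum(((pred - ym) / ym) ** 2))
    return beta, R
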