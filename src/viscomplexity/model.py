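"""The complexity model: weighted feature combination fitted to subjective scores.

An image's complexity score is a linear combination of its K = 11 min-max
normalized measures,

    x_j = sum_k a_k x_kj,        a_k in [-1, 1],

and the weights are chosen to maximize the Pearson correlation between the
scores and the per-image mean subjective scores y_j, after passing the
scores through a fitted monotone logistic map f (the standard calibration
used in image-quality assessment, which absorbs the unknown monotone
nonlinearity between an objective scale and human ratings):

    fitness(A) = PCC(f(x), y),
    f(x) = b1 (1/2 - 1/(1 + exp(b2 (x - b3)))) + b4 x + b5.

The maximization runs a global-best Particle Swarm Optimization over
[-1, 1]^K, repeated over many independently seeded runs; the published
protocol averages the per-run best weight vectors and reports the
mean/SD/min/max of the per-run best fitness.  Two fitted presets ship with
the package: ``LC_RS1`` (real-world scenes) and ``LC_TXT1`` (textures).

Because f is re-fitted for every candidate, the fitness is invariant to
affine transforms of x (including sign flips) — weights are identifiable
only up to scale, so recovery is judged by direction (cosine), not
magnitude.  Each run's best vector is oriented so the raw combined score
correlates positively with y, which makes the multi-run average well
defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .table import FeatureTable

__all__ = [
    "LogisticParams",
    "PsoConfig",
    "FitResult",
    "EvalReport",
    "PRESETS",
    "lc_score",
    "logistic_fit",
    "fitness_pcc",
    "pso_optimize",
    "evaluate",
    "preset",
]

N_FEATURES = 11

# Fitted weight presets (a_1 .. a_11), each the average of 1000 PSO runs.
PRESETS: dict[str, np.ndarray] = {
    # real-world scenes
    "LC_RS1": np.array(
        [0.2076, 0.1986, -0.4046, 0.1305, 0.5548, -0.1245,
         -0.1257, 0.6167, -0.2588, 0.4645, -0.0692]
    ),
    # texture patches
    "LC_TXT1": np.array(
        [0.3653, 0.0913, -0.0161, 0.0127, -0.7150, 0.3961,
         0.2774, -0.0358, -0.0099, 0.4854, 0.0209]
    ),
}


def preset(name: str) -> np.ndarray:
    """Return a copy of a published weight preset (``LC_RS1`` or ``LC_TXT1``)."""
    try:
        return PRESETS[name].copy()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    if isinstance(y, pd.DataFrame):
        y = y["y"]
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: x has {x.size}, y has {y.size}")
    return x, y


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; plain formula (hot path: no scipy overhead)."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        raise ValueError("zero variance: correlation undefined")
    return float((a @ b) / denom)


def lc_score(x: np.ndarray, a: np.ndarray) -> np.ndarray | float:
    """Linear combination sum_k a_k x_k for one feature vector or an N x K block."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float).ravel()
    if x.shape[-1] != a.size:
        raise ValueError(
            f"feature count {x.shape[-1]} does not match weight count {a.size}"
        )
    out = x @ a
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the 5-parameter monotone calibration curve."""

    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    linear_fallback: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = np.clip(self.b2 * (x - self.b3), -500.0, 500.0)
        return (
            self.b1 * (0.5 - 1.0 / (1.0 + np.exp(z))) + self.b4 * x + self.b5
        )


# Minimum |b2| on the standardized-x scale.  A sigmoid flatter than this is
# numerically collinear with the explicit linear term (same model space,
# exploding coefficients), so the slope is kept away from zero.
_B2_MIN = 0.5


def _clamp_b2(b2: float) -> float:
    if abs(b2) < _B2_MIN:
        return _B2_MIN if b2 >= 0 else -_B2_MIN
    return b2


def _make_varpro(x: np.ndarray, y: np.ndarray):
    """Build a fast solver for the linear coefficients given (b2, b3).

    For fixed (b2, b3) the model is linear in (b1, b4, b5); the normal
    equations are assembled from precomputed moments of x and y, leaving
    only the sigmoid column to recompute per candidate.  The SSE is
    evaluated from the residuals directly (the moment identity cancels
    catastrophically when the basis is near-collinear).
    """
    n = float(x.size)
    xx, sx, xy, sy = x @ x, x.sum(), x @ y, y.sum()

    def solve(b2: float, b3: float):
        b2 = _clamp_b2(b2)
        z = np.clip(b2 * (x - b3), -500.0, 500.0)
        g = 0.5 - 1.0 / (1.0 + np.exp(z))
        ata = np.array(
            [[g @ g, g @ x, g.sum()], [0.0, xx, sx], [0.0, 0.0, n]]
        )
        ata[1, 0], ata[2, 0], ata[2, 1] = ata[0, 1], ata[0, 2], ata[1, 2]
        aty = np.array([g @ y, xy, sy])
        try:
            coef = np.linalg.solve(ata, aty)
        except np.linalg.LinAlgError:
            design = np.column_stack([g, x, np.ones_like(x)])
            coef = np.linalg.lstsq(design, y, rcond=None)[0]
        resid = y - (coef[0] * g + coef[1] * x + coef[2])
        return float(resid @ resid), coef

    return solve


def _nelder_mead_2d(f, start, maxiter: int, xatol: float = 1e-7,
                    fatol: float = 1e-12) -> np.ndarray:
    """Minimal deterministic Nelder-Mead for a 2-D objective.

    Standard coefficients (reflect 1, expand 2, contract 0.5, shrink 0.5)
    and a scipy-style initial simplex (5% perturbation per coordinate).
    The fit runs inside every PSO fitness evaluation, so the generic
    optimizer's per-iteration overhead matters; this loop is ~3x faster.
    """
    # plain-float simplex: numpy overhead on 3x2 arrays would dominate
    a0, b0 = float(start[0]), float(start[1])
    pts = [
        (a0, b0),
        (a0 * 1.05 if a0 != 0 else 0.00025, b0),
        (a0, b0 * 1.05 if b0 != 0 else 0.00025),
    ]
    simplex = sorted(((f(p), p) for p in pts), key=lambda t: t[0])
    for _ in range(maxiter):
        (f0, p0), (f1, p1), (f2, p2) = simplex
        if (max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]),
                abs(p2[0] - p0[0]), abs(p2[1] - p0[1])) <= xatol
                and f2 - f0 <= fatol):
            break
        cx, cy = 0.5 * (p0[0] + p1[0]), 0.5 * (p0[1] + p1[1])
        dx, dy = cx - p2[0], cy - p2[1]
        xr = (cx + dx, cy + dy)
        fr = f(xr)
        if fr < f0:
            xe = (cx + 2.0 * dx, cy + 2.0 * dy)
            fe = f(xe)
            new = (fe, xe) if fe < fr else (fr, xr)
        elif fr < f1:
            new = (fr, xr)
        else:
            if fr < f2:  # outside contraction
                xc = (cx + 0.5 * dx, cy + 0.5 * dy)
            else:  # inside contraction
                xc = (cx - 0.5 * dx, cy - 0.5 * dy)
            fc = f(xc)
            if fc < min(fr, f2):
                new = (fc, xc)
            else:  # shrink toward the best point
                q1 = (p0[0] + 0.5 * (p1[0] - p0[0]), p0[1] + 0.5 * (p1[1] - p0[1]))
                q2 = (p0[0] + 0.5 * (p2[0] - p0[0]), p0[1] + 0.5 * (p2[1] - p0[1]))
                simplex = sorted(
                    [(f0, p0), (f(q1), q1), (f(q2), q2)], key=lambda t: t[0]
                )
                continue
        simplex = sorted([(f0, p0), (f1, p1), new], key=lambda t: t[0])
    return np.array(simplex[0][1])


def logistic_fit(x, y, maxiter: int = 120) -> LogisticParams:
    """Least-squares fit of the monotone logistic calibration f to (x, y).

    The linear parameters (b1, b4, b5) are solved exactly by least squares
    for any (b2, b3) (variable projection), and (b2, b3) are refined by
    Nelder-Mead from the deterministic start b2 = 1/SD(x), b3 = median(x).
    x is standardized internally before optimizing and the parameters are
    mapped back afterwards, so the fit — and hence the fitness — is exactly
    invariant to positive affine transforms of x.  On numerical failure the
    fit degrades to the plain linear map (b1 = 0) with a warning.
    """
    x, y = _as_xy(x, y)
    if x.size < 6:
        raise ValueError("logistic fit needs at least 6 points")
    sd = x.std()
    if sd <= 0:
        raise ValueError("objective scores are constant; cannot fit")
    mu = x.mean()
    u = (x - mu) / sd  # scale-free problem for the simplex search
    solve = _make_varpro(u, y)

    def objective(p):
        return solve(p[0], p[1])[0]

    start = np.array([1.0, float(np.median(u))])
    try:
        c2, c3 = _nelder_mead_2d(objective, start, maxiter=maxiter)
        c2 = _clamp_b2(c2)  # match the slope actually used by the solver
        _, (c1, c4, c5) = solve(c2, c3)
        # map parameters from u = (x - mu)/sd back to the x scale
        params = LogisticParams(
            float(c1), float(c2 / sd), float(mu + sd * c3),
            float(c4 / sd), float(c5 - c4 * mu / sd),
        )
        if not np.all(np.isfinite(params.predict(x))):
            raise FloatingPointError("non-finite prediction")
        return params
    except Exception as e:
        warnings.warn(f"logistic fit failed ({e}); falling back to linear", stacklevel=2)
        design = np.column_stack([x, np.ones_like(x)])
        b4, b5 = np.linalg.lstsq(design, y, rcond=None)[0]
        return LogisticParams(0.0, 1.0, float(np.median(x)), float(b4), float(b5),
                              linear_fallback=True)


def fitness_pcc(x, y, maxiter: int = 120) -> float:
    """Pearson correlation between the logistic-calibrated scores f(x) and y.

    Because f is fitted to y by least squares, the value equals the multiple
    correlation of y on the calibration basis and is non-negative for any
    informative x.  Raises on constant x or y.
    """
    x, y = _as_xy(x, y)
    if y.std() <= 0:
        raise ValueError("subjective scores are constant; correlation undefined")
    params = logistic_fit(x, y, maxiter=maxiter)
    fx = params.predict(x)
    if fx.std() <= 0:
        raise ValueError("calibrated scores are constant; correlation undefined")
    return _pcc(fx, y)


@dataclass
class PsoConfig:
    """Hyperparameters of the global-best PSO and the multi-run protocol.

    Defaults: 40 particles, 200 iterations, constriction-style inertia
    0.7298 with cognitive = social = 1.4962, velocities clamped to half the
    search range, positions clamped to [-1, 1] per coordinate, 1000
    independent runs (run r uses seed ``seed + r``).  ``fit_maxiter`` bounds
    the inner logistic-fit refinement per fitness evaluation.
    """

    swarm: int = 40
    iterations: int = 200
    inertia: float = 0.7298
    cognitive: float = 1.4962
    social: float = 1.4962
    vmax_frac: float = 0.5
    bounds: tuple[float, float] = (-1.0, 1.0)
    runs: int = 1000
    seed: int = 0
    fit_maxiter: int = 60

    def __post_init__(self) -> None:
        if self.swarm < 2:
            raise ValueError("swarm must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.bounds[1] <= self.bounds[0]:
            raise ValueError("invalid bounds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bounds"] = list(d["bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PsoConfig":
        d = dict(d)
        if "bounds" in d:
            d["bounds"] = tuple(d["bounds"])
        return cls(**d)


@dataclass
class FitResult:
    """Multi-run PSO output.

    ``run_weights`` stacks each run's global-best weight vector (runs x K);
    ``run_fitness`` holds the matching best fitness values.  The reported
    weight estimate is the arithmetic mean over runs; fitness statistics use
    the sample SD.
    """

    run_weights: np.ndarray
    run_fitness: np.ndarray
    config: PsoConfig

    @property
    def weights_mean(self) -> np.ndarray:
        return self.run_weights.mean(axis=0)

    @property
    def fitness_mean(self) -> float:
        return float(self.run_fitness.mean())

    @property
    def fitness_sd(self) -> float:
        return float(self.run_fitness.std(ddof=1)) if len(self.run_fitness) > 1 else 0.0

    @property
    def fitness_min(self) -> float:
        return float(self.run_fitness.min())

    @property
    def fitness_max(self) -> float:
        return float(self.run_fitness.max())

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights_mean": self.weights_mean.tolist(),
                "fitness": {
                    "mean": self.fitness_mean,
                    "sd": self.fitness_sd,
                    "min": self.fitness_min,
                    "max": self.fitness_max,
                },
                "runs": [
                    {"weights": w.tolist(), "fitness": float(f)}
                    for w, f in zip(self.run_weights, self.run_fitness)
                ],
                "config": self.config.to_dict(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        return cls(
            run_weights=np.array([r["weights"] for r in d["runs"]]),
            run_fitness=np.array([r["fitness"] for r in d["runs"]]),
            config=PsoConfig.from_dict(d["config"]),
        )


def _features_matrix(t) -> np.ndarray:
    if isinstance(t, FeatureTable):
        if not t.normalized:
            raise ValueError("feature table must be normalized before fitting")
        return t.values
    x = np.asarray(t, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be an N x K matrix")
    return x


def _pso_single_run(X, y, cfg: PsoConfig, seed: int) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    k = X.shape[1]
    lo, hi = cfg.bounds
    vmax = cfg.vmax_frac * (hi - lo)

    def fit_of(a: np.ndarray) -> float:
        try:
            return fitness_pcc(X @ a, y, maxiter=cfg.fit_maxiter)
        except ValueError:
            return -1.0  # degenerate candidate (e.g. all-zero weights)

    pos = rng.uniform(lo, hi, size=(cfg.swarm, k))
    vel = rng.uniform(-vmax, vmax, size=(cfg.swarm, k))
    fitness = np.array([fit_of(p) for p in pos])
    pbest = pos.copy()
    pbest_fit = fitness.copy()
    g = int(np.argmax(pbest_fit))  # ties -> lowest index
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    for _ in range(cfg.iterations):
        r1 = rng.random((cfg.swarm, k))
        r2 = rng.random((cfg.swarm, k))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - pos)
            + cfg.social * r2 * (gbest - pos)
        )
        np.clip(vel, -vmax, vmax, out=vel)
        pos = np.clip(pos + vel, lo, hi)
        fitness = np.array([fit_of(p) for p in pos])
        improved = fitness > pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fitness[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    # The calibration absorbs any affine map of the score, including sign
    # flips, so A and -A have identical fitness.  Orient each run's best so
    # the raw combined score correlates positively with y; without this the
    # multi-run weight average would cancel across mirrored solutions.
    s = X @ gbest
    if s.std() > 0 and _pcc(s, y) < 0:
        gbest = -gbest
    return gbest, gbest_fit


def pso_optimize(t, y, cfg: PsoConfig | None = None) -> FitResult:
    """Fit the combination weights by multi-run global-best PSO.

    Parameters
    ----------
    t : FeatureTable (normalized) or N x K array with values in [0, 1]
    y : per-image mean scores (array, Series, or mean-scores frame)
    cfg : PsoConfig
        Run r is seeded with ``cfg.seed + r``, so the whole protocol is
        reproducible bit-for-bit from the base seed.
    """
    cfg = cfg or PsoConfig()
    X = _features_matrix(t)
    _, y = _as_xy(X[:, 0], y)
    weights = np.empty((cfg.runs, X.shape[1]))
    fits = np.empty(cfg.runs)
    for r in range(cfg.runs):
        weights[r], fits[r] = _pso_single_run(X, y, cfg, cfg.seed + r)
    return FitResult(run_weights=weights, run_fitness=fits, config=cfg)


@dataclass(frozen=True)
class EvalReport:
    """Correlation of one objective measure against mean subjective scores."""

    name: str
    pcc: float
    n: int
    logistic: LogisticParams


def evaluate(x, y, name: str = "measure", maxiter: int = 120) -> EvalReport:
    """Logistic-calibrated Pearson correlation of any measure against scores.

    Returns the PCC together with the fitted calibration curve, so the
    objective-vs-subjective scatter plot and its monotone fit can be
    regenerated.
    """
    x, y = _as_xy(x, y)
    params = logistic_fit(x, y, maxiter=maxiter)
    fx = params.predict(x)
    if fx.std() <= 0 or y.std() <= 0:
        raise ValueError("degenerate variance in evaluation")
    return EvalReport(
        name=name, pcc=_pcc(fx, y), n=int(x.size), logistic=params
    )
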