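"""3x3 factorial design, quadratic response surfaces, ANOVA/Tukey and
multi-response desirability optimization.

The wall-material design crosses agavin and whey-protein concentrations
over {2.5, 3.75, 5}% (coded -1/0/+1).  Each response is modelled as a
full quadratic in the coded factors,

    y = b0 + bA a + bW w + bAA a^2 + bWW w^2 + bAW a w,

fit by ordinary least squares on the replicate-level data.  Optimization
maximizes the importance-weighted geometric mean of per-response
desirabilities (Derringer-Suich ramps) over the experimental square
[2.5, 5]^2 with a deterministic dense-grid search plus local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LEVELS",
    "DESIGN_TREATMENTS",
    "code_levels",
    "decode_levels",
    "ResponseSurfaceModel",
    "DesirabilityGoal",
    "OptimizationResult",
    "AnovaTukeyResult",
    "fit_quadratic_surface",
    "predict_surface",
    "desirability",
    "default_goals",
    "optimize_composite",
    "anova_tukey",
]

LEVELS = (2.5, 3.75, 5.0)
_CENTER, _HALF = 3.75, 1.25

#: treatment label -> (agavin %, whey protein %), per the study's naming
DESIGN_TREATMENTS = {
    "AWB1": (2.5, 2.5),
    "AWB2": (3.75, 2.5),
    "AWB3": (5.0, 2.5),
    "AWB4": (2.5, 3.75),
    "AWB5": (3.75, 3.75),
    "AWB6": (5.0, 3.75),
    "AWB7": (2.5, 5.0),
    "AWB8": (3.75, 5.0),
    "AWB9": (5.0, 5.0),
}


def code_levels(agavin_pct, whey_pct):
    """Natural (A%, W%) -> coded (a, w); 2.5 -> -1, 3.75 -> 0, 5 -> +1."""
    a = np.asarray(agavin_pct, dtype=float)
    w = np.asarray(whey_pct, dtype=float)
    if np.any(a < LEVELS[0]) or np.any(a > LEVELS[-1]) or np.any(w < LEVELS[0]) or np.any(w > LEVELS[-1]):
        raise ValueError(f"levels must lie within [{LEVELS[0]}, {LEVELS[-1]}]%")
    return (a - _CENTER) / _HALF, (w - _CENTER) / _HALF


def decode_levels(a_coded, w_coded):
    """Coded (a, w) -> natural (A%, W%)."""
    return (
        np.asarray(a_coded, dtype=float) * _HALF + _CENTER,
        np.asarray(w_coded, dtype=float) * _HALF + _CENTER,
    )


_COEF_NAMES = ("b0", "bA", "bW", "bAA", "bWW", "bAW")


def _design_matrix(a: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(a), a, w, a * a, w * w, a * w])


@dataclass
class ResponseSurfaceModel:
    """Quadratic surface over the coded design square."""

    response: str
    coefficients: dict[str, float]
    r2: float
    residual_variance: float

    def predict(self, agavin_pct, whey_pct, allow_extrapolation: bool = False):
        a = np.asarray(agavin_pct, dtype=float)
        w = np.asarray(whey_pct, dtype=float)
        if not allow_extrapolation:
            ac, wc = code_levels(a, w)  # raises outside the design region
        else:
            ac, wc = (a - _CENTER) / _HALF, (w - _CENTER) / _HALF
        b = np.array([self.coefficients[c] for c in _COEF_NAMES])
        return _design_matrix(np.atleast_1d(ac), np.atleast_1d(wc)) @ b


def fit_quadratic_surface(design: pd.DataFrame, response: str) -> ResponseSurfaceModel:
    """OLS fit of the full quadratic to one response of a tidy design table.

    ``design`` needs columns agavin_pct, whey_pct, response, value; at
    least 6 distinct design points must carry data.
    """
    sub = design[design["response"] == response]
    if sub.empty:
        raise ValueError(f"no rows for response {response!r}")
    pts = sub[["agavin_pct", "whey_pct"]].drop_duplicates()
    if len(pts) < 6:
        raise ValueError("need >= 6 distinct design points for a full quadratic")
    a, w = code_levels(sub["agavin_pct"].to_numpy(), sub["whey_pct"].to_numpy())
    X = _design_matrix(a, w)
    y = sub["value"].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 6:
        raise np.linalg.LinAlgError("rank-deficient design")
    pred = X @ coef
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if sst == 0 else float(1.0 - np.sum((y - pred) ** 2) / sst)
    dof = max(len(y) - 6, 1)
    resid_var = float(np.sum((y - pred) ** 2) / dof)
    return ResponseSurfaceModel(response, dict(zip(_COEF_NAMES, map(float, coef))), r2, resid_var)


def predict_surface(model: ResponseSurfaceModel, points, allow_extrapolation: bool = False):
    """Evaluate the surface at (A%, W%) points (sequence of pairs)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return model.predict(pts[:, 0], pts[:, 1], allow_extrapolation=allow_extrapolation)


# ---------------------------------------------------------------------------
# desirability


@dataclass(frozen=True)
class DesirabilityGoal:
    response: str
    goal: Literal["maximize", "minimize"]
    lower: float
    upper: float
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError("lower bound must be < upper bound")
        if self.weight <= 0 or self.importance <= 0:
            raise ValueError("weight and importance must be positive")


def desirability(value, goal: DesirabilityGoal):
    """Derringer-Suich one-sided desirability ramp in [0, 1]."""
    y = np.asarray(value, dtype=float)
    span = goal.upper - goal.lower
    if goal.goal == "maximize":
        ramp = (y - goal.lower) / span
    elif goal.goal == "minimize":
        ramp = (goal.upper - y) / span
    else:
        raise ValueError(f"unknown goal {goal.goal!r}")
    return np.clip(ramp, 0.0, 1.0) ** goal.weight


def default_goals(
    models: Mapping[str, ResponseSurfaceModel],
    directions: Mapping[str, str],
    grid_n: int = 101,
) -> list[DesirabilityGoal]:
    """Goals with L/U set to each surface's min/max over the design region."""
    g = np.linspace(LEVELS[0], LEVELS[-1], grid_n)
    A, W = np.meshgrid(g, g, indexing="ij")
    goals = []
    for name, direction in directions.items():
        pred = models[name].predict(A.ravel(), W.ravel())
        lo, hi = float(pred.min()), float(pred.max())
        if hi - lo < 1e-12:
            hi = lo + 1e-12
        goals.append(DesirabilityGoal(name, direction, lo, hi))
    return goals


@dataclass
class OptimizationResult:
    agavin_pct: float
    whey_pct: float
    predicted: dict[str, float]
    desirabilities: dict[str, float]
    composite: float

    def to_dict(self) -> dict:
        return {
            "agavin_pct": self.agavin_pct,
            "whey_pct": self.whey_pct,
            "predicted": self.predicted,
            "desirabilities": self.desirabilities,
            "composite_desirability": self.composite,
        }


def _composite_at(a_pct, w_pct, models, goals):
    total_imp = sum(g.importance for g in goals)
    logd = 0.0
    for g in goals:
        d = float(desirability(models[g.response].predict(a_pct, w_pct)[0], g))
        if d <= 0.0:
            return 0.0
        logd += g.importance * np.log(d)
    return float(np.exp(logd / total_imp))


def optimize_composite(
    models: Mapping[str, ResponseSurfaceModel],
    goals: Sequence[DesirabilityGoal],
    grid_n: int = 201,
    refine: bool = True,
) -> OptimizationResult:
    """Maximize the importance-weighted geometric mean of desirabilities.

    Deterministic: a ``grid_n`` x ``grid_n`` exhaustive search over the
    design square (ties broken toward lowest agavin %, then lowest
    whey %), optionally refined by Nelder-Mead clipped into the square.
    """
    if not goals:
        raise ValueError("goals must be nonempty")
    for g in goals:
        if g.response not in models:
            raise ValueError(f"goal references unfitted response {g.response!r}")
    g1 = np.linspace(LEVELS[0], LEVELS[-1], grid_n)
    best = (-1.0, None, None)
    for a in g1:  # A ascending outer, W inner -> first max = lowest A, then lowest W
        comp = np.array([_composite_at(a, w, models, goals) for w in g1])
        i = int(np.argmax(comp))
        if comp[i] > best[0]:
            best = (float(comp[i]), float(a), float(g1[i]))
    comp_best, a_best, w_best = best
    if comp_best <= 0.0:
        raise ValueError("composite desirability is zero everywhere on the grid")
    if refine:
        def neg(x):
            a = float(np.clip(x[0], LEVELS[0], LEVELS[-1]))
            w = float(np.clip(x[1], LEVELS[0], LEVELS[-1]))
            return -_composite_at(a, w, models, goals)

        res = optimize.minimize(neg, [a_best, w_best], method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12})
        if -res.fun > comp_best:
            a_best = float(np.clip(res.x[0], LEVELS[0], LEVELS[-1]))
            w_best = float(np.clip(res.x[1], LEVELS[0], LEVELS[-1]))
            comp_best = float(-res.fun)
    predicted = {g.response: float(models[g.response].predict(a_best, w_best)[0]) for g in goals}
    desir = {g.response: float(desirability(predicted[g.response], g)) for g in goals}
    return OptimizationResult(a_best, w_best, predicted, desir, comp_best)


# ---------------------------------------------------------------------------
# ANOVA + Tukey


@dataclass
class AnovaTukeyResult:
    means: dict[str, float]
    f_statistic: float
    p_value: float
    alpha: float
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]  # compact letter display, highest mean = 'a'


def _maximal_cliques(adj: dict[str, set[str]]) -> list[set[str]]:
    # Bron-Kerbosch without pivoting; group counts are tiny
    cliques: list[set[str]] = []

    def bk(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            bk(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bk(set(), set(adj), set())
    return cliques


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD and a compact letter display.

    Letters are assigned deterministically: non-significant cliques are
    ordered by their highest group mean (descending) and lettered
    a, b, c, ...; every group carries the letters of the cliques it
    belongs to.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    f_stat, p_val = stats.f_oneway(*arrays.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * arrays[k].size for k in arrays])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]].rename(columns={"p-adj": "p_adj"})

    means = {k: float(v.mean()) for k, v in arrays.items()}
    adj: dict[str, set[str]] = {k: set() for k in arrays}
    for _, row in pairwise.iterrows():
        if not bool(row["reject"]):
            adj[row["group1"]].add(row["group2"])
            adj[row["group2"]].add(row["group1"])
    cliques = _maximal_cliques(adj)
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters: dict[str, list[str]] = {k: [] for k in arrays}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g].append(letter)
    return AnovaTukeyResult(
        means=means,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        alpha=alpha,
        pairwise=pairwise,
        letters={k: "".join(sorted(v)) for k, v in letters.items()},
    )
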