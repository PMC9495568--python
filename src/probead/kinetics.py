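"""Release-kinetics model fitting and mechanism classification.

Fits the four classical controlled-release models to a fraction-released
time series ``Mt/Minf`` (``f``) sampled during simulated gastrointestinal
digestion:

* zero order          ``f = k t``
* Higuchi             ``f = k sqrt(t)``        (valid for 0.1 < f < 0.6)
* Korsmeyer-Peppas    ``f = k t**n``
* Peppas-Sahlin       ``f = k1 t**m + k2 t**(2m)``

and derives the mechanistic quantities the release literature reads off
them: the Korsmeyer-Peppas exponent category (Fickian / anomalous /
Case II / Super Case II for spheres), the diffusion-vs-relaxation
dominance of the two Peppas-Sahlin terms, the Damkohler number
``Da = growth rate / release rate`` coupling in-bead cell growth to cell
release, and the equilibrium point where the released (medium) and
retained (in-bead) viable-cell concentrations intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ReleaseCurve",
    "GrowthCurve",
    "ModelFit",
    "MechanismCall",
    "DamkohlerResult",
    "InsufficientWindowError",
    "MODEL_ORDER",
    "MODEL_N_PARAMS",
    "predict_model",
    "r_squared",
    "fit_zero_order",
    "fit_higuchi",
    "fit_korsmeyer_peppas",
    "fit_peppas_sahlin",
    "fit_all_models",
    "select_model",
    "classify_kp_exponent",
    "ps_contributions",
    "estimate_rates",
    "damkohler",
    "find_equilibrium_time",
]

#: canonical model order, also the tie-break order in :func:`select_model`
MODEL_ORDER = ("zero_order", "higuchi", "korsmeyer_peppas", "peppas_sahlin")

#: free parameters per model (fixed-m Peppas-Sahlin has two: k1, k2)
MODEL_N_PARAMS = {
    "zero_order": 1,
    "higuchi": 1,
    "korsmeyer_peppas": 2,
    "peppas_sahlin": 2,
}

HIGUCHI_WINDOW = (0.1, 0.6)

#: near-tie tolerance on R-squared; within it the simpler model wins
R2_TIE_TOL = 1e-9


class InsufficientWindowError(ValueError):
    """Raised when a fitting window contains too few usable points."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ReleaseCurve:
    """A sampled release time series with optional paired CFU series.

    Parameters
    ----------
    time_min:
        Sampling times in minutes, strictly increasing, first >= 0.
    fraction_released:
        ``Mt/Minf`` at each time; small noise excursions outside [0, 1]
        are tolerated within [-0.05, 1.05].
    cfu_medium, cfu_inbead:
        Optional viable counts (CFU/mL) released into the medium and
        retained in the bead.
    phase:
        Optional digestion-phase label per sample
        (``oral`` / ``gastric`` / ``intestinal``).
    m_infinity:
        The normalisation total (CFU) used to form ``Mt/Minf``.
    """

    time_min: np.ndarray
    fraction_released: np.ndarray
    cfu_medium: np.ndarray | None = None
    cfu_inbead: np.ndarray | None = None
    phase: np.ndarray | None = None
    m_infinity: float | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fraction_released = np.asarray(self.fraction_released, dtype=float)
        t = self.time_min
        if t.ndim != 1 or t.size == 0:
            raise ValueError("time_min must be a nonempty 1-D array")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_min must be strictly increasing and >= 0")
        for name in ("fraction_released", "cfu_medium", "cfu_inbead", "phase"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                setattr(self, name, v)
                if v.shape != t.shape:
                    raise ValueError(f"{name} length does not match time_min")
        f = self.fraction_released
        if np.any(f < -0.05) or np.any(f > 1.05):
            raise ValueError("fraction_released outside [-0.05, 1.05]")
        if self.m_infinity is not None and self.m_infinity <= 0:
            raise ValueError("m_infinity must be positive")
        if self.m_infinity is None and self.cfu_medium is not None:
            raise ValueError("m_infinity required when CFU series present")

    def __len__(self) -> int:
        return self.time_min.size

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "time_min": self.time_min,
            "fraction_released": self.fraction_released,
        }
        if self.cfu_medium is not None:
            cols["cfu_medium_per_ml"] = self.cfu_medium
        if self.cfu_inbead is not None:
            cols["cfu_inbead_per_ml"] = self.cfu_inbead
        if self.phase is not None:
            cols["phase"] = self.phase
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, m_infinity: float | None = None) -> "ReleaseCurve":
        get = lambda c: df[c].to_numpy() if c in df.columns else None
        return cls(
            time_min=df["time_min"].to_numpy(),
            fraction_released=df["fraction_released"].to_numpy(),
            cfu_medium=get("cfu_medium_per_ml"),
            cfu_inbead=get("cfu_inbead_per_ml"),
            phase=get("phase"),
            m_infinity=m_infinity,
        )

    @classmethod
    def read_csv(cls, path, m_infinity: float | None = None) -> "ReleaseCurve":
        df = pd.read_csv(path)
        if m_infinity is None and "m_infinity" in df.columns:
            m_infinity = float(df["m_infinity"].iloc[0])
        return cls.from_frame(df, m_infinity=m_infinity)


@dataclass
class GrowthCurve:
    """A growth time series; ``time_unit`` tags hours vs minutes."""

    time: np.ndarray
    density: np.ndarray
    time_unit: Literal["min", "h"] = "h"
    density_unit: str = "od"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.density.shape != self.time.shape:
            raise ValueError("density length does not match time")
        if np.any(self.density < 0):
            raise ValueError("densities must be >= 0")

    @property
    def time_min(self) -> np.ndarray:
        return self.time * 60.0 if self.time_unit == "h" else self.time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f"time_{self.time_unit}": self.time, "density": self.density})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GrowthCurve":
        df = pd.read_csv(path)
        unit = "h" if "time_h" in df.columns else "min"
        return cls(df[f"time_{unit}"].to_numpy(), df["density"].to_numpy(), time_unit=unit)


@dataclass
class ModelFit:
    """A fitted release model with its goodness of fit and window."""

    model_id: str
    params: dict[str, float]
    r2: float
    window: np.ndarray  # indices of curve points used
    n_points_used: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return predict_model(self.model_id, self.params, t)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": {k: float(v) for k, v in self.params.items()},
            "r2": float(self.r2),
            "window": [int(i) for i in np.asarray(self.window)],
            "n_points_used": int(self.n_points_used),
        }


@dataclass
class MechanismCall:
    """A mechanism classification with its numeric evidence."""

    scheme: Literal["kp_exponent", "ps_dominance"]
    category: str
    evidence: dict[str, float] = field(default_factory=dict)


@dataclass
class DamkohlerResult:
    """Damkohler number ``Da = growth_rate / release_rate`` with regime flag."""

    growth_rate: float
    release_rate: float
    da: float
    regime: str  # "reaction_governed" | "transport_governed" | "boundary"


# ---------------------------------------------------------------------------
# model evaluation and R^2


def predict_model(model_id: str, params: Mapping[str, float], t) -> np.ndarray:
    """Evaluate a release model at times ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    if model_id == "zero_order":
        return params["k"] * t
    if model_id == "higuchi":
        return params["k"] * np.sqrt(t)
    if model_id == "korsmeyer_peppas":
        pos = t > 0
        return params["k"] * np.where(pos, t, 1.0) ** params["n"] * pos
    if model_id == "peppas_sahlin":
        pos = t > 0
        tm = np.where(pos, t, 1.0) ** params["m"] * pos
        return params["k1"] * tm + params["k2"] * tm * tm
    raise ValueError(f"unknown model_id: {model_id!r}")


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SSE/SST``; may be negative."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("series must have equal length >= 2")
    sst = np.sum((obs - obs.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed series has zero total variance")
    sse = np.sum((obs - pred) ** 2)
    return float(1.0 - sse / sst)


# ---------------------------------------------------------------------------
# fitting


def _window_indices(curve: ReleaseCurve, window) -> np.ndarray:
    n = len(curve)
    if window is None:
        return np.arange(n)
    i0, i1 = window
    idx = np.arange(n)[int(i0):int(i1)]
    if idx.size == 0:
        raise InsufficientWindowError("window selects no points")
    return idx


def fit_zero_order(curve: ReleaseCurve, window=None) -> ModelFit:
    """Least-squares ``f = k t`` through the origin."""
    idx = _window_indices(curve, window)
    t = curve.time_min[idx]
    f = curve.fraction_released[idx]
    if t.size < 2:
        raise InsufficientWindowError("zero-order fit needs >= 2 points")
    tt = float(np.dot(t, t))
    if tt == 0:
        raise ValueError("all times are zero")
    k = float(np.dot(t, f) / tt)
    return ModelFit("zero_order", {"k": k}, r_squared(f, k * t), idx, t.size)


def fit_higuchi(curve: ReleaseCurve, window=None) -> ModelFit:
    """Least-squares ``f = k sqrt(t)`` on points with 0.1 < f < 0.6."""
    idx = _window_indices(curve, window)
    lo, hi = HIGUCHI_WINDOW
    f_all = curve.fraction_released[idx]
    keep = (f_all > lo) & (f_all < hi)
    if keep.sum() < 2:
        raise InsufficientWindowError(
            f"Higuchi fit needs >= 2 points with {lo} < Mt/Minf < {hi}; "
            f"found {int(keep.sum())}"
        )
    idx = idx[keep]
    t = curve.time_min[idx]
    f = curve.fraction_released[idx]
    s = np.sqrt(t)
    k = float(np.dot(s, f) / np.dot(s, s))
    return ModelFit("higuchi", {"k": k}, r_squared(f, k * s), idx, t.size)


def fit_korsmeyer_peppas(
    curve: ReleaseCurve,
    method: Literal["log_linear", "nonlinear"] = "nonlinear",
    window=None,
    max_fraction: float | None = None,
) -> ModelFit:
    """Fit ``f = k t**n``.

    ``log_linear`` regresses ``log f`` on ``log t`` over points with
    ``t > 0`` and ``f > 0``.  ``nonlinear`` refines that estimate by
    least squares on the untransformed points with ``t > 0`` (so the
    reported R-squared is on the natural scale).  ``max_fraction`` turns
    on the customary early-time restriction (e.g. 0.6) — off by default.
    """
    idx0 = _window_indices(curve, window)
    t_all = curve.time_min[idx0]
    f_all = curve.fraction_released[idx0]
    usable = t_all > 0
    if max_fraction is not None:
        usable &= f_all <= max_fraction
    idx = idx0[usable]
    t = t_all[usable]
    f = f_all[usable]
    pos = f > 0
    if (pos & (t > 0)).sum() < 3:
        raise InsufficientWindowError(
            "Korsmeyer-Peppas fit needs >= 3 points with t > 0 and f > 0"
        )
    # log-linear start
    lt, lf = np.log(t[pos]), np.log(f[pos])
    n_hat, logk = np.polyfit(lt, lf, 1)
    k_hat = float(np.exp(logk))
    n_hat = float(n_hat)
    k_hat = max(k_hat, 1e-12)
    n_hat = max(n_hat, 1e-12)
    if method == "log_linear":
        params = {"k": k_hat, "n": n_hat}
    elif method == "nonlinear":
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, k, n: k * tt**n,
                t,
                f,
                p0=(k_hat, n_hat),
                bounds=((1e-12, 1e-12), (np.inf, np.inf)),
                maxfev=10000,
            )
        except RuntimeError as err:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"Korsmeyer-Peppas nonlinear fit did not converge "
                f"(start k={k_hat:.4g}, n={n_hat:.4g}): {err}"
            ) from err
        params = {"k": float(popt[0]), "n": float(popt[1])}
    else:
        raise ValueError(f"unknown method: {method!r}")
    pred = params["k"] * t ** params["n"]
    return ModelFit("korsmeyer_peppas", params, r_squared(f, pred), idx, t.size)


def _ps_linear_solve(t: np.ndarray, f: np.ndarray, m: float):
    tm = t**m
    X = np.column_stack([tm, tm * tm])
    coef, _, rank, _ = np.linalg.lstsq(X, f, rcond=None)
    if rank < 2:
        raise np.linalg.LinAlgError(
            "singular Peppas-Sahlin design (need >= 2 distinct positive times)"
        )
    resid = f - X @ coef
    return coef, float(np.dot(resid, resid))


def fit_peppas_sahlin(
    curve: ReleaseCurve,
    m: float | Literal["free"] = 0.43,
    window=None,
) -> ModelFit:
    """Fit ``f = k1 t**m + k2 t**(2m)``.

    With fixed ``m`` the problem is linear in ``(k1, k2)`` and solved in
    closed form; ``m="free"`` profiles ``m`` over a deterministic grid and
    refines the best cell by bounded scalar minimisation.  Coefficients
    may be negative.
    """
    idx0 = _window_indices(curve, window)
    usable = curve.time_min[idx0] > 0
    idx = idx0[usable]
    t = curve.time_min[idx]
    f = curve.fraction_released[idx]
    free = isinstance(m, str)
    min_pts = 5 if free else 4
    if t.size < min_pts:
        raise InsufficientWindowError(
            f"Peppas-Sahlin fit needs >= {min_pts} points with t > 0"
        )
    if np.unique(t).size < 2:
        raise np.linalg.LinAlgError("singular design: a single distinct positive time")
    if free:
        grid = np.arange(0.05, 1.51, 0.05)
        sse = [_ps_linear_solve(t, f, g)[1] for g in grid]
        i = int(np.argmin(sse))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda g: _ps_linear_solve(t, f, g)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        m_val = float(res.x)
    else:
        m_val = float(m)
    coef, _ = _ps_linear_solve(t, f, m_val)
    params = {"k1": float(coef[0]), "k2": float(coef[1]), "m": m_val}
    pred = predict_model("peppas_sahlin", params, t)
    return ModelFit("peppas_sahlin", params, r_squared(f, pred), idx, t.size)


_FITTERS: dict[str, Callable] = {
    "zero_order": fit_zero_order,
    "higuchi": fit_higuchi,
    "korsmeyer_peppas": fit_korsmeyer_peppas,
    "peppas_sahlin": fit_peppas_sahlin,
}


def fit_all_models(
    curve: ReleaseCurve,
    models: Sequence[str] = MODEL_ORDER,
    ps_m: float | str = 0.43,
    kp_max_fraction: float | None = None,
) -> dict[str, ModelFit]:
    """Fit the requested models; models whose window is unusable are skipped."""
    fits: dict[str, ModelFit] = {}
    for mid in models:
        try:
            if mid == "peppas_sahlin":
                fits[mid] = fit_peppas_sahlin(curve, m=ps_m)
            elif mid == "korsmeyer_peppas":
                fits[mid] = fit_korsmeyer_peppas(curve, max_fraction=kp_max_fraction)
            else:
                fits[mid] = _FITTERS[mid](curve)
        except InsufficientWindowError:
            continue
    if not fits:
        raise InsufficientWindowError("no model could be fitted to this curve")
    return fits


def select_model(fits: Sequence[ModelFit] | Mapping[str, ModelFit]) -> ModelFit:
    """Return the fit with maximal R-squared.

    Near-ties (within ``R2_TIE_TOL``) are broken toward the model with
    fewer free parameters, then by the fixed order of ``MODEL_ORDER``.
    """
    if isinstance(fits, Mapping):
        fits = list(fits.values())
    if not fits:
        raise ValueError("select_model requires a nonempty list of fits")
    best_r2 = max(f.r2 for f in fits)
    tied = [f for f in fits if f.r2 >= best_r2 - R2_TIE_TOL]
    tied.sort(key=lambda f: (MODEL_N_PARAMS[f.model_id], MODEL_ORDER.index(f.model_id)))
    return tied[0]


# ---------------------------------------------------------------------------
# mechanism classification


def classify_kp_exponent(n: float, geometry: str = "sphere") -> MechanismCall:
    """Classify the Korsmeyer-Peppas exponent for spherical particles.

    ``n <= 0.43`` Fickian (Case I); ``0.43 < n < 0.85`` anomalous
    (non-Fickian); ``0.85 <= n <= 1`` Case II; ``n > 1`` Super Case II.
    """
    if geometry != "sphere":
        raise ValueError("only spherical geometry thresholds are implemented")
    if not np.isfinite(n):
        raise ValueError("n must be finite")
    if n <= 0.43:
        cat = "fickian"
    elif n < 0.85:
        cat = "non_fickian"
    elif n <= 1.0:
        cat = "case_II"
    else:
        cat = "super_case_II"
    return MechanismCall("kp_exponent", cat, {"n": float(n)})


def ps_contributions(fit: ModelFit, window: tuple[float, float]) -> MechanismCall:
    """Diffusion-vs-relaxation dominance of a Peppas-Sahlin fit.

    Integrates the absolute diffusion term ``|k1| t**m`` and relaxation
    term ``|k2| t**(2m)`` over the time window (closed form); the larger
    integral names the dominant transport.  The pointwise ratio
    ``R/F = (k2/k1) t**m`` at the window end is reported as evidence.
    """
    if fit.model_id != "peppas_sahlin":
        raise ValueError("ps_contributions requires a peppas_sahlin fit")
    k1, k2, m = fit.params["k1"], fit.params["k2"], fit.params["m"]
    if k1 == 0 and k2 == 0:
        raise ValueError("both coefficients are zero")
    t0, t1 = float(window[0]), float(window[1])
    if not 0 <= t0 < t1:
        raise ValueError("window must satisfy 0 <= t0 < t1")

    def power_integral(p: float) -> float:
        return (t1 ** (p + 1) - t0 ** (p + 1)) / (p + 1)

    diff = abs(k1) * power_integral(m)
    relax = abs(k2) * power_integral(2 * m)
    category = "mainly_diffusion" if diff >= relax else "mainly_relaxation"
    ratio = (k2 / k1) * t1**m if k1 != 0 else np.inf
    return MechanismCall(
        "ps_dominance",
        category,
        {
            "diffusion_integral": float(diff),
            "relaxation_integral": float(relax),
            "rf_ratio_at_end": float(ratio),
        },
    )


# ---------------------------------------------------------------------------
# Damkohler coupling and equilibrium point


def estimate_rates(
    growth: GrowthCurve,
    release: ReleaseCurve,
    window: tuple[float, float],
) -> tuple[float, float]:
    """Per-minute specific growth and first-order release rates.

    Growth rate is the slope of ``ln(density)`` vs time inside the window;
    release rate is the negated slope of ``ln(1 - Mt/Minf)`` — the
    first-order release constant.  Both are returned in 1/min.
    """
    t0, t1 = window
    tg = growth.time_min
    gsel = (tg >= t0) & (tg <= t1)
    if gsel.sum() < 3:
        raise ValueError("growth window contains fewer than 3 points")
    dens = growth.density[gsel]
    if np.any(dens <= 0):
        raise ValueError("nonpositive density inside growth window")
    growth_rate = float(np.polyfit(tg[gsel], np.log(dens), 1)[0])

    tr = release.time_min
    rsel = (tr >= t0) & (tr <= t1)
    if rsel.sum() < 3:
        raise ValueError("release window contains fewer than 3 points")
    f = release.fraction_released[rsel]
    if np.any(f >= 1):
        raise ValueError("release fraction >= 1 inside window; 1 - f not loggable")
    release_rate = float(-np.polyfit(tr[rsel], np.log(1.0 - f), 1)[0])
    return growth_rate, release_rate


def damkohler(growth_rate: float, release_rate: float) -> DamkohlerResult:
    """``Da = growth_rate / release_rate``; Da > 1 means reaction-governed
    (cells are trapped faster than they escape), Da < 1 transport-governed."""
    if release_rate <= 0:
        raise ValueError("release_rate must be positive")
    da = growth_rate / release_rate
    regime = "boundary" if da == 1 else ("reaction_governed" if da > 1 else "transport_governed")
    return DamkohlerResult(float(growth_rate), float(release_rate), float(da), regime)


def find_equilibrium_time(medium, inbead, times) -> float | None:
    """First time where the medium and in-bead series intersect.

    Located by linear interpolation between the bracketing samples; an
    exact equality at a sample returns that sample time; ``None`` if the
    difference never changes sign.
    """
    med = np.asarray(medium, dtype=float)
    inb = np.asarray(inbead, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (med.shape == inb.shape == t.shape):
        raise ValueError("series length mismatch")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    d = med - inb
    for i in range(d.size):
        if d[i] == 0:
            return float(t[i])
        if i + 1 < d.size and d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None
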