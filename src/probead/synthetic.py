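"""Synthetic measurement generator with known ground truth.

The study this package re-analyses deposits no raw data, so every
analysis is exercised against synthetic measurements that emulate its
structure: 15-point release sampling over an oral/gastric/intestinal
digestion, power-law and two-term release profiles with additive noise,
logistic yeast growth, paired medium/in-bead viable-count series whose
noiseless crossing time is known analytically, textured disc "bead"
phantom images with an internal filament network, and 3x3 factorial
response tables drawn from known quadratic surfaces.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize

from .kinetics import GrowthCurve, ReleaseCurve, predict_model
from .viability import DEFAULT_TIMELINE, PhaseTimeline, label_phases

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "KineticTruth",
    "GrowthTruth",
    "BeadPhantomSpec",
    "BeadPhantom",
    "FactorialTruth",
    "DigestionPair",
    "simulate_release_curve",
    "simulate_growth_curve",
    "simulate_digestion_pair",
    "simulate_bead_image",
    "simulate_factorial_experiment",
    "RELAXATION_DOMINANT_PAIR",
    "DIFFUSION_DOMINANT_PAIR",
    "BEAD_SIGN_PATTERNS",
    "DEFAULT_FACTORIAL_TRUTH",
]

#: the study's sampling schedule (minutes)
DEFAULT_TIMEPOINTS = (0, 1, 2, 5, 20, 35, 65, 95, 125, 130, 145, 160, 190, 220, 250)

_REQUIRED_PARAMS = {
    "zero_order": ("k",),
    "higuchi": ("k",),
    "korsmeyer_peppas": ("k", "n"),
    "peppas_sahlin": ("k1", "k2", "m"),
}


@dataclass(frozen=True)
class KineticTruth:
    """Generating release model, parameters and noise level."""

    model_id: str
    params: Mapping[str, float]
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in _REQUIRED_PARAMS:
            raise ValueError(f"unknown model_id: {self.model_id!r}")
        missing = [p for p in _REQUIRED_PARAMS[self.model_id] if p not in self.params]
        if missing:
            raise ValueError(f"{self.model_id} is missing parameters: {missing}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def predict(self, t) -> np.ndarray:
        """Noiseless fraction released, clipped to [0, 1]."""
        return np.clip(predict_model(self.model_id, self.params, t), 0.0, 1.0)


@dataclass(frozen=True)
class GrowthTruth:
    """Logistic growth ground truth.

    Defaults are calibrated so the noiseless curve plateaus near
    O.D. 1.34 by 12 h — the study organism's stationary entry.
    """

    n0: float = 0.05
    capacity: float = 1.34
    mu: float = 0.52  # per hour
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n0) and np.isfinite(self.capacity) and np.isfinite(self.mu)):
            raise ValueError("growth parameters must be finite")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.capacity < self.n0:
            raise ValueError("capacity must be >= n0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    def predict(self, t_hours) -> np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        a = (self.capacity - self.n0) / self.n0
        return self.capacity / (1.0 + a * np.exp(-self.mu * t))


@dataclass(frozen=True)
class BeadPhantomSpec:
    """Geometry/texture parameters of a synthetic bead micrograph."""

    image_size: int = 256
    disc_radius: int = 80
    boundary_roughness: float = 3.0
    network_density: float = 12.0  # expected filament count (Poisson)
    texture_contrast: float = 40.0
    background_level: float = 30.0
    disc_level: float = 130.0
    network_boost: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disc_radius + self.boundary_roughness + 2 > self.image_size / 2:
            raise ValueError("disc (plus roughness margin) does not fit inside image")
        for name in ("background_level", "disc_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} outside [0, 255]")

    @property
    def suggested_threshold(self) -> float:
        """Midpoint threshold separating background from disc interior."""
        return 0.5 * (self.background_level + self.disc_level)


@dataclass
class BeadPhantom:
    """A generated phantom: image plus its ground-truth masks."""

    image: np.ndarray  # uint8
    disc_mask: np.ndarray
    network_mask: np.ndarray
    spec: BeadPhantomSpec


@dataclass(frozen=True)
class FactorialTruth:
    """Quadratic ground-truth surfaces over the 3x3 wall-material design.

    ``coefficients`` maps each response name to coded-unit coefficients
    ``(b0, bA, bW, bAA, bWW, bAW)``; agavin and whey levels are the
    study's {2.5, 3.75, 5}% crossed grid.
    """

    coefficients: Mapping[str, Mapping[str, float]]
    replicate_count: int = 3
    noise_sd: Mapping[str, float] | float = 0.0

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def sd_for(self, response: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(response, 0.0))
        return float(self.noise_sd)

    def surface_value(self, response: str, agavin_pct: float, whey_pct: float) -> float:
        from .doe import code_levels

        a, w = code_levels(agavin_pct, whey_pct)
        b = self.coefficients[response]
        return (
            b["b0"] + b["bA"] * a + b["bW"] * w
            + b["bAA"] * a * a + b["bWW"] * w * w + b["bAW"] * a * w
        )


@dataclass
class DigestionPair:
    """Paired medium/in-bead viable series with analytic crossing truth."""

    curve: ReleaseCurve
    inbead_growth: GrowthCurve  # biological factor sampled at the schedule
    crossing_min: float | None
    noiseless_medium: np.ndarray
    noiseless_inbead: np.ndarray


# ---------------------------------------------------------------------------
# release and growth


def simulate_release_curve(
    truth: KineticTruth,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    timeline: PhaseTimeline = DEFAULT_TIMELINE,
) -> ReleaseCurve:
    """Sample the noiseless model at ``timepoints``, clip to [0, 1], add
    Gaussian noise of sd ``truth.noise_sd`` and clip the result into the
    tolerated band."""
    t = np.asarray(timepoints, dtype=float)
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing with first >= 0")
    clean = truth.predict(t)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        noisy = clean + rng.normal(0.0, truth.noise_sd, size=t.shape)
        noisy = np.clip(noisy, 0.0, 1.0)
    else:
        noisy = clean
    return ReleaseCurve(t, noisy, phase=label_phases(t, timeline))


def simulate_growth_curve(truth: GrowthTruth, timepoints_h: Sequence[float]) -> GrowthCurve:
    """Logistic growth plus Gaussian noise, floored at zero."""
    t = np.asarray(timepoints_h, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    dens = truth.predict(t)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        dens = np.maximum(dens + rng.normal(0.0, truth.noise_sd, size=t.shape), 0.0)
    return GrowthCurve(t, dens, time_unit="h")


# ---------------------------------------------------------------------------
# digestion pair


def _death_integral(death_rate_per_phase: Mapping[str, float], timeline: PhaseTimeline, t: float) -> float:
    total = 0.0
    for p in timeline.phases:
        overlap = max(0.0, min(t, p.end_min) - p.start_min)
        total += death_rate_per_phase[p.name] * overlap
    return total


def simulate_digestion_pair(
    total_cfu: float,
    release_truth: KineticTruth,
    inbead_growth: GrowthTruth | None = None,
    death_rate_per_phase: Mapping[str, float] | None = None,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    timeline: PhaseTimeline = DEFAULT_TIMELINE,
    cfu_noise_log10_sd: float = 0.1,
    seed: int = 0,
) -> DigestionPair:
    """Generate paired medium / in-bead viable-count series.

    Noiseless model: ``medium(t) = total * f(t)`` and
    ``inbead(t) = total * (1 - f(t)) * L(t) * S(t)`` where ``f`` is the
    release fraction, ``L`` the logistic growth multiplier
    ``n(t)/n0`` (no growth: 1) and ``S`` the per-phase first-order
    survival factor ``exp(-integral of the phase death rate)``.  The
    first crossing of the noiseless pair is located by bracketing on a
    0.1-min grid and Brent root refinement, and returned as ground truth
    (``None`` if the curves never meet).  Counts get multiplicative
    log-normal noise (sd in log10 units).
    """
    if total_cfu <= 0:
        raise ValueError("total_cfu must be positive")
    death = dict(death_rate_per_phase or {})
    for p in timeline.phases:
        if p.name not in death:
            raise ValueError(f"death_rate_per_phase is missing phase {p.name!r}")
        if death[p.name] < 0:
            raise ValueError("death rates must be >= 0")
    t = np.asarray(timepoints, dtype=float)

    def medium_clean(tt):
        return total_cfu * release_truth.predict(tt)

    def bio_factor(tt):
        tt = np.asarray(tt, dtype=float)
        L = inbead_growth.predict(tt / 60.0) / inbead_growth.n0 if inbead_growth else np.ones_like(tt)
        S = np.exp(-np.array([_death_integral(death, timeline, x) for x in np.atleast_1d(tt)]))
        return L * S.reshape(np.shape(L))

    def inbead_clean(tt):
        return (total_cfu - medium_clean(tt)) * bio_factor(tt)

    # analytic crossing of the noiseless pair
    grid = np.arange(t[0], t[-1] + 1e-9, 0.1)
    diff = medium_clean(grid) - inbead_clean(grid)
    crossing: float | None = None
    for i in range(diff.size - 1):
        if diff[i] == 0:
            crossing = float(grid[i])
            break
        if diff[i] * diff[i + 1] < 0:
            crossing = float(
                optimize.brentq(
                    lambda x: float(medium_clean(x) - inbead_clean(x)),
                    grid[i],
                    grid[i + 1],
                    xtol=1e-6,
                )
            )
            break
    else:
        if diff[-1] == 0:
            crossing = float(grid[-1])

    rng = np.random.default_rng(seed)
    f_clean = release_truth.predict(t)
    if release_truth.noise_sd > 0:
        f = np.clip(f_clean + rng.normal(0, release_truth.noise_sd, t.shape), 0.0, 1.0)
    else:
        f = f_clean
    med = total_cfu * f
    inb = (total_cfu - med) * bio_factor(t)
    if cfu_noise_log10_sd > 0:
        med = med * 10.0 ** rng.normal(0, cfu_noise_log10_sd, t.shape)
        inb = inb * 10.0 ** rng.normal(0, cfu_noise_log10_sd, t.shape)
    curve = ReleaseCurve(
        t, f, cfu_medium=med, cfu_inbead=inb,
        phase=label_phases(t, timeline), m_infinity=total_cfu,
    )
    growth = GrowthCurve(
        t, total_cfu * bio_factor(t) / 1.0, time_unit="min", density_unit="cfu_scale"
    )
    return DigestionPair(curve, growth, crossing, medium_clean(t), inbead_clean(t))


# ---------------------------------------------------------------------------
# bead phantom images


def simulate_bead_image(spec: BeadPhantomSpec) -> BeadPhantom:
    """One rough-edged bright disc with an internal filament network.

    The network is laid down as persistent random-walk filaments from the
    disc centre (the study's beads show cells depositing along the
    crosslink network, so the phantom's ground truth is filamentous).
    Texture is smoothed multiplicative noise on the disc interior.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - c, xx - c
    r_pix = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    if spec.boundary_roughness > 0:
        modes = np.arange(2, 8)
        amps = rng.normal(0.0, 1.0, modes.size)
        phases = rng.uniform(0, 2 * np.pi, modes.size)
        wobble = np.zeros_like(theta)
        for m, a, p in zip(modes, amps, phases):
            wobble += a * np.cos(m * theta + p)
        wobble *= spec.boundary_roughness / np.sqrt(modes.size)
    else:
        rng.normal(0.0, 1.0, 6)  # keep stream alignment across specs
        rng.uniform(0, 2 * np.pi, 6)
        wobble = 0.0
    disc = r_pix <= spec.disc_radius + wobble

    network = np.zeros((n, n), dtype=bool)
    n_fil = int(rng.poisson(spec.network_density)) if spec.network_density > 0 else 0
    for _ in range(n_fil):
        y, x = c, c
        ang = rng.uniform(0, 2 * np.pi)
        length = int(rng.uniform(0.4, 0.9) * spec.disc_radius)
        for _ in range(length):
            ang += rng.normal(0.0, 0.25)
            y += np.sin(ang)
            x += np.cos(ang)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < n and 0 <= ix < n) or not disc[iy, ix]:
                break
            network[iy, ix] = True

    img = np.full((n, n), spec.background_level, dtype=float)
    interior = np.full((n, n), spec.disc_level, dtype=float)
    if spec.texture_contrast > 0:
        noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=2.0)
        noise /= max(noise.std(), 1e-12)
        interior += 0.5 * spec.texture_contrast * noise
    else:
        ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=2.0)
    img[disc] = interior[disc]
    if network.any():
        fat = ndimage.binary_dilation(network, ndimage.generate_binary_structure(2, 2))
        img[fat & disc] += spec.network_boost
    img = np.clip(img, 0, 255)
    return BeadPhantom(img.astype(np.uint8), disc, network, spec)


# ---------------------------------------------------------------------------
# factorial experiment


def simulate_factorial_experiment(truth: FactorialTruth, seed: int = 0):
    """Tidy factorial dataset: one row per treatment x replicate x response."""
    import pandas as pd

    from .doe import DESIGN_TREATMENTS

    rng = np.random.default_rng(seed)
    rows = []
    for label, (a_pct, w_pct) in DESIGN_TREATMENTS.items():
        for rep in range(1, truth.replicate_count + 1):
            for resp in truth.coefficients:
                mu = truth.surface_value(resp, a_pct, w_pct)
                sd = truth.sd_for(resp)
                val = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append(
                    {
                        "treatment": label,
                        "agavin_pct": a_pct,
                        "whey_pct": w_pct,
                        "replicate": rep,
                        "response": resp,
                        "value": val,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-condition scenario truths

#: Peppas-Sahlin sign patterns spanning the two mechanism groups the
#: analysis distinguishes.  Magnitudes are chosen once so that each
#: noiseless curve is a physical, essentially monotone fraction in
#: [0, 1] over the 250-min schedule (see docs/methods.md); the signs are
#: what the classification consumes.
RELAXATION_DOMINANT_PAIR = {"k1": -0.02, "k2": 0.009, "m": 0.43}  # k1 < 0 < k2
DIFFUSION_DOMINANT_PAIR = {"k1": 0.06, "k2": -0.0015, "m": 0.43}  # k2 < 0 < k1

#: bead type -> generating Peppas-Sahlin pair (two-group split: the
#: controls and the equal-mix bead release by relaxation, the optimized
#: agavin/whey mixes by diffusion)
BEAD_SIGN_PATTERNS = {
    "B": RELAXATION_DOMINANT_PAIR,
    "AB": RELAXATION_DOMINANT_PAIR,
    "WB": RELAXATION_DOMINANT_PAIR,
    "AWB5": RELAXATION_DOMINANT_PAIR,
    "AWB6": DIFFUSION_DOMINANT_PAIR,
    "AWB8": DIFFUSION_DOMINANT_PAIR,
}

#: coded-unit quadratic surfaces emulating the study's morphometric
#: responses: area and perimeter ride on the whey-protein axis,
#: circularity has an interior optimum, solidity a high plateau.
DEFAULT_FACTORIAL_TRUTH = FactorialTruth(
    coefficients={
        "area": {"b0": 5.0, "bA": 0.10, "bW": 0.35, "bAA": -0.05, "bWW": 0.10, "bAW": 0.05},
        "perimeter": {"b0": 9.0, "bA": 0.10, "bW": 0.50, "bAA": 0.02, "bWW": 0.08, "bAW": 0.02},
        "circularity": {"b0": 0.79, "bA": 0.010, "bW": 0.005, "bAA": -0.02, "bWW": -0.02, "bAW": 0.005},
        "solidity": {"b0": 0.985, "bA": 0.004, "bW": 0.002, "bAA": -0.003, "bWW": -0.002, "bAW": 0.001},
    },
    replicate_count=3,
    noise_sd={"area": 0.15, "perimeter": 0.20, "circularity": 0.01, "solidity": 0.003},
)


def write_truth_json(path, truth) -> None:
    """Ground-truth sidecar for a generated dataset."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, Mapping):
            return dict(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=default)
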