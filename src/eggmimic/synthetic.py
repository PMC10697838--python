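"""Synthetic egg images, population score tables and rejection trials.

Real data for this system are museum and field photographs of host
(tawny-flanked prinia) and parasite (cuckoo finch) eggs.  This module
emulates the three inputs every downstream stage needs, with the
statistical structure the study system exhibits:

* **Egg images** — elliptical eggs rendered at 29 px/mm with spot/blotch
  markings of controllable count, size, elongation, orientation
  concentration and spatial clustering; host eggs additionally carry
  pigment 'scribbles' (parasite eggs never do — the diagnostic difference
  between the species).  Every image comes with a ground-truth marking
  list, which makes detector and trait computations testable.
* **Population tables** — per-egg log-complexity drawn from a linear model
  in species and year.  Defaults: hosts ~58% more complex than parasites
  (a gap of ln(1.58) on the log scale), both species drifting upward by
  ~0.5%/yr (slope ln(1.005)) over years coded 0-50, host residual SD
  exceeding parasite residual SD, and period sample sizes of 82 host/34
  parasite (historical) and 332 host/128 parasite (current) eggs.
* **Rejection trials** — pairs of trait vectors (experimental egg, host
  clutch) with a Bernoulli rejection outcome whose log-odds are linear in
  the absolute log-complexity difference under a known ground-truth
  metric.  These drive the metric-weight optimizer.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .images import EggImage, STANDARD_SCALE
from .metric import (
    CURRENT_YEARS,
    N_TRAITS,
    TraitVector,
    MetricWeights,
    YEAR_CODE_ORIGIN,
)

#: Default logistic link (intercept, slope on |Δ log complexity|) for
#: rejection trials; calibrated once so the population-average rejection
#: probability is ~0.4 under the reference metric, keeping both outcome
#: classes common.
DEFAULT_REJECTION_LINK = (-1.7, 5.0)

#: Canonical trait-normalization bounds for the reference metric, spanning
#: the range of the synthetic trait distributions.
_REFERENCE_LO = np.zeros(N_TRAITS)
_REFERENCE_HI = np.array([80.0, 0.7, 1.0, 1.0, 0.2, 0.5])


@dataclass(frozen=True)
class EggPatternParams:
    """Phenotype knobs for one synthetic egg image.

    Lengths are in mm; intensities are fractions in [0, 1].
    ``spatial_clustering`` interpolates between uniform marking placement
    (0) and a strongly clustered parent-offspring point process (1).
    Parasite presets have ``has_scribbles=False``: parasite eggs lack the
    scribbles host eggs always exhibit.
    """

    egg_axes: tuple[float, float] = (18.0, 13.0)  # (major, minor), mm
    background_intensity: float = 0.35
    n_markings: int = 25
    marking_size_mean: float = 0.9  # mm
    marking_size_cv: float = 0.4
    marking_elongation: float = 1.5  # >= 1
    marking_orientation_concentration: float = 0.0  # von Mises kappa
    spatial_clustering: float = 0.0
    has_scribbles: bool = False
    scribble_count: int = 3
    scribble_length: float = 8.0  # mm
    marking_amplitude: float = 0.45
    poisson_markings: bool = False  # draw count ~ Poisson(n_markings)
    min_separation_mm: float = 0.0  # Matern-style thinning of close pairs
    placement_margin: float = 0.92  # markings placed within this ellipse shrink

    def __post_init__(self) -> None:
        major, minor = self.egg_axes
        if major <= 0 or minor <= 0 or major < minor:
            raise ValueError("egg_axes must be positive with major >= minor")
        if not (0.0 <= self.background_intensity <= 1.0):
            raise ValueError("background_intensity must be in [0, 1]")
        if self.n_markings < 0:
            raise ValueError("n_markings must be non-negative")
        if self.marking_size_mean <= 0 or self.marking_size_cv < 0:
            raise ValueError("marking size mean must be positive, CV >= 0")
        if self.marking_elongation < 1.0:
            raise ValueError("marking_elongation must be >= 1")
        if self.marking_orientation_concentration < 0:
            raise ValueError("orientation concentration must be >= 0")
        if not (0.0 <= self.spatial_clustering <= 1.0):
            raise ValueError("spatial_clustering must be in [0, 1]")
        if self.scribble_count < 0 or self.scribble_length <= 0:
            raise ValueError("scribble count >= 0 and length > 0 required")
        if not (0.0 < self.placement_margin <= 1.0):
            raise ValueError("placement_margin must be in (0, 1]")

    @classmethod
    def host_preset(cls, **overrides) -> "EggPatternParams":
        """A host-like egg: many markings, scribbles present."""
        base = cls(n_markings=30, spatial_clustering=0.4, has_scribbles=True)
        return replace(base, **overrides)

    @classmethod
    def parasite_preset(cls, **overrides) -> "EggPatternParams":
        """A parasite-like egg: fewer, blobbier markings, no scribbles."""
        base = cls(
            egg_axes=(17.0, 12.5), n_markings=12, marking_size_mean=1.1,
            marking_elongation=1.2, spatial_clustering=0.1, has_scribbles=False,
        )
        if overrides.get("has_scribbles"):
            raise ValueError("parasite eggs never carry scribbles")
        return replace(base, **overrides)


def _uniform_in_ellipse(rng: np.random.Generator, a: float, b: float,
                        n: int) -> np.ndarray:
    """n points uniform in the ellipse with semi-axes (a, b), centred at 0."""
    r = np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([a * r * np.cos(th), b * r * np.sin(th)])


def _marking_positions(
    rng: np.random.Generator, params: EggPatternParams, n: int
) -> np.ndarray:
    """Marking centres (mm, egg-centre origin) from the interpolated
    parent-offspring process: each marking is cluster-born with probability
    ``spatial_clustering``, else placed uniformly."""
    a = params.placement_margin * params.egg_axes[0] / 2
    b = params.placement_margin * params.egg_axes[1] / 2
    if n == 0:
        return np.empty((0, 2))
    c = params.spatial_clustering
    n_parents = max(1, int(np.ceil(n / 5)))
    parents = _uniform_in_ellipse(rng, 0.7 * a, 0.7 * b, n_parents)
    sigma_c = params.egg_axes[1] / 12.0
    out = np.empty((0, 2))
    attempts = 0
    while len(out) < n and attempts < 200:
        attempts += 1
        todo = n - len(out)
        clustered = rng.random(todo) < c
        pts = _uniform_in_ellipse(rng, a, b, todo)
        if clustered.any():
            idx = rng.integers(0, n_parents, clustered.sum())
            pts[clustered] = parents[idx] + rng.normal(
                scale=sigma_c, size=(clustered.sum(), 2)
            )
        inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 <= 1.0
        pts = pts[inside]
        if params.min_separation_mm > 0:
            for p in pts:
                if len(out) == n:
                    break
                if len(out) == 0 or np.hypot(
                    *(out - p).T
                ).min() >= params.min_separation_mm:
                    out = np.vstack([out, p])
        else:
            out = np.vstack([out, pts])
    return out[:n]


def _stamp_gaussian(
    img: np.ndarray, cx: float, cy: float, sx: float, sy: float,
    theta: float, amplitude: float,
) -> None:
    """Additively stamp a rotated anisotropic Gaussian blob (px units)."""
    rad = int(np.ceil(4 * max(sx, sy)))
    h, w = img.shape
    x0, x1 = max(0, int(cx) - rad), min(w, int(cx) + rad + 1)
    y0, y1 = max(0, int(cy) - rad), min(h, int(cy) + rad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * ((u / sx) ** 2 + (v / sy) ** 2)
    )


def generate_egg_image(
    params: EggPatternParams, seed: int, *, scale: float = STANDARD_SCALE,
    egg_id: str = "synthetic", species: str | None = None,
    year: int | None = None,
) -> tuple[EggImage, pd.DataFrame]:
    """Render one synthetic egg and return it with its ground truth.

    The ground-truth table lists every rendered marking: centre (mm, image
    coordinates), size (mm), orientation (rad) and type ('spot' or
    'scribble').  Identical params + seed give bit-identical images.

    Raises
    ------
    ValueError
        If the egg axes are too small to render at the requested scale.
    """
    rng = np.random.default_rng(seed)
    major, minor = params.egg_axes
    a_px, b_px = major * scale / 2, minor * scale / 2
    if min(a_px, b_px) < 5:
        raise ValueError(
            f"egg axes {params.egg_axes} mm too small to render at "
            f"{scale} px/mm"
        )
    margin = 5
    w = int(np.ceil(major * scale)) + 2 * margin
    h = int(np.ceil(minor * scale)) + 2 * margin
    cx, cy = w / 2.0, h / 2.0

    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0

    img = np.full((h, w), params.background_intensity, dtype=float)

    n = params.n_markings
    if params.poisson_markings:
        n = int(rng.poisson(params.n_markings))
    centres = _marking_positions(rng, params, n)
    n = len(centres)  # thinning may drop close pairs when a separation is set
    sizes = _lognormal(rng, params.marking_size_mean, params.marking_size_cv, n)
    if params.marking_orientation_concentration > 0:
        orientations = np.mod(
            rng.vonmises(0.0, params.marking_orientation_concentration, n),
            2 * np.pi,
        )
    else:
        orientations = rng.uniform(0, 2 * np.pi, n)

    truth_rows = []
    for i in range(n):
        x_mm, y_mm = centres[i]
        sigma_mm = sizes[i] / 2.0
        e = params.marking_elongation
        sx = sigma_mm * np.sqrt(e) * scale
        sy = sigma_mm / np.sqrt(e) * scale
        _stamp_gaussian(
            img, cx + x_mm * scale, cy + y_mm * scale, sx, sy,
            orientations[i], params.marking_amplitude,
        )
        truth_rows.append(
            {
                "x_mm": (cx + x_mm * scale) / scale,
                "y_mm": (cy + y_mm * scale) / scale,
                "size_mm": sizes[i],
                "orientation_rad": orientations[i],
                "type": "spot",
            }
        )

    if params.has_scribbles:
        for _ in range(params.scribble_count):
            path = _scribble_path(rng, params)
            for px, py in path:
                _stamp_gaussian(
                    img, cx + px * scale, cy + py * scale,
                    0.12 * scale, 0.12 * scale, 0.0,
                    0.35 * params.marking_amplitude,
                )
            mean = path.mean(axis=0)
            truth_rows.append(
                {
                    "x_mm": (cx + mean[0] * scale) / scale,
                    "y_mm": (cy + mean[1] * scale) / scale,
                    "size_mm": params.scribble_length,
                    "orientation_rad": 0.0,
                    "type": "scribble",
                }
            )

    img = np.where(mask, np.clip(img, 0.0, 1.0), 0.0)
    truth = pd.DataFrame(
        truth_rows, columns=["x_mm", "y_mm", "size_mm", "orientation_rad", "type"]
    )
    egg = EggImage(
        pixels=img, mask=mask, scale=scale, egg_id=egg_id,
        species=species, year=year,
    )
    return egg, truth


def _lognormal(rng: np.random.Generator, mean: float, cv: float,
               n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def _scribble_path(
    rng: np.random.Generator, params: EggPatternParams, step: float = 0.15
) -> np.ndarray:
    """A smoothed random walk inside the egg, in mm (egg-centre origin)."""
    a = 0.85 * params.egg_axes[0] / 2
    b = 0.85 * params.egg_axes[1] / 2
    start = _uniform_in_ellipse(rng, 0.7 * a, 0.7 * b, 1)[0]
    heading = rng.uniform(0, 2 * np.pi)
    n_steps = max(2, int(params.scribble_length / step))
    pts = [start]
    p = start.copy()
    for _ in range(n_steps - 1):
        heading += rng.normal(scale=0.35)
        q = p + step * np.array([np.cos(heading), np.sin(heading)])
        if (q[0] / a) ** 2 + (q[1] / b) ** 2 > 1.0:
            heading += np.pi  # bounce back toward the interior
            q = p + step * np.array([np.cos(heading), np.sin(heading)])
        p = q
        pts.append(p.copy())
    path = np.array(pts)
    # light smoothing so the walk reads as a drawn line
    kernel = np.array([0.25, 0.5, 0.25])
    for j in (0, 1):
        path[1:-1, j] = np.convolve(path[:, j], kernel, mode="valid")
    return path


@dataclass(frozen=True)
class PopulationConfig:
    """Generating model for population-level complexity tables.

    Log-complexity of an egg from species s in year-code t (years since
    1970) is Normal(intercept_s + slope_s * t, sd_s).  Defaults encode the
    study system: a host-parasite gap of ln(1.58) at fixed year, a shared
    upward drift of ln(1.005) per year, host residual SD well above
    parasite SD, historical sampling concentrated in 1980-1990 and current
    sampling in 2012-2020, with period sample sizes (82, 34) and (332, 128).
    """

    host_intercept: float = -2.0 + np.log(1.58)
    parasite_intercept: float = -2.0
    host_slope: float = np.log(1.005)
    parasite_slope: float = np.log(1.005)
    host_sd: float = 0.35
    parasite_sd: float = 0.18
    n_historical: tuple[int, int] = (82, 34)  # (host, parasite)
    n_current: tuple[int, int] = (332, 128)
    historical_year_range: tuple[int, int] = (1980, 1990)
    current_year_range: tuple[int, int] = CURRENT_YEARS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.host_sd <= 0 or self.parasite_sd <= 0:
            raise ValueError("residual SDs must be positive")
        for lohi in (self.historical_year_range, self.current_year_range):
            if lohi[0] > lohi[1]:
                raise ValueError(f"invalid year range {lohi}")
        if min(*self.n_historical, *self.n_current) < 0:
            raise ValueError("sample sizes must be non-negative")


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a complexity-record table from the configured population model.

    Returns the canonical record table (egg_id, species, year, year_code,
    period, complexity, log_complexity, excluded) with exactly the
    configured per-period, per-species sample sizes.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    spec_params = {
        "host": (config.host_intercept, config.host_slope, config.host_sd),
        "parasite": (
            config.parasite_intercept, config.parasite_slope, config.parasite_sd
        ),
    }
    counter = {"host": 0, "parasite": 0}
    for period, (n_host, n_para), yr_range in (
        ("historical", config.n_historical, config.historical_year_range),
        ("current", config.n_current, config.current_year_range),
    ):
        for species, n in (("host", n_host), ("parasite", n_para)):
            icept, slope, sd = spec_params[species]
            years = rng.integers(yr_range[0], yr_range[1] + 1, n)
            t = years - YEAR_CODE_ORIGIN
            logc = icept + slope * t + rng.normal(scale=sd, size=n)
            ids = [
                f"{species[0]}{counter[species] + i:04d}" for i in range(n)
            ]
            counter[species] += n
            frames.append(
                pd.DataFrame(
                    {
                        "egg_id": ids,
                        "species": species,
                        "year": years,
                        "year_code": t,
                        "period": period,
                        "complexity": np.exp(logc),
                        "log_complexity": logc,
                        "excluded": False,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class RejectionTrial:
    """One egg-rejection experiment: an experimental egg placed in a host
    clutch, and whether the host rejected it."""

    experimental_traits: TraitVector
    host_traits: TraitVector
    rejected: bool


def reference_weights(
    weights: np.ndarray | None = None, epsilon: float = 0.01
) -> MetricWeights:
    """The reference metric over canonical trait bounds; equal weights
    unless given.  Serves as a ground-truth metric for simulations."""
    if weights is None:
        weights = np.full(N_TRAITS, 1.0 / N_TRAITS)
    return MetricWeights(
        lo=_REFERENCE_LO.copy(), hi=_REFERENCE_HI.copy(),
        weights=np.asarray(weights, dtype=float), epsilon=epsilon,
    )


def sample_trait_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Plausible per-egg trait vectors for trial simulation (n x 6)."""
    return np.column_stack(
        [
            rng.poisson(30, n).astype(float),  # T1 feature count
            rng.uniform(0.05, 0.6, n),  # T2 positional variation
            rng.uniform(0.05, 0.8, n),  # T3 scale CV
            rng.uniform(0.0, 1.0, n),  # T4 orientation circular variance
            rng.uniform(0.005, 0.15, n),  # T5 Redies change
            rng.uniform(0.0, 0.4, n),  # T6 clustering score
        ]
    )


def generate_rejection_trials(
    n: int,
    link_params: tuple[float, float] = DEFAULT_REJECTION_LINK,
    weights_truth: MetricWeights | None = None,
    seed: int = 0,
) -> list[RejectionTrial]:
    """Simulate egg-rejection trials under a known ground-truth metric.

    Each trial's rejection indicator is Bernoulli with
    logit(p) = intercept + slope * |Δ log complexity|, where the complexity
    of both the experimental egg and the host clutch is computed under
    ``weights_truth`` (the reference metric by default).

    Raises
    ------
    ValueError
        If n <= 0 or the link slope is not finite.
    """
    from .metric import complexity_score

    if n <= 0:
        raise ValueError("n must be positive")
    intercept, slope = link_params
    if not np.isfinite(slope) or not np.isfinite(intercept):
        raise ValueError("link parameters must be finite")
    if weights_truth is None:
        weights_truth = reference_weights()
    rng = np.random.default_rng(seed)
    exp_mat = sample_trait_matrix(rng, n)
    host_mat = sample_trait_matrix(rng, n)
    d = np.abs(
        np.log(complexity_score(exp_mat, weights_truth))
        - np.log(complexity_score(host_mat, weights_truth))
    )
    p = expit(intercept + slope * d)
    rejected = rng.random(n) < p
    return [
        RejectionTrial(
            experimental_traits=TraitVector(*exp_mat[i]),
            host_traits=TraitVector(*host_mat[i]),
            rejected=bool(rejected[i]),
        )
        for i in range(n)
    ]
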