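"""The six-trait pattern-complexity metric and its logarithmic scale.

Six traits summarize an egg's pattern: the number of local features (T1),
the variation of their positions (T2), scales (T3) and orientations (T4),
the Redies change — mean intensity gradient over the egg (T5) — and a
clustering score combining spatial clustering tendency with within-cluster
descriptor variation (T6).  Complexity is a simplex-weighted linear
combination of min-max normalized traits, floored at a small positive
epsilon so its logarithm always exists.  All downstream statistics work
on log(complexity): hosts perceive relative, not absolute, differences in
complexity (Weber's Law), so the log scale is the perceptually meaningful
one and effect sizes back-transform to percentages via exp.

Metric weights are chosen by maximizing the cross-validated AUC with which
the absolute log-complexity difference between an experimental egg and its
host clutch predicts rejection of that egg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.optimize import minimize
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score, silhouette_score
from sklearn.model_selection import KFold

from .features import FeatureSet
from .images import EggImage

if TYPE_CHECKING:
    from .synthetic import RejectionTrial

N_TRAITS = 6
TRAIT_NAMES = ("T1", "T2", "T3", "T4", "T5", "T6")

#: Positivity floor for the complexity score.
EPSILON = 0.01

#: Period definitions (calendar years, inclusive).
HISTORICAL_YEARS = (1970, 2002)
CURRENT_YEARS = (2012, 2020)
YEAR_CODE_ORIGIN = 1970


@dataclass(frozen=True)
class TraitVector:
    """The six pattern traits of one egg.

    t1 : feature count (non-negative integer).
    t2 : mean pairwise feature distance / egg major-axis length.
    t3 : coefficient of variation of feature scales.
    t4 : circular variance of feature orientations, in [0, 1].
    t5 : Redies change — mean absolute intensity gradient within the mask.
    t6 : clustering score — between-cluster position-variance fraction
         times mean within-cluster descriptor SD.
    """

    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    t6: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("traits must be finite")
        if np.any(arr < 0):
            raise ValueError("traits must be non-negative")
        if self.t4 > 1 + 1e-12:
            raise ValueError("t4 is a circular variance and must be <= 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3, self.t4, self.t5, self.t6])


@dataclass
class MetricWeights:
    """Normalization bounds plus simplex weights defining the metric.

    ``lo``/``hi`` are per-trait min-max bounds fitted on a reference set;
    ``weights`` lie on the unit simplex (non-negative, sum to one); the
    floor ``epsilon`` keeps every score strictly positive so the logarithm
    is defined.  Scores therefore lie in [epsilon, 1].
    """

    lo: np.ndarray
    hi: np.ndarray
    weights: np.ndarray
    epsilon: float = EPSILON
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lo.shape != (N_TRAITS,) or self.hi.shape != (N_TRAITS,):
            raise ValueError("normalization bounds must have one entry per trait")
        if self.weights.shape != (N_TRAITS,):
            raise ValueError("need one weight per trait")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def from_traits(
        cls,
        traits: np.ndarray | Sequence[TraitVector],
        weights: Sequence[float] | None = None,
        epsilon: float = EPSILON,
    ) -> "MetricWeights":
        """Fit min-max bounds on a reference trait matrix; equal weights
        unless given."""
        mat = _trait_matrix(traits)
        if weights is None:
            weights = np.full(N_TRAITS, 1.0 / N_TRAITS)
        return cls(
            lo=mat.min(axis=0), hi=mat.max(axis=0), weights=np.asarray(weights),
            epsilon=epsilon,
        )

    def normalize(self, traits: np.ndarray) -> np.ndarray:
        """Min-max normalize a trait matrix to [0, 1], clipping outside the
        fitted bounds; constant traits map to 0."""
        span = self.hi - self.lo
        safe = np.where(span > 0, span, 1.0)
        u = (np.atleast_2d(traits) - self.lo) / safe
        u = np.where(span > 0, u, 0.0)
        return np.clip(u, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "weights": self.weights.tolist(),
            "epsilon": float(self.epsilon),
            "meta": {
                k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in self.meta.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricWeights":
        return cls(
            lo=np.array(d["lo"]), hi=np.array(d["hi"]),
            weights=np.array(d["weights"]), epsilon=float(d["epsilon"]),
            meta=dict(d.get("meta", {})),
        )


def _trait_matrix(traits: np.ndarray | Sequence[TraitVector]) -> np.ndarray:
    if isinstance(traits, np.ndarray):
        mat = np.atleast_2d(np.asarray(traits, dtype=float))
    else:
        mat = np.array([t.as_array() for t in traits])
    if mat.shape[1] != N_TRAITS:
        raise ValueError(f"expected {N_TRAITS} traits per row, got {mat.shape[1]}")
    return mat


def compute_traits(features: FeatureSet, egg: EggImage) -> TraitVector:
    """Compute the six pattern traits of one egg.

    With at most one feature the feature-statistics traits (T2, T3, T4, T6)
    are zero by definition; T5 is a pixel statistic and is always computed.

    Raises
    ------
    ValueError
        If the feature set and image belong to different eggs.
    """
    if features.egg_id and egg.egg_id and features.egg_id != egg.egg_id:
        raise ValueError(
            f"feature set is for egg {features.egg_id!r} but image is "
            f"{egg.egg_id!r}"
        )
    n = len(features)
    t5 = _redies_change(egg)
    if n <= 1:
        return TraitVector(float(n), 0.0, 0.0, 0.0, t5, 0.0)

    pos = features.positions()
    t2 = _mean_pairwise_distance(pos) / egg.major_axis_mm()

    scales = features.scales()
    mean_scale = scales.mean()
    t3 = float(scales.std(ddof=1) / mean_scale) if mean_scale > 0 else 0.0

    t4 = _circular_variance(features.orientations())
    t6 = clustering_score(pos, features.descriptors())
    return TraitVector(float(n), float(t2), t3, float(t4), t5, float(t6))


def _mean_pairwise_distance(pos: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(pos).mean())


def _circular_variance(angles: np.ndarray) -> float:
    """1 - mean resultant length: 0 for identical angles, -> 1 for a
    uniform sample on the circle."""
    r = np.hypot(np.cos(angles).mean(), np.sin(angles).mean())
    return float(np.clip(1.0 - r, 0.0, 1.0))


def _redies_change(egg: EggImage, erosion_px: int = 2) -> float:
    """Mean absolute intensity gradient over the mask interior.

    The mask is eroded slightly so the artificial step at the egg boundary
    does not contribute.
    """
    interior = binary_erosion(egg.mask, iterations=erosion_px)
    if not interior.any():
        interior = egg.mask
    gy, gx = np.gradient(egg.pixels)
    grad = np.hypot(gx, gy)
    return float(grad[interior].mean())


def clustering_score(
    positions: np.ndarray,
    descriptors: np.ndarray,
    k_range: Iterable[int] = range(2, 9),
    random_state: int = 0,
) -> float:
    """T6: silhouette-selected k-means on feature positions.

    The clustering-tendency factor is the best silhouette width over
    k-means partitions with k in ``k_range`` (clipped at 0: a silhouette
    near or below zero means no spatial clustering structure).  It is
    multiplied by the mean within-cluster descriptor SD, so the score is
    large when features form distinct spatial clusters whose members are
    nevertheless heterogeneous.  When no multi-cluster partition is
    admissible (fewer than 4 features, or degenerate positions) the
    tendency factor is 0, hence T6 = 0.
    """
    n = len(positions)
    if n < 4 or np.allclose(positions, positions[0]):
        return 0.0
    best_sil, best_labels = -np.inf, None
    for k in k_range:
        if k >= n:
            break
        km = KMeans(n_clusters=k, n_init=4, random_state=random_state)
        labels = km.fit_predict(positions)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(positions, labels)
        if sil > best_sil:
            best_sil, best_labels = sil, labels
    if best_labels is None or best_sil <= 0:
        return 0.0
    within_sds = []
    for c in np.unique(best_labels):
        d = descriptors[best_labels == c]
        within_sds.append(float(d.std(axis=0, ddof=0).mean()) if len(d) > 1 else 0.0)
    return float(best_sil) * float(np.mean(within_sds))


def complexity_score(
    traits: TraitVector | np.ndarray, weights: MetricWeights
) -> float | np.ndarray:
    """Score = sum_i w_i * u_i of normalized traits, floored at epsilon.

    Accepts a single :class:`TraitVector` (returns a float) or an (n, 6)
    trait matrix (returns an array).  Scores lie in [epsilon, 1].
    """
    single = isinstance(traits, TraitVector)
    mat = _trait_matrix([traits] if single else traits)
    u = weights.normalize(mat)
    s = np.maximum(u @ weights.weights, weights.epsilon)
    return float(s[0]) if single else s


def optimize_weights(
    trials: Sequence["RejectionTrial"],
    *,
    n_folds: int = 5,
    n_restarts: int = 10,
    seed: int = 0,
    epsilon: float = EPSILON,
) -> MetricWeights:
    """Choose metric weights that best predict egg rejection.

    Maximizes the cross-validated AUC of ``rejected ~ |Δ log complexity|``
    over simplex-constrained weights, where Δ is between the experimental
    egg and its host clutch.  The simplex is parameterized by a softmax and
    searched with multi-start Nelder-Mead under a fixed seed, so the result
    is deterministic for a given trial set.

    Raises
    ------
    ValueError
        If fewer than 50 trials are supplied or only one outcome class is
        present.
    """
    if len(trials) < 50:
        raise ValueError(f"need at least 50 trials, got {len(trials)}")
    exp_mat = np.array([t.experimental_traits.as_array() for t in trials])
    host_mat = np.array([t.host_traits.as_array() for t in trials])
    y = np.array([t.rejected for t in trials], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("trials contain a single outcome class; cannot optimize")

    both = np.vstack([exp_mat, host_mat])
    lo, hi = both.min(axis=0), both.max(axis=0)
    base = MetricWeights(lo=lo, hi=hi, weights=np.full(N_TRAITS, 1 / N_TRAITS),
                         epsilon=epsilon)
    folds = list(
        KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(y)
    )

    def cv_auc(theta: np.ndarray) -> float:
        w = _softmax(theta)
        mw = MetricWeights(lo=lo, hi=hi, weights=w, epsilon=epsilon)
        d = np.abs(
            np.log(complexity_score(exp_mat, mw))
            - np.log(complexity_score(host_mat, mw))
        )
        aucs = []
        for _, test_idx in folds:
            if len(np.unique(y[test_idx])) < 2:
                continue
            aucs.append(roc_auc_score(y[test_idx], d[test_idx]))
        return float(np.mean(aucs)) if aucs else 0.5

    rng = np.random.default_rng(seed)
    starts = [np.zeros(N_TRAITS)] + [
        rng.normal(scale=1.5, size=N_TRAITS) for _ in range(n_restarts - 1)
    ]
    best_theta, best_auc = None, -np.inf
    for theta0 in starts:
        res = minimize(
            lambda th: -cv_auc(th), theta0, method="Nelder-Mead",
            options={"maxiter": 500, "xatol": 1e-3, "fatol": 1e-4},
        )
        auc = -res.fun
        if auc > best_auc:
            best_auc, best_theta = auc, res.x

    return MetricWeights(
        lo=lo, hi=hi, weights=_softmax(best_theta), epsilon=epsilon,
        meta={"cv_auc": best_auc, "n_trials": len(trials), "seed": seed,
              "n_folds": n_folds, "n_restarts": n_restarts},
    )


def _softmax(theta: np.ndarray) -> np.ndarray:
    z = np.exp(theta - theta.max())
    return z / z.sum()


def classify_period(year: int) -> str:
    """Map a calendar year to its study period.

    1970-2002 is 'historical', 2012-2020 'current'; 2003-2011 is 'excluded'
    (images from those years are not comparable to the rest).  Years
    outside 1970-2020 raise.
    """
    if HISTORICAL_YEARS[0] <= year <= HISTORICAL_YEARS[1]:
        return "historical"
    if CURRENT_YEARS[0] <= year <= CURRENT_YEARS[1]:
        return "current"
    if HISTORICAL_YEARS[1] < year < CURRENT_YEARS[0]:
        return "excluded"
    raise ValueError(f"year {year} outside the study range 1970-2020")


def to_records(
    scores: Sequence[float] | np.ndarray, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Attach study metadata to complexity scores.

    ``metadata`` must carry ``egg_id``, ``species`` and ``year`` columns,
    one row per score.  Returns the canonical record table with columns
    egg_id, species, year, year_code, period, complexity, log_complexity,
    excluded.  Years in the 2003-2011 gap are kept but flagged excluded.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores <= 0):
        raise ValueError("complexity scores must be positive")
    if len(scores) != len(metadata):
        raise ValueError("one metadata row per score required")
    years = metadata["year"].astype(int)
    periods = [classify_period(y) for y in years]
    return pd.DataFrame(
        {
            "egg_id": metadata["egg_id"].to_numpy(),
            "species": metadata["species"].to_numpy(),
            "year": years.to_numpy(),
            "year_code": years.to_numpy() - YEAR_CODE_ORIGIN,
            "period": periods,
            "complexity": scores,
            "log_complexity": np.log(scores),
            "excluded": [p == "excluded" for p in periods],
        }
    )
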