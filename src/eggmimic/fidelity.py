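"""Mimetic-fidelity statistics: all-pairs complexity differences and
single-predictor discriminant performance, per period and over time.

Two complementary views of how well parasite eggs mimic host eggs:

1. **All-pairs differences.**  Every (host, parasite) pair within a period
   contributes |Δ log complexity|; the period's fidelity is the mean of
   these (smaller = better mimicry).  Pairing every host with every
   parasite is justified because parasites lay at random with respect to
   host egg phenotype.  Since the pair count (e.g. 42,496 for 460 eggs)
   vastly exceeds the underlying degrees of freedom, uncertainty comes
   from a two-sample bootstrap: eggs — not pairs — are resampled with
   replacement within each species, and the 95% CI is mean ± 2 bootstrap
   s.e.m.  The change between periods is expressed as a percentage,
   (exp(mean_hist - mean_curr) - 1) * 100, positive when differences
   shrank, i.e. when fidelity improved.

2. **Discriminant performance.**  A discriminant analysis with
   log(complexity) as the only predictor and equal priors: good
   classification means hosts and parasites are distinguishable, i.e. low
   fidelity.  With one predictor this is the pooled-variance linear rule
   with its threshold at the midpoint of the class means.  Because
   discriminant performance grows with sample size, current eggs are
   subsampled (without replacement) to the historical sample sizes before
   each fit, over many iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trend import percent_change


def _period_values(records: pd.DataFrame, period: str) -> tuple[np.ndarray, np.ndarray]:
    sub = records
    if "excluded" in sub.columns:
        sub = sub[~sub["excluded"].astype(bool)]
    sub = sub[sub["period"] == period]
    host = sub.loc[sub["species"] == "host", "log_complexity"].to_numpy(float)
    para = sub.loc[sub["species"] == "parasite", "log_complexity"].to_numpy(float)
    if len(host) == 0 or len(para) == 0:
        raise ValueError(f"period {period!r} must contain both species")
    return host, para


def enumerate_pairs(records: pd.DataFrame, period: str) -> np.ndarray:
    """|Δ log complexity| for every (host, parasite) pair in a period.

    Returns one value per ordered pair, so the length is
    n_host × n_parasite.
    """
    host, para = _period_values(records, period)
    return np.abs(host[:, None] - para[None, :]).ravel()


def _all_pairs_mean(host: np.ndarray, para: np.ndarray) -> float:
    return float(np.abs(host[:, None] - para[None, :]).mean())


@dataclass
class FidelityResult:
    """All-pairs fidelity summary for one period.

    ``mean_absdiff`` is the mean |Δ log complexity| over all host-parasite
    pairs; the CI is mean ± 2 × bootstrap s.e.m. (symmetric by
    construction).
    """

    period: str
    n_host: int
    n_parasite: int
    mean_absdiff: float
    sem: float
    n_replicates: int
    replicate_means: np.ndarray = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return self.n_host * self.n_parasite

    @property
    def ci(self) -> tuple[float, float]:
        return (self.mean_absdiff - 2 * self.sem, self.mean_absdiff + 2 * self.sem)


def bootstrap_fidelity(
    records: pd.DataFrame, period: str, B: int = 500, seed: int = 0
) -> FidelityResult:
    """Two-sample bootstrap of the all-pairs mean |Δ log complexity|.

    Eggs (not pairs) are resampled with replacement independently within
    each species; the all-pairs mean is recomputed per replicate; the
    s.e.m. is the SD of replicate means.
    """
    if B < 100:
        warnings.warn(f"B={B} replicates is low for a stable s.e.m.", stacklevel=2)
    host, para = _period_values(records, period)
    point = _all_pairs_mean(host, para)
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        hb = host[rng.integers(0, len(host), len(host))]
        pb = para[rng.integers(0, len(para), len(para))]
        reps[b] = _all_pairs_mean(hb, pb)
    return FidelityResult(
        period=period,
        n_host=len(host),
        n_parasite=len(para),
        mean_absdiff=point,
        sem=float(reps.std(ddof=1)),
        n_replicates=B,
        replicate_means=reps,
    )


@dataclass
class FidelityChange:
    """Change in all-pairs fidelity between periods, as a percentage.

    Positive = differences shrank = mimetic fidelity improved.
    """

    percent_increase: float
    ci: tuple[float, float]
    n_replicates: int


def fidelity_change(
    historical: FidelityResult, current: FidelityResult
) -> FidelityChange:
    """Percentage increase in fidelity between two periods.

    The point estimate is (exp(mean_hist - mean_curr) - 1) * 100 — a
    decrease in the mean log-complexity difference is an increase in
    fidelity.  The CI comes from applying the same transform to paired
    bootstrap replicates of the two periods, so both periods' resampling
    noise enters.

    Raises
    ------
    ValueError
        If the two results carry different replicate counts.
    """
    if historical.n_replicates != current.n_replicates:
        raise ValueError("periods must be bootstrapped with equal replicate counts")
    point = percent_change(historical.mean_absdiff - current.mean_absdiff)
    reps = percent_change(historical.replicate_means - current.replicate_means)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return FidelityChange(
        percent_increase=float(point),
        ci=(float(lo), float(hi)),
        n_replicates=historical.n_replicates,
    )


@dataclass
class DiscriminantRule:
    """Equal-prior, pooled-variance linear discriminant on one predictor.

    The decision threshold sits at the midpoint of the class means;
    ``proportion_correct`` is the in-sample fraction of all eggs assigned
    to their true species.
    """

    mean_host: float
    mean_parasite: float
    pooled_sd: float
    threshold: float
    proportion_correct: float

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Assign 'host'/'parasite' labels to log-complexity values."""
        values = np.asarray(values, dtype=float)
        host_side = values >= self.threshold
        if self.mean_host < self.mean_parasite:
            host_side = ~host_side
        return np.where(host_side, "host", "parasite")


def fit_discriminant(
    log_values: np.ndarray, labels: np.ndarray
) -> DiscriminantRule:
    """Fit the 1-D equal-prior discriminant of species on log(complexity).

    With a single predictor and equal priors the flexible/linear
    discriminant reduces to thresholding at the midpoint of the class
    means (pooled-variance Gaussian classes).

    Raises
    ------
    ValueError
        If either class has fewer than 2 values.
    """
    log_values = np.asarray(log_values, dtype=float)
    labels = np.asarray(labels)
    host = log_values[labels == "host"]
    para = log_values[labels == "parasite"]
    if len(host) < 2 or len(para) < 2:
        raise ValueError("each class needs at least 2 values")
    mh, mp = host.mean(), para.mean()
    pooled_var = (
        (len(host) - 1) * host.var(ddof=1) + (len(para) - 1) * para.var(ddof=1)
    ) / (len(host) + len(para) - 2)
    rule = DiscriminantRule(
        mean_host=float(mh),
        mean_parasite=float(mp),
        pooled_sd=float(np.sqrt(pooled_var)),
        threshold=float((mh + mp) / 2),
        proportion_correct=np.nan,
    )
    correct = rule.predict(log_values) == labels
    rule.proportion_correct = float(correct.mean())
    return rule


@dataclass
class DiscriminantResult:
    """Resampled discriminant performance for one period."""

    period: str
    proportions: np.ndarray = field(repr=False)
    subsample_sizes: tuple[int, int] = (0, 0)  # (host, parasite)

    @property
    def mean_correct(self) -> float:
        return float(self.proportions.mean())

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.proportions, [2.5, 97.5])
        return (float(lo), float(hi))

    @property
    def iterations(self) -> int:
        return len(self.proportions)


def resampled_fda(
    records: pd.DataFrame,
    period: str = "current",
    sizes: tuple[int, int] = (82, 34),
    iterations: int = 1000,
    seed: int = 0,
    replace: bool | None = None,
) -> DiscriminantResult:
    """Discriminant performance under repeated resampling to fixed sizes.

    Per iteration, ``sizes`` = (host, parasite) eggs are drawn from the
    period and the discriminant refit; the correct-assignment proportions
    over iterations give the mean and 2.5/97.5-percentile CI.  Current
    eggs are subsampled *without* replacement to the historical sizes so
    both periods' discriminants see equally sized samples.  When the
    target sizes equal the period's actual sizes (as for the historical
    period itself), subsampling without replacement would be a no-op, so
    resampling switches to with-replacement (an ordinary bootstrap);
    ``replace`` overrides this choice.

    Raises
    ------
    ValueError
        If the period holds fewer eggs than requested.
    """
    host, para = _period_values(records, period)
    n_h, n_p = sizes
    if len(host) < n_h or len(para) < n_p:
        raise ValueError(
            f"period {period!r} has ({len(host)}, {len(para)}) eggs; "
            f"cannot draw ({n_h}, {n_p})"
        )
    if replace is None:
        replace = len(host) == n_h and len(para) == n_p
    rng = np.random.default_rng(seed)
    labels = np.array(["host"] * n_h + ["parasite"] * n_p)
    props = np.empty(iterations)
    for i in range(iterations):
        hs = rng.choice(host, size=n_h, replace=replace)
        ps = rng.choice(para, size=n_p, replace=replace)
        rule = fit_discriminant(np.concatenate([hs, ps]), labels)
        props[i] = rule.proportion_correct
    return DiscriminantResult(
        period=period, proportions=props, subsample_sizes=(n_h, n_p)
    )


class MimeticFidelity:
    """Model object bundling both fidelity analyses over a record table.

    Parameters
    ----------
    records : DataFrame
        Canonical complexity-record table covering both periods.
    pair_replicates, fda_iterations : int
        Bootstrap replicates for the all-pairs statistic and iterations
        for the resampled discriminant.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        pair_replicates: int = 500,
        fda_iterations: int = 1000,
    ) -> None:
        self.records = records
        self.pair_replicates = pair_replicates
        self.fda_iterations = fda_iterations

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MimeticFidelity":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, seed: int = 0) -> "FidelityResults":
        """Run both analyses; sub-stage seeds derive from ``seed``."""
        ss = np.random.SeedSequence(seed)
        s_hist, s_curr, s_fda_h, s_fda_c = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
        ]
        hist = bootstrap_fidelity(
            self.records, "historical", B=self.pair_replicates, seed=s_hist
        )
        curr = bootstrap_fidelity(
            self.records, "current", B=self.pair_replicates, seed=s_curr
        )
        change = fidelity_change(hist, curr)
        hist_sizes = (hist.n_host, hist.n_parasite)
        fda_hist = resampled_fda(
            self.records, "historical", sizes=hist_sizes,
            iterations=self.fda_iterations, seed=s_fda_h,
        )
        fda_curr = resampled_fda(
            self.records, "current", sizes=hist_sizes,
            iterations=self.fda_iterations, seed=s_fda_c,
        )
        return FidelityResults(self, hist, curr, change, fda_hist, fda_curr)


class FidelityResults:
    """Results of both fidelity analyses, with tidy-table exports."""

    def __init__(
        self,
        model: MimeticFidelity,
        historical: FidelityResult,
        current: FidelityResult,
        change: FidelityChange,
        fda_historical: DiscriminantResult,
        fda_current: DiscriminantResult,
    ) -> None:
        self.model = model
        self.historical = historical
        self.current = current
        self.change = change
        self.fda_historical = fda_historical
        self.fda_current = fda_current

    @property
    def fda_change_percent(self) -> tuple[float, tuple[float, float]]:
        """Change in fidelity by the discriminant measure, in percentage
        points (historical minus current correct-assignment), with a CI
        from paired iteration differences."""
        diff = (
            self.fda_historical.proportions - self.fda_current.proportions
        ) * 100.0
        lo, hi = np.percentile(diff, [2.5, 97.5])
        return float(diff.mean()), (float(lo), float(hi))

    def pairs_table(self) -> pd.DataFrame:
        rows = []
        for r in (self.historical, self.current):
            lo, hi = r.ci
            rows.append(
                {
                    "period": r.period,
                    "n_host": r.n_host,
                    "n_parasite": r.n_parasite,
                    "n_pairs": r.n_pairs,
                    "mean_absdiff_log": r.mean_absdiff,
                    "sem": r.sem,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "replicates": r.n_replicates,
                }
            )
        return pd.DataFrame(rows)

    def fda_table(self) -> pd.DataFrame:
        rows = []
        for r in (self.fda_historical, self.fda_current):
            lo, hi = r.ci
            rows.append(
                {
                    "period": r.period,
                    "mean_correct": r.mean_correct,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "iterations": r.iterations,
                    "n_host_sub": r.subsample_sizes[0],
                    "n_parasite_sub": r.subsample_sizes[1],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        h, c = self.historical, self.current
        fda_chg, fda_ci = self.fda_change_percent
        lines = [
            "Mimetic fidelity",
            f"  historical: mean |dlog| = {h.mean_absdiff:.3f} "
            f"(95% CI {h.ci[0]:.3f}-{h.ci[1]:.3f}; "
            f"{h.n_pairs} pairs from {h.n_host}+{h.n_parasite} eggs)",
            f"  current:    mean |dlog| = {c.mean_absdiff:.3f} "
            f"(95% CI {c.ci[0]:.3f}-{c.ci[1]:.3f}; "
            f"{c.n_pairs} pairs from {c.n_host}+{c.n_parasite} eggs)",
            f"  fidelity increase = {self.change.percent_increase:.1f}% "
            f"(95% CI {self.change.ci[0]:.1f}-{self.change.ci[1]:.1f}%)",
            f"  FDA correct: historical {self.fda_historical.mean_correct:.1%}"
            f" (CI {self.fda_historical.ci[0]:.1%}-"
            f"{self.fda_historical.ci[1]:.1%}), "
            f"current {self.fda_current.mean_correct:.1%}"
            f" (CI {self.fda_current.ci[0]:.1%}-{self.fda_current.ci[1]:.1%})",
            f"  FDA fidelity change = {fda_chg:.1f} points "
            f"(95% CI {fda_ci[0]:.1f}-{fda_ci[1]:.1f})",
        ]
        return "\n".join(lines)
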