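"""Temporal-trend models for egg-pattern complexity.

The core model is an ordinary least squares fit of log-complexity on
species, time and their interaction::

    log_complexity ~ species + year + species:year

with species coded host = 1, parasite = 0 (so a positive species effect
means host eggs are more complex) and year coded 0 (1970) to 50 (2020).
A categorical variant replaces continuous year with a historical/current
period indicator.  Because hosts exhibit much higher residual variance
than parasites, the authoritative uncertainty comes from a stratified
case-resampling bootstrap (eggs resampled with replacement within species,
model refit per replicate, percentile intervals); OLS t-based inference is
reported alongside for reference.

Coefficients live on the natural-log scale; the percentage transform
``(exp(b) - 1) * 100`` gives the per-unit percentage change in complexity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

TERMS_YEAR = ("Intercept", "species", "year", "species:year")
TERMS_PERIOD = ("Intercept", "species", "period", "species:period")


def percent_change(coefficient: float | np.ndarray) -> float | np.ndarray:
    """Back-transform a log-scale coefficient to a percentage change:
    (exp(b) - 1) * 100."""
    return (np.exp(coefficient) - 1.0) * 100.0


class ComplexityTrend:
    """OLS model of log-complexity on species, time and their interaction.

    Parameters
    ----------
    records : DataFrame
        Canonical complexity-record table with columns ``species``
        ('host'/'parasite'), ``year_code`` (or ``period``) and
        ``log_complexity``.  Rows flagged ``excluded`` are dropped.
    variant : {'year', 'period'}
        Continuous year-code predictor, or categorical period
        (historical = 0, current = 1).
    """

    def __init__(self, records: pd.DataFrame, variant: str = "year") -> None:
        if variant not in ("year", "period"):
            raise ValueError(f"unknown variant {variant!r}")
        records = records.copy()
        if "excluded" in records.columns:
            records = records[~records["excluded"].astype(bool)]
        species = records["species"].to_numpy()
        if set(np.unique(species)) != {"host", "parasite"}:
            raise ValueError("both species (host, parasite) must be present")
        if len(records) < 5:
            raise ValueError("need at least 5 records")
        y = records["log_complexity"].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("constant response: nothing to fit")
        s = (species == "host").astype(float)
        if variant == "year":
            x = records["year_code"].to_numpy(dtype=float)
            self.terms = TERMS_YEAR
        else:
            per = records["period"].to_numpy()
            if not set(np.unique(per)) <= {"historical", "current"}:
                raise ValueError("period variant needs historical/current labels")
            x = (per == "current").astype(float)
            self.terms = TERMS_PERIOD
        self.variant = variant
        self.records = records.reset_index(drop=True)
        self.endog = y
        self.exog = np.column_stack([np.ones_like(y), s, x, s * x])
        self._species_ind = s

    @classmethod
    def from_csv(cls, path, variant: str = "year") -> "ComplexityTrend":
        return cls(pd.read_csv(path), variant=variant)

    def fit(self) -> "TrendResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return TrendResults(self, res)


@dataclass
class BootstrapCI:
    """Percentile bootstrap intervals for the trend coefficients."""

    terms: tuple[str, ...]
    estimate: np.ndarray  # point estimates (log scale)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_replicates: int
    replicates: np.ndarray  # (B, 4) replicate coefficient draws

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate_log": self.estimate,
                "ci_lo_log": self.ci_lower,
                "ci_hi_log": self.ci_upper,
                "percent": percent_change(self.estimate),
                "ci_lo_percent": percent_change(self.ci_lower),
                "ci_hi_percent": percent_change(self.ci_upper),
                "replicates": self.n_replicates,
            }
        )


class TrendResults:
    """Fitted trend model: coefficients, uncertainty and transforms.

    Wraps the OLS results; ``params``, ``bse``, ``tvalues``, ``pvalues``
    and ``df_resid`` follow statsmodels conventions (df_resid = n - 4).
    ``percent`` back-transforms each coefficient to a percentage change.
    """

    def __init__(self, model: ComplexityTrend, ols_results) -> None:
        self.model = model
        self._ols = ols_results
        self.terms = model.terms
        self.params = pd.Series(ols_results.params, index=model.terms)
        self.bse = pd.Series(ols_results.bse, index=model.terms)
        self.tvalues = pd.Series(ols_results.tvalues, index=model.terms)
        self.pvalues = pd.Series(ols_results.pvalues, index=model.terms)
        self.df_resid = int(ols_results.df_resid)
        self.nobs = int(ols_results.nobs)

    @property
    def percent(self) -> pd.Series:
        """Percentage-change transform of each non-intercept coefficient."""
        return pd.Series(
            percent_change(self.params.to_numpy()), index=self.terms
        )[list(self.terms[1:])]

    def bootstrap(self, B: int = 1000, seed: int = 0) -> BootstrapCI:
        """Stratified case-resampling bootstrap of the coefficients.

        Eggs are resampled with replacement within species (preserving the
        two species' sample sizes, the relevant design feature under
        heteroscedasticity); the model is refit per replicate and 95%
        percentile intervals are returned.  Stratification guarantees both
        species appear in every replicate.
        """
        if B < 100:
            warnings.warn(
                f"B={B} replicates is low for stable percentile intervals",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        X, y = self.model.exog, self.model.endog
        host_idx = np.flatnonzero(self.model._species_ind == 1.0)
        para_idx = np.flatnonzero(self.model._species_ind == 0.0)
        boot = np.empty((B, 4))
        for b in range(B):
            idx = np.concatenate(
                [
                    rng.choice(host_idx, size=len(host_idx), replace=True),
                    rng.choice(para_idx, size=len(para_idx), replace=True),
                ]
            )
            Xb, yb = X[idx], y[idx]
            # normal equations: much faster than a full OLS refit per replicate
            try:
                boot[b] = np.linalg.solve(Xb.T @ Xb, Xb.T @ yb)
            except np.linalg.LinAlgError:
                boot[b] = np.linalg.lstsq(Xb, yb, rcond=None)[0]
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
        return BootstrapCI(
            terms=self.terms,
            estimate=self.params.to_numpy(),
            ci_lower=lo,
            ci_upper=hi,
            n_replicates=B,
            replicates=boot,
        )

    def coefficient_table(
        self, bootstrap_ci: BootstrapCI | None = None
    ) -> pd.DataFrame:
        """Tidy coefficient table (term, log estimate, percent, se, t, df,
        p, and bootstrap CI bounds when supplied)."""
        df = pd.DataFrame(
            {
                "term": self.terms,
                "estimate_log": self.params.to_numpy(),
                "percent": percent_change(self.params.to_numpy()),
                "se": self.bse.to_numpy(),
                "t": self.tvalues.to_numpy(),
                "df": self.df_resid,
                "p": self.pvalues.to_numpy(),
            }
        )
        if bootstrap_ci is not None:
            df["ci_lo_log"] = bootstrap_ci.ci_lower
            df["ci_hi_log"] = bootstrap_ci.ci_upper
            df["ci_lo_percent"] = percent_change(bootstrap_ci.ci_lower)
            df["ci_hi_percent"] = percent_change(bootstrap_ci.ci_upper)
            df["method"] = "ols+bootstrap"
        else:
            df["method"] = "ols"
        return df

    def summary(self) -> str:
        """A readable summary of the fit, statsmodels-style."""
        lines = [
            "Complexity trend model "
            f"(variant={self.model.variant!r}, n={self.nobs}, "
            f"df_resid={self.df_resid})",
            "log_complexity ~ species + "
            f"{'year' if self.model.variant == 'year' else 'period'} + "
            "interaction",
            f"{'term':<16}{'coef(log)':>12}{'percent':>10}{'se':>10}"
            f"{'t':>8}{'p':>10}",
        ]
        for i, term in enumerate(self.terms):
            pct = percent_change(self.params.iloc[i])
            lines.append(
                f"{term:<16}{self.params.iloc[i]:>12.4f}{pct:>9.1f}%"
                f"{self.bse.iloc[i]:>10.4f}{self.tvalues.iloc[i]:>8.2f}"
                f"{self.pvalues.iloc[i]:>10.3g}"
            )
        return "\n".join(lines)
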