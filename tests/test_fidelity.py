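"""Mimetic fidelity: all-pairs statistics, the two-sample bootstrap and
the single-predictor discriminant."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from eggmimic import (
    MimeticFidelity,
    PopulationConfig,
    bootstrap_fidelity,
    enumerate_pairs,
    fidelity_change,
    fit_discriminant,
    generate_population,
    resampled_fda,
)


def _records(host_vals, para_vals, period="historical"):
    rows = []
    for i, v in enumerate(host_vals):
        rows.append(
            {"egg_id": f"h{i}", "species": "host", "period": period,
             "log_complexity": v, "complexity": np.exp(v)}
        )
    for i, v in enumerate(para_vals):
        rows.append(
            {"egg_id": f"p{i}", "species": "parasite", "period": period,
             "log_complexity": v, "complexity": np.exp(v)}
        )
    return pd.DataFrame(rows)


class TestPairs:
    def test_pair_counts_match_species_product(self, default_population):
        assert len(enumerate_pairs(default_population, "historical")) == 82 * 34
        assert len(enumerate_pairs(default_population, "current")) == 332 * 128

    def test_single_equal_pair_is_zero(self):
        rec = _records([0.5, 0.7], [0.5, 0.9])
        pairs = enumerate_pairs(rec, "historical")
        assert len(pairs) == 4
        assert pairs.min() == 0.0

    def test_missing_species_raises(self, default_population):
        only_host = default_population[default_population.species == "host"]
        with pytest.raises(ValueError, match="both species"):
            enumerate_pairs(only_host, "current")

    def test_brute_force_oracle(self, default_population):
        """Vectorized all-pairs mean equals a naive double loop."""
        host = default_population.query(
            "period == 'historical' and species == 'host'"
        ).log_complexity.to_numpy()[:50]
        para = default_population.query(
            "period == 'historical' and species == 'parasite'"
        ).log_complexity.to_numpy()[:20]
        naive = np.mean([abs(h - p) for h in host for p in para])
        rec = _records(host, para)
        vectorized = bootstrap_fidelity(rec, "historical", B=100, seed=0)
        assert vectorized.mean_absdiff == pytest.approx(naive, abs=1e-12)

    def test_order_invariance(self, default_population):
        shuffled = default_population.sample(frac=1, random_state=1)
        a = enumerate_pairs(default_population, "current")
        b = enumerate_pairs(shuffled, "current")
        assert np.sort(a).tolist() == pytest.approx(np.sort(b).tolist())


class TestBootstrapFidelity:
    def test_identical_values_zero_sem(self):
        rec = _records([0.3] * 10, [0.3] * 5)
        r = bootstrap_fidelity(rec, "historical", B=100, seed=0)
        assert r.mean_absdiff == 0.0
        assert r.sem == 0.0
        assert r.ci == (0.0, 0.0)

    def test_ci_symmetric_about_mean(self, default_population):
        r = bootstrap_fidelity(default_population, "current", B=200, seed=1)
        lo, hi = r.ci
        assert hi - r.mean_absdiff == pytest.approx(r.mean_absdiff - lo)
        assert r.n_pairs == r.n_host * r.n_parasite

    def test_historical_ci_wider_than_current(self):
        """Smaller historical samples give wider intervals, seed over seed."""
        wider = 0
        for seed in range(6):
            rec = generate_population(PopulationConfig(seed=seed))
            h = bootstrap_fidelity(rec, "historical", B=200, seed=seed)
            c = bootstrap_fidelity(rec, "current", B=200, seed=seed)
            if h.sem > c.sem:
                wider += 1
        assert wider >= 5

    def test_translation_invariance(self, default_population):
        """Adding a constant to every log-complexity leaves the all-pairs
        statistic unchanged (it depends only on differences)."""
        shifted = default_population.assign(
            log_complexity=default_population.log_complexity + 2.5
        )
        a = bootstrap_fidelity(default_population, "current", B=100, seed=2)
        b = bootstrap_fidelity(shifted, "current", B=100, seed=2)
        assert a.mean_absdiff == pytest.approx(b.mean_absdiff, abs=1e-12)
        np.testing.assert_allclose(a.replicate_means, b.replicate_means)


class TestFidelityChange:
    def test_worked_example_four_percent(self):
        """Period means 0.46 and 0.42 give a 4.08% fidelity increase."""
        hist = _records([0.46, 0.46], [0.0, 0.0])
        curr = _records([0.42, 0.42], [0.0, 0.0], period="current")
        h = bootstrap_fidelity(hist, "historical", B=100, seed=0)
        c = bootstrap_fidelity(curr, "current", B=100, seed=0)
        chg = fidelity_change(h, c)
        assert chg.percent_increase == pytest.approx(
            (np.exp(0.04) - 1) * 100, abs=1e-9
        )
        assert round(chg.percent_increase) == 4

    def test_identical_periods_zero_change(self, default_population):
        h = bootstrap_fidelity(default_population, "current", B=100, seed=3)
        chg = fidelity_change(h, h)
        assert chg.percent_increase == 0.0

    def test_sign_convention(self):
        """Differences growing over time = fidelity loss = negative."""
        hist = _records([0.3, 0.3], [0.0, 0.0])
        curr = _records([0.6, 0.6], [0.0, 0.0], period="current")
        h = bootstrap_fidelity(hist, "historical", B=100, seed=0)
        c = bootstrap_fidelity(curr, "current", B=100, seed=0)
        assert fidelity_change(h, c).percent_increase < 0

    def test_mismatched_replicates_raise(self, default_population):
        h = bootstrap_fidelity(default_population, "historical", B=100, seed=0)
        c = bootstrap_fidelity(default_population, "current", B=200, seed=0)
        with pytest.raises(ValueError, match="replicate counts"):
            fidelity_change(h, c)


class TestDiscriminant:
    def test_identical_distributions_chance_level(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 4000)
        labels = np.array(["host"] * 2000 + ["parasite"] * 2000)
        rule = fit_discriminant(vals, labels)
        assert abs(rule.proportion_correct - 0.5) < 0.03

    def test_perfect_separation(self):
        vals = np.concatenate([np.ones(50) * 5, np.zeros(50)])
        labels = np.array(["host"] * 50 + ["parasite"] * 50)
        assert fit_discriminant(vals, labels).proportion_correct == 1.0

    def test_closed_form_accuracy(self):
        """Two Gaussians with known means/SD: accuracy matches
        Phi(|mu1 - mu2| / (2 sigma)) within 2% at n = 10,000."""
        rng = np.random.default_rng(6)
        mu1, mu2, sigma = 0.0, 1.2, 0.8
        vals = np.concatenate(
            [rng.normal(mu1, sigma, 5000), rng.normal(mu2, sigma, 5000)]
        )
        labels = np.array(["parasite"] * 5000 + ["host"] * 5000)
        rule = fit_discriminant(vals, labels)
        expected = norm.cdf(abs(mu1 - mu2) / (2 * sigma))
        assert abs(rule.proportion_correct - expected) < 0.02

    def test_affine_invariance(self):
        """Any increasing affine transform of the predictor leaves the
        correct-assignment proportion unchanged."""
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.normal(0, 1, 200), rng.normal(1, 1, 200)]
        )
        labels = np.array(["parasite"] * 200 + ["host"] * 200)
        a = fit_discriminant(vals, labels).proportion_correct
        b = fit_discriminant(3.0 * vals - 7.0, labels).proportion_correct
        assert a == b

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_discriminant(
                np.array([1.0, 2.0, 3.0]), np.array(["host", "host", "parasite"])
            )


class TestResampledFDA:
    def test_subsample_sizes_fixed(self, default_population):
        r = resampled_fda(
            default_population, "current", sizes=(82, 34), iterations=50,
            seed=0,
        )
        assert r.subsample_sizes == (82, 34)
        assert r.iterations == 50
        assert np.all((r.proportions >= 0) & (r.proportions <= 1))

    def test_deterministic(self, default_population):
        a = resampled_fda(default_population, iterations=50, seed=4)
        b = resampled_fda(default_population, iterations=50, seed=4)
        np.testing.assert_array_equal(a.proportions, b.proportions)

    def test_insufficient_records_raise(self, default_population):
        with pytest.raises(ValueError, match="cannot draw"):
            resampled_fda(default_population, "historical", sizes=(500, 34))

    def test_matched_populations_similar_performance(self):
        """Current drawn from the same distribution as historical: the two
        periods' mean FDA proportions agree within 3 points."""
        diffs = []
        for seed in range(3):
            cfg = PopulationConfig(
                host_slope=0.0, parasite_slope=0.0, seed=200 + seed
            )
            rec = generate_population(cfg)
            fh = resampled_fda(
                rec, "historical", sizes=(82, 34), iterations=300,
                seed=seed,
            )
            fc = resampled_fda(
                rec, "current", sizes=(82, 34), iterations=300, seed=seed
            )
            diffs.append(abs(fh.mean_correct - fc.mean_correct))
        assert np.mean(diffs) < 0.03


class TestModelObject:
    def test_fit_produces_all_components(self, default_population):
        model = MimeticFidelity(
            default_population, pair_replicates=150, fda_iterations=150
        )
        res = model.fit(seed=9)
        assert res.historical.n_pairs == 2788
        assert res.current.n_pairs == 42496
        assert res.fda_current.subsample_sizes == (82, 34)
        assert len(res.pairs_table()) == 2
        assert len(res.fda_table()) == 2
        assert "fidelity increase" in res.summary()

    def test_constant_gap_population_shows_no_change(self):
        """Generator holds the host-parasite gap constant across periods,
        so the estimated fidelity change should hover near zero."""
        changes = []
        for seed in range(5):
            rec = generate_population(PopulationConfig(seed=300 + seed))
            res = MimeticFidelity(
                rec, pair_replicates=150, fda_iterations=10
            ).fit(seed=seed)
            changes.append(res.change.percent_increase)
        assert abs(np.mean(changes)) < 10.0
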