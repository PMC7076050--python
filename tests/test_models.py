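"""Hierarchical model fits: closed-form oracles, calibration, robustness."""

import math

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import chisquare

from smearshed import (
    AmselGroup,
    CohortConfig,
    CSTLabel,
    McmcConfig,
    PosteriorSamples,
    SmearRecord,
    StudyTable,
    contrast_tail_p,
    fit_location_model,
    fit_sci_model,
    fit_within_subject_poisson,
    generate_cohort,
)
from smearshed.errors import ConvergenceError, DomainError, EstimabilityError, PairingError
from smearshed.models import (
    sample_binomial_logit,
    sample_laplace_location,
    sample_poisson_paired,
)


def tiny_mcmc(seed, chains=2, iters=1200, warmup=600):
    return McmcConfig(n_chains=chains, n_iterations=iters, n_warmup=warmup, seed=seed)


def two_group_table(y_a, y_b, sci=False):
    """One observation per subject, two groups, response = field counts."""
    records = []
    for i, y in enumerate(list(y_a) + list(y_b)):
        grp = "noBV" if i < len(y_a) else "aBV"
        y = int(round(y))
        rec = dict(
            subject_id=f"S{i}", visit_week=0, amsel_group=AmselGroup(grp),
            cst=CSTLabel.IV, field_counts=(y, y, y),
            aggregate_areas_um2=(1000.0, 1000.0, 1000.0),
        )
        if sci and y <= 50:
            rec["total_cells_scored"] = 3 * y
            rec["superficial_count"] = y
        records.append(SmearRecord(**rec))
    return StudyTable(records)


class TestLaplaceLocation:
    def test_single_group_matches_sample_median(self):
        """No random effects: posterior location ~ sample median (Laplace MLE)."""
        rng = np.random.default_rng(7)
        z = rng.laplace(1.5, 0.2, size=300)
        draws = sample_laplace_location(
            z, np.zeros(300, dtype=np.intp), ["g"], mcmc=McmcConfig(seed=3)
        )
        post = PosteriorSamples(draws=draws, coords={"mu": ["g"]})
        post_med = np.median(post.extract("mu", "g"))
        mc_err = 4 * np.std(post.extract("mu", "g")) / math.sqrt(200)
        assert abs(post_med - np.median(z)) < max(0.01, mc_err)

    def test_identical_groups_centre_at_zero(self):
        vals = [40, 50, 60, 70, 80] * 4
        table = two_group_table(vals, vals)
        post = fit_location_model(table, "mean_count", mcmc=McmcConfig(seed=9),
                                  check=False)
        res = contrast_tail_p(post, "noBV", "aBV")
        assert abs(res.mean) < 0.05
        assert res.p >= 0.5

    def test_nonpositive_response_rejected(self):
        table = two_group_table([10, 20], [30, 40])
        bad = StudyTable([r.replace(field_counts=(0, 0, 0)) for r in table.records[:1]]
                         + table.records[1:])
        with pytest.raises(DomainError):
            fit_location_model(bad, "mean_count", mcmc=tiny_mcmc(1))

    def test_single_group_is_not_a_comparison(self):
        table = two_group_table([10, 20, 30], [])
        with pytest.raises(EstimabilityError):
            fit_location_model(table, "mean_count", mcmc=tiny_mcmc(1))

    def test_outlier_robustness_vs_gaussian_reference(self):
        """One 100x outlier moves the Laplace location less than the mean."""
        rng = np.random.default_rng(21)
        base = np.round(10 ** rng.laplace(1.9, 0.12, size=40)).astype(int)
        contaminated = base.copy()
        contaminated[0] = base[0] * 100
        meds = []
        for y in (base, contaminated):
            tab = two_group_table(y, 10 ** rng.laplace(1.5, 0.12, size=10))
            post = fit_location_model(tab, "mean_count", mcmc=tiny_mcmc(2),
                                      check=False)
            meds.append(np.median(post.extract("mu", "noBV")))
        laplace_shift = abs(meds[1] - meds[0])
        gauss_shift = abs(np.mean(np.log10(contaminated)) - np.mean(np.log10(base)))
        assert laplace_shift < gauss_shift

    def test_convergence_failure_is_loud(self):
        table = two_group_table([30, 40, 50, 60], [20, 25, 35, 45])
        with pytest.raises(ConvergenceError) as err:
            fit_location_model(table, "mean_count",
                               mcmc=McmcConfig(n_chains=2, n_iterations=30,
                                               n_warmup=15, seed=1))
        assert err.value.rhat  # carries the diagnostic table


class TestBinomialSci:
    def test_pooled_proportion_closed_form(self):
        """No random effects: expit(alpha) ~ pooled proportion (binomial MLE)."""
        rng = np.random.default_rng(5)
        n = rng.integers(20, 120, size=60)
        s = rng.binomial(n, 0.37)
        draws = sample_binomial_logit(
            s.astype(float), n.astype(float), np.zeros(60, dtype=np.intp), ["g"],
            mcmc=McmcConfig(seed=8),
        )
        post = PosteriorSamples(draws=draws, coords={"alpha": ["g"]})
        p_draws = expit(post.extract("alpha", "g"))
        pooled = s.sum() / n.sum()
        assert abs(np.median(p_draws) - pooled) < 4 * np.std(p_draws) + 0.005

    def test_all_zero_successes_pushes_proportion_to_zero(self):
        n = np.full(20, 50.0)
        draws = sample_binomial_logit(
            np.zeros(20), n, np.zeros(20, dtype=np.intp), ["g"],
            mcmc=McmcConfig(seed=2, n_iterations=4000, n_warmup=2000),
        )
        post = PosteriorSamples(draws=draws, coords={"alpha": ["g"]})
        assert np.mean(expit(post.extract("alpha", "g")) < 0.05) > 0.99

    def test_missing_group_named_in_error(self, default_cohort):
        table, _ = default_cohort
        with pytest.raises(EstimabilityError, match="sBV"):
            fit_sci_model(table, mcmc=tiny_mcmc(1), groups=["noBV", "aBV", "sBV"])


class TestPoissonPaired:
    def test_identical_counts_centre_delta_at_zero(self):
        y = np.array([60.0, 60.0] * 15)
        g = np.array([0.0, 1.0] * 15)
        sub = np.repeat(np.arange(15), 2)
        draws = sample_poisson_paired(y, g, sub, 15, McmcConfig(seed=4))
        delta = PosteriorSamples(draws=draws).extract("delta")
        assert abs(np.mean(delta)) < 0.05

    def test_single_subject_halving_oracle(self):
        """Counts (100, 50): posterior mean of exp(delta) near 1/2."""
        draws = sample_poisson_paired(
            np.array([100.0, 50.0]), np.array([0.0, 1.0]), np.array([0, 0]), 1,
            McmcConfig(seed=5),
        )
        delta = PosteriorSamples(draws=draws).extract("delta")
        assert np.mean(np.exp(delta)) == pytest.approx(0.5, abs=0.06)

    def test_recovery_at_fifty_subjects(self):
        rng = np.random.default_rng(9)
        true = math.log(35 / 91)
        th = rng.normal(math.log(90), 0.2, size=50)
        y, g, sub = [], [], []
        for i in range(50):
            y += [rng.poisson(math.exp(th[i])), rng.poisson(math.exp(th[i] + true))]
            g += [0.0, 1.0]
            sub += [i, i]
        draws = sample_poisson_paired(np.array(y, float), np.array(g),
                                      np.array(sub), 50, McmcConfig(seed=6))
        delta = PosteriorSamples(draws=draws).extract("delta")
        assert abs(np.mean(delta) - true) < 0.1

    def test_unpaired_subject_listed(self):
        recs = []
        for i, grp in enumerate(["aBV", "sBV", "aBV"]):
            recs.append(SmearRecord(
                subject_id=f"S{i // 2}", visit_week=(0, 5, 10)[i],
                amsel_group=AmselGroup(grp), cst=CSTLabel.IV,
                field_counts=(60, 60, 60), aggregate_areas_um2=(1e3, 1e3, 1e3)))
        with pytest.raises(PairingError, match="S1"):
            fit_within_subject_poisson(StudyTable(recs), groups=("aBV", "sBV"),
                                       mcmc=tiny_mcmc(1))


class TestChainInvariance:
    def test_permuting_chains_preserves_summaries(self):
        rng = np.random.default_rng(1)
        z = rng.laplace(1.0, 0.2, size=50)
        draws = sample_laplace_location(
            z, np.zeros(50, dtype=np.intp), ["g"],
            mcmc=McmcConfig(n_chains=4, n_iterations=800, n_warmup=400, seed=2),
        )
        post = PosteriorSamples(draws=draws, coords={"mu": ["g"]})
        perm = post.permute_chains([3, 1, 0, 2])
        a, b = post.summary().set_index("parameter"), perm.summary().set_index("parameter")
        for col in ("mean", "sd", "median", "rhat"):
            assert np.allclose(a[col], b[col])


def _rank_of_truth(truth, draws, n_ranks=20):
    thinned = draws[:: max(1, draws.size // (n_ranks - 1))][: n_ranks - 1]
    return int(np.sum(thinned < truth))


class TestSimulationBasedCalibration:
    """Rank of the generating parameter among posterior draws is uniform."""

    N_REPS = 60
    BINS = 5

    def _chisq_ok(self, ranks, n_ranks=20):
        edges = np.linspace(0, n_ranks, self.BINS + 1)
        obs, _ = np.histogram(ranks, bins=edges)
        return chisquare(obs).pvalue

    def test_laplace_location_sbc(self):
        rng = np.random.default_rng(100)
        ranks = []
        for rep in range(self.N_REPS):
            mu = rng.normal(0, 2.5)
            s = abs(2.5 * rng.standard_cauchy())
            z = rng.laplace(mu, s, size=15)
            draws = sample_laplace_location(
                z, np.zeros(15, dtype=np.intp), ["g"],
                mcmc=tiny_mcmc(200 + rep), prior_location_sd=2.5,
            )
            ranks.append(_rank_of_truth(mu, draws["mu"][:, :, 0].ravel()))
        assert self._chisq_ok(ranks) > 0.001

    def test_binomial_logit_sbc(self):
        rng = np.random.default_rng(300)
        ranks = []
        for rep in range(self.N_REPS):
            alpha = rng.normal(0, 1.5)
            n = rng.integers(10, 60, size=12).astype(float)
            s = rng.binomial(n.astype(int), expit(alpha)).astype(float)
            draws = sample_binomial_logit(
                s, n, np.zeros(12, dtype=np.intp), ["g"],
                mcmc=tiny_mcmc(400 + rep), prior_location_sd=1.5,
            )
            ranks.append(_rank_of_truth(alpha, draws["alpha"][:, :, 0].ravel()))
        assert self._chisq_ok(ranks) > 0.001

    def test_poisson_paired_sbc(self):
        rng = np.random.default_rng(500)
        ranks = []
        for rep in range(self.N_REPS):
            delta = rng.normal(0, 1.0)
            theta = rng.normal(math.log(40), 1.0, size=8)
            y, g, sub = [], [], []
            for i in range(8):
                y += [rng.poisson(math.exp(theta[i] - delta / 2)),
                      rng.poisson(math.exp(theta[i] + delta / 2))]
                g += [0.0, 1.0]
                sub += [i, i]
            draws = sample_poisson_paired(
                np.array(y, float), np.array(g), np.array(sub), 8,
                mcmc=tiny_mcmc(600 + rep), prior_location_sd=1.0,
                theta_center=math.log(40),
            )
            ranks.append(_rank_of_truth(delta, draws["delta"].ravel()))
        assert self._chisq_ok(ranks) > 0.001


class TestContrastCoverage:
    def test_credible_interval_coverage_on_generator_matched_data(self):
        """95% CI for the noBV-aBV count contrast covers truth 85-99% of runs."""
        cfg0 = CohortConfig()
        truth = cfg0.count_location_log10[0] - cfg0.count_location_log10[1]
        covered = 0
        n_reps = 100
        for rep in range(n_reps):
            table, _ = generate_cohort(CohortConfig(seed=1000 + rep))
            post = fit_location_model(table, "mean_count",
                                      mcmc=tiny_mcmc(2000 + rep), check=False)
            res = contrast_tail_p(post, "noBV", "aBV")
            covered += res.ci_low <= truth <= res.ci_high
        assert 0.85 * n_reps <= covered <= 0.99 * n_reps
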