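"""Bayesian hierarchical comparison models and multiplicity adjustment.

Three model families cover the pipeline's group comparisons:

* ``laplace_location`` — robust location comparison of a positive outcome
  on the log10 scale: z_ij = log10 y_ij ~ Laplace(mu_g(ij) + b_i, s) with
  subject effects b_i ~ Normal(0, sigma_b). The Laplace likelihood makes
  the group location a posterior median-type estimate, robust to the heavy
  tails of per-smear counts and aggregate areas.
* ``binomial_logit`` — superficial cell index: s_ij ~ Binomial(n_ij, p_ij),
  logit p_ij = alpha_g(ij) + u_i, u_i ~ Normal(0, sigma_u). The group-level
  SCI summary is expit(alpha_g), the median-subject proportion.
* ``poisson_paired`` — within-woman two-group comparison of counts:
  y_ij ~ Poisson(lambda_ij), log lambda_ij = theta_i + delta * [g = second],
  for subjects observed in both groups; delta is the within-subject
  log rate ratio.

Priors are weakly informative: Normal(0, 10) on locations on the modelled
scale and half-Cauchy(2.5) on every positive scale parameter. These forms
and the sampler settings are this package's choices, exposed in
:class:`ModelSpec` and :class:`~smearshed.mcmc.McmcConfig`.

Group contrasts are summarised with a two-sided tail probability computed
from the Gaussian approximation to the contrast's posterior (mean and sd of
the draws), which can resolve probabilities far below 1/number-of-draws;
the raw empirical tail fraction is reported alongside. Families of
contrasts are adjusted with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import (
    ConfigError,
    DomainError,
    EstimabilityError,
    PairingError,
)
from .mcmc import (
    McmcConfig,
    PosteriorSamples,
    StepAdapter,
    half_cauchy_logpdf,
    mh_accept,
    require_converged,
    segment_layout,
    segment_sums,
)
from .records import StudyTable

_CANONICAL_GROUP_ORDER = ("noBV", "aBV", "sBV")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model fit."""

    likelihood: str = "laplace_location"  # laplace_location | binomial_logit | poisson_paired
    response: str = "mean_count"
    transform: str = "log10"  # log10 | identity
    group: str = "amsel_group"
    subject: Optional[str] = "subject_id"
    prior_location_sd: float = 10.0
    prior_scale_gamma: float = 2.5

    def validate(self) -> None:
        if self.likelihood not in ("laplace_location", "binomial_logit", "poisson_paired"):
            raise ConfigError(f"unknown likelihood {self.likelihood!r}")
        if self.transform not in ("log10", "identity"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        if self.prior_location_sd <= 0 or self.prior_scale_gamma <= 0:
            raise ConfigError("prior hyperparameters must be strictly positive")

    @property
    def location_param(self) -> str:
        return {"laplace_location": "mu", "binomial_logit": "alpha",
                "poisson_paired": "delta"}[self.likelihood]


def _order_levels(levels: Sequence[str]) -> list[str]:
    canon = [g for g in _CANONICAL_GROUP_ORDER if g in levels]
    extra = sorted(set(levels) - set(canon))
    return canon + extra


def _index(values, levels: Sequence[str]) -> np.ndarray:
    lookup = {lab: i for i, lab in enumerate(levels)}
    return np.asarray([lookup[v] for v in values], dtype=np.intp)


# ---------------------------------------------------------------------------
# low-level samplers (array in, draws out)


def sample_laplace_location(
    z: np.ndarray,
    group_idx: np.ndarray,
    group_levels: Sequence[str],
    subject_idx: Optional[np.ndarray] = None,
    n_subjects: int = 0,
    mcmc: McmcConfig = None,
    prior_location_sd: float = 10.0,
    prior_scale_gamma: float = 2.5,
) -> dict:
    """MCMC for the Laplace location model on already-transformed data.

    With ``subject_idx=None`` the subject random effect is omitted
    (sigma_b fixed at zero), which reduces the model to independent Laplace
    location estimation per group.
    """
    mcmc = mcmc or McmcConfig()
    mcmc.validate()
    rng = np.random.default_rng(mcmc.seed)
    z = np.asarray(z, dtype=float)
    n = z.size
    C, G = mcmc.n_chains, len(group_levels)
    hier = subject_idx is not None
    S = n_subjects if hier else 0

    ord_g, starts_g = segment_layout(group_idx, G)
    z_g = z[ord_g]
    g_g = group_idx[ord_g]
    sub_g = subject_idx[ord_g] if hier else None
    if hier:
        ord_s, starts_s = segment_layout(subject_idx, S)
        z_s = z[ord_s]
        g_s = group_idx[ord_s]
        sub_s = subject_idx[ord_s]

    # dispersed initialisation around data-driven values
    med = np.array([np.median(z[group_idx == g]) for g in range(G)])
    mad = float(np.mean(np.abs(z - med[group_idx]))) or 0.1
    mu = med[None, :] + 0.3 * rng.standard_normal((C, G))
    log_s = math.log(mad) + 0.3 * rng.standard_normal(C)
    b = 0.05 * rng.standard_normal((C, S)) if hier else None
    log_sigma_b = math.log(0.1) + 0.3 * rng.standard_normal(C) if hier else None

    ad_mu = StepAdapter((C, G), 0.1, mcmc.target_accept)
    ad_s = StepAdapter((C,), 0.2, mcmc.target_accept)
    if hier:
        ad_b = StepAdapter((C, S), 0.1, mcmc.target_accept)
        ad_sb = StepAdapter((C,), 0.3, mcmc.target_accept)
        ad_sb_nc = StepAdapter((C,), 0.3, mcmc.target_accept)
        ad_shift = StepAdapter((C,), 0.05, mcmc.target_accept)

    D = mcmc.n_draws
    out_mu = np.empty((C, D, G))
    out_s = np.empty((C, D))
    out_sigma_b = np.empty((C, D)) if hier else None
    out_b = np.empty((C, D, S)) if hier else None

    p_var2 = 2.0 * prior_location_sd ** 2
    for it in range(mcmc.n_iterations):
        warm = it < mcmc.n_warmup
        s = np.exp(log_s)

        # group locations (independent across groups given b and s)
        r = z_g[None, :] - (b[:, sub_g] if hier else 0.0)
        mu_p = mu + ad_mu.step * rng.standard_normal((C, G))
        cur = segment_sums(np.abs(r - mu[:, g_g]), starts_g)
        new = segment_sums(np.abs(r - mu_p[:, g_g]), starts_g)
        logr = (cur - new) / s[:, None] + (mu ** 2 - mu_p ** 2) / p_var2
        acc, ap = mh_accept(logr, rng)
        mu = np.where(acc, mu_p, mu)
        if warm:
            ad_mu.update(ap)

        if hier:
            sigma_b = np.exp(log_sigma_b)
            r2 = z_s[None, :] - mu[:, g_s]
            b_p = b + ad_b.step * rng.standard_normal((C, S))
            cur = segment_sums(np.abs(r2 - b[:, sub_s]), starts_s)
            new = segment_sums(np.abs(r2 - b_p[:, sub_s]), starts_s)
            logr = (cur - new) / s[:, None] + (b ** 2 - b_p ** 2) / (
                2.0 * sigma_b[:, None] ** 2
            )
            acc, ap = mh_accept(logr, rng)
            b = np.where(acc, b_p, b)
            if warm:
                ad_b.update(ap)

            # random-effect scale
            ssq = np.sum(b ** 2, axis=1)
            lsb_p = log_sigma_b + ad_sb.step * rng.standard_normal(C)
            sb_p = np.exp(lsb_p)
            logr = (
                -ssq / (2 * sb_p ** 2) - S * lsb_p
                + half_cauchy_logpdf(sb_p, prior_scale_gamma) + lsb_p
            ) - (
                -ssq / (2 * sigma_b ** 2) - S * log_sigma_b
                + half_cauchy_logpdf(sigma_b, prior_scale_gamma) + log_sigma_b
            )
            acc, ap = mh_accept(logr, rng)
            log_sigma_b = np.where(acc, lsb_p, log_sigma_b)
            if warm:
                ad_sb.update(ap)

            # interweaved non-centered scale update (b = sigma_b * eta with
            # eta held fixed) — breaks the funnel when sigma_b is near zero
            sigma_b = np.exp(log_sigma_b)
            lsb_p = log_sigma_b + ad_sb_nc.step * rng.standard_normal(C)
            fac = np.exp(lsb_p - log_sigma_b)
            b_p = b * fac[:, None]
            base = z_g[None, :] - mu[:, g_g]
            cur_ll = -np.sum(np.abs(base - b[:, sub_g]), axis=1) / s
            new_ll = -np.sum(np.abs(base - b_p[:, sub_g]), axis=1) / s
            logr = (
                new_ll - cur_ll
                + half_cauchy_logpdf(np.exp(lsb_p), prior_scale_gamma) + lsb_p
                - half_cauchy_logpdf(sigma_b, prior_scale_gamma) - log_sigma_b
            )
            acc, ap = mh_accept(logr, rng)
            b = np.where(acc[:, None], b_p, b)
            log_sigma_b = np.where(acc, lsb_p, log_sigma_b)
            if warm:
                ad_sb_nc.update(ap)

            # likelihood-invariant translation (mu + e, b - e) breaks the
            # slow trade-off between group locations and the subject mean
            sigma_b = np.exp(log_sigma_b)
            e = ad_shift.step * rng.standard_normal(C)
            logr = (
                ((mu ** 2).sum(axis=1) - ((mu + e[:, None]) ** 2).sum(axis=1)) / p_var2
                + ((b ** 2).sum(axis=1) - ((b - e[:, None]) ** 2).sum(axis=1))
                / (2.0 * sigma_b ** 2)
            )
            acc, ap = mh_accept(logr, rng)
            mu = mu + np.where(acc, e, 0.0)[:, None]
            b = b - np.where(acc, e, 0.0)[:, None]
            if warm:
                ad_shift.update(ap)

        # observation scale
        resid = z_g[None, :] - mu[:, g_g] - (b[:, sub_g] if hier else 0.0)
        T = np.sum(np.abs(resid), axis=1)
        ls_p = log_s + ad_s.step * rng.standard_normal(C)
        s_p = np.exp(ls_p)
        logr = (
            -T / s_p - n * (math.log(2.0) + ls_p)
            + half_cauchy_logpdf(s_p, prior_scale_gamma) + ls_p
        ) - (
            -T / s - n * (math.log(2.0) + log_s)
            + half_cauchy_logpdf(s, prior_scale_gamma) + log_s
        )
        acc, ap = mh_accept(logr, rng)
        log_s = np.where(acc, ls_p, log_s)
        if warm:
            ad_s.update(ap)

        if not warm:
            d = it - mcmc.n_warmup
            out_mu[:, d, :] = mu
            out_s[:, d] = np.exp(log_s)
            if hier:
                out_sigma_b[:, d] = np.exp(log_sigma_b)
                out_b[:, d, :] = b

    draws = {"mu": out_mu, "s": out_s}
    if hier:
        draws["sigma_b"] = out_sigma_b
        draws["b"] = out_b
    return draws


def sample_binomial_logit(
    successes: np.ndarray,
    trials: np.ndarray,
    group_idx: np.ndarray,
    group_levels: Sequence[str],
    subject_idx: Optional[np.ndarray] = None,
    n_subjects: int = 0,
    mcmc: McmcConfig = None,
    prior_location_sd: float = 10.0,
    prior_scale_gamma: float = 2.5,
) -> dict:
    """MCMC for the binomial mixed model with subject random intercept."""
    mcmc = mcmc or McmcConfig()
    mcmc.validate()
    rng = np.random.default_rng(mcmc.seed)
    sfl = np.asarray(successes, dtype=float)
    nfl = np.asarray(trials, dtype=float)
    C, G = mcmc.n_chains, len(group_levels)
    hier = subject_idx is not None
    S = n_subjects if hier else 0

    ord_g, starts_g = segment_layout(group_idx, G)
    s_g, n_g, g_g = sfl[ord_g], nfl[ord_g], group_idx[ord_g]
    sub_g = subject_idx[ord_g] if hier else None
    if hier:
        ord_s, starts_s = segment_layout(subject_idx, S)
        s_s, n_s = sfl[ord_s], nfl[ord_s]
        g_s, sub_s = group_idx[ord_s], subject_idx[ord_s]

    def binom_ll(eta, s_, n_):
        # log-likelihood up to the binomial coefficient
        return s_ * eta - n_ * np.logaddexp(0.0, eta)

    pooled = np.array(
        [
            (sfl[group_idx == g].sum() + 0.5) / (nfl[group_idx == g].sum() + 1.0)
            for g in range(G)
        ]
    )
    alpha = np.log(pooled / (1 - pooled))[None, :] + 0.3 * rng.standard_normal((C, G))
    u = 0.05 * rng.standard_normal((C, S)) if hier else None
    log_sigma_u = math.log(0.2) + 0.3 * rng.standard_normal(C) if hier else None

    ad_a = StepAdapter((C, G), 0.1, mcmc.target_accept)
    if hier:
        ad_u = StepAdapter((C, S), 0.2, mcmc.target_accept)
        ad_su = StepAdapter((C,), 0.3, mcmc.target_accept)
        ad_su_nc = StepAdapter((C,), 0.3, mcmc.target_accept)
        ad_shift = StepAdapter((C,), 0.05, mcmc.target_accept)

    D = mcmc.n_draws
    out_alpha = np.empty((C, D, G))
    out_sigma_u = np.empty((C, D)) if hier else None
    out_u = np.empty((C, D, S)) if hier else None

    p_var2 = 2.0 * prior_location_sd ** 2
    for it in range(mcmc.n_iterations):
        warm = it < mcmc.n_warmup

        off = u[:, sub_g] if hier else 0.0
        alpha_p = alpha + ad_a.step * rng.standard_normal((C, G))
        cur = segment_sums(binom_ll(alpha[:, g_g] + off, s_g, n_g), starts_g)
        new = segment_sums(binom_ll(alpha_p[:, g_g] + off, s_g, n_g), starts_g)
        logr = new - cur + (alpha ** 2 - alpha_p ** 2) / p_var2
        acc, ap = mh_accept(logr, rng)
        alpha = np.where(acc, alpha_p, alpha)
        if warm:
            ad_a.update(ap)

        if hier:
            sigma_u = np.exp(log_sigma_u)
            base = alpha[:, g_s]
            u_p = u + ad_u.step * rng.standard_normal((C, S))
            cur = segment_sums(binom_ll(base + u[:, sub_s], s_s, n_s), starts_s)
            new = segment_sums(binom_ll(base + u_p[:, sub_s], s_s, n_s), starts_s)
            logr = new - cur + (u ** 2 - u_p ** 2) / (2.0 * sigma_u[:, None] ** 2)
            acc, ap = mh_accept(logr, rng)
            u = np.where(acc, u_p, u)
            if warm:
                ad_u.update(ap)

            ssq = np.sum(u ** 2, axis=1)
            lsu_p = log_sigma_u + ad_su.step * rng.standard_normal(C)
            su_p = np.exp(lsu_p)
            logr = (
                -ssq / (2 * su_p ** 2) - S * lsu_p
                + half_cauchy_logpdf(su_p, prior_scale_gamma) + lsu_p
            ) - (
                -ssq / (2 * sigma_u ** 2) - S * log_sigma_u
                + half_cauchy_logpdf(sigma_u, prior_scale_gamma) + log_sigma_u
            )
            acc, ap = mh_accept(logr, rng)
            log_sigma_u = np.where(acc, lsu_p, log_sigma_u)
            if warm:
                ad_su.update(ap)

            # interweaved non-centered scale update (u = sigma_u * eta)
            sigma_u = np.exp(log_sigma_u)
            lsu_p = log_sigma_u + ad_su_nc.step * rng.standard_normal(C)
            fac = np.exp(lsu_p - log_sigma_u)
            u_p = u * fac[:, None]
            base = alpha[:, g_s]
            cur_ll = segment_sums(binom_ll(base + u[:, sub_s], s_s, n_s), starts_s).sum(axis=1)
            new_ll = segment_sums(binom_ll(base + u_p[:, sub_s], s_s, n_s), starts_s).sum(axis=1)
            logr = (
                new_ll - cur_ll
                + half_cauchy_logpdf(np.exp(lsu_p), prior_scale_gamma) + lsu_p
                - half_cauchy_logpdf(sigma_u, prior_scale_gamma) - log_sigma_u
            )
            acc, ap = mh_accept(logr, rng)
            u = np.where(acc[:, None], u_p, u)
            log_sigma_u = np.where(acc, lsu_p, log_sigma_u)
            if warm:
                ad_su_nc.update(ap)

            # likelihood-invariant translation (alpha + e, u - e)
            sigma_u = np.exp(log_sigma_u)
            e = ad_shift.step * rng.standard_normal(C)
            logr = (
                ((alpha ** 2).sum(axis=1) - ((alpha + e[:, None]) ** 2).sum(axis=1))
                / p_var2
                + ((u ** 2).sum(axis=1) - ((u - e[:, None]) ** 2).sum(axis=1))
                / (2.0 * sigma_u ** 2)
            )
            acc, ap = mh_accept(logr, rng)
            alpha = alpha + np.where(acc, e, 0.0)[:, None]
            u = u - np.where(acc, e, 0.0)[:, None]
            if warm:
                ad_shift.update(ap)

        if not warm:
            d = it - mcmc.n_warmup
            out_alpha[:, d, :] = alpha
            if hier:
                out_sigma_u[:, d] = np.exp(log_sigma_u)
                out_u[:, d, :] = u

    draws = {"alpha": out_alpha}
    if hier:
        draws["sigma_u"] = out_sigma_u
        draws["u"] = out_u
    return draws


def sample_poisson_paired(
    y: np.ndarray,
    second_group: np.ndarray,
    subject_idx: np.ndarray,
    n_subjects: int,
    mcmc: McmcConfig = None,
    prior_location_sd: float = 10.0,
    theta_center: Optional[float] = None,
) -> dict:
    """MCMC for the within-subject Poisson two-group model.

    log lambda = theta_i + delta * [second group]; theta_i ~
    Normal(theta_center, prior_location_sd) with the centre defaulting to
    log mean(y); delta ~ Normal(0, prior_location_sd).
    """
    mcmc = mcmc or McmcConfig()
    mcmc.validate()
    rng = np.random.default_rng(mcmc.seed)
    y = np.asarray(y, dtype=float)
    # centred group coding (-1/2, +1/2) decorrelates theta and delta;
    # stored theta draws are shifted back to the first-group baseline
    d_ind = np.asarray(second_group, dtype=float) - 0.5
    C, S = mcmc.n_chains, n_subjects

    ord_s, starts_s = segment_layout(subject_idx, S)
    y_s, d_s, sub_s = y[ord_s], d_ind[ord_s], subject_idx[ord_s]

    if theta_center is None:
        ybar = float(np.mean(y))
        if ybar <= 0:
            raise DomainError("all counts are zero; Poisson rates are not estimable")
        theta0 = math.log(ybar)
    else:
        theta0 = float(theta_center)
    theta = theta0 + 0.3 * rng.standard_normal((C, S))
    delta = 0.3 * rng.standard_normal(C)

    ad_t = StepAdapter((C, S), 0.2, mcmc.target_accept)
    ad_d = StepAdapter((C,), 0.05, mcmc.target_accept)

    D = mcmc.n_draws
    out_theta = np.empty((C, D, S))
    out_delta = np.empty((C, D))

    p_var2 = 2.0 * prior_location_sd ** 2

    def pois_ll(eta, y_):
        return y_ * eta - np.exp(eta)

    for it in range(mcmc.n_iterations):
        warm = it < mcmc.n_warmup

        eta_off = delta[:, None] * d_s[None, :]
        theta_p = theta + ad_t.step * rng.standard_normal((C, S))
        cur = segment_sums(pois_ll(theta[:, sub_s] + eta_off, y_s), starts_s)
        new = segment_sums(pois_ll(theta_p[:, sub_s] + eta_off, y_s), starts_s)
        logr = new - cur + ((theta - theta0) ** 2 - (theta_p - theta0) ** 2) / p_var2
        acc, ap = mh_accept(logr, rng)
        theta = np.where(acc, theta_p, theta)
        if warm:
            ad_t.update(ap)

        delta_p = delta + ad_d.step * rng.standard_normal(C)
        base = theta[:, sub_s]
        cur = np.sum(pois_ll(base + delta[:, None] * d_s, y_s), axis=1)
        new = np.sum(pois_ll(base + delta_p[:, None] * d_s, y_s), axis=1)
        logr = new - cur + (delta ** 2 - delta_p ** 2) / p_var2
        acc, ap = mh_accept(logr, rng)
        delta = np.where(acc, delta_p, delta)
        if warm:
            ad_d.update(ap)

        if not warm:
            dd = it - mcmc.n_warmup
            out_theta[:, dd, :] = theta - 0.5 * delta[:, None]
            out_delta[:, dd] = delta

    return {"delta": out_delta, "theta": out_theta}


# ---------------------------------------------------------------------------
# table-level fits


def _prepare_groups(frame, spec: ModelSpec, groups: Optional[Sequence[str]]):
    present = list(dict.fromkeys(frame[spec.group]))
    levels = _order_levels(groups if groups is not None else present)
    for g in levels:
        if g not in present or not (frame[spec.group] == g).any():
            raise EstimabilityError(f"group {g!r} has no usable rows")
    frame = frame[frame[spec.group].isin(levels)]
    return frame, levels


def fit_location_model(
    table: StudyTable,
    response: str = "mean_count",
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[McmcConfig] = None,
    groups: Optional[Sequence[str]] = None,
    check: bool = True,
) -> PosteriorSamples:
    """Fit the Laplace subject-wise random-effects location model.

    The response is log10-transformed (default) and modelled as Laplace
    around group location + subject intercept. Back-transform group
    locations with ``10**mu`` to read them on the original scale.
    """
    spec = spec or ModelSpec(likelihood="laplace_location", response=response)
    spec = replace(spec, response=response, likelihood="laplace_location")
    spec.validate()
    mcmc = mcmc or McmcConfig()
    frame = table.to_frame()
    frame = frame[frame[response].notna()]
    frame, levels = _prepare_groups(frame, spec, groups)
    y = frame[response].to_numpy(dtype=float)
    if spec.transform == "log10":
        if np.any(y <= 0):
            raise DomainError(
                f"response {response!r} must be strictly positive for log10 transform"
            )
        z = np.log10(y)
    else:
        z = y
    if len(levels) < 2:
        raise EstimabilityError("at least two groups are required for a comparison")
    g_idx = _index(frame[spec.group], levels)
    if spec.subject is not None:
        subjects = list(dict.fromkeys(frame[spec.subject]))
        s_idx = _index(frame[spec.subject], subjects)
    else:
        subjects, s_idx = [], None
    draws = sample_laplace_location(
        z, g_idx, levels, s_idx, len(subjects), mcmc,
        spec.prior_location_sd, spec.prior_scale_gamma,
    )
    post = PosteriorSamples(
        draws=draws, coords={"mu": list(levels), "b": list(subjects)},
        model=spec, mcmc=mcmc,
    )
    return require_converged(post) if check else post


def fit_sci_model(
    table: StudyTable,
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[McmcConfig] = None,
    groups: Optional[Sequence[str]] = None,
    check: bool = True,
) -> PosteriorSamples:
    """Fit the binomial mixed model to the SCI-eligible samples.

    Rows are restricted to samples below the count gate with superficial /
    total counts present. ``expit(alpha_g)`` is the group-level SCI on the
    median-subject scale.
    """
    spec = spec or ModelSpec(likelihood="binomial_logit", response="superficial_count",
                             transform="identity")
    spec = replace(spec, likelihood="binomial_logit", transform="identity")
    spec.validate()
    mcmc = mcmc or McmcConfig()
    eligible = table.filter(
        lambda r: r.sci_eligible and r.superficial_count is not None
        and r.total_cells_scored and r.total_cells_scored > 0
    )
    frame = eligible.to_frame()
    if len(frame) == 0:
        raise EstimabilityError("no SCI-eligible rows with scored cells")
    frame, levels = _prepare_groups(frame, spec, groups)
    s = frame["superficial_count"].to_numpy(dtype=float)
    n = frame["total_cells_scored"].to_numpy(dtype=float)
    g_idx = _index(frame[spec.group], levels)
    if spec.subject is not None:
        subjects = list(dict.fromkeys(frame[spec.subject]))
        s_idx = _index(frame[spec.subject], subjects)
    else:
        subjects, s_idx = [], None
    draws = sample_binomial_logit(
        s, n, g_idx, levels, s_idx, len(subjects), mcmc,
        spec.prior_location_sd, spec.prior_scale_gamma,
    )
    post = PosteriorSamples(
        draws=draws, coords={"alpha": list(levels), "u": list(subjects)},
        model=spec, mcmc=mcmc,
    )
    return require_converged(post) if check else post


def fit_within_subject_poisson(
    paired_table: StudyTable,
    response: str = "mean_count",
    groups: Optional[Sequence[str]] = None,
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[McmcConfig] = None,
    check: bool = True,
) -> PosteriorSamples:
    """Within-woman Poisson comparison between exactly two groups.

    Every subject in the table must contribute at least one sample in each
    of the two groups; the response is rounded to integer counts. The
    posterior of ``delta`` is the within-woman natural-log rate ratio of
    the second group over the first (divide by ln 10 for a log10 scale).
    """
    spec = spec or ModelSpec(likelihood="poisson_paired", response=response,
                             transform="identity")
    spec = replace(spec, likelihood="poisson_paired", response=response,
                   transform="identity")
    spec.validate()
    mcmc = mcmc or McmcConfig()
    frame = paired_table.to_frame()
    frame = frame[frame[response].notna()]
    levels = _order_levels(groups if groups is not None else
                           list(dict.fromkeys(frame[spec.group])))
    if len(levels) != 2:
        raise PairingError(f"exactly two groups are required, got {levels}")
    frame = frame[frame[spec.group].isin(levels)]
    offenders = []
    for sid, sub in frame.groupby(spec.subject, sort=False):
        if set(sub[spec.group]) != set(levels):
            offenders.append(sid)
    if offenders:
        raise PairingError(
            f"subjects missing one arm of ({levels[0]}, {levels[1]}): {offenders}"
        )
    if len(frame) == 0:
        raise EstimabilityError("no rows available for the paired comparison")
    y = np.rint(frame[response].to_numpy(dtype=float))
    if np.any(y < 0):
        raise DomainError("Poisson responses must be non-negative")
    subjects = list(dict.fromkeys(frame[spec.subject]))
    s_idx = _index(frame[spec.subject], subjects)
    second = (frame[spec.group] == levels[1]).to_numpy()
    draws = sample_poisson_paired(
        y, second, s_idx, len(subjects), mcmc, spec.prior_location_sd
    )
    post = PosteriorSamples(
        draws=draws, coords={"theta": list(subjects), "delta_levels": list(levels)},
        model=spec, mcmc=mcmc,
    )
    return require_converged(post) if check else post


# ---------------------------------------------------------------------------
# contrasts and FDR


@dataclass(frozen=True)
class ContrastResult:
    """Posterior summary of one group difference."""

    label: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    p: float  # two-sided Gaussian tail probability
    p_empirical: float  # raw two-sided tail fraction of the draws
    q: Optional[float] = None  # BH-FDR adjusted, filled at the family level

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        if self.ci_low > self.ci_high:
            raise ValueError("credible interval bounds out of order")

    def with_q(self, q: float) -> "ContrastResult":
        return replace(self, q=q)


def _tail_p_from_draws(delta: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(delta))
    sd = float(np.std(delta, ddof=1))
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 1e-300
    else:
        p = float(min(1.0, 2.0 * norm.sf(abs(mean) / sd)))
        p = max(p, 1e-300)
    emp = 2.0 * min(float(np.mean(delta > 0)), float(np.mean(delta < 0)))
    return p, min(1.0, emp)


def contrast_tail_p(
    posterior: PosteriorSamples, g1: str, g2: str, param: Optional[str] = None
) -> ContrastResult:
    """Posterior contrast g1 − g2 with a two-sided tail probability.

    ``p`` uses the Gaussian approximation from the draws' mean and sd so it
    can resolve values far below 1/number-of-draws; ``p_empirical`` is the
    raw two-sided tail fraction of the draws.
    """
    if param is None:
        param = posterior.model.location_param if posterior.model else "mu"
    delta = posterior.extract(param, g1) - posterior.extract(param, g2)
    mean = float(np.mean(delta))
    sd = float(np.std(delta, ddof=1))
    lo, hi = np.quantile(delta, [0.025, 0.975])
    p, emp = _tail_p_from_draws(delta)
    return ContrastResult(
        label=f"{g1}-{g2}", mean=mean, sd=sd,
        ci_low=float(lo), ci_high=float(hi), p=p, p_empirical=emp,
    )


def paired_delta_result(posterior: PosteriorSamples, log10_scale: bool = False) -> ContrastResult:
    """Summary of the paired-model within-subject effect ``delta``.

    With ``log10_scale`` the effect is reported as delta / ln(10), i.e. the
    within-woman difference in log10 rates.
    """
    delta = posterior.extract("delta")
    if log10_scale:
        delta = delta / math.log(10.0)
    levels = posterior.coords.get("delta_levels", ["g2", "g1"])
    mean = float(np.mean(delta))
    sd = float(np.std(delta, ddof=1))
    lo, hi = np.quantile(delta, [0.025, 0.975])
    p, emp = _tail_p_from_draws(delta)
    return ContrastResult(
        label=f"{levels[1]}-{levels[0]} (within-subject)",
        mean=mean, sd=sd, ci_low=float(lo), ci_high=float(hi), p=p, p_empirical=emp,
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def adjust_family(contrasts: Sequence[ContrastResult]) -> list[ContrastResult]:
    """Attach BH-FDR q-values to one family of contrasts."""
    if not contrasts:
        return []
    q = bh_fdr([c.p for c in contrasts])
    return [c.with_q(float(qi)) for c, qi in zip(contrasts, q)]
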