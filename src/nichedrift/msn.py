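"""Hierarchical multi-site neutral (MSN) model: likelihoods and Gibbs fitting.

The model couples a neutral metacommunity with per-site local communities.
The metacommunity species pool is a Dirichlet-process draw with biodiversity
(concentration) parameter ``theta``; each local community of size ``J_i`` is
assembled by immigration from the pool with per-site immigration
concentration ``I_i`` (migration probability ``m_i = I_i / (I_i + J_i - 1)``).
The finite-sample marginal factorizes into the Ewens sampling formula for the
pooled metacommunity abundance configuration and a Dirichlet-multinomial for
each local community given the metacommunity relative abundances.

Inference is Gibbs sampling in the Chinese-restaurant-franchise
representation of the hierarchical Dirichlet process: per-site per-taxon
ancestor (table) counts are drawn from their exact conditional, the
metacommunity proportions from a Dirichlet, and the two concentration
parameters by the auxiliary-variable scheme of Escobar & West under gamma
priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.random import Generator, default_rng
from scipy.special import gammaln, logsumexp

from .bank import MetacommunitySample

logger = logging.getLogger(__name__)

__all__ = [
    "MsnConfig",
    "MsnPosterior",
    "ewens_log_prob",
    "dirmult_log_prob",
    "sample_ancestor_counts",
    "ancestor_count_log_pmf",
    "msn_log_likelihood",
    "fit_msn_gibbs",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MsnConfig:
    """Gibbs schedule and priors for one MSN fit.

    Defaults mirror the full-scale schedule: 50,000 iterations, the first
    25,000 discarded as burn-in, every tenth of the rest retained, giving
    N = 2,500 posterior draws.
    """

    n_iterations: int = 50_000
    burn_in: int = 25_000
    thin: int = 10
    prior_theta: tuple[float, float] = (1.0, 0.01)  # gamma (shape, rate)
    prior_I: tuple[float, float] = (1.0, 0.01)
    seed: int = 0
    truncation: int = 4000  # stick-breaking atoms for pool simulation

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.thin <= 0:
            raise ValueError("n_iterations and thin must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if (self.n_iterations - self.burn_in) % self.thin != 0:
            raise ValueError("(n_iterations - burn_in) must be divisible by thin")

    @property
    def n_retained(self) -> int:
        """Number of retained posterior draws N."""
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def scaled(cls, seed: int = 0, **kw) -> "MsnConfig":
        """Desk-scale schedule (5,000 iterations, N = 500 retained draws)."""
        kw.setdefault("n_iterations", 5000)
        kw.setdefault("burn_in", 2500)
        kw.setdefault("thin", 5)
        return cls(seed=seed, **kw)


@dataclass
class MsnPosterior:
    """Retained Gibbs draws and point summaries of one MSN fit."""

    site_ids: list[str]
    theta_chain: np.ndarray          # (N,)
    I_chains: np.ndarray             # (N, n_sites)
    p_hat: np.ndarray                # posterior-mean metacommunity simplex
    J: np.ndarray                    # per-site totals the fit used
    theta_median: float = field(init=False)
    I_medians: np.ndarray = field(init=False)
    M_value: float = field(init=False)
    m_i: np.ndarray = field(init=False)
    L0: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        if np.any(self.theta_chain <= 0) or np.any(self.I_chains <= 0):
            raise RuntimeError("posterior chains must be strictly positive")
        self.theta_median = float(np.median(self.theta_chain))
        self.I_medians = np.median(self.I_chains, axis=0)
        # M-value: mean over sites of the median immigration concentration
        self.M_value = float(np.mean(self.I_medians))
        self.m_i = self.I_medians / (self.I_medians + self.J - 1.0)


# ---------------------------------------------------------------------------
# likelihood components


def ewens_log_prob(species_counts, theta: float) -> float:
    """Log Ewens-sampling-formula probability of an unordered abundance
    configuration under a neutral (Dirichlet-process) pool.

    P = n! / theta_(n) * theta^S / (prod_s n_s * prod_j a_j!) where
    theta_(n) is the rising factorial and a_j the number of species with
    abundance j.
    """
    counts = np.asarray(species_counts)
    if counts.size == 0:
        raise ValueError("species_counts must be non-empty")
    if np.any(counts < 1):
        raise ValueError("species abundances must all be >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive")
    n = int(counts.sum())
    S = counts.size
    _, mult = np.unique(counts, return_counts=True)
    logp = (
        gammaln(n + 1)
        - (gammaln(theta + n) - gammaln(theta))
        + S * np.log(theta)
        - np.sum(np.log(counts))
        - np.sum(gammaln(mult + 1.0))
    )
    return float(logp)


def dirmult_log_prob(local_counts, props, I: float) -> float:
    """Log Dirichlet-multinomial probability of ``local_counts`` with
    concentration vector ``I * props``.

    A zero entry of ``props`` carrying a positive count gives -inf (the
    configuration is impossible), not an exception.
    """
    counts = np.asarray(local_counts, dtype=float)
    p = np.asarray(props, dtype=float)
    if counts.shape != p.shape:
        raise ValueError("counts and props must have the same length")
    if I <= 0:
        raise ValueError("immigration concentration I must be positive")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("props must sum to 1")
    if np.any(counts[p == 0] > 0):
        return -np.inf
    J = counts.sum()
    pos = counts > 0
    a = I * p[pos]
    logp = (
        gammaln(J + 1)
        - np.sum(gammaln(counts[pos] + 1))
        + gammaln(I)
        - gammaln(I + J)
        + np.sum(gammaln(a + counts[pos]) - gammaln(a))
    )
    return float(logp)


def msn_log_likelihood(sample: MetacommunitySample, theta: float, I, props) -> float:
    """Joint MSN log-likelihood: sum of per-site Dirichlet-multinomial terms
    plus the Ewens term for the pooled metacommunity abundances.

    This is the L quantity all neutrality comparisons use.
    """
    I = np.atleast_1d(np.asarray(I, dtype=float))
    if I.size != sample.n_sites:
        raise ValueError("need one immigration concentration per site")
    total = ewens_log_prob(sample.species_totals(), theta)
    for i in range(sample.n_sites):
        total += dirmult_log_prob(sample.counts[i], props, I[i])
    return float(total)


# ---------------------------------------------------------------------------
# ancestor-count (Antoniak) draws


@lru_cache(maxsize=4096)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, t)| for t = 1..n, unsigned Stirling numbers of the first
    kind, by the triangular recursion carried in log space."""
    row = np.array([0.0])  # n = 1
    for m in range(1, n):
        new = np.full(m + 1, -np.inf)
        new[1:] = row                                  # |s(m, t-1)|
        with np.errstate(divide="ignore"):
            shifted = row + np.log(m)                  # m * |s(m, t)|
        new[:m] = np.logaddexp(new[:m], shifted)
        row = new
    return tuple(row)


def ancestor_count_log_pmf(n: int, a: float) -> np.ndarray:
    """Exact log pmf of the ancestor (table) count t in 1..n:
    P(t) = |s(n,t)| a^t / a_(n).  Used as the analytic reference for the
    sequential sampler."""
    if n < 1 or a <= 0:
        raise ValueError("need n >= 1 and a > 0")
    ls = np.array(_log_stirling_row(n))
    t = np.arange(1, n + 1)
    logp = ls + t * np.log(a) - (gammaln(a + n) - gammaln(a))
    return logp - logsumexp(logp)  # guard rounding; sums to 1 analytically


def sample_ancestor_counts(n: int, a: float, rng: Generator) -> int:
    """Draw the number of immigration ancestors t for n individuals of one
    taxon at one site, t ~ |s(n,t)| a^t / a_(n).

    Uses the exact sequential construction: seating n customers at a CRP
    with concentration a, t is the number of tables opened, i.e. a sum of
    independent Bernoulli(a / (a + j)) for j = 0..n-1.
    """
    if a <= 0:
        raise ValueError("concentration a must be positive")
    if n == 0:
        return 0
    j = np.arange(n)
    return int(np.count_nonzero(rng.random(n) * (a + j) < a))


# ---------------------------------------------------------------------------
# concentration-parameter resampling (Escobar & West auxiliary scheme)


def _sample_concentration(
    cur: float, k: int, n: int, shape: float, rate: float, rng: Generator
) -> float:
    """Resample a Dirichlet-process concentration given k clusters among n
    observations, under a gamma(shape, rate) prior."""
    if n == 0:
        return float(rng.gamma(shape, 1.0 / rate))
    eta = rng.beta(cur + 1.0, n)
    b = rate - np.log(eta)
    odds = (shape + k - 1.0) / (n * b)
    if rng.random() < odds / (1.0 + odds):
        return float(rng.gamma(shape + k, 1.0 / b))
    return float(rng.gamma(shape + k - 1.0, 1.0 / b))


# ---------------------------------------------------------------------------
# the Gibbs sampler


def fit_msn_gibbs(sample: MetacommunitySample, config: MsnConfig) -> MsnPosterior:
    """Fit the MSN model by Chinese-restaurant-franchise Gibbs sampling.

    Per iteration: (1) for every site i and taxon s with n_is > 0 draw the
    ancestor count t_is from its exact conditional given a = I_i * p_s;
    (2) draw metacommunity proportions p ~ Dirichlet(T_1..T_S, theta) with
    T_s = sum_i t_is and the last mass an aggregate unseen component;
    (3) resample theta given the total table count and S dishes;
    (4) resample each I_i given (sum_s t_is, J_i).  Reproducible from
    ``config.seed``.
    """
    J = sample.J
    keep = J > 0
    if not keep.all():
        dropped = [s for s, k in zip(sample.site_ids, keep) if not k]
        logger.warning("dropping %d empty site(s): %s", len(dropped), dropped)
        sample = MetacommunitySample(
            [s for s, k in zip(sample.site_ids, keep) if k],
            sample.counts[keep],
        )
        J = sample.J

    rng = default_rng(np.random.SeedSequence(config.seed))
    counts = sample.counts
    n_sites, S = counts.shape

    # Fixed per-site scatter structure for the vectorized Bernoulli sums:
    # for each site, concatenate ranges 0..n_is-1 over its occupied taxa.
    site_taxa: list[np.ndarray] = []
    site_j: list[np.ndarray] = []
    site_seg: list[np.ndarray] = []
    for i in range(n_sites):
        tax = np.flatnonzero(counts[i])
        c = counts[i, tax]
        site_taxa.append(tax)
        site_j.append(np.concatenate([np.arange(ni) for ni in c]).astype(float))
        site_seg.append(np.repeat(np.arange(tax.size), c))

    theta = 1.0
    I = np.ones(n_sites)
    p = np.full(S + 1, 1.0 / (S + 1))  # last entry: unseen mass

    N = config.n_retained
    theta_chain = np.empty(N)
    I_chains = np.empty((N, n_sites))
    p_acc = np.zeros(S)
    kept = 0

    for it in range(config.n_iterations):
        T = np.zeros(S)
        tables_per_site = np.empty(n_sites)
        for i in range(n_sites):
            a = (I[i] * p[site_taxa[i]])[site_seg[i]]
            opened = rng.random(a.size) * (a + site_j[i]) < a
            t_i = np.bincount(site_seg[i], weights=opened, minlength=site_taxa[i].size)
            t_i = np.maximum(t_i, 1.0)  # j=0 term opens with prob 1
            T[site_taxa[i]] += t_i
            tables_per_site[i] = t_i.sum()

        p = rng.dirichlet(np.append(T, theta))
        if p[:S].min() <= 0:  # numerical underflow guard for tiny T_s
            p = np.clip(p, 1e-300, None)
            p /= p.sum()

        theta = _sample_concentration(
            theta, S, int(tables_per_site.sum()), *config.prior_theta, rng=rng
        )
        for i in range(n_sites):
            I[i] = _sample_concentration(
                I[i], int(tables_per_site[i]), int(J[i]), *config.prior_I, rng=rng
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            theta_chain[kept] = theta
            I_chains[kept] = I
            obs = p[:S] / p[:S].sum()
            p_acc += obs
            kept += 1

    assert kept == N
    p_hat = p_acc / N
    p_hat /= p_hat.sum()

    post = MsnPosterior(
        site_ids=list(sample.site_ids),
        theta_chain=theta_chain,
        I_chains=I_chains,
        p_hat=p_hat,
        J=J.astype(float),
    )
    post.L0 = msn_log_likelihood(sample, post.theta_median, post.I_medians, p_hat)
    return post
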