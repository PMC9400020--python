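"""Two-level pseudo-p neutrality test for the multi-site neutral model.

Communities are simulated from the fitted model at its posterior point
estimates and their log-likelihoods compared with the observed data's L0.
The metacommunity-level test redraws the species pool and the local samples
(the full neutral assembly); the local-level test holds the fitted
metacommunity proportions fixed and redraws only the local sampling step.
The pseudo-p is the fraction of simulations whose likelihood does not exceed
L0; a small value rejects neutrality at that level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.random import Generator, default_rng

from .bank import MetacommunitySample
from .msn import MsnPosterior, dirmult_log_prob, ewens_log_prob, msn_log_likelihood

logger = logging.getLogger(__name__)

__all__ = [
    "MsnNeutralityResult",
    "crp_pool_counts",
    "simulate_neutral_metacommunity",
    "simulate_neutral_locals",
    "msn_neutrality_test",
]


@dataclass
class MsnNeutralityResult:
    """Outputs of the two-level pseudo-p neutrality test (one table row)."""

    L0: float
    theta_median: float
    M_value: float
    L_M: float   # median log-likelihood of metacommunity-level simulations
    N_M: int     # simulations with L <= L0
    N: int
    L_L: float   # median log-likelihood of local-level simulations
    N_L: int

    @property
    def P_M(self) -> float:
        return self.N_M / self.N

    @property
    def P_L(self) -> float:
        return self.N_L / self.N

    @property
    def pass_meta(self) -> bool:
        """Metacommunity indistinguishable from the neutral model."""
        return self.P_M > 0.05

    @property
    def pass_local(self) -> bool:
        return self.P_L > 0.05


def _stick_breaking(theta: float, rng: Generator, max_atoms: int,
                    residual: float = 1e-9) -> np.ndarray:
    """Truncated GEM(theta) stick weights covering all but ``residual`` mass."""
    weights = []
    remaining = 1.0
    while remaining > residual:
        block = rng.beta(1.0, theta, size=min(max_atoms, 256))
        for v in block:
            w = remaining * v
            weights.append(w)
            remaining *= 1.0 - v
            if remaining <= residual:
                break
        if len(weights) >= max_atoms and remaining > residual:
            logger.info(
                "stick-breaking truncation %d left %.2e mass; enlarging",
                max_atoms, remaining,
            )
            max_atoms *= 2
    w = np.asarray(weights)
    return w / w.sum()


def crp_pool_counts(theta: float, n: int, rng: Generator,
                    max_atoms: int = 100_000) -> np.ndarray:
    """Species counts of a size-``n`` neutral metacommunity pool.

    Drawn as ``n`` iid picks from a stick-breaking Dirichlet-process
    realization, whose species-count marginal is exactly the Chinese
    restaurant / Ewens distribution with concentration ``theta``.
    """
    if theta <= 0 or n < 1:
        raise ValueError("need theta > 0 and n >= 1")
    sticks = _stick_breaking(theta, rng, max_atoms)
    counts = rng.multinomial(n, sticks)
    return counts[counts > 0]


def _dirmult_rvs(J: int, alpha: np.ndarray, rng: Generator) -> np.ndarray:
    """One Dirichlet-multinomial draw of total J with concentration alpha."""
    g = rng.gamma(np.maximum(alpha, 1e-300))
    tot = g.sum()
    if tot <= 0 or not np.isfinite(tot):  # all shapes underflowed
        g = np.zeros_like(alpha)
        g[int(np.argmax(alpha))] = 1.0
        tot = 1.0
    return rng.multinomial(J, g / tot)


def simulate_neutral_metacommunity(
    theta: float, I, J, rng: Generator, return_pool: bool = False
):
    """Simulate one metacommunity under the full neutral model.

    A species pool of ``sum(J)`` individuals is drawn by the Chinese
    restaurant construction with concentration ``theta``; each local
    community of size ``J_i`` is then drawn by a Polya urn (Dirichlet-
    multinomial) with immigration mass ``I_i`` against the realized pool
    proportions.
    """
    I = np.atleast_1d(np.asarray(I, dtype=float))
    J = np.atleast_1d(np.asarray(J, dtype=int))
    if np.any(I <= 0) or np.any(J < 1) or theta <= 0:
        raise ValueError("need theta > 0, I > 0, J >= 1")
    pool = crp_pool_counts(theta, int(J.sum()), rng)
    props = pool / pool.sum()
    rows = np.vstack([_dirmult_rvs(int(j), i * props, rng) for i, j in zip(I, J)])
    occupied = rows.sum(axis=0) > 0
    # keep at least one taxon per site guaranteed since J_i >= 1
    sample = MetacommunitySample(
        [f"site{i}" for i in range(len(J))], rows[:, occupied]
    )
    if return_pool:
        return sample, pool
    return sample


def simulate_neutral_locals(p_hat, I, J, rng: Generator) -> MetacommunitySample:
    """Redraw only the local sampling step against fixed metacommunity
    proportions ``p_hat`` (Dirichlet-multinomial with concentration
    ``I_i * p_hat`` per site)."""
    p = np.asarray(p_hat, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p_hat must be a simplex")
    I = np.atleast_1d(np.asarray(I, dtype=float))
    J = np.atleast_1d(np.asarray(J, dtype=int))
    rows = np.vstack([_dirmult_rvs(int(j), i * p, rng) for i, j in zip(I, J)])
    return MetacommunitySample([f"site{i}" for i in range(len(J))], rows)


def _meta_sim_log_likelihood(sim_counts: np.ndarray, pool: np.ndarray,
                             theta: float, I: np.ndarray) -> float:
    """L of a metacommunity-level simulation, conditioning the local terms on
    the realized pool proportions (restricted to taxa present in the
    simulated sample)."""
    occupied = sim_counts.sum(axis=0) > 0
    counts = sim_counts[:, occupied]
    props = pool[occupied] / pool[occupied].sum()
    total = ewens_log_prob(counts.sum(axis=0), theta)
    for i in range(counts.shape[0]):
        total += dirmult_log_prob(counts[i], props, I[i])
    return total


def msn_neutrality_test(
    sample: MetacommunitySample,
    posterior: MsnPosterior,
    N: int = 2500,
    rng: Generator | int | None = None,
) -> MsnNeutralityResult:
    """Two-level pseudo-p neutrality test against the fitted MSN model.

    For each of ``N`` simulations at each level, the joint log-likelihood is
    evaluated at the posterior point estimates (theta median, per-site I
    medians, posterior-mean proportions) and compared with L0; N_M and N_L
    count simulations with L <= L0, and P = N_*/N.
    """
    if N < 100:
        warnings.warn("N < 100 gives an unstable pseudo-p", stacklevel=2)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = default_rng(rng)
    theta = posterior.theta_median
    I = posterior.I_medians
    J = posterior.J.astype(int)
    p_hat = posterior.p_hat
    L0 = posterior.L0

    L_meta = np.empty(N)
    L_loc = np.empty(N)
    for k in range(N):
        sim_rows = np.vstack([
            _dirmult_rvs(int(j), i * p_hat, rng) for i, j in zip(I, J)
        ])
        occ = sim_rows.sum(axis=0) > 0
        loc_sample = MetacommunitySample(list(posterior.site_ids), sim_rows[:, occ])
        L_loc[k] = msn_log_likelihood(
            loc_sample, theta, I, p_hat[occ] / p_hat[occ].sum()
        )

        pool = crp_pool_counts(theta, int(J.sum()), rng)
        props = pool / pool.sum()
        meta_rows = np.vstack([
            _dirmult_rvs(int(j), i * props, rng) for i, j in zip(I, J)
        ])
        L_meta[k] = _meta_sim_log_likelihood(meta_rows, pool.astype(float), theta, I)

    N_M = int(np.count_nonzero(L_meta <= L0))
    N_L = int(np.count_nonzero(L_loc <= L0))
    return MsnNeutralityResult(
        L0=L0,
        theta_median=theta,
        M_value=posterior.M_value,
        L_M=float(np.median(L_meta)),
        N_M=N_M,
        N=N,
        L_L=float(np.median(L_loc)),
        N_L=N_L,
    )
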