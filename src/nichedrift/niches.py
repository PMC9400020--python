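"""Niche detection from pairwise migration-rate estimates.

Fitting the MSN model to every pair of sites yields a site-by-site matrix of
M-values (mean median immigration concentrations).  Migration homogenizes
communities, so a large pairwise M marks similar sites; clustering the
M-matrix partitions sites into niches, and contrasts of M and theta against
a focal site (e.g. stool against the oral sites) quantify dispersal
asymmetries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from zlib import crc32

import numpy as np
from numpy.random import Generator, default_rng
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .bank import MetacommunitySample, SiteSampleBank
from .msn import MsnConfig, fit_msn_gibbs

logger = logging.getLogger(__name__)

__all__ = [
    "PairwiseMsnMatrix",
    "NicheClustering",
    "pairwise_msn_matrix",
    "cluster_sites",
    "dispersal_contrast",
]


@dataclass
class PairwiseMsnMatrix:
    """Site x site mean M-values and per-site theta from pairwise MSN fits."""

    site_ids: list[str]
    M: np.ndarray        # symmetric, diagonal from same-site individual pairs
    theta: np.ndarray    # per-site mean theta over that site's pairwise fits
    n_pairs: int         # number of off-diagonal pairs fitted


@dataclass
class NicheClustering:
    labels: dict[str, int]
    K_selected: int
    silhouette_by_K: dict[int, float]


def pairwise_msn_matrix(
    bank: SiteSampleBank,
    config: MsnConfig | None = None,
    n_draws_per_pair: int = 30,
    rng: Generator | int | None = None,
) -> PairwiseMsnMatrix:
    """Fit a two-site MSN model to every unordered site pair.

    For each pair (including same-site pairs for the diagonal, drawn from
    two distinct individuals), ``n_draws_per_pair`` random individual pairs
    are fitted and the M-value and theta averaged.  Per-site theta is the
    mean over all pairwise fits involving that site.

    Randomness for each pair is derived from the root seed and the pair's
    site labels, so the matrix is equivariant under permutations of the
    bank's site order.
    """
    if config is None:
        config = MsnConfig.scaled()
    if isinstance(rng, Generator):
        root_seed = int(rng.integers(2**31))
    else:
        root_seed = int(rng) if rng is not None else 0

    usable = [i for i, s in enumerate(bank.samples) if s.shape[0] >= 2]
    skipped = [bank.site_ids[i] for i in range(bank.n_sites) if i not in usable]
    if skipped:
        logger.warning("excluding sites with < 2 individuals: %s", skipped)
    if len(usable) < 2:
        raise ValueError("need at least two sites with >= 2 individuals")
    ids = [bank.site_ids[i] for i in usable]
    k = len(usable)

    M = np.zeros((k, k))
    theta_sums = np.zeros(k)
    theta_n = np.zeros(k)
    for a in range(k):
        for b in range(a, k):
            ia, ib = usable[a], usable[b]
            ha, hb = sorted(
                (crc32(ids[a].encode()), crc32(ids[b].encode()))
            )
            m_vals, th_vals = [], []
            for d in range(n_draws_per_pair):
                seq = np.random.SeedSequence([root_seed, ha, hb, d])
                pair_rng = default_rng(seq)
                if a == b:
                    ja, jb = pair_rng.choice(
                        bank.samples[ia].shape[0], 2, replace=False
                    )
                elif ids[a] <= ids[b]:  # draw in label order: equivariance
                    ja = pair_rng.integers(bank.samples[ia].shape[0])
                    jb = pair_rng.integers(bank.samples[ib].shape[0])
                else:
                    jb = pair_rng.integers(bank.samples[ib].shape[0])
                    ja = pair_rng.integers(bank.samples[ia].shape[0])
                members = [(ids[a], bank.samples[ia][ja]),
                           (ids[b], bank.samples[ib][jb])]
                members.sort(key=lambda t: t[0])  # row order label-canonical
                pair = MetacommunitySample(
                    [f"{members[0][0]}#1", f"{members[1][0]}#2"],
                    np.vstack([members[0][1], members[1][1]]),
                )
                cfg = MsnConfig(
                    n_iterations=config.n_iterations, burn_in=config.burn_in,
                    thin=config.thin, prior_theta=config.prior_theta,
                    prior_I=config.prior_I,
                    seed=int(pair_rng.integers(2**31)),
                    truncation=config.truncation,
                )
                post = fit_msn_gibbs(pair, cfg)
                m_vals.append(post.M_value)
                th_vals.append(post.theta_median)
            M[a, b] = M[b, a] = float(np.mean(m_vals))
            theta_sums[a] += float(np.sum(th_vals))
            theta_n[a] += len(th_vals)
            if b != a:
                theta_sums[b] += float(np.sum(th_vals))
                theta_n[b] += len(th_vals)
    return PairwiseMsnMatrix(
        site_ids=ids, M=M, theta=theta_sums / theta_n,
        n_pairs=k * (k - 1) // 2,
    )


def cluster_sites(matrix: PairwiseMsnMatrix, K_range=None,
                  constant_tol: float = 1e-9) -> NicheClustering:
    """Partition sites into niches from the M-matrix.

    M is converted to the distance d(a,b) = 1 - M_ab / max(M) (invariant to
    monotone rescaling of M), clustered by average-linkage agglomeration,
    and K chosen by maximum average silhouette over ``K_range``.  A matrix
    constant within tolerance returns a single cluster.
    """
    n = len(matrix.site_ids)
    if K_range is None:
        K_range = range(2, min(n - 1, 8) + 1)
    K_range = [int(K) for K in K_range]
    if not K_range:
        raise ValueError("K_range must be non-empty")
    if any(K < 1 or K > n for K in K_range):
        raise ValueError("K_range must lie within [1, number of sites]")
    if np.ptp(matrix.M) <= constant_tol:
        return NicheClustering(
            labels={s: 0 for s in matrix.site_ids}, K_selected=1,
            silhouette_by_K={1: np.nan},
        )
    D = 1.0 - matrix.M / matrix.M.max()
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)

    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for K in K_range:
        if K < 2 or K > n - 1:
            continue  # silhouette undefined
        model = AgglomerativeClustering(
            n_clusters=K, metric="precomputed", linkage="average"
        )
        lab = model.fit_predict(D)
        scores[K] = float(silhouette_score(D, lab, metric="precomputed"))
        labelings[K] = lab
    if not scores:
        raise ValueError("no K in K_range admits a silhouette score")
    K_sel = max(scores, key=lambda K: scores[K])
    return NicheClustering(
        labels={s: int(l) for s, l in zip(matrix.site_ids, labelings[K_sel])},
        K_selected=K_sel,
        silhouette_by_K=scores,
    )


def dispersal_contrast(matrix: PairwiseMsnMatrix, focal_site: str) -> dict:
    """Contrast migration and diversity of a focal site against the rest.

    Returns the mean M between the focal site and the others, the mean M
    among the others, their ratio, the analogous theta contrast, and a
    Wilcoxon rank-sum p-value comparing the two sets of M values.
    """
    if focal_site not in matrix.site_ids:
        raise ValueError(f"unknown focal site {focal_site!r}")
    n = len(matrix.site_ids)
    if n < 3:
        raise ValueError("need at least 2 non-focal sites")
    f = matrix.site_ids.index(focal_site)
    others = [i for i in range(n) if i != f]
    m_focal = matrix.M[f, others]
    iu = [(a, b) for ai, a in enumerate(others) for b in others[ai + 1:]]
    m_among = np.array([matrix.M[a, b] for a, b in iu])
    theta_focal = float(matrix.theta[f])
    theta_others = float(np.mean(matrix.theta[others]))
    ranksum = stats.mannwhitneyu(m_focal, m_among, alternative="two-sided")
    return {
        "focal_site": focal_site,
        "mean_M_focal_vs_others": float(np.mean(m_focal)),
        "mean_M_among_others": float(np.mean(m_among)),
        "M_ratio": float(np.mean(m_focal) / np.mean(m_among)),
        "theta_focal": theta_focal,
        "theta_others_mean": theta_others,
        "theta_ratio": theta_focal / theta_others,
        "ranksum_p": float(ranksum.pvalue),
    }
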