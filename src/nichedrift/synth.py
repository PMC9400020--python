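"""Synthetic site-sample banks with known ground truth.

Emulates the shape of multi-site digestive-tract 16S surveys — about 10
sites, about 200 individuals per site, per-sample totals in the thousands,
per-niche richness of a few dozen species — under three regimes spanning the
niche-neutral continuum:

``neutral``
    one metacommunity pool shared by all sites; every sample is a
    Dirichlet-multinomial draw against the pool (pure drift + dispersal).
``nnh``
    K niche pools with niche-specific biodiversity theta_k and migration
    m_k, overlap-controlled taxon sharing between niches; neutral sampling
    within each niche (niche differentiation between, drift within).
``niche``
    disjoint fixed site compositions with only multinomial sampling noise
    (deterministic selection dominant).

Generation is at the OTU-count level; read-level artifacts (chimeras, copy
number) are out of scope.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from numpy.random import default_rng

from .bank import SiteSampleBank
from .neutrality import _dirmult_rvs, _stick_breaking

__all__ = ["SyntheticConfig", "simulate_bank", "table3_like_bank"]

_POOL_SIZE = 50_000  # individuals realized per CRP pool construction


@dataclass
class SyntheticConfig:
    regime: str
    n_sites: int = 10
    n_individuals: int = 200
    J_target: int = 5000
    J_sigma: float = 0.3                  # log-normal depth jitter
    theta: float | list[float] = 30.0     # scalar (neutral) or per-niche list
    m: float | list[float] = 0.005        # migration probability per site/niche
    niche_map: dict[str, int] | None = None
    overlap: float = 0.1
    seed: int = 0
    taxa_per_site: int = 40               # niche regime block width

    def __post_init__(self) -> None:
        if self.regime not in ("neutral", "nnh", "niche"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if self.J_target < 100:
            raise ValueError("J_target must be >= 100")
        ms = np.atleast_1d(np.asarray(self.m, dtype=float))
        if np.any((ms <= 0) | (ms >= 1)):
            raise ValueError("migration probabilities must lie in (0, 1)")

    def to_dict(self) -> dict:
        """JSON-serializable form of the generating truth."""
        d = asdict(self)
        if isinstance(d["theta"], np.ndarray):
            d["theta"] = list(d["theta"])
        if isinstance(d["m"], np.ndarray):
            d["m"] = list(d["m"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


def _site_ids(n: int) -> list[str]:
    return [f"S{i}" for i in range(n)]


def _immigration(m: float, J: int) -> float:
    """Concentration I matching migration probability m at sample size J."""
    return m * (J - 1) / (1.0 - m)


def _draw_J(cfg: SyntheticConfig, rng) -> int:
    J = int(round(rng.lognormal(np.log(cfg.J_target), cfg.J_sigma)))
    return max(J, 100)


def _crp_pool_props(theta: float, rng, n: int = _POOL_SIZE) -> np.ndarray:
    sticks = _stick_breaking(theta, rng, max_atoms=100_000)
    counts = rng.multinomial(n, sticks)
    counts = counts[counts > 0]
    return counts / counts.sum()


def simulate_bank(config: SyntheticConfig) -> SiteSampleBank:
    """Generate a bank under ``config``; the generating truth is recorded."""
    rng = default_rng(np.random.SeedSequence(config.seed))
    ids = _site_ids(config.n_sites)

    if config.regime == "neutral":
        pool = _crp_pool_props(float(np.asarray(config.theta).ravel()[0]), rng)
        m_per_site = np.broadcast_to(
            np.atleast_1d(np.asarray(config.m, dtype=float)), (config.n_sites,)
        )
        samples = []
        for i in range(config.n_sites):
            rows = []
            for _ in range(config.n_individuals):
                J = _draw_J(config, rng)
                I = _immigration(m_per_site[i], J)
                rows.append(_dirmult_rvs(J, I * pool, rng))
            samples.append(np.vstack(rows))
        taxa = [f"T{k}" for k in range(pool.size)]
        return SiteSampleBank(ids, samples, taxon_ids=taxa, truth=config)

    if config.regime == "nnh":
        niche_map = config.niche_map or {s: k for k, s in enumerate(ids)}
        niches = sorted(set(niche_map[s] for s in ids))
        K = len(niches)
        thetas = np.broadcast_to(
            np.atleast_1d(np.asarray(config.theta, dtype=float)), (K,)
        )
        ms = np.broadcast_to(
            np.atleast_1d(np.asarray(config.m, dtype=float)), (K,)
        )
        shared = _crp_pool_props(float(np.mean(thetas)), rng)
        own = [_crp_pool_props(thetas[k], rng) for k in range(K)]
        # global index: [shared block | niche 0 block | niche 1 block | ...]
        offs = np.cumsum([shared.size] + [o.size for o in own])
        n_taxa = int(offs[-1])
        niche_pool = np.zeros((K, n_taxa))
        for k in range(K):
            niche_pool[k, : shared.size] = config.overlap * shared
            niche_pool[k, offs[k]:offs[k + 1]] = (1.0 - config.overlap) * own[k]
        samples = []
        for i, s in enumerate(ids):
            k = niches.index(niche_map[s])
            rows = []
            for _ in range(config.n_individuals):
                J = _draw_J(config, rng)
                I = _immigration(ms[k], J)
                rows.append(_dirmult_rvs(J, I * niche_pool[k], rng))
            samples.append(np.vstack(rows))
        taxa = [f"T{k}" for k in range(n_taxa)]
        return SiteSampleBank(ids, samples, taxon_ids=taxa, truth=config)

    # niche regime: fixed disjoint compositions, multinomial noise only
    B = config.taxa_per_site
    n_taxa = B * config.n_sites
    comps = np.zeros((config.n_sites, n_taxa))
    for i in range(config.n_sites):
        comps[i, i * B:(i + 1) * B] = rng.dirichlet(np.full(B, 0.8))
    samples = []
    for i in range(config.n_sites):
        rows = [
            rng.multinomial(_draw_J(config, rng), comps[i])
            for _ in range(config.n_individuals)
        ]
        samples.append(np.vstack(rows))
    taxa = [f"T{k}" for k in range(n_taxa)]
    return SiteSampleBank(ids, samples, taxon_ids=taxa, truth=config)


# site -> group layout mimicking the five-niche digestive-tract structure:
# two plaque-like pairs, one four-site saliva-like group, plus two
# standalone sites (a weakly coupled KG analogue and a high-diversity
# stool analogue).
TABLE3_GROUPS: dict[str, int] = {
    "BM": 0, "HP": 0,
    "KG": 1,
    "Sal": 2, "PT": 2, "Th": 2, "TD": 2,
    "SubP": 3, "SupP": 3,
    "Stool": 4,
}


def table3_like_bank(
    seed: int = 0,
    n_individuals: int = 12,
    J_target: int = 600,
) -> SiteSampleBank:
    """A 10-site bank with a planted five-group coupling structure.

    Sites within a group share one niche pool and are sampled with high
    migration (similar individuals, hence high pairwise M); the oral-type
    groups additionally share a small common taxon fraction, as oral sites
    do.  The KG analogue is a standalone weakly coupled niche; the stool
    analogue is a standalone, fully disjoint niche with a several-fold
    richer pool and deeper samples, so its fitted theta dominates while its
    pairwise coupling stays low.
    """
    rng = default_rng(np.random.SeedSequence([seed, 0x7AB1E3]))
    ids = list(TABLE3_GROUPS)
    groups = sorted(set(TABLE3_GROUPS.values()))
    theta_by_group = {0: 18.0, 1: 16.0, 2: 18.0, 3: 20.0, 4: 300.0}
    m_by_group = {0: 0.12, 1: 0.035, 2: 0.12, 3: 0.10, 4: 0.02}
    J_factor_by_group = {0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 2.0}
    oral_shared = 0.2  # mass fraction oral-type groups draw from a common pool
    pools = {g: _crp_pool_props(theta_by_group[g], rng, n=20_000) for g in groups}
    shared = _crp_pool_props(20.0, rng, n=20_000)
    offs = np.cumsum([shared.size] + [pools[g].size for g in groups])
    n_taxa = int(offs[-1])

    samples = []
    for s in ids:
        g = TABLE3_GROUPS[s]
        gi = groups.index(g)
        alpha_full = np.zeros(n_taxa)
        if g == 4:  # stool: no taxa in common with the oral sites
            alpha_full[offs[gi]:offs[gi + 1]] = pools[g]
        else:
            alpha_full[: shared.size] = oral_shared * shared
            alpha_full[offs[gi]:offs[gi + 1]] = (1 - oral_shared) * pools[g]
        rows = []
        for _ in range(n_individuals):
            J = max(100, int(round(rng.lognormal(
                np.log(J_target * J_factor_by_group[g]), 0.2))))
            I = _immigration(m_by_group[g], J)
            rows.append(_dirmult_rvs(J, I * alpha_full, rng))
        samples.append(np.vstack(rows))
    taxa = [f"T{k}" for k in range(n_taxa)]
    cfg = SyntheticConfig(
        regime="nnh", n_sites=len(ids), n_individuals=n_individuals,
        J_target=max(J_target, 100), theta=[theta_by_group[g] for g in groups],
        m=[m_by_group[g] for g in groups],
        niche_map=dict(TABLE3_GROUPS), overlap=0.0, seed=seed,
    )
    return SiteSampleBank(ids, samples, taxon_ids=taxa, truth=cfg)
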