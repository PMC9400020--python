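"""Containers for multi-site community count data.

A :class:`SiteSampleBank` holds, for each body site, a collection of
per-individual taxon count vectors on a shared global taxon index — the raw
input of the whole pipeline.  A :class:`MetacommunitySample` is one count
vector per site (one individual drawn per site), the unit on which the
multi-site neutral and niche-neutral hybrid models are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class MetacommunitySample:
    """Counts for one metacommunity: ``sites x taxa`` on a shared taxon index.

    Taxa absent from every site are dropped at construction; sites with a
    zero total are invalid (drop them before constructing).
    """

    site_ids: list[str]
    counts: np.ndarray  # (n_sites, n_taxa) non-negative ints
    taxon_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D sites x taxa matrix")
        if len(self.site_ids) != self.counts.shape[0]:
            raise ValueError("site_ids length does not match counts rows")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        keep = self.counts.sum(axis=0) > 0
        if not keep.all():
            self.counts = self.counts[:, keep]
            if self.taxon_ids is not None:
                self.taxon_ids = [t for t, k in zip(self.taxon_ids, keep) if k]
        if np.any(self.counts.sum(axis=1) < 1):
            raise ValueError("every retained site needs J_i >= 1")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def J(self) -> np.ndarray:
        """Per-site total individuals (row sums)."""
        return self.counts.sum(axis=1)

    def species_totals(self) -> np.ndarray:
        """Metacommunity abundance of each taxon (column sums, all > 0)."""
        return self.counts.sum(axis=0)


@dataclass
class SiteSampleBank:
    """Per-site lists of per-individual count vectors on a global taxon index.

    ``samples[i]`` is an ``(n_individuals_i, n_taxa)`` integer matrix for site
    ``site_ids[i]``.  ``truth`` optionally records the generating synthetic
    configuration (absent for real data).
    """

    site_ids: list[str]
    samples: list[np.ndarray]
    taxon_ids: list[str] | None = None
    truth: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.site_ids) != len(self.samples):
            raise ValueError("site_ids and samples length mismatch")
        self.samples = [np.asarray(s, dtype=np.int64) for s in self.samples]
        widths = {s.shape[1] for s in self.samples}
        if len(widths) > 1:
            raise ValueError("all sites must share one global taxon index")
        for sid, s in zip(self.site_ids, self.samples):
            if np.any(s < 0):
                raise ValueError(f"negative counts in site {sid}")
            if np.any(s.sum(axis=1) < 1):
                raise ValueError(f"empty sample (total 0) in site {sid}")
        total = sum(s.sum(axis=0) for s in self.samples)
        keep = total > 0
        if not keep.all():  # taxa never observed anywhere carry no signal
            self.samples = [s[:, keep] for s in self.samples]
            if self.taxon_ids is not None:
                self.taxon_ids = [t for t, k in zip(self.taxon_ids, keep) if k]

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_taxa(self) -> int:
        return self.samples[0].shape[1]

    def n_individuals(self) -> list[int]:
        return [s.shape[0] for s in self.samples]

    def metacommunity(self, individual_indices: Sequence[int]) -> MetacommunitySample:
        """Assemble one metacommunity: individual ``individual_indices[i]``
        from site ``i``."""
        if len(individual_indices) != self.n_sites:
            raise ValueError("need one individual index per site")
        rows = [self.samples[i][j] for i, j in enumerate(individual_indices)]
        return MetacommunitySample(
            site_ids=list(self.site_ids),
            counts=np.vstack(rows),
            taxon_ids=list(self.taxon_ids) if self.taxon_ids else None,
        )
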