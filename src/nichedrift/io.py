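"""OTU-table reading/writing and result serialization.

Input dialect: tab-separated taxa x samples count matrix (first column taxon
ids, remaining columns sample ids) plus a sample-metadata table mapping
sample id to site label — the common 16S OTU-table export.  Results are
written as CSVs in the standard MSN / NNH / per-site summary column layouts
plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import SiteSampleBank
from .neutrality import MsnNeutralityResult
from .niches import PairwiseMsnMatrix
from .nnh import NnhMetaResult
from .pipeline import DuoSummary

logger = logging.getLogger(__name__)

__all__ = [
    "read_bank", "write_bank", "write_results",
    "msn_results_frame", "nnh_results_frame", "site_summary_frame",
]

MSN_COLUMNS = ["ID", "L_O", "theta", "M-value",
               "L_M", "N_M", "N", "P_M", "L_L", "N_L", "P_L"]
NNH_COLUMNS = ["ID", "J", "S", "theta", "m", "x", "gamma",
               "R2", "chi2", "P-value", "N", "N_pass", "pct_pass"]


def read_bank(counts_path, metadata_path) -> SiteSampleBank:
    """Read a taxa x samples TSV and its sample->site metadata into a bank.

    Taxa with zero total are dropped (logged); a sample present in the count
    table but absent from the metadata (or vice versa) is a hard error.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"sample_id", "site"} <= set(meta.columns):
        raise ValueError("metadata needs 'sample_id' and 'site' columns")
    meta_map = dict(zip(meta.sample_id.astype(str), meta.site.astype(str)))

    unknown = [c for c in counts.columns if c not in meta_map]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown}")
    absent = [s for s in meta_map if s not in counts.columns]
    if absent:
        raise ValueError(f"metadata samples missing from counts: {absent}")

    values = counts.to_numpy()
    if not np.allclose(values, np.round(values)):
        bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(
            f"non-integer count at taxon {counts.index[bad[0]]!r}, "
            f"sample {counts.columns[bad[1]]!r}"
        )
    values = values.astype(np.int64)

    keep = values.sum(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d all-zero taxa", dropped)
    values = values[keep]
    taxon_ids = list(counts.index[keep].astype(str))

    site_ids = sorted(set(meta_map.values()))
    samples = []
    for site in site_ids:
        cols = [i for i, c in enumerate(counts.columns) if meta_map[c] == site]
        samples.append(values[:, cols].T.copy())
    return SiteSampleBank(site_ids, samples, taxon_ids=taxon_ids)


def write_bank(bank: SiteSampleBank, counts_path, metadata_path) -> None:
    """Write a bank in the same TSV dialect ``read_bank`` consumes."""
    taxon_ids = bank.taxon_ids or [f"T{k}" for k in range(bank.n_taxa)]
    cols, names, sites = [], [], []
    for site, mat in zip(bank.site_ids, bank.samples):
        for j in range(mat.shape[0]):
            cols.append(mat[j])
            names.append(f"{site}.{j}")
            sites.append(site)
    df = pd.DataFrame(np.column_stack(cols), index=taxon_ids, columns=names)
    df.index.name = "taxon_id"
    df.to_csv(counts_path, sep="\t")
    pd.DataFrame({"sample_id": names, "site": sites}).to_csv(
        metadata_path, sep="\t", index=False
    )


def msn_results_frame(results: list[MsnNeutralityResult],
                      ids=None) -> pd.DataFrame:
    """One row per metacommunity in the standard MSN result layout."""
    ids = list(ids) if ids is not None else list(range(1, len(results) + 1))
    rows = [
        [i, r.L0, r.theta_median, r.M_value,
         r.L_M, r.N_M, r.N, r.P_M, r.L_L, r.N_L, r.P_L]
        for i, r in zip(ids, results)
    ]
    return pd.DataFrame(rows, columns=MSN_COLUMNS)


def nnh_results_frame(results: list[NnhMetaResult], ids=None) -> pd.DataFrame:
    """One row per metacommunity in the standard NNH result layout (the
    parameter columns are means over included niches)."""
    ids = list(ids) if ids is not None else list(range(1, len(results) + 1))
    rows = []
    for i, r in zip(ids, results):
        mean = r.means()
        rows.append([
            i, mean["J"], mean["S"], mean["theta"], mean["m"], mean["x"],
            mean["gamma"], mean["R2"], r.chi2_total, r.p_meta,
            r.N, r.N_pass, r.pct_pass,
        ])
    return pd.DataFrame(rows, columns=NNH_COLUMNS)


def site_summary_frame(matrix: PairwiseMsnMatrix) -> pd.DataFrame:
    """Per-site mean theta and M (mean over that site's pairings)."""
    n = len(matrix.site_ids)
    m_means = [
        float(np.mean([matrix.M[i, j] for j in range(n) if j != i]))
        for i in range(n)
    ]
    return pd.DataFrame({
        "Site": matrix.site_ids,
        "theta": matrix.theta,
        "M": m_means,
    })


def write_results(results, out_dir) -> list[Path]:
    """Serialize any pipeline result object; returns the files written.

    CSV column orders are fixed, so re-running with an identical
    configuration reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    if isinstance(results, MsnNeutralityResult):
        _csv(msn_results_frame([results]), "msn_results.csv")
    elif isinstance(results, NnhMetaResult):
        _csv(nnh_results_frame([results]), "nnh_results.csv")
    elif isinstance(results, PairwiseMsnMatrix):
        mdf = pd.DataFrame(results.M, index=results.site_ids,
                           columns=results.site_ids)
        mdf.index.name = "Site"
        path = out / "pairwise_M.csv"
        mdf.to_csv(path, float_format="%.6g")
        written.append(path)
        _csv(site_summary_frame(results), "site_summary.csv")
    elif isinstance(results, DuoSummary):
        _csv(results.rows, "duo_replicates.csv")
        summary = {
            "pct_msn_meta_pass": results.pct_msn_meta_pass,
            "pct_msn_local_pass": results.pct_msn_local_pass,
            "pct_nnh_meta_niche": results.pct_nnh_meta_niche,
            "pct_nnh_local_neutral": results.pct_nnh_local_neutral,
            "crosstab": results.crosstab,
            "n_failed": results.n_failed,
        }
        path = out / "duo_summary.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(path)
    else:
        raise TypeError(f"cannot serialize result of type {type(results)!r}")
    return written
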