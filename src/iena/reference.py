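"""Sparse-OTU filtering and baseline reference statistics.

All single-sample correlation machinery is calibrated against a *reference
group*: the baseline (pre-challenge / first-visit) samples pooled across
subjects.  From these we compute, per OTU, the reference mean mu and
*population* standard deviation sigma (divide by n_ref, not n_ref - 1), and,
per OTU pair, the reference Pearson correlation rho.

Population normalisation is deliberate: with z = (x - mu) / sigma, the
average of the single-sample product z_x * z_y over the reference samples
equals rho(x, y) *exactly*, which makes the single-sample correlation an
unbiased per-sample decomposition of the reference correlation.  The same
identity holds one level up for edge variables (see
:func:`compute_edge_reference_stats`), and both are asserted as oracles in
the test suite.

OTUs that are constant over the reference group (sigma == 0) cannot be
standardised and are dropped, never epsilon-patched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OTUTable, SampleMetadata

__all__ = [
    "ReferenceStats",
    "EdgeReferenceStats",
    "filter_otus",
    "compute_reference_stats",
    "compute_edge_reference_stats",
    "zscore_matrix",
]


@dataclass
class ReferenceStats:
    """Per-OTU and per-pair statistics of the reference group.

    Attributes
    ----------
    otu_ids : list of kept OTU ids (order matches ``mu``/``sigma``/``rho``)
    mu, sigma : reference mean and population SD per kept OTU
    rho : kept-OTU pairwise reference Pearson correlation matrix
    n_ref : number of reference samples used
    dropped : (otu_id, reason) pairs, reason in {"sparse", "zero_variance"}
    """

    otu_ids: pd.Index
    mu: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    n_ref: int
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def index_of(self, otu_ids) -> np.ndarray:
        idx = self.otu_ids.get_indexer(list(otu_ids))
        if (idx < 0).any():
            missing = [o for o, i in zip(otu_ids, idx) if i < 0]
            raise KeyError(f"OTU(s) not in reference statistics: {missing[:5]}")
        return idx

    def dropped_report(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["otu_id", "reason"])


@dataclass
class EdgeReferenceStats:
    """Reference calibration of edge (OTU-pair) product variables.

    For an edge e = (x, y) the per-sample edge variable is E = z_x * z_y.
    ``m`` is its reference mean — equal to rho(x, y) by the population
    identity — and ``t`` its reference population SD.  Edges whose product is
    constant over the reference (t == 0) are unusable and recorded in
    ``dropped_edges``.
    """

    edges: list[tuple[str, str]]
    m: np.ndarray
    t: np.ndarray
    dropped_edges: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)


def filter_otus(table: OTUTable, min_nonzero_frac: float = 0.85):
    """Drop OTUs whose fraction of non-zero samples is not strictly above
    ``min_nonzero_frac``.

    16S tables are heavily zero-inflated; OTUs observed in too few samples
    destabilise every division in the standardisation.  The comparison is
    strictly greater-than, so with threshold 0.85 an OTU non-zero in exactly
    85% of samples is dropped.

    Returns
    -------
    (filtered_table, dropped) where dropped is a list of removed OTU ids.
    """
    if not (0 < min_nonzero_frac <= 1):
        raise ValueError(f"min_nonzero_frac must be in (0, 1], got {min_nonzero_frac}")
    frac = (table.data.to_numpy() > 0).mean(axis=0)
    keep = frac > min_nonzero_frac
    if not keep.any():
        raise ValueError(
            f"no OTU exceeds non-zero fraction {min_nonzero_frac}; "
            "lower the threshold for this dataset"
        )
    dropped = [str(o) for o in table.otu_ids[~keep]]
    return table.subset_otus(table.otu_ids[keep]), dropped


def compute_reference_stats(table: OTUTable, metadata: SampleMetadata) -> ReferenceStats:
    """Compute mu, sigma (population) and rho from reference samples only.

    Zero-variance OTUs are moved to the dropped list with reason
    ``zero_variance`` and excluded from ``otu_ids``.
    """
    metadata.validate_against(table)
    ref_ids = metadata.reference_ids().intersection(table.sample_ids)
    n_ref = len(ref_ids)
    if n_ref < 2:
        raise ValueError(f"need at least 2 reference samples, found {n_ref}")
    X = table.data.loc[ref_ids].to_numpy(dtype=float)

    mu = X.mean(axis=0)
    sigma = X.std(axis=0)  # population SD (ddof=0)
    keep = sigma > 0
    dropped = [(str(o), "zero_variance") for o in table.otu_ids[~keep]]

    Xk = X[:, keep]
    Z = (Xk - mu[keep]) / sigma[keep]
    rho = (Z.T @ Z) / n_ref
    np.fill_diagonal(rho, 1.0)

    return ReferenceStats(
        otu_ids=table.otu_ids[keep],
        mu=mu[keep],
        sigma=sigma[keep],
        rho=rho,
        n_ref=n_ref,
        dropped=dropped,
    )


def zscore_matrix(table: OTUTable, stats: ReferenceStats) -> pd.DataFrame:
    """Standardise every sample against the reference: z = (x - mu) / sigma.

    Rows are samples, columns the kept OTUs of ``stats``.  Raises if the
    table lacks a kept OTU (filtering mismatch).
    """
    missing = stats.otu_ids.difference(table.otu_ids)
    if len(missing):
        raise KeyError(f"table is missing kept OTU {missing[0]!r}; filter/stats mismatch")
    X = table.data.loc[:, stats.otu_ids].to_numpy(dtype=float)
    Z = (X - stats.mu) / stats.sigma
    return pd.DataFrame(Z, index=table.sample_ids, columns=stats.otu_ids)


def compute_edge_reference_stats(
    table: OTUTable,
    metadata: SampleMetadata,
    stats: ReferenceStats,
    edges: list[tuple[str, str]],
) -> EdgeReferenceStats:
    """Reference mean and population SD of each edge's product variable.

    For every edge e = (x, y): over the reference samples, the per-sample
    product E = z_x * z_y has mean m_e (== rho(x, y), asserted to 1e-12) and
    population SD t_e.  Edges with t_e == 0 are dropped.
    """
    ref_ids = metadata.reference_ids().intersection(table.sample_ids)
    Z = zscore_matrix(table, stats).loc[ref_ids].to_numpy()

    ia = stats.index_of([a for a, _ in edges])
    ib = stats.index_of([b for _, b in edges])
    E = Z[:, ia] * Z[:, ib]  # n_ref × n_edges
    m = E.mean(axis=0)
    t = E.std(axis=0)

    # internal consistency: population identity mean(z_x z_y) == rho
    rho_e = stats.rho[ia, ib]
    err = np.max(np.abs(m - rho_e)) if len(edges) else 0.0
    if err > 1e-10:
        raise AssertionError(f"edge product mean deviates from rho by {err:g}")

    keep = t > 0
    kept_edges = [e for e, k in zip(edges, keep) if k]
    dropped = [e for e, k in zip(edges, keep) if not k]
    return EdgeReferenceStats(edges=kept_edges, m=m[keep], t=t[keep], dropped_edges=dropped)
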