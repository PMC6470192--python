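"""Single-sample node networks (sPCC), edge-pair networks (shPCC) and
individual edge-biomarker selection.

The single-sample Pearson correlation (sPCC) of an OTU pair (x, y) in sample
d is the product of the two standardised deviations,

    sPCC_d(x, y) = z_x * z_y,   z_x = (x_d - mu_x) / sigma_x,

with mu and sigma taken from the reference group.  Averaged over the
reference samples themselves this reproduces the reference correlation
rho(x, y) exactly (population normalisation), so each sample contributes one
term of the reference correlation — a per-sample correlation reading that
needs no within-subject replication.  sPCC is unbounded: a sample far from
baseline can carry |sPCC| >> 1.

One level up, an edge e = (x, y) carries the per-sample product variable
E_d = z_x * z_y.  Standardising E against its own reference mean m_e and
population SD t_e and multiplying two standardised edge deviations gives the
single-sample higher-order correlation between two edges,

    shPCC_d(e1, e2) = (E1_d - m_e1)/t_e1 * (E2_d - m_e2)/t_e2,

fourth-order in the raw abundances and obeying the same reference-average
identity (its reference mean is the Pearson correlation of the two edge
variables).

Networks are built by direct rank cut-off on |sPCC| / |shPCC| — the values
are not normally distributed, so no significance test is attached.  Ties are
broken lexicographically on OTU ids so outputs are bit-reproducible and
invariant to input column order.

A practical caveat of fourth-order single-sample statistics on compositional
data: one extremely deviating OTU creates a "star" of strong edges, and any
two star edges share that OTU and multiply its deviation twice.  The
``disjoint`` option of :func:`build_edge_network` therefore restricts
edge-pairs to edges with four distinct OTUs — a genuine fourth-order
association among four taxa — which the pipeline uses by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OTUTable
from .reference import EdgeReferenceStats, ReferenceStats, zscore_matrix

__all__ = [
    "NodeNetwork",
    "EdgeNetwork",
    "MarkerSet",
    "spcc_sample",
    "build_node_network",
    "shpcc_sample",
    "build_edge_network",
    "select_markers",
]


@dataclass
class NodeNetwork:
    """Top-k sPCC edges of one sample, sorted by |sPCC| descending."""

    sample_id: str
    edges: list[tuple[str, str]]  # canonical otu_a < otu_b
    spcc: np.ndarray
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "otu_a": [a for a, _ in self.edges],
                "otu_b": [b for _, b in self.edges],
                "spcc": self.spcc,
            }
        )


@dataclass
class EdgeNetwork:
    """Top-m shPCC edge-pairs of one sample, sorted by |shPCC| descending."""

    sample_id: str
    pairs: list[tuple[tuple[str, str], tuple[str, str]]]
    shpcc: np.ndarray
    m: int

    def strength(self) -> float:
        """Median |shPCC| over the retained pairs — the network's overall
        signal level, robust to a single extreme pair."""
        return float(np.median(np.abs(self.shpcc)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "edge1_a": [p[0][0] for p in self.pairs],
                "edge1_b": [p[0][1] for p in self.pairs],
                "edge2_a": [p[1][0] for p in self.pairs],
                "edge2_b": [p[1][1] for p in self.pairs],
                "shpcc": self.shpcc,
            }
        )


@dataclass
class MarkerSet:
    """Individual OTU(-pair) biomarkers for one subject.

    ``otus`` is the union of the constituent OTUs of the selected edge-pairs
    (the candidate DNB members); ``provenance`` records, per time point, the
    edge-pairs that contributed.
    """

    subject_id: str
    otus: set[str]
    provenance: dict[int, list[tuple[tuple[str, str], tuple[str, str]]]] = field(
        default_factory=dict
    )
    #: selection evidence per marker OTU (participation × deviation summed
    #: over contributing time points); empty when selected by plain pair rank
    weights: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tp in sorted(self.provenance):
            for (e1, e2) in self.provenance[tp]:
                rows.append(
                    {
                        "subject_id": self.subject_id,
                        "time_point": tp,
                        "edge1_a": e1[0],
                        "edge1_b": e1[1],
                        "edge2_a": e2[0],
                        "edge2_b": e2[1],
                    }
                )
        return pd.DataFrame(
            rows, columns=["subject_id", "time_point", "edge1_a", "edge1_b", "edge2_a", "edge2_b"]
        )


def _sample_z(
    sample_id: str, table: OTUTable, stats: ReferenceStats, z: np.ndarray | None = None
) -> np.ndarray:
    """Standardised profile of one sample; ``z`` short-circuits recomputation."""
    if z is not None:
        return np.asarray(z, dtype=float)
    if sample_id not in table.sample_ids:
        raise KeyError(f"sample {sample_id!r} not in table")
    return zscore_matrix(table.subset_otus(stats.otu_ids), stats).loc[sample_id].to_numpy()


def spcc_sample(sample_id: str, table: OTUTable, stats: ReferenceStats) -> pd.DataFrame:
    """All-pairs sPCC matrix of one sample (kept OTUs × kept OTUs).

    Symmetric, unbounded, zero row/column wherever the sample sits exactly at
    the reference mean of an OTU.
    """
    z = _sample_z(sample_id, table, stats)
    S = np.outer(z, z)
    return pd.DataFrame(S, index=stats.otu_ids, columns=stats.otu_ids)


def _top_k_desc(absvals: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values, ties broken by ascending index.

    The caller arranges candidate order so that ascending index equals
    lexicographic id order; a value-threshold partition keeps the selection
    exact under ties without sorting the full array.
    """
    n = absvals.size
    if k >= n:
        return np.argsort(-absvals, kind="stable")
    kth = np.partition(absvals, n - k)[n - k]
    cand = np.nonzero(absvals >= kth)[0]  # >= catches boundary ties
    cand = cand[np.argsort(-absvals[cand], kind="stable")]
    return cand[:k]


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        if len(_TRIU_CACHE) > 8:
            _TRIU_CACHE.clear()
        _TRIU_CACHE[n] = np.triu_indices(n, 1)
    return _TRIU_CACHE[n]


def build_node_network(
    sample_id: str,
    table: OTUTable,
    stats: ReferenceStats,
    k: int = 1500,
    z: np.ndarray | None = None,
) -> NodeNetwork:
    """The k strongest |sPCC| edges of one sample.

    The candidate universe is every unordered pair of kept OTUs; if fewer
    than k exist, all are returned.  Deterministic: sorted by |sPCC|
    descending, ties by (otu_a, otu_b).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    # lexicographic OTU order makes row-major triu order == pair lex order
    ids_raw = stats.otu_ids.to_numpy().astype(str)
    order = np.argsort(ids_raw)
    ids = ids_raw[order]
    zv = _sample_z(sample_id, table, stats, z)[order]
    iu, ju = _triu(len(ids))
    vals = zv[iu] * zv[ju]
    sel = _top_k_desc(np.abs(vals), k)
    edges = [(ids[i], ids[j]) for i, j in zip(iu[sel], ju[sel])]
    return NodeNetwork(sample_id=sample_id, edges=edges, spcc=vals[sel], k=k)


def _edge_index(edge_stats: EdgeReferenceStats) -> dict[tuple[str, str], int]:
    return {e: i for i, e in enumerate(edge_stats.edges)}


def shpcc_sample(
    sample_id: str,
    edge1: tuple[str, str],
    edge2: tuple[str, str],
    table: OTUTable,
    stats: ReferenceStats,
    edge_stats: EdgeReferenceStats,
) -> float:
    """Single-sample higher-order correlation between two edges."""
    idx = _edge_index(edge_stats)
    for e in (edge1, edge2):
        if e not in idx:
            raise KeyError(
                f"edge {e} has no reference calibration (zero-variance edges are dropped upstream)"
            )
    z = _sample_z(sample_id, table, stats)
    pos = stats.otu_ids.get_indexer([edge1[0], edge1[1], edge2[0], edge2[1]])
    E1 = z[pos[0]] * z[pos[1]]
    E2 = z[pos[2]] * z[pos[3]]
    i1, i2 = idx[edge1], idx[edge2]
    u1 = (E1 - edge_stats.m[i1]) / edge_stats.t[i1]
    u2 = (E2 - edge_stats.m[i2]) / edge_stats.t[i2]
    return float(u1 * u2)


def build_edge_network(
    sample_id: str,
    node_network: NodeNetwork,
    table: OTUTable,
    stats: ReferenceStats,
    edge_stats: EdgeReferenceStats,
    m: int = 50,
    disjoint: bool = False,
    z: np.ndarray | None = None,
) -> EdgeNetwork:
    """The m strongest |shPCC| edge-pairs among a sample's node-network edges.

    Only edges surviving reference calibration (t_e > 0) participate; the
    candidate set is every unordered pair of distinct surviving edges, or,
    with ``disjoint=True``, only pairs whose two edges involve four distinct
    OTUs (suppresses the self-amplified pairs of a single-OTU deviation
    star; see the module docstring).
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    surviving = set(edge_stats.edges)
    edges = sorted(e for e in node_network.edges if e in surviving)
    if len(edges) < 2:
        raise ValueError(
            f"sample {sample_id!r}: fewer than 2 calibrated edges; cannot build edge network"
        )
    idx = _edge_index(edge_stats)
    pos = [idx[e] for e in edges]

    zv = _sample_z(sample_id, table, stats, z)
    ia = stats.index_of([a for a, _ in edges])
    ib = stats.index_of([b for _, b in edges])
    E = zv[ia] * zv[ib]
    u = (E - edge_stats.m[pos]) / edge_stats.t[pos]

    iu, ju = _triu(len(edges))
    vals = u[iu] * u[ju]
    if disjoint:
        ok = (ia[iu] != ia[ju]) & (ia[iu] != ib[ju]) & (ib[iu] != ia[ju]) & (ib[iu] != ib[ju])
        cand = np.nonzero(ok)[0]
        if cand.size == 0:
            # every pair of surviving edges shares an OTU (tiny or star-shaped
            # networks): fall back to the unrestricted candidate set
            sel = _top_k_desc(np.abs(vals), m)
        else:
            sel = cand[_top_k_desc(np.abs(vals[cand]), m)]
    else:
        sel = _top_k_desc(np.abs(vals), m)
    pairs = [(edges[i], edges[j]) for i, j in zip(iu[sel], ju[sel])]
    return EdgeNetwork(sample_id=sample_id, pairs=pairs, shpcc=vals[sel], m=m)


def select_markers(
    subject_id: str,
    edge_networks: dict[int, EdgeNetwork],
    n_markers: int = 5,
    peaks: str = "all",
    method: str = "pairs",
    zscores: pd.DataFrame | None = None,
    band_fraction: float = 0.3,
) -> MarkerSet:
    """Pick a subject's OTU(-pair) biomarkers from its edge networks.

    Parameters
    ----------
    edge_networks
        Mapping time point -> EdgeNetwork for the subject's non-reference
        samples.
    n_markers
        ``method="pairs"``: edge-pairs taken per contributing time point.
        ``method="weighted"``: final marker OTUs taken per contributing time
        point.
    peaks
        Which time points contribute.  ``"all"``: every time point.
        ``"max"``: only the time point whose strongest |shPCC| is the
        subject's maximum.  ``"band"``: every time point whose network
        strength (median |shPCC| of its retained pairs) is at least
        ``band_fraction`` times the subject's maximum strength — the
        "signal peak" window; a forming DNB module is elevated over several
        consecutive samples, while one-off deviation spikes contribute a
        single time point.
    method
        ``"pairs"``: markers are the union of the constituent OTUs of the
        top ``n_markers`` edge-pairs per contributing time point.
        ``"weighted"``: per contributing time point, each OTU appearing in
        the network's pairs is scored by participation × deviation — the
        number of retained pairs it appears in times its own |z| — and the
        ``n_markers`` highest-scoring OTUs are taken.  DNB members both
        recur across the strongest edge-pairs and deviate strongly
        themselves; a star partner does neither.  Requires ``zscores``.
    zscores
        Samples × kept-OTUs standardised matrix (needed for "weighted").

    Returns the union of the selected OTUs with per-time-point provenance
    (the contributing time points' edge-pairs that involve selected OTUs).
    """
    if not edge_networks:
        raise ValueError(f"subject {subject_id!r}: no edge networks to select markers from")
    if any(len(net.pairs) == 0 for net in edge_networks.values()):
        raise ValueError(f"subject {subject_id!r}: empty edge network")
    if peaks not in ("all", "max", "band"):
        raise ValueError(f"peaks must be 'all', 'max' or 'band', got {peaks!r}")
    if method not in ("pairs", "weighted"):
        raise ValueError(f"method must be 'pairs' or 'weighted', got {method!r}")
    if method == "weighted" and zscores is None:
        raise ValueError("method='weighted' requires the zscores matrix")

    if peaks == "max":
        # ties on the peak value: earliest time point wins (deterministic)
        peak_tp = min(
            edge_networks,
            key=lambda tp: (-float(np.abs(edge_networks[tp].shpcc[0])), tp),
        )
        contributing = [peak_tp]
    elif peaks == "band":
        strength = {tp: net.strength() for tp, net in edge_networks.items()}
        mx = max(strength.values())
        contributing = sorted(tp for tp, s in strength.items() if s >= band_fraction * mx)
    else:
        contributing = sorted(edge_networks)

    otus: set[str] = set()
    provenance: dict[int, list] = {}
    weights: dict[str, float] = {}
    for tp in contributing:
        net = edge_networks[tp]
        if method == "pairs":
            chosen_pairs = list(net.pairs[:n_markers])
            chosen_otus = {o for (a, b), (c, d) in chosen_pairs for o in (a, b, c, d)}
        else:
            counts: dict[str, int] = {}
            for (a, b), (c, d) in net.pairs:
                for o in {a, b, c, d}:
                    counts[o] = counts.get(o, 0) + 1
            zrow = zscores.loc[net.sample_id]
            weight = {o: c * abs(float(zrow[o])) for o, c in counts.items()}
            ranked = sorted(weight, key=lambda o: (-weight[o], o))
            chosen_otus = set(ranked[:n_markers])
            for o in chosen_otus:
                weights[o] = weights.get(o, 0.0) + weight[o]
            chosen_pairs = [
                p for p in net.pairs
                if chosen_otus & {p[0][0], p[0][1], p[1][0], p[1][1]}
            ]
        provenance[tp] = chosen_pairs
        otus |= chosen_otus
    return MarkerSet(subject_id=subject_id, otus=otus, provenance=provenance, weights=weights)
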