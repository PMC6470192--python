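"""Single-sample DNB composite index (sCI) and marker-set aggregation.

A dynamic network biomarker (DNB) is a group of variables whose intra-group
correlation and variance rise — while group-to-outside correlation falls —
just before a state transition.  The classical multi-sample composite index
is

    CI = (PCC_in / PCC_out) * SD_in,

with PCC_in the average absolute correlation inside the candidate group,
PCC_out the average absolute correlation between the group and the rest, and
SD_in the average standard deviation inside the group.  Its single-sample
counterpart replaces each Pearson correlation with the sample's sPCC and the
SD with the sample's standardised deviation from the reference mean:

    sCI_d = ( mean_{x<y in Marker} |sPCC_d(x,y)|
              / mean_{x in Marker, y not in Marker} |sPCC_d(x,y)| )
            * mean_{x in Marker} |x_d - mu_x| / sigma_x.

All three terms are averages, so sCI is comparable across marker sets of
different size.  Two printed-formula readings are configurable:

* ``denominator_mode="out_group"`` (default) takes PCC_out between Marker
  and its complement, matching the CI definition; ``"literal_eq2"`` takes
  both sums inside Marker (the single-sample formula as sometimes printed),
  which makes the ratio ~1 and leaves only the deviation term informative.
* ``deviation_mode="standardized"`` (default) divides |x - mu| by sigma so
  the deviation term is unit-free across OTUs; ``"raw"`` uses |x - mu| on
  the abundance scale, letting abundant OTUs dominate.

High sCI flags the disease-warning (pre-transition) state of that sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import OTUTable, SampleMetadata
from .networks import MarkerSet
from .reference import ReferenceStats, zscore_matrix

__all__ = [
    "ScoreSeries",
    "compute_sci",
    "score_series",
    "aggregate_subject_markers",
    "group_common_markers",
]

EPSILON_DEFAULT = 1e-8


@dataclass
class ScoreSeries:
    """Per-time-point sCI trajectory of one subject with its components."""

    subject_id: str
    frame: pd.DataFrame  # columns: time_point, sci, numerator, denominator, deviation, clamped

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sci(self) -> np.ndarray:
        return self.frame["sci"].to_numpy()

    @property
    def time_points(self) -> np.ndarray:
        return self.frame["time_point"].to_numpy()


def compute_sci(
    sample_id: str,
    marker_otus: Iterable[str],
    background: Iterable[str],
    table: OTUTable,
    stats: ReferenceStats,
    epsilon: float = EPSILON_DEFAULT,
    denominator_mode: str = "out_group",
    deviation_mode: str = "standardized",
) -> dict:
    """Evaluate the composite index for one sample and one marker set.

    Returns a dict with keys ``sci``, ``numerator``, ``denominator``,
    ``deviation``, ``clamped``.  The denominator is clamped at ``epsilon``;
    a clamp is flagged, never silent.
    """
    marker = sorted(set(marker_otus))
    bg = sorted(set(background))
    if len(marker) < 2:
        raise ValueError(f"marker set must contain >= 2 OTUs, got {len(marker)}")
    if not set(marker) <= set(bg):
        raise ValueError("marker set must be a subset of the background OTU set")
    outside = sorted(set(bg) - set(marker))
    if denominator_mode == "out_group" and not outside:
        raise ValueError("background equals marker set; PCC_out is undefined")
    if denominator_mode not in ("out_group", "literal_eq2"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if deviation_mode not in ("standardized", "raw"):
        raise ValueError(f"unknown deviation_mode {deviation_mode!r}")

    Z = zscore_matrix(table.subset_otus(stats.otu_ids), stats)
    if sample_id not in Z.index:
        raise KeyError(f"sample {sample_id!r} not in table")
    z = Z.loc[sample_id]
    zm = np.abs(z.loc[marker].to_numpy())

    # mean |z_x z_y| over unordered within-marker pairs; |z_x z_y| = |z_x||z_y|
    q = len(marker)
    s1 = zm.sum()
    numerator = (s1 * s1 - (zm * zm).sum()) / (q * (q - 1))

    if denominator_mode == "out_group":
        zo = np.abs(z.loc[outside].to_numpy())
        denominator = float(zm.mean() * zo.mean())
    else:
        denominator = float(numerator)

    if deviation_mode == "standardized":
        deviation = float(zm.mean())
    else:
        x = table.data.loc[sample_id, marker].to_numpy(dtype=float)
        mu = stats.mu[stats.index_of(marker)]
        deviation = float(np.mean(np.abs(x - mu)))

    clamped = denominator < epsilon
    sci = (numerator / max(denominator, epsilon)) * deviation
    return {
        "sci": float(sci),
        "numerator": float(numerator),
        "denominator": float(denominator),
        "deviation": deviation,
        "clamped": bool(clamped),
    }


def score_series(
    subject_id: str,
    marker: MarkerSet,
    table: OTUTable,
    metadata: SampleMetadata,
    stats: ReferenceStats,
    background: Iterable[str] | None = None,
    epsilon: float = EPSILON_DEFAULT,
    denominator_mode: str = "out_group",
    deviation_mode: str = "standardized",
) -> ScoreSeries:
    """sCI trajectory over a subject's non-reference time points.

    ``background`` defaults to all kept OTUs — the largest stable complement
    for the PCC_out term.  A subject with only reference samples yields an
    empty series (with a warning via the empty frame).
    """
    if background is None:
        background = list(stats.otu_ids)
    rows = metadata.subject_samples(subject_id, include_reference=False)
    records = []
    for sample_id, row in rows.iterrows():
        if sample_id not in table.sample_ids:
            continue
        entry = compute_sci(
            sample_id,
            marker.otus,
            background,
            table,
            stats,
            epsilon=epsilon,
            denominator_mode=denominator_mode,
            deviation_mode=deviation_mode,
        )
        records.append({"time_point": int(row["time_point"]), **entry})
    frame = pd.DataFrame(
        records, columns=["time_point", "sci", "numerator", "denominator", "deviation", "clamped"]
    )
    return ScoreSeries(subject_id=subject_id, frame=frame)


def aggregate_subject_markers(marker_sets: Iterable[MarkerSet]) -> MarkerSet:
    """Union a subject's per-time marker sets, merging provenance."""
    marker_sets = list(marker_sets)
    if not marker_sets or all(not m.otus for m in marker_sets):
        raise ValueError("no marker OTUs to aggregate")
    subject = marker_sets[0].subject_id
    otus: set[str] = set()
    provenance: dict[int, list] = {}
    for ms in marker_sets:
        otus |= ms.otus
        for tp, pairs in ms.provenance.items():
            bucket = provenance.setdefault(tp, [])
            for p in pairs:
                if p not in bucket:
                    bucket.append(p)
    return MarkerSet(subject_id=subject, otus=otus, provenance=provenance)


def group_common_markers(
    subject_markers: dict[str, set[str]], mode: str = "majority"
) -> set[str]:
    """OTUs shared across subjects' marker sets.

    ``intersection``: present in every subject's set.  ``majority``: present
    in strictly more than half of the subjects' sets.  An empty result is
    allowed (disjoint individual markers) and simply returned empty.
    """
    if len(subject_markers) < 2:
        raise ValueError("group_common_markers needs >= 2 subjects")
    sets = list(subject_markers.values())
    if mode == "intersection":
        out = set.intersection(*sets)
    elif mode == "majority":
        counts: dict[str, int] = {}
        for s in sets:
            for otu in s:
                counts[otu] = counts.get(otu, 0) + 1
        out = {otu for otu, c in counts.items() if c > len(sets) / 2}
    else:
        raise ValueError(f"mode must be 'intersection' or 'majority', got {mode!r}")
    return out
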