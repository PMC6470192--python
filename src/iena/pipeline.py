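"""End-to-end orchestration: filter → reference stats → per-sample node and
edge networks → individual markers → sCI trajectories → classification.

The analysis itself is fully deterministic; the only randomness in the
package lives in the synthetic-cohort generator.  Re-running the pipeline
on identical inputs and configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import classify as _classify
from .io import OTUTable, SampleMetadata, to_relative_abundance, write_tsv
from .networks import EdgeNetwork, MarkerSet, build_edge_network, build_node_network, select_markers
from .reference import (
    compute_edge_reference_stats,
    compute_reference_stats,
    filter_otus,
    zscore_matrix,
)
from .scoring import ScoreSeries, group_common_markers, score_series

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "PRESETS"]


@dataclass
class PipelineConfig:
    """All analysis knobs in one serialisable object.

    min_nonzero_frac : OTU sparsity filter — keep OTUs non-zero in strictly
        more than this fraction of samples (default 0.85).
    top_edges : node-network capacity k, strongest |sPCC| edges per sample
        (default 1500).
    top_edge_pairs : edge-network capacity m, strongest |shPCC| edge-pairs
        per sample (default 50).
    edge_pair_disjoint : restrict edge-pairs to four distinct OTUs
        (default True; see the networks module on deviation stars).
    n_markers : with marker_method="pairs", edge-pairs per contributing time
        point (default 5); with "weighted", final marker OTUs per
        contributing time point (n_otu_markers, default 10, is used
        instead).
    marker_method : "weighted" (default) — participation × deviation
        ranking; "pairs" — plain union of top edge-pairs' OTUs.
    marker_peaks : "band" (default) — time points within
        marker_band_fraction of the subject's peak network strength
        contribute; "max" — only the single peak; "all" — every time point.
    score_marker_source : "common" (default) — score every subject's sCI on
        the group-consensus marker set when one exists (falls back to the
        subject's own markers); "subject" — always the subject's own set.
    epsilon : PCC_out clamp in the sCI ratio (default 1e-8).
    denominator_mode / deviation_mode / agg / threshold_method : see the
        scoring and classification modules.
    normalize : close count tables to relative abundance first (default).
    common_marker_mode : group-level marker consensus across Sx subjects.
    """

    min_nonzero_frac: float = 0.85
    top_edges: int = 1500
    top_edge_pairs: int = 50
    edge_pair_disjoint: bool = True
    n_markers: int = 5
    n_otu_markers: int = 10
    marker_method: str = "weighted"
    marker_peaks: str = "band"
    marker_band_fraction: float = 0.3
    score_marker_source: str = "common"
    epsilon: float = 1e-8
    denominator_mode: str = "out_group"
    deviation_mode: str = "standardized"
    agg: str = "max"
    threshold_method: str = "youden"
    fixed_threshold: float | None = None
    normalize: bool = True
    common_marker_mode: str = "majority"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Published parameterisations: the ETEC challenge analysis and the
#: bacterial-vaginosis daily time-series analysis.
PRESETS: dict[str, dict] = {
    "etec": {"min_nonzero_frac": 0.85, "top_edges": 1500},
    "bv": {"min_nonzero_frac": 0.5, "top_edges": 10},
}


def config_from_preset(name: str, **overrides) -> PipelineConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = {**PRESETS[name], **overrides}
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, ready for writing or inspection."""

    config: PipelineConfig
    kept_otus: list[str]
    dropped: pd.DataFrame
    node_networks: dict[str, object]
    edge_networks: dict[str, EdgeNetwork]
    subject_markers: dict[str, MarkerSet]
    common_markers: set[str]
    score_serieses: dict[str, ScoreSeries]
    subject_scores: dict[str, float]
    classification: _classify.ClassificationResult | None

    def summary(self) -> dict:
        out = {
            "config": self.config.to_dict(),
            "n_kept_otus": len(self.kept_otus),
            "n_dropped_otus": int(len(self.dropped)),
            "subjects": sorted(self.subject_markers),
            "common_markers": sorted(self.common_markers),
            "subject_scores": {s: self.subject_scores[s] for s in sorted(self.subject_scores)},
        }
        if self.classification is not None:
            c = self.classification
            out["auc"] = c.auc
            out["threshold"] = c.threshold
            out["accuracy"] = c.accuracy
            out["predicted"] = dict(zip(c.subject_ids, c.predicted))
        return out


def _consensus_rank(marker_sets, size: int) -> list[str]:
    """Fixed-size consensus of marker sets: OTUs ranked by how many sets
    contain them, ties by total selection weight, then id."""
    count: dict[str, int] = {}
    weight: dict[str, float] = {}
    for ms in marker_sets:
        for o in ms.otus:
            count[o] = count.get(o, 0) + 1
            weight[o] = weight.get(o, 0.0) + ms.weights.get(o, 0.0)
    ranked = sorted(count, key=lambda o: (-count[o], -weight[o], o))
    return ranked[:size]


def run_pipeline(
    table: OTUTable,
    metadata: SampleMetadata,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; optionally write every intermediate artifact.

    Stages raise with their stage name prefixed so a failure in a long run
    is attributable.
    """
    config = config or PipelineConfig()
    metadata.validate_against(table)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    if config.normalize and table.mode == "counts":
        table = stage("normalize", to_relative_abundance, table)

    filtered, sparse_dropped = stage("filter", filter_otus, table, config.min_nonzero_frac)
    stats = stage("reference_stats", compute_reference_stats, filtered, metadata)
    dropped = pd.concat(
        [
            pd.DataFrame({"otu_id": sparse_dropped, "reason": "sparse"}),
            stats.dropped_report(),
        ],
        ignore_index=True,
    )

    Z = stage("zscores", zscore_matrix, filtered, stats)
    non_ref = metadata.frame[~metadata.frame["is_reference"]]
    non_ref_ids = [s for s in non_ref.index if s in filtered.sample_ids]

    node_networks, edge_networks = {}, {}
    for sid in non_ref_ids:
        zrow = Z.loc[sid].to_numpy()
        nn = stage(
            "node_network", build_node_network, sid, filtered, stats, config.top_edges, z=zrow
        )
        node_networks[sid] = nn
        estats = stage(
            "edge_reference_stats", compute_edge_reference_stats, filtered, metadata, stats, nn.edges
        )
        edge_networks[sid] = stage(
            "edge_network", build_edge_network, sid, nn, filtered, stats, estats,
            config.top_edge_pairs, disjoint=config.edge_pair_disjoint, z=zrow,
        )

    n_select = config.n_otu_markers if config.marker_method == "weighted" else config.n_markers
    subject_markers: dict[str, MarkerSet] = {}
    for subject in metadata.subjects():
        rows = metadata.subject_samples(subject, include_reference=False)
        nets = {
            int(row["time_point"]): edge_networks[sid]
            for sid, row in rows.iterrows()
            if sid in edge_networks
        }
        if not nets:
            continue
        subject_markers[subject] = stage(
            "markers", select_markers, subject, nets, n_select, config.marker_peaks,
            method=config.marker_method, zscores=Z,
            band_fraction=config.marker_band_fraction,
        )

    outcomes = {
        s: metadata.frame.loc[metadata.frame["subject_id"] == s, "outcome"].iloc[0]
        for s in subject_markers
    }
    sx_markers = {
        s: m.otus for s, m in subject_markers.items() if outcomes.get(s) == "Sx"
    }
    common = (
        group_common_markers(sx_markers, mode=config.common_marker_mode)
        if len(sx_markers) >= 2
        else set()
    )

    score_serieses: dict[str, ScoreSeries] = {}
    subject_scores: dict[str, float] = {}
    for subject in subject_markers:
        marker = subject_markers[subject]
        if config.score_marker_source == "common" and len(sx_markers) >= 3:
            # Score each subject on a consensus marker set derived from the
            # symptomatic subjects EXCLUDING the subject itself (the
            # exclusion is vacuous for non-Sx subjects).  Scoring a subject
            # on markers selected from its own extreme samples would inflate
            # its score even without any signal; the held-out consensus
            # removes that circularity.  The set has fixed size so score
            # variability is comparable across subjects.
            others = {s: m for s, m in subject_markers.items()
                      if s in sx_markers and s != subject}
            score_otus = _consensus_rank(others.values(), config.n_otu_markers)
            if len(score_otus) < 2:
                continue
            marker = MarkerSet(subject_id=subject, otus=set(score_otus))
        elif len(marker.otus) < 2:
            continue
        series = stage(
            "score", score_series, subject, marker, filtered, metadata, stats,
            epsilon=config.epsilon,
            denominator_mode=config.denominator_mode,
            deviation_mode=config.deviation_mode,
        )
        score_serieses[subject] = series
        subject_scores[subject] = stage(
            "subject_score", _classify.subject_score, series, config.agg, config.fixed_threshold
        )

    known = {s: outcomes[s] for s in subject_scores if outcomes.get(s) in ("Sx", "Asx")}
    classification = None
    if len(set(known.values())) == 2:
        scores_known = {s: subject_scores[s] for s in known}
        classification = stage("roc", _classify.roc_auc, scores_known, known)
        classification.threshold = stage(
            "threshold", _classify.choose_threshold, classification,
            config.threshold_method, config.fixed_threshold,
        )
        predicted, accuracy = stage(
            "predict", _classify.predict, scores_known, classification.threshold, known
        )
        classification.predicted = [predicted[s] for s in classification.subject_ids]
        classification.accuracy = accuracy

    result = PipelineResult(
        config=config,
        kept_otus=list(stats.otu_ids),
        dropped=dropped,
        node_networks=node_networks,
        edge_networks=edge_networks,
        subject_markers=subject_markers,
        common_markers=common,
        score_serieses=score_serieses,
        subject_scores=subject_scores,
        classification=classification,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write all artifacts as TSV plus a JSON summary with the config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_tsv(result.dropped, out / "dropped_otus.tsv")
    if result.node_networks:
        write_tsv(
            pd.concat([n.to_frame() for n in result.node_networks.values()], ignore_index=True),
            out / "node_networks.tsv",
        )
    if result.edge_networks:
        write_tsv(
            pd.concat([n.to_frame() for n in result.edge_networks.values()], ignore_index=True),
            out / "edge_networks.tsv",
        )
    if result.subject_markers:
        write_tsv(
            pd.concat([m.to_frame() for m in result.subject_markers.values()], ignore_index=True),
            out / "markers.tsv",
        )
        write_tsv(
            pd.DataFrame(
                [
                    {"subject_id": s, "otu_id": o}
                    for s in sorted(result.subject_markers)
                    for o in sorted(result.subject_markers[s].otus)
                ]
            ),
            out / "marker_otus.tsv",
        )
    if result.score_serieses:
        frames = []
        for s in sorted(result.score_serieses):
            f = result.score_serieses[s].frame.copy()
            f.insert(0, "subject_id", s)
            frames.append(f)
        write_tsv(pd.concat(frames, ignore_index=True), out / "scores.tsv")

    summary = result.summary()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        "parameters:\n"
        + "\n".join(f"  {k} = {v}" for k, v in sorted(result.config.to_dict().items()))
        + f"\nkept_otus = {len(result.kept_otus)}\nsubjects = {sorted(result.subject_markers)}\n"
    )
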