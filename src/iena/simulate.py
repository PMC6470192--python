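"""Seeded synthetic longitudinal microbiome cohorts with a planted DNB module.

The generator emulates the study design the pipeline targets: a cohort of
subjects sampled at ordered time points, the leading time points forming the
baseline reference group, with symptomatic (Sx) subjects carrying a planted
dynamic-network-biomarker signature during a disease window and asymptomatic
(Asx) subjects carrying none.

Model
-----
Latent per-sample log-abundances are multivariate normal with an
exchangeable correlation structure built from shared factors:

* baseline / Asx / out-of-window:  l_i = b_i + sqrt(rho_base) * g
  + sqrt(1 - rho_base) * e_i  for every OTU i, with one shared factor g per
  sample — pairwise latent correlation rho_base everywhere.
* Sx inside the disease window: the planted module block uses its own factor
  with correlation rho_in and its noise scaled by gamma (variance
  inflation), while the rest keeps rho_base with an independent factor — so
  module-to-outside correlation drops to 0.  This plants all three DNB
  components: intra-module correlation up, intra-module variance up,
  module-outside correlation down.

Log-abundances are exponentiated, independent per-cell dropout with
probability ``zero_inflation`` sets entries to zero (16S sparsity), and each
row is closed to relative abundance (compositionality).  The same seed
yields bit-identical cohorts.

Deliberately not modelled: sequencing depth / read counts, ecological
dynamics (e.g. generalized Lotka–Volterra), taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OTUTable, SampleMetadata

__all__ = ["SyntheticParams", "SyntheticTruth", "generate_cohort", "empirical_check"]


@dataclass
class SyntheticParams:
    """Cohort design and planted-signal strengths.

    Defaults mirror the ETEC-style challenge design: 5 symptomatic and 7
    asymptomatic subjects, 12 time points of which the first 2 are baseline
    reference, 200 OTUs with a 10-OTU planted module active over time points
    6–9, background correlation 0.1 vs in-window module correlation 0.8,
    threefold variance inflation, 30% dropout.
    """

    n_sx: int = 5
    n_asx: int = 7
    n_time: int = 12
    n_ref: int = 2
    p: int = 200
    module_size: int = 10
    disease_window: tuple[int, int] = (6, 9)  # inclusive time-point interval
    rho_base: float = 0.1
    rho_in: float = 0.8
    gamma: float = 3.0
    zero_inflation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sx < 0 or self.n_asx < 0 or self.n_sx + self.n_asx == 0:
            raise ValueError("need at least one subject")
        if not (1 <= self.n_ref < self.n_time):
            raise ValueError(f"n_ref must be in [1, n_time), got {self.n_ref}")
        if not (0 <= self.rho_base <= self.rho_in <= 0.99):
            raise ValueError(
                f"require 0 <= rho_base <= rho_in <= 0.99, got ({self.rho_base}, {self.rho_in})"
            )
        if self.gamma < 1:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")
        if not (0 < self.module_size < self.p):
            raise ValueError(f"module_size must be in (0, p), got {self.module_size}")
        if not (0 <= self.zero_inflation <= 0.9):
            raise ValueError(f"zero_inflation must be in [0, 0.9], got {self.zero_inflation}")
        lo, hi = self.disease_window
        if not (self.n_ref < lo <= hi <= self.n_time):
            raise ValueError(
                f"disease_window {self.disease_window} must lie within the "
                f"non-reference time points ({self.n_ref + 1}..{self.n_time})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort (for recovery evaluation only)."""

    module_otus: set[str]
    disease_window: tuple[int, int]
    subject_class: dict[str, str]  # subject_id -> Sx/Asx
    params: SyntheticParams
    latent: pd.DataFrame = field(repr=False)  # samples × OTUs latent log-abundances


def _exchangeable(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """One draw of n exchangeable standard normals with correlation rho."""
    g = rng.standard_normal()
    e = rng.standard_normal(n)
    return np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e


def generate_cohort(params: SyntheticParams) -> tuple[OTUTable, SampleMetadata, SyntheticTruth]:
    """Generate (table, metadata, truth) for one seeded cohort.

    Output table is in relative-abundance mode (rows close to 1).  The first
    ``n_ref`` time points of every subject are flagged ``is_reference``.
    """
    rng = np.random.default_rng(params.seed)
    p = params.p
    otu_ids = [f"OTU{i:04d}" for i in range(1, p + 1)]
    module_idx = np.sort(rng.choice(p, size=params.module_size, replace=False))
    module = np.zeros(p, dtype=bool)
    module[module_idx] = True
    module_otus = {otu_ids[i] for i in module_idx}

    base_mean = rng.normal(0.0, 1.0, size=p)  # per-OTU baseline log-abundance

    subjects = [(f"Sx{i + 1:02d}", "Sx") for i in range(params.n_sx)] + [
        (f"Asx{i + 1:02d}", "Asx") for i in range(params.n_asx)
    ]
    lo, hi = params.disease_window

    rows, meta_rows, sample_ids = [], [], []
    for subject_id, outcome in subjects:
        for tp in range(1, params.n_time + 1):
            in_window = outcome == "Sx" and lo <= tp <= hi
            if in_window:
                noise = np.empty(p)
                noise[module] = params.gamma * _exchangeable(
                    rng, params.module_size, params.rho_in
                )
                noise[~module] = _exchangeable(rng, p - params.module_size, params.rho_base)
            else:
                noise = _exchangeable(rng, p, params.rho_base)
            rows.append(base_mean + noise)
            sample_ids.append(f"{subject_id}_t{tp:02d}")
            meta_rows.append(
                {
                    "sample_id": sample_ids[-1],
                    "subject_id": subject_id,
                    "time_point": tp,
                    "is_reference": tp <= params.n_ref,
                    "outcome": outcome,
                }
            )

    latent = np.array(rows)
    abundance = np.exp(latent)
    if params.zero_inflation > 0:
        dropout = rng.random(abundance.shape) < params.zero_inflation
        abundance = np.where(dropout, 0.0, abundance)
        # a fully zeroed row cannot be closed; re-instate its largest OTU
        dead = abundance.sum(axis=1) == 0
        if dead.any():
            revive = np.argmax(latent[dead], axis=1)
            abundance[np.nonzero(dead)[0], revive] = np.exp(latent[dead, revive])
    abundance = abundance / abundance.sum(axis=1, keepdims=True)

    table = OTUTable(
        pd.DataFrame(abundance, index=pd.Index(sample_ids, name="sample_id"), columns=otu_ids),
        mode="relative",
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = SyntheticTruth(
        module_otus=module_otus,
        disease_window=params.disease_window,
        subject_class={s: c for s, c in subjects},
        params=params,
        latent=pd.DataFrame(latent, index=sample_ids, columns=otu_ids),
    )
    return table, metadata, truth


def empirical_check(table: OTUTable, truth: SyntheticTruth) -> dict:
    """Realized planted-signal strengths, from the generator's own draws.

    Confirms the cohort hits its targets within sampling error: mean latent
    intra-module correlation over in-window Sx samples vs the configured
    rho_in; mean background correlation out of window vs rho_base; the
    in-window / out-of-window module SD ratio vs gamma; and the realized
    zero fraction of the closed table vs zero_inflation.
    """
    params = truth.params
    lo, hi = truth.disease_window
    module = sorted(truth.module_otus)
    sx = [s for s, c in truth.subject_class.items() if c == "Sx"]

    def _ids(subjects, tps):
        return [f"{s}_t{tp:02d}" for s in subjects for tp in tps]

    in_win = _ids(sx, range(lo, hi + 1))
    out_tps = [t for t in range(1, params.n_time + 1) if not (lo <= t <= hi)]
    out_win = _ids(sx, out_tps) + _ids(
        [s for s in truth.subject_class if s not in sx], range(1, params.n_time + 1)
    )

    def _mean_offdiag_corr(frame: pd.DataFrame) -> float:
        c = np.corrcoef(frame.to_numpy(), rowvar=False)
        iu = np.triu_indices(c.shape[0], 1)
        return float(c[iu].mean())

    L = truth.latent
    report = {
        "n_in_window_samples": len(in_win),
        "realized_rho_in": _mean_offdiag_corr(L.loc[in_win, module]) if len(in_win) > 2 else np.nan,
        "realized_rho_background": _mean_offdiag_corr(L.loc[out_win, module]),
        "sd_ratio_module": float(
            L.loc[in_win, module].to_numpy().std(axis=0).mean()
            / L.loc[out_win, module].to_numpy().std(axis=0).mean()
        )
        if len(in_win) > 2
        else np.nan,
        "zero_fraction": float((table.data.to_numpy() == 0).mean()),
        "targets": {
            "rho_in": params.rho_in,
            "rho_base": params.rho_base,
            "gamma": params.gamma,
            "zero_inflation": params.zero_inflation,
        },
    }
    return report
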