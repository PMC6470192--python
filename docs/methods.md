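# Methods

## Problem setting

Longitudinal 16S rRNA studies sample each subject's microbiota at a handful
of time points around a perturbation (a controlled enterotoxigenic *E. coli*
challenge, the onset of bacterial vaginosis).  The question is whether a
*single* sample — one subject, one day — carries an early-warning signature
of the coming symptomatic state.  Dynamic network biomarker (DNB) theory
predicts such a signature: approaching a state transition, a small group of
variables (here, OTUs) shows rising intra-group correlation, rising
intra-group variance, and falling correlation with everything else.
Conventional correlation estimates need many samples; the individual-specific
edge-network approach replaces them with per-sample quantities calibrated
against a baseline reference group, so a trajectory of per-sample scores can
be computed for every subject separately.

## Single-sample statistics

All samples are closed to relative abundance (compositions) and sparse OTUs
are removed: an OTU is kept only if it is non-zero in strictly more than a
configurable fraction of samples (0.85 in the challenge configuration, 0.5
in the vaginosis configuration).  The *reference group* is the pooled set of
every subject's baseline samples.  From it we take, per OTU, the mean
`mu_x` and the **population** standard deviation `sigma_x` (divide by
`n_ref`, not `n_ref − 1`), and, per OTU pair, the Pearson correlation
`rho(x,y)`.

For sample *d*, with `z_x = (x_d − mu_x) / sigma_x`:

* **sPCC** (single-sample Pearson correlation): `sPCC_d(x,y) = z_x · z_y`.
  With population normalisation the average of `sPCC_d` over the reference
  samples equals `rho(x,y)` *exactly* — each sample contributes one term of
  the reference correlation.  This identity (tolerance 1e-12) is the test
  suite's analytic oracle for the whole standardisation chain.  sPCC is
  unbounded and deliberately not clamped to [−1, 1].
* **Node network**: the k strongest |sPCC| pairs of the sample
  (k = 1500 in the challenge configuration, 10 in the vaginosis one), a
  plain rank cut-off — the sPCC distribution is not normal, so no test
  statistic is attached.  Ties break lexicographically on OTU ids; outputs
  are bit-reproducible and invariant to input column order.
* **shPCC** (single-sample higher-order correlation): every node-network
  edge e = (x,y) carries the product variable `E_d = z_x z_y`, standardised
  against its own reference mean `m_e` (= `rho(x,y)` by the identity above)
  and reference population SD `t_e`; the shPCC of two edges is the product
  of their standardised deviations — fourth order in the raw abundances,
  and obeying the same reference-average identity one level up.  Edges with
  `t_e = 0` (constant product over the reference) are dropped, never
  epsilon-patched, as are OTUs with `sigma = 0`.
* **Edge network**: the m strongest |shPCC| pairs of node-network edges.
  By default the two edges of a pair must involve **four distinct OTUs**.
  This matters on heavy-tailed compositional data: one extremely deviating
  OTU forms a "star" of strong edges, and any two star edges share the OTU
  and multiply its deviation twice (a z⁴ term), swamping every ranking
  while carrying only one OTU's worth of evidence.  Requiring disjoint
  edges makes the statistic a genuine fourth-order association among four
  taxa.  (For very small or fully star-shaped networks, where no disjoint
  pair exists, the constraint falls back to all pairs.)

## Marker selection

Per subject, markers are the candidate DNB members extracted from its edge
networks across time.  Two rules are provided:

* `pairs` — the union of the constituent OTUs of the top n edge-pairs per
  time point; the simplest reading of edge-biomarker selection.
* `weighted` (pipeline default) — only time points in the subject's **signal
  band** contribute: those whose network strength (median |shPCC| of the
  retained pairs) reaches 30% of the subject's maximum.  A forming DNB
  module stays elevated over consecutive samples, while one-off deviation
  spikes light up a single time point.  Within each band sample, every
  participating OTU is scored by *participation × deviation* — the number
  of retained edge-pairs containing it times its own |z| — and the top 10
  are taken.  A DNB member recurs across the strongest pairs *and* deviates
  strongly itself; a star partner does neither.

Group-level consensus markers are the OTUs present in more than half of the
symptomatic subjects' marker sets (majority rule; strict intersection is
available).  On synthetic cohorts this consensus is what recovers the
planted module: subject-specific noise OTUs do not recur across subjects.

## Composite index

The multi-sample DNB criterion `CI = (PCC_in / PCC_out) × SD_in` becomes,
per sample and marker set M:

    sCI_d = ( mean_{x<y ∈ M} |sPCC_d(x,y)|
              / mean_{x ∈ M, y ∉ M} |sPCC_d(x,y)| )
            × mean_{x ∈ M} |z_x|

All three terms are averages, so sCI is comparable across marker-set sizes.
Two printed-formula ambiguities are resolved as config switches with these
defaults: the denominator runs between the marker set and its complement
(`out_group`; the literal within-group reading, which makes the ratio ≈ 1,
is available as `literal_eq2`), and the deviation term is standardised by
`sigma_x` (raw |x − mu| is available, but lets one abundant OTU dominate).
The denominator is clamped at ε = 1e-8 and any clamp is flagged in the
output.  The background set for PCC_out is all kept OTUs — the largest
stable complement.

## Classification

A subject's trajectory is reduced to its peak sCI (mean and
earliest-crossing reductions are available), scores are compared between
symptomatic (Sx) and asymptomatic (Asx) subjects by ROC/AUC (trapezoidal;
equal to the Mann–Whitney pair count with ties at 1/2, which the tests
verify exhaustively on small cohorts), and the operating threshold maximises
Youden's J over midpoints between consecutive observed scores, ties to the
higher threshold.

**Held-out consensus scoring.**  Scoring a subject with markers selected
from its own extreme samples inflates its score even when no signal exists
— on matched null cohorts (no planted module) that circularity alone
produced a mean AUC near 0.8.  The pipeline therefore scores every subject
on a fixed-size consensus of the symptomatic subjects' marker sets
*excluding the scored subject* (vacuously for Asx subjects): OTUs ranked by
how many of the remaining sets contain them, ties by total selection
weight, truncated to the marker-count parameter.  This restores a chance
level null (mean AUC ≈ 0.47 over 20 null cohorts) at the cost of a few AUC
points on planted-signal cohorts; scoring on the subject's own markers
remains available (`score_marker_source="subject"`).

## Synthetic cohorts

The generator emulates the challenge design: `n_sx = 5` symptomatic and
`n_asx = 7` asymptomatic subjects, 12 time points with the first 2 as
baseline reference, `p = 200` OTUs, a planted module of 10.  Latent
log-abundances are multivariate normal with exchangeable correlation 0.1
built from shared factors (unit latent variance); for Sx subjects inside
the disease window (time points 6–9, a sustained mid-study episode) the
module block switches to correlation 0.8 with its noise scaled by γ = 3 and
its correlation to the outside dropped to 0 — all three DNB components
planted.  Log-abundances are exponentiated, independent per-cell dropout
(probability 0.3) imposes 16S-style zero inflation, and rows are closed to
relative abundance.  The same seed is bit-reproducible.
`empirical_check` reports the realized latent intra-module correlation, the
background correlation, the in/out-window SD ratio and the zero fraction
against their targets.

Deliberately not modelled: sequencing depth and read counts, ecological
dynamics (e.g. generalized Lotka–Volterra), taxonomy, per-subject baseline
offsets.  Passing tests on these cohorts show the machinery detects the
planted covariance/variance signature through the compositional observation
layer; they do not certify performance on real dysbiosis, where effect
sizes, tail behaviour and confounding differ.

## Synthetic-experiment configuration and observed behaviour

The synthetic experiments run the pipeline at: sparsity filter 0.5 (a
30%-dropout table leaves no OTU above the 0.85 challenge threshold — the
filter correctly refuses), k = 1500 node edges, m = 100 disjoint edge-pairs,
weighted band markers with 10 OTUs per contributing time point, majority
consensus, held-out consensus scoring, peak aggregation, Youden threshold.
Problem sizes: 20 cohorts of 144 samples × 200 OTUs per experiment arm.

Observed over 20 seeds (the acceptance script recomputes all of these):
consensus-marker recovery of the planted module reaches a median Jaccard
around 0.5; subject classification reaches a median AUC around 0.86 and
median accuracy around 0.92; the null configuration is at chance; and the
mean peak sCI of planted-module subjects rises strictly with γ ∈ {1, 2, 3}
when scored on the true module.

Two observation-layer effects bound marker recovery and AUC on this
generator, and are worth knowing about when interpreting real data:

* a *negative* shared module factor drives module abundances toward zero,
  where the standardised deviation saturates at `−mu/sigma`; only
  positive-factor window samples are conspicuous, so roughly a quarter of
  symptomatic subjects present no recoverable single-sample signature;
* with a reference of 24 samples, `sigma` of a heavy-tailed composition is
  noisy, and OTUs with underestimated `sigma` become cohort-wide "spike"
  sources that fourth-order statistics amplify (z⁴) past the planted
  module.

Scoring on the true planted module yields median AUC 1.0 on the same
cohorts, so the composite index itself is not the limiting factor; marker
recovery through the exponentiated, zero-inflated, closed observation layer
is.

## Numerical and degenerate-input policy

Population (÷ n) normalisation everywhere in reference statistics, so the
single-sample identities are exact rather than asymptotic.  Zero-variance
OTUs and zero-variance edges are excluded and reported, never patched.
All rankings break ties lexicographically on ids; re-running the pipeline
on identical inputs and configuration is byte-identical (logs carry no
timestamps).  The only randomness in the package is the cohort generator's
single seed.  Relative-abundance closure is validated to 1e-9; an all-zero
sample row is an error naming the sample.

## Known limitations

The shPCC construction standardises the edge product variable against its
reference distribution — the natural one-level-up analogue of sPCC — but
other fourth-order normalisations exist and printed descriptions of the
statistic are not detailed enough to fix one; results at the edge level
should be read as method-family, not method-identical.  The pipeline has no
notion of time-lagged association, partial correlation, or a prior
interaction network.  Consensus markers require at least two (scoring,
three) labelled symptomatic subjects.  Per-stage results are recomputed on
every run; there is no cache.
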