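# Methods

`stressdfc` implements a dynamic functional connectivity (DFC) analysis
for acute-stress resting-state designs: three resting-state runs per
subject (RS1 before a stressor, RS2 and RS3 after it), with trait
mindfulness, subjective ratings and salivary cortisol measured around
the stressor. This note describes the models and procedures, the
defaults and why they were chosen, what the synthetic cohort does and
does not emulate, and the numerical conventions.

## Motion quality control

Framewise displacement (FD) is the sum of absolute backward differences
of the six rigid-body parameters, with rotations converted to arc
length on a 50 mm sphere — the field-standard convention; the radius is
configurable. DVARS is the root-mean-square over ROIs of the backward
signal difference, expressed as percent of the run's global mean
signal. DVARS is classically defined on voxel data; computing it on ROI
time series (this package's input) is an approximation, and the
percent-of-global-mean denominator is our documented choice since no
universal ROI-level convention exists.

Volumes with FD > 0.2 mm or DVARS > 5 % (strict inequalities; boundary
values are not marked) are marked high-motion, together with one volume
before and two after each spike, clipped at run boundaries. Marked
volumes are replaced by per-ROI linear interpolation between the
nearest unmarked neighbours (nearest-value extension at run edges)
rather than removed, because deleting volumes distorts the temporal
structure a windowed coupling estimator relies on. A run fails QC when
more than 50 % of its volumes are marked (strictly above; exactly half
passes). The fixed stage order is: discard the first 4 volumes →
compute FD/DVARS → mark → interpolate.

## MTD windowed coupling

Coupling between regions i and j at time t is estimated by
multiplication of temporal derivatives:

    raw(t, i, j) = dx_i(t) · dx_j(t) / (σ_i · σ_j)

where dx is the backward difference of the BOLD series and σ the
population (ddof = 0) standard deviation of dx over the whole run.
Run-level normalisation makes the estimator exactly invariant to
per-ROI positive affine rescaling. Flat ROIs (σ = 0) would make the
ratio undefined; their couplings are set to 0 with a warning so the
clustering input stays finite.

The raw product series is smoothed with an unweighted moving average of
w = 7 TRs. The edge convention drops the first w positions of the
difference series, retaining exactly T − 1 − w windows — 292 windows
for a 300-volume run. Other conventions (centred windows, symmetric
trimming) give 289–293 windows and are not used. Windows are
vectorised as the row-major upper triangle excluding the diagonal
(6441 values for 114 ROIs); the diagonal is kept in matrices but never
enters clustering.

Note an internal tension the package exposes rather than hides: with
the default 4 discarded volumes a 300-volume run enters MTD with 296
volumes and yields 288 windows; the canonical 292 arises when the MTD
stage sees all 300. Both behaviours are available (`discard_frames` in
`AnalysisConfig`), with 4 as the pipeline default.

## Connectivity states: cityblock k-medians

Window vectors from all subjects and runs are concatenated and
clustered with k = 5 (fixed; no model selection) under the Manhattan
(cityblock) distance. The objective-consistent centroid update for L1
is the component-wise median, so the fit is Lloyd-style k-medians:
assign to the nearest centroid (ties toward the lowest state index),
update by medians, re-seed any emptied cluster from the point farthest
from its centroid, stop when labels are stable or after 300 iterations.
Total within-cluster cityblock distance (inertia) is asserted
non-increasing at every iteration. The best of `n_restarts` (default
10) seeded initialisations by inertia is kept; restart seeds are
spawned from the model seed, so fits are exactly reproducible.

Fitted centroids are matched to reference centroids (e.g. canonical
task-ready / high-arousal / low-arousal patterns) by Spearman rank
correlation (average ranks on ties) under an optimal one-to-one
assignment minimising total 1 − ρ (Hungarian algorithm). Pairs with
ρ below a configurable floor (default 0.5) are reported unmatched, as
are surplus centroids; constant centroids have undefined ranks and are
reported as missing. State names (TRS/HAS/LAS) are applied only via
this matching — nothing anatomical is hard-coded.

## Occupancy and change scores

Fractional occupancy is the proportion of a run's retained windows
assigned to each state; never-visited states get exactly 0. Change
scores are simple differences between runs, Δ21 = RS2 − RS1 (stress
effect) and Δ32 = RS3 − RS2 (recovery). Subjects missing a run are
excluded from change scores and logged — never imputed — to avoid
biasing the group tests. Because per-run occupancies sum to 1, each
subject's deltas sum to 0 across states: the deltas are compositional,
which matters for interpreting between-state correlations (below).

## Cortisol summaries

Cortisol is sampled at −30, 0, +20, +60 and +90 minutes around
stressor onset. Because salivary cortisol is positively skewed, the
series is natural-log transformed before summarising (configurable:
`auc_log_scale`; log10 is not used). Two trapezoid-rule summaries are
computed over all five samples: AUCg, the area with respect to ground,
and AUCi, the increase above baseline, with baseline defined as the
first sample held constant over the span. The identity
AUCi = AUCg − c₁·(t_last − t_first) holds exactly and is asserted in
tests. Whether the transform should precede integration is genuinely
open; transform-first is the package default and the report records
the convention used.

## Inferential battery

All tests are two-tailed at α = 0.05. The battery comprises:
pre-planned paired t-tests for the three named states (RS1↔RS2 and
RS2↔RS3); Pearson correlations of stress/alertness change with ΔHAS
and ΔLAS; AUCg and AUCi against ΔTRS/ΔHAS/ΔLAS (a family of six);
trait mindfulness (FFMQ full-scale score, range 39–195, 16
reverse-keyed items from the Non-Judging and Acting-with-Awareness
facets) against baseline TRS occupancy and against ΔTRS/ΔHAS/ΔLAS (a
family of three); and the pairwise correlations among the three named
states' deltas. Family-wise adjustment is Holm by default (Bonferroni
available); raw and adjusted p are reported side by side, and tests
outside a named family carry their raw p as the adjusted value.
Missing data are handled pairwise-complete per test; tests with fewer
than three complete subjects are skipped with a logged reason.

A structural caveat: the delta–delta correlations are computed on
compositional data (per subject the deltas sum to zero), so they are
negatively dependent by construction — roughly −1/(k−1) under
exchangeable noise — and a zero-correlation null is false for them in
any cohort. Calibration claims in the test-suite therefore cover the
tests whose null can actually hold: the paired t-tests and the
correlations with external variables.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not fMRI physics. Defaults are the targeted study conditions: 40
subjects, 3 runs of 300 volumes at TR = 2 s, 114 cortical ROIs, k = 5
states.

* **Centroids** are random low-rank-factor correlation matrices (3
  latent factors, 10 % identity blend, nearest-correlation projection)
  — distinct by construction (pairwise |ρ| < 0.95 enforced by redraw).
* **State sequences** switch at block granularity with geometric dwell
  lengths (mean 30 volumes ≈ 60 s, the seconds-to-minutes timescale of
  resting-state dynamics); block states are drawn with probability
  proportional to each state's remaining occupancy quota, which keeps
  empirical occupancy within about one block of target.
* **BOLD** is sampled i.i.d. within a state from a zero-mean
  multivariate normal with the active centroid as correlation matrix,
  plus independent noise (default σ = 0.5) and a 1000 a.u. baseline so
  percent-based QC metrics behave. No hemodynamic convolution, no
  autocorrelation, no physiological noise — which is precisely why the
  MTD recovery tests are interpretable.
* **The stress effect** is a subject-level latent drop in the
  designated (task-ready-like) state's occupancy between RS1 and RS2
  (population mean 0.30 → 0.18, subject SD 0.10, other states rescaled
  on the simplex); RS3 keeps the RS2 target (no recovery, matching the
  design's persistence finding). Trait scores (FFMQ scale, mean 117,
  SD 20, clipped to 39–195) and a cortisol response factor are drawn
  jointly normal with the latent drop at configurable correlations
  (defaults 0.32 and −0.33); subjective stress change correlates with
  trait at −0.41. Cortisol curves are gamma-shaped (peak ≈ 30 min
  post-onset, baseline 0.18 µg/dL, ~2.5× peak response) with
  multiplicative log-normal noise.
* **Motion** is a six-parameter random walk calibrated to a mean FD
  near 0.05 mm, with rare spikes (default 1 % of volumes) injected
  into both the trace (0.5 mm) and the signal (~6 % DVARS), so the
  marking rule has something to catch.

Everything is a pure function of the master seed; sub-seeds are drawn
from a single seeded stream so the latent structure is identical
whether or not BOLD is generated.

What passing recovery tests show — and do not show. With
well-separated centroids, low noise and long dwells, the pipeline
recovers window labels (≥ 95 %), centroid identity (Spearman ρ > 0.9)
and per-run occupancy (± 0.05). That validates the estimator chain,
not performance on real BOLD, where hemodynamic smoothing,
autocorrelation and weaker state separation will reduce accuracy.
Similarly, the injected-effect recovery uses the noiseless occupancy
readout (the generating targets): with the default 60 s dwell a
292-window run estimates its own occupancy with an SD near 0.1, which
attenuates a subject-level correlation of 0.6 to roughly 0.24 — a
realistic reminder that run length bounds the detectable effect size.

## Problem sizes used in the automated checks

Recovery checks run on 23 subjects × 3 runs × 300 volumes over 30 ROIs
(20,148 windows ≥ 20,000) with σ = 0.05 noise and 60-volume dwells;
effect recovery on 200 subjects with an injected trait correlation of
0.6; type-I calibration on 1000 null cohorts of 40 subjects (400 in
the acceptance script). These sizes are the package's documented
study conditions for its own validation.

## Known limitations

* DVARS on ROI averages is gentler than voxel-level DVARS; thresholds
  tuned for voxel data may need revisiting on ROI inputs.
* The k-medians fit, like all Lloyd-style algorithms, finds local
  optima; restarts mitigate but do not guarantee the global optimum.
* The synthetic cohort's cortisol–connectivity coupling is injected at
  the level of a latent response factor; the realised correlation of
  log-AUC with the occupancy drop is attenuated by baseline variation
  and curve-shape noise.
* No dwell-time, transition-matrix or switching-rate analyses are
  provided; occupancy and its change scores are the only state
  summaries.
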