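# Methods

`ftdnet` implements a functional-connectome resilience analysis for
presymptomatic genetic frontotemporal dementia (FTD): wavelet-band
connectivity from parcellated fMRI-like time series, weighted graph metrics
normalized against degree-preserving null graphs, hub analysis, and
mixed-effects group / breakpoint / association inference.  Because
multicentre genetic-FTD imaging data are not publicly distributable, the
package ships a seeded synthetic-cohort generator that emulates the
*statistical* structure of such a study, and every pipeline stage is
validated against that generator's known ground truth.

## Cohort model

A cohort consists of three groups — gene-negative relatives, presymptomatic
pathogenic-variant carriers (C9orf72 / MAPT / GRN), and symptomatic FTD —
with default sizes 80 / 68 / 24 (the 172-subject analyzed cohort).  Each
subject carries age, sex, scan site (default 5 sites), family gene, years to
expected symptom onset (negative before onset; carriers drawn uniformly on
[−25, −1] years, FTD on (0, 10], gene negatives on [−25, 5] as a family
covariate), a motion spike percentage, brain volume as % of total
intracranial volume, and cognitive z-scores.  Group-level age and sex
distributions follow the demographics of a genetic-FTD family study (FTD
older, fewer males).

### Connectivity generative model

Each subject has a target correlation matrix built from a cohort-level
template:

* **Ring of communities.** Regions are divided into communities of
  `community_size` (default 6) arranged on a ring; correlations are 0.45
  within a community, 0.18 between ring-adjacent communities, and 0 at
  larger ring distances.  This layout is close to a latent community-factor
  model and therefore near-positive-semi-definite by construction; the final
  eigenvalue-clipping projection is mild and does not smear the planted
  structure.
* **Hubs.** A fixed, evenly spaced 10% of regions get elevated correlations
  to their own community (0.65) and to members of the two neighbouring
  communities (0.30).  Realized hub connection strengths then stand more
  than 2 SD above the across-region mean, so the strength-based hub
  definition recovers them.
* **Integration (organization level λ).** A subject's λ sets how many
  long-range pairs (ring distance ≥ 2) carry correlation 0.35:
  `round(20·λ)` pairs, drawn nested from a seeded cohort-level ordering.
  These are small-world shortcuts; their count is the dial that moves the
  network between a segregated lattice and an integrated small world, and it
  is what normalized global efficiency responds to.
* **Connectivity loss (retention fraction).** Disease-related loss of
  functional connections is modelled as *pruning*: a fraction of the
  non-hub local pairs is reset to background, nested in a seeded order.
  Pruning lowers total connection strength while leaving the correlation
  amplitude of surviving connections — and therefore the noise behaviour of
  the thresholding step — unchanged.

Both dials follow deterministic trajectories in years-to-onset *t* plus
per-subject lognormal jitter (SD 0.05):

* retention declines linearly along the whole onset axis,
  `1 − 0.008·(t + 25)`, for every family member, and is multiplied by
  `ftd_strength_scale` (default 1) in the symptomatic group.  FTD subjects
  therefore sit furthest along the loss gradient — reproducing the FTD
  strength deficit — without any step at the diagnosis boundary.  An
  onset-locked step was deliberately rejected: piloting showed the
  discontinuous breakpoint model detects such a step in ~90% of cohorts,
  whereas the observed phenomenon is a strength deficit *without* an onset
  breakpoint.
* organization rises linearly from 1 (25 years before onset) to
  1 + `carrier_efficiency_offset` (default 0.25) at expected onset — the
  resilience/compensation phase — and declines after onset at
  `post_onset_efficiency_slope` per year.  The default post-onset slope was
  fixed by a one-off calibration study (pipeline runs on large calibration
  cohorts) at the value that balances the carrier and FTD group means of
  realized normalized efficiency, because the emulated finding is a
  *non-significant* carrier-vs-FTD efficiency contrast coexisting with a
  clear post-onset decline.  A residual, approximately linear-in-*t*
  coupling between pruning and normalized efficiency (pruned local edges
  are replaced at fixed density by relatively more bridging edges) is
  harmless to the breakpoint analysis — the model absorbs linear trends —
  and is included in the balance calibration.

Outcome couplings: FTD brain volumes are coupled to the subject's
connectivity jitter at target correlation `volume_coupling_r` (default
0.65, consistent with the strongly significant strength–atrophy correlation
the analysis is meant to detect at n = 24); gene-negative and carrier
volumes are uncoupled.  Cognitive z-scores are linear in the subject's
connectivity level with a −2 SD symptomatic intercept shift and unit-scale
noise.  Spike percentages follow a scaled Beta distribution with a
configurable fraction of high-motion (> 10%) subjects so the exclusion
stage can be exercised; the default cohort is post-QC and sets that
fraction to zero.

### BOLD synthesis

Signals are multivariate Gaussian innovations with the subject's target
covariance, bandpass-filtered (3rd-order Butterworth, zero-phase) into the
analysis band.  Filtering is identical across regions, so wavelet-scale
correlations converge to the target correlations as the series lengthens.
No hemodynamic response, drift, or motion beyond the scalar spike
percentage is modelled.  The default series length is 512 samples at TR
2.2 s — longer than a typical 5-minute acquisition — because
wavelet-correlation estimation noise at ~150 samples would dominate the
cohort-level topology effects we need to resolve at 90 regions; this is a
deliberate trade of protocol realism for statistical resolution at desk
scale, and it is the main respect in which passing tests understate the
noise of real 5-minute data.

### What the generator does not emulate

No hemodynamics, no head-motion time structure, no family pedigrees or
family random effects in expected onset, no scanner/field-strength effects
beyond additive site intercepts in the outcome simulators, no
language-corrected cognitive norms.  Passing tests therefore demonstrate
that the pipeline recovers the imposed statistical structure, not that it
would be unbiased under realistic fMRI artefacts.

## Connectivity estimation

Subjects with spike percentage strictly greater than 10% are excluded.  The
analysis band (target 0.0675–0.125 Hz) rarely matches a dyadic wavelet band
exactly, so the scale is chosen by maximal frequency overlap with the
nominal band `[fs/2^(j+1), fs/2^j]`; for TR 2.0–2.2 s this selects scale 2.
Wavelet coefficients come from the stationary (maximal-overlap) discrete
wavelet transform with Daubechies-4 filters, reflection-extended to a
length divisible by `2^j`; the `(2^j − 1)(L − 1)` boundary-affected
coefficients are dropped from each end before Pearson correlation.
Zero-variance regions raise an error rather than propagating NaN.

## Graphs and metrics

Connectivity matrices are thresholded to a target edge density (default
10%) over a maximum-spanning-tree backbone, which guarantees connectedness;
negative correlations are zeroed by default (an absolute-value policy is
available).  Path lengths use the standard distance transform d = 1/w.
Per node: strength (sum of incident weights), farness (mean shortest-path
length to the other nodes; the closeness-centrality variant where lower is
better), and nodal efficiency (mean inverse shortest-path length).
Globally: total connection strength (sum of nodal strengths) and global
efficiency (mean inverse shortest-path length over ordered pairs — the mean
is used rather than the literal sum, which differs only by the constant
n(n−1)).

Efficiency and farness are normalized by their means over an ensemble of
degree-preserving surrogates (default 500, reduced to 50 in desk-scale
runs): connectivity-preserving double-edge swaps randomize the binary
topology (swaps that would disconnect the graph are rolled back; a
saturated graph admits no swaps and keeps its topology) and the empirical
edge-weight multiset is randomly permuted onto the rewired edges.  Hubs are
regions whose mean strength across gene-negative subjects exceeds the
across-region mean by more than 2 sample SDs (strict inequality); the hub
definition uses gene negatives only and is therefore independent of the
groups being compared.

## Inference

Group contrasts fit `outcome ~ group + age` with crossed random intercepts
for scan site and gene by REML (statsmodels MixedLM in its
variance-components formulation), on all three groups so the age effect is
anchored by the gene-negative group; the requested pairwise contrast is
tested with Satterthwaite degrees of freedom.  Satterthwaite df are
computed in-package — `df = 2f²/(∇f' Σ_θ ∇f)` with `f = c'(X'V⁻¹X)⁻¹c`, the
gradient by central finite differences over the variance parameters, and
`Σ_θ` the inverse observed information of the REML log-likelihood — and are
validated against R's lmerTest in the test suite (agreement to ~4
significant figures on a crossed-design fixture).  Random factors with
fewer than two observed levels are dropped with a warning; with none left
the model is ordinary least squares and df are exact.

The breakpoint model fits
`outcome ~ t + (t − knot)₊ + 1{t > knot} + age` on carrier and FTD rows
(years to onset is not meaningful for non-carriers; a flag can include
them), where `t` is years to expected onset and the knot defaults to
onset.  Both a slope change and a level discontinuity are allowed.  The
headline test is the joint 2-df test of those two terms: the exact nested F
test in the OLS path, and the analogous Wald F with Satterthwaite
denominator df on the REML fit otherwise.  A likelihood-ratio test with ML
refits was implemented first and rejected: near zero-variance boundaries
the refits are numerically unreliable (occasionally negative LR statistics,
type-I error 0.195); the Wald-F formulation calibrates at 0.055 over 1000
null simulations.

The hub × group interaction uses the within-subject hub-minus-nonhub gap:
under the model `outcome ~ hub_flag × group + age + (1|subject)` the
per-subject gap is the sufficient statistic for the interaction —
differencing cancels the subject intercept exactly and leaves
homoscedastic gaps — so the interaction is the group effect in
`gap ~ group + age` with site/gene random intercepts where estimable.
Fitting the two-rows-per-subject cell means directly was conservative
(empirical size 0.02) because averaging unequal numbers of hub and non-hub
regions makes the cell residuals heteroscedastic.

Associations report Pearson r and p within each group plus a
slope-difference (interaction) test from `y ~ x × group + age` on the two
groups pooled.  No multiple-comparison correction is applied anywhere —
network measures are not independent — and this is stamped into the run
report.

## Numerical choices and degenerate inputs

Eigenvalue clipping at 1e−6 with diagonal renormalization projects jittered
covariances to valid correlation matrices.  Connectivity estimates are
symmetrized and clipped to [−1, 1].  Graph construction raises on inputs
that cannot yield a connected graph; constant outcomes yield a flagged
degenerate contrast (estimate 0, undefined p) rather than an error; an
empty hub set raises with an instruction to re-run hub identification;
zero-variance association variables are reported as NaN correlations.
Null-ensemble swaps, cohort generation, and BOLD synthesis are all driven
by explicit integer seeds; identical configuration and seed reproduce every
output table bit-for-bit.

## Parcellation

A centroidal Voronoi tessellation generator (Lloyd's algorithm on voxel
coordinates: nearest-centroid assignment alternating with centroid
recomputation, both steps non-increasing in quantization energy; empty
parcels reseeded at the worst-quantized voxel) produces approximately
equally sized parcels — on a ~60k-voxel ellipsoidal mask, 500 parcels with
a size coefficient of variation below 0.25.  The pipeline's synthetic
regions are indices, not volumes, so the parcellation generator stands
alone as the tool one would run on a real mask.

## Scale of the shipped analyses

Desk-scale runs use 90 regions (not ~500), 50 null graphs (not 500), and
one cohort per configuration; the acceptance script's simulation studies
use 100–400 replicates per quantity.  These sizes were chosen so a full
reproduction completes on a single CPU in minutes while every effect the
generator imposes remains comfortably detectable; all of them are exposed
as configuration, and the full-scale values are the documented defaults of
`RunConfig` (500 nulls) and the parcellation generator (k = 500).

## Known limitations

The generator's effect trajectories are piecewise linear in years to
onset; real trajectories are unlikely to be linear or common across
families.  The balance between the pruning confound and the organization
slope is calibrated at the default configuration; changing region count,
density, or series length shifts that balance and with it the size of the
carrier-vs-FTD efficiency contrast.  Normalized-efficiency values depend on
the estimation noise of the correlation step and are therefore not
comparable across different series lengths.  The mixed-model layer covers
crossed random intercepts only, not random slopes.
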