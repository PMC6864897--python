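# Methods

This note records the models the package implements, the defaults and why,
the numerical choices, and what the synthetic studies do and do not show.

## Functional pipeline

The per-subject pipeline runs in a fixed order: motion QC → scrubbing →
nuisance regression → temporal filtering → correlation. Re-running on
identical input is bit-identical.

**Frame-wise displacement.** FD_t = Σᵢ|Δtransᵢ| + r·Σⱼ|Δrotⱼ| with head
radius r = 50 mm and FD₀ = 0 — the standard convention for converting
rotations to arc length. Frames with FD strictly above 0.5 mm are flagged;
a subject with more than 10 % flagged frames raises an exclusion signal.
Rotations are radians unless the caller sets the degrees flag; the
units contract is explicit because motion files do not self-describe.

**Scrubbing.** Flagged frames are replaced per node by a cubic B-spline
interpolant through the unflagged frame indices (cubic because it is the
standard order and reproduces linear signals exactly, which doubles as a
test oracle). Flagged frames at a sequence boundary would require
extrapolation; they are clamped to the nearest valid frame with a warning.
Whether scrubbing runs before or after nuisance regression is not uniquely
determined by common practice; scrub-first is the default (remove artifact
frames before any statistic touches them) and the stages are separately
callable if a different order is wanted.

**Nuisance regression.** OLS of each node signal on [intercept | WM | CSF |
(task means, active tasks only) | 6 motion parameters]; residuals are
orthogonal to every column by construction. Task regressors supplied with
resting-state data are rejected. Rank-deficient designs are rejected naming
the collinear columns (QR with pivoting).

**Temporal filtering.** Resting data: zero-phase second-order Butterworth
band-pass 0.008–0.1 Hz applied forward–backward (no phase distortion).
Task data: high-pass via regression on a discrete-cosine drift basis with a
128 s cutoff — the convention of SPM-style pipelines, and exactly mean-
removing for constant signals.

**Correlation.** Pairwise Pearson r over all node pairs; diagonal stored as
0. Zero-variance nodes (detected with a relative tolerance, since a
constant signal's sample std is rounding noise) get all their edges set to
0 and are recorded in the QC log.

**Structural ingestion.** Streamline-count matrices must be square,
nonnegative and integer. Triangles are merged by element-wise max (counts
are direction-agnostic; max also handles upper-triangle-only files), the
diagonal is zeroed, and asymmetry beyond tolerance is QC-logged. Tracking
parameters (seeding, minimum streamline length) are preconditions of the
input, not operations of this package.

## Network-based statistics

Edge-wise model: weight ~ intercept + group + age + sex + site + protocol,
fit by least squares; the group test is the partial F with 1 numerator df
(equivalently ANCOVA; with no covariates it reduces exactly to the squared
pooled-variance two-sample t, an identity the tests assert at 1e-8).
Functional weights are Fisher z-transformed before fitting (variance
stabilization; switchable off). Zero-variance edges are untestable and are
excluded with a log entry.

Components: edges with p ≤ .005 (inclusive) form a graph whose connected
components are the candidate sub-networks; all components are reported,
sorted by extent then lexicographically smallest node pair. The permutation
null shuffles group labels across subjects — covariate rows stay attached —
and records the maximal component extent per permutation (0 when the graph
is empty); 5,000 permutations by default. Plain relabeling is the default
scheme because it is the literal procedure; it is approximate when
covariates are strongly group-associated.

FWE p per component: the add-one estimator (1 + #{null ≥ extent})/(K + 1),
which can never return 0 and is exact under exchangeability; a literal mode
returns the raw proportion of strictly larger null maxima instead. Every
observed component is compared against the same max-extent null.

**Discreteness and calibration.** The max-extent statistic is integer-
valued. When the expected number of suprathreshold edges under the null is
of order one (e.g. 190 edges at threshold .005), null maxima concentrate on
{0, 1, 2}; the add-one p then inherits strong tie-conservatism (measured
rejection rate ≈ 0.015 at nominal .05 over 200 null cohorts) while the raw
proportion becomes anticonservative (≈ 0.105) — both are artifacts of ties,
not of the machinery. The calibration study in `studies.fwe_calibration`
therefore uses an initial threshold of .05, at which the null component-
size distribution is non-degenerate and the measured family-wise error sits
at ≈ 0.034 (pooled over 1,000 cohorts), mildly conservative as expected for
a discrete add-one estimator. FWE control holds at any fixed threshold; the
densest-threshold choice only makes the check informative at desk scale.

## Synthetic cohorts

Functional signals: stationary multivariate Gaussian AR(1), x_t = φx_{t−1}
+ √(1−φ²)ε_t with ε ~ N(0, Σ_g), so the stationary covariance is exactly
Σ_g and analytic population correlations are available as test oracles.
Baseline Σ is compound symmetric (unit variance, off-diagonal ρ = 0.1 —
weak global coupling; ρ = 0 is used where edge independence is wanted). The
low-expression group's Σ adds the effect size to each planted entry and is
eigenvalue-clipped to the nearest positive-definite matrix; if clipping
moves a planted entry by more than 25 % of the requested effect, the
configuration is rejected naming the worst edge (the effect is not
faithfully plantable — e.g. a high-degree hub of mutually uncorrelated
targets). AR coefficient φ = 0.3, TR = 2 s, 150 frames by default.

Structural counts: negative binomial per edge (mean 50, dispersion 5 —
overdispersed as tract counts are), with the planted edges' means
multiplied by exp(effect size) in the low group.

Motion: a slow random walk (drift well under threshold) plus step-like
translation spikes at a configurable per-frame rate (2 % default), each
producing one flagged transition, so the flagged fraction estimates the
rate. Covariates are generated independently of group; sex composition per
group defaults to the observed 107/89 vs 65/15 male/female split.
Behavioral scores (ERQ reappraisal 27.2 ± 6.6, suppression 14.0 ± 4.9,
SRRS 287 ± 195) optionally load on the standardized mean planted-edge
structural connectivity with coefficient λ; with unit residual noise the
population correlation is λ/√(1+λ²).

Reference settings used by the recovery studies, chosen once: effect size
0.3 (a moderate, detectable covariance increment at 30 + 30 subjects ×
150 frames), behavioral loading 0.5 (population partial r ≈ 0.45).

What the generator does *not* emulate: realistic spatial covariance of
real connectomes (compound symmetry/independence is a stand-in), spatially
structured motion artifacts coupled into the BOLD signal, scanner/site
effects on the signal itself, non-Gaussian heavy tails, or realistic
tractography geometry. Passing recovery tests therefore demonstrate that
the *procedures* are correct and calibrated under a known generative model,
not that real acquisitions meet these assumptions.

## Characterization and associations

The bundled 116-label partition maps each region to one of six divisions
(frontal, parietal, occipital, temporal, cingulate, subcortical). The
six-division scheme is standard; a handful of assignments are conventional
rather than forced: cerebellum and vermis, insula, hippocampus,
parahippocampal gyrus, amygdala and the basal ganglia/thalamus are filed
under "subcortical", fusiform and the temporal poles under "temporal",
paracentral lobule and olfactory cortex under "frontal". The table is a
plain TSV and user-overridable.

Top-fraction ranking sorts component links by ascending p (ties: descending
F, then node pair) and takes ⌈fraction·extent⌉ — ceiling, so a nonempty
component always yields at least one link. Mean sub-network connectivity
averages *raw* edge weights (r or counts, no Fisher transform) because the
scores feed plots and follow-ups on the connectivity scale.

Interaction test: OLS score ~ group + sex + group:sex + age + site; the
interaction has 1 df so F = t². Empty group × sex cells are rejected by
name. Sex-matched re-tests: seeded random down-sampling of each group's
over-represented sex until male fractions match the most balanced group
(the subsampling seed is part of the reported output); male-only and
female-only strata drop sex as a covariate. Partial correlation:
residualize both variables on [intercept | age | sex | site dummies], then
Pearson r of residuals with p from the t transform at df = n − 2 − k,
k counting all residualized regressor columns; two-sided; listwise deletion
with the exact n reported.

## Study sizes and determinism

The bundled studies use 20-node cohorts of 30 + 30 subjects with K = 99
permutations (200 cohorts for null calibration, 20 for recovery), 200
replicates for interaction type-I error and 100 for loading-sign recovery —
sizes at which each study completes in seconds to a couple of minutes on a
single core while leaving the binomial acceptance bands meaningful. All
randomness flows from one master seed through named substreams
(`numpy.random.SeedSequence`); identical configuration implies bitwise-
identical cohorts, null distributions and output files (the pipeline
manifest digests every output to make this checkable).

## Known limitations

- Plain group relabeling ignores covariate-group association; Freedman–Lane
  style residual permutation is not implemented.
- Cluster *extent* is the only component statistic (no intensity/mass, no
  threshold-free enhancement).
- The B-spline scrubber interpolates each node independently and does not
  propagate interpolation uncertainty.
- Discreteness makes permutation p-values conservative when the
  suprathreshold graph is nearly empty (see above); at very sparse
  thresholds a detected single edge can never reach small p, which is the
  intended behaviour of extent-based inference.
- The atlas partition's conventional assignments (insula, medial temporal
  structures, cerebellum) materially affect iso/aniso percentages; studies
  sensitive to this should supply their own table.
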