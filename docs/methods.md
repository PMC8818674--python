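# Methods

`ojipnet` implements a reusable version of a salt-stress analysis workflow
for glycophyte/halophyte physiology studies: fast chlorophyll-a
fluorescence (OJIP) screening of photosystem II, leaf gas-exchange
statistics, and label-free root-proteome comparison with correlation-network
inference. This note records the models, conventions, parameter defaults and
numerical choices, and what the synthetic generators do and do not emulate.

## OJIP transients and the JIP-test

A dark-adapted leaf exposed to saturating light shows a polyphasic
fluorescence rise with inflections O (~50 us), K (300 us), J (2 ms),
I (30 ms) and P (the peak F_M). The JIP-test condenses the curve into
landmark intensities and derives quantum yields, per-reaction-centre (RC)
and per-cross-section (CSm) energy fluxes, pool sizes and performance
indices.

Conventions (each is the mainstream JIP-test choice; the alternatives are
noted where a choice was genuinely open):

- **Fo is F at 50 us.** All windowed normalizations anchor there.
- **Interpolation is linear in log10(time).** The rise is log-time native;
  cardinal times rarely coincide with instrument samples. Queries outside
  the sampled range are errors, never extrapolations.
- **Mo = 4 (F_300us − Fo)/Fv per ms** (Fv = F_M − Fo), the standard
  finite-difference estimate of the initial relative rise slope.
- **ABS/CSm is approximated by F_M.** The de-excitation constants use the
  same scale: Kp = ABS/CSm (1/Fo − 1/F_M), Kn = ABS/CSm / F_M. A
  consequence worth stating plainly: with this scale Kp = Fv/Fo and Kn = 1,
  so Kp/Kn are *invariant* under a uniform detector-gain rescaling of F,
  while the five CSm fluxes and PI(csm) scale linearly with gain. The
  gain-invariance test asserts exactly this behaviour.
- **Sm = (complementary area)/Fv**, the area integrated on the native grid
  in linear time between 50 us and t(F_M) (units: intensity x ms, making Sm
  a dimensionless turnover count). Whether the area should be bounded by
  t(F_M) or the full record is a genuinely open convention; the
  t(F_M)-bounded form was chosen and is what N = Sm Mo / V_J inherits.
- **PI(csm) = PI(abs) x ABS/CSm**, the standard cross-section performance
  index.
- An "OCE" parameter sometimes listed alongside DF has no standard closed
  form and is deliberately **not** computed.

Degenerate inputs are flagged, never silently infinite: F_M <= Fo yields
phi_Po = 0 with all RC-normalized quantities NaN plus a
`degenerate_fm_le_fo` flag; V_J in {0, 1} NaNs the ratios that divide by
V_J or 1 − V_J. A maximum sitting on the last sample sets `truncated=True`.
Ties in the maximum resolve to the earliest time.

## Difference bands and the I-P half-time

Relative variable fluorescence is computed on five windows (V_OP, V_OK,
V_OJ, V_OI, V_IP, anchored as in the module docstring), each on a log grid
of 60 points/decade with exact endpoint normalization. The V_OI upper bound
defaults to the 30-ms I step and is configurable (`voi_upper_us`), since
published window definitions for this band vary.

Difference bands (treated minus control) are computed on the shared log
grid after resampling; group-level bands use replicate-mean curves, which
matches the mean +/- SD presentation convention of instrument studies;
per-replicate bands remain available for SD envelopes. The band peak is the
extremum of largest magnitude, reported with sign: a negative bell near
150 us (L-band) reports loss of antenna-PSII connectivity; a positive band
near 300 us (K-band) reports donor-side/OEC limitation.

The V_IP rise is summarized by v(t') = vmax t'/(Km + t') with t' = t − 30 ms
(origin at the I step, where "half of the I-P amplitude" is physically
meaningful). The fit is bounded nonlinear least squares with a
deterministic multi-start (Km initialized at the observed half-rise
crossing plus a fixed 10/50/150 ms ladder; vmax at 1). Flat curves, tiny
windows (< 6 points) and Km collapsing to zero report `converged=False`
with a diagnostic message rather than raising.

## Gas exchange

WUE_i = A_sat/E (umol CO2 per mmol H2O). The two-sample comparison is the
classical pooled-variance Student's t-test (the equal-variance form, not
Welch, matching the named test) with explicit degenerate handling for
zero pooled variance. The two-way ANOVA is the balanced fixed-effects
closed form (cell-mean sums of squares with interaction); unbalanced
designs are rejected rather than silently approximated, because the
closed-form decomposition is only orthogonal under equal cell counts.
Significance stars: ns / * / ** / *** at 0.05 / 0.01 / 0.001. Light- and
CO2-response curves are stored and summarized but not model-fitted; a
non-rectangular-hyperbola fit is a documented extension point.

Treatment grouping is left to the caller: the salt factor can enter with
all levels at once or one salt level against control at a time (both are
just different row subsets of the tidy input).

## Proteome classification and correlation networks

Detection: a protein counts as present in a condition when at least
`detection_min_reps` (default 1) replicates are positive; proteins absent
from both conditions are dropped with a logged count. Common proteins are
classified by FC = mean(treated)/mean(control): FC >= 2 is HAP, FC <= 0.5
is LAP, otherwise unchanged, boundaries inclusive. The widely quoted
phrasing "log2 fold change (<= 0.5 or >= 2)" mixes scales — 0.5 and 2 are
ratio thresholds (|log2 FC| >= 1) — so the thresholds are implemented on
the ratio scale and are configurable. A "common" protein with control mean
zero (possible when `detection_min_reps` is below the replicate count) is
an infinite fold increase: classed HAP with an explicit flag.

Correlation profiles default to **replicate-wise treated/control fold
values** (one value per replicate pair). This is a modelling choice, not a
forced one — the correlated dimension is rarely stated in publications —
and raw replicate abundances are selectable (`profile='raw'`). Pearson r
comes with a two-sided p from the exact t transform on n − 2 df. The
network keeps edges with |r| >= 0.99 and p <= 0.05 (both configurable),
undirected and simple. Note the df consequence: with 3 replicate fold
values (df = 1), p <= 0.05 already requires |r| >= 0.997, and ~5% of
*independent* profile pairs exceed |r| = 0.997 by chance; sparse networks
from triplicate designs should therefore be read as hypothesis generators,
not estimates. Network-recovery experiments in the tests use 6-replicate
profiles, where the chance rate at the 0.99 cut is ~1.5e-4 per pair.

Graph statistics: mean degree 2E/N; Watts-Strogatz local clustering
(degree < 2 contributes 0) averaged over all nodes; closeness with the
Wasserman-Faust component scaling so disconnected graphs are well-defined.
Degree classes default to cuts at 40 and 50 edges (low/mid/high).
Hierarchical clustering is average-linkage agglomeration on d = 1 − r,
written out explicitly so the tie break is deterministic (smallest index
pair); scipy's implementation serves as an independent oracle in the test
suite. Exports: GraphML or paired edge/node TSVs, round-trippable with all
attributes.

## Synthetic generators

Every generator is a pure function of (spec, seed); reruns are
bit-identical.

**OJIP**: F(t) = Fo + Fv Σ_k w_k t^h/(t^h + tau_k^h) — one Hill sigmoid per
kinetic phase — plus optional Gaussian-in-log10(t) band perturbations and
i.i.d. Gaussian noise. Defaults: Fo = 500, F_M = 2500 (Fv/Fm = 0.8, the
healthy-leaf value), tau = 0.6/10/80 ms, w = 0.5/0.3/0.2 (V_J ≈ 0.47,
V_I ≈ 0.79), h = 2, 40 points/decade from 10 us to 1 s. Analytic values at
the cardinal times are stored as ground truth. The preset salt experiment
lowers F_M and raises Fo with dose and injects a +K-band (300 us) at the
moderate dose and a −L-band (150 us) at the severe dose.

What the generator does **not** emulate: the post-peak fluorescence decline
(quenching) of real traces — the model is monotone non-decreasing. One
consequence is an identifiability limit the tests respect: under plateau
noise the time of the maximum, t(F_M), is degenerate (the noiseless argmax
sits at the end of the record), so t(F_M) and the ratio Sm/Tfm cannot be
recovered to tight tolerance at any realistic replication; recovery checks
therefore cover the landmark intensities and all derived parameters except
Sm/Tfm, with noisy-recovery measured on the pointwise mean of 512
replicates (so that estimator scatter is small against the 5% check
tolerance). It also does not emulate detector saturation, lamp rise time,
or correlated (1/f) noise.

**Proteome**: log-normal base abundances; condition-specific proteins
zeroed on one side; common proteins get a true FC drawn log-uniformly from
per-class ranges (HAP [2, 8], LAP [1/8, 1/2], unchanged [0.8, 1.25]);
class fractions default to 7.8% / 9.8% / 82.4%. Differential proteins share
latent block factors: fold profiles within a block are correlated to
`block_r` (via an additive latent-noise construction with
sigma_w = sqrt(1/r − 1)) and independent across blocks. A single `noise_sd`
dial controls both replicate-level technical scatter and fold noise, so a
noiseless spec reproduces classes exactly. Not emulated: intensity-dependent
missingness, shared-peptide inference artifacts, normalization drift.

**Gas exchange**: Gaussian noise around group means, clipped at zero. The
preset encodes a ~45% A_sat decline (and stronger stomatal closure) at the
severe dose, ~25% at the moderate dose.

Because the generators are idealized, green recovery tests demonstrate
correctness of the analysis machinery under the stated statistical
structure — not robustness to the full pathology of instrument or MS data.

## Problem sizes and determinism

The packaged test suite and the acceptance script run experiments at desk
scale, chosen as the smallest sizes at which each estimator's sampling
error is small against its check tolerance: 4 replicates per treatment
group for transient and gas-exchange experiments (the usual biological
replication), 200-protein tables (study-like class proportions preserved),
512-replicate means for the noisy JIP recovery experiment, and 100-node
tables for network block recovery. All randomness flows from a single seed
through `numpy.random.default_rng` / `SeedSequence.spawn`; pipeline reruns
with the same config and seed are byte-identical on every CSV/JSON output.
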