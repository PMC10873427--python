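# Methods

This note records the statistical models, the defaults and why they were
chosen, the numerical choices, and what the synthetic-data generators do
and do not emulate.

## FRET efficiency decomposition

The assay reads donor (mTq2) fluorescence at a single wavelength, 476 nm,
after sequential detergent treatments of suspended transfected cells. SDS
dissolves all receptor complexes, so the SDS spectrum is taken as the
fully dequenched, zero-FRET reference; the efficiency under any condition
is the fractional dequenching relative to that reference. Mild detergent
(DM) dissolves oligomers of folded receptor but not aggregates, which
splits total FRET into a DM-sensitive (oligomer) and DM-insensitive
(aggregate) component:

    E_ins  = (F_SDS − F_DM) / F_SDS
    E_sens = (F_DM  − F_0)  / F_SDS
    E_tot  = E_sens + E_ins          (≡ (F_SDS − F_0)/F_SDS)

The components are computed directly from intensities and the total is
their float sum, so conservation holds bit-exactly, not only
algebraically. The 476 nm read is a linear interpolation on the measured
wavelength grid (exact on grid hits); a band integral would be an
alternative, but a single-wavelength read was adopted as the simplest
convention consistent with a stated readout wavelength. Small negative
efficiencies produced by noise are retained — clipping them would bias the
fitted plateau upward.

### Saturation-curve fit and specificity test

E versus the acceptor:donor expression ratio x is fit by unweighted least
squares to E = E_max·x/(EC50 + x) with bounds E_max ∈ [0, 1],
EC50 > 0, multi-started from the A:D quartiles (the SS surface has a
shallow valley toward large EC50). Standard errors come from the
Gauss-Newton covariance σ²(JᵀJ)⁻¹ with σ² = SS/(n − p).

A component is only evidence of physiological complexes if its E_max
exceeds an empirically defined non-specific ceiling (random-collision
FRET at high expression). The ceiling is a required configuration value
per component — it is an empirical constant of the assay, not something
the pipeline can derive. Specificity is tested by the extra
sum-of-squares F test against the null model with E_max pinned at the
ceiling (EC50 refit), F = (SS0 − SS1)/(SS1/(n − 2)) referred to
F(1, n − 2), combined with the one-sided requirement that the free E_max
actually exceed the ceiling. The free fit is re-polished from the null
solution so SS1 ≤ SS0 always holds; when the null SS is essentially zero
or the SS difference is below optimizer resolution, F is reported as 0
(the models are indistinguishable on those data). Simulated type-I error
at the study design (6-point A:D ladder, σ = 0.01) is 0.04–0.05 at
nominal 0.05.

## Colocalization

Whole-frame (or user-masked) sample Pearson correlation of two channels,
nothing more: no automatic thresholding, Costes randomization, or Manders
coefficients, since only r with replicate mean ± SD is consumed
downstream. Constant channels raise an error rather than returning NaN.
Replicate summaries use the n − 1 SD; an n = 1 summary reports SD 0 with
an explicit flag.

## ONL decay kinetics

Counts of nuclei spanning the ONL at signed eccentricities (positive =
superior) are windowed by averaging the 600, 800 and 1000 µm positions of
one region. Time courses are fit to
y = (y0 − plateau)·e^(−kx) + plateau by global least squares with:

- **plateau fixed at 1 nucleus** — the residual cone row, excluded from
  the rod-loss model;
- **one shared y0 across series fit together** — all series start from
  the same developmentally determined count; the default grouping co-fits
  all series of one region panel, and the grouping is a configuration
  choice because any partition is statistically valid;
- **one k ≥ 0 per series**, with SEs from the joint fit covariance.

Ages are in months with 2 weeks encoded as 0.5 so that k is in month⁻¹.
A joint fit of a single series reduces exactly to the ordinary
two-parameter fit. Rate comparisons report the ratio, the percent
difference 100·(ratio − 1), and the nearest integer (half away from
zero), matching how fold statements are conventionally quoted.

### One-hit vs cumulative-damage discrimination

Exponential loss follows from one-hit (constant-risk, stochastic) death;
cumulative damage predicts sigmoidal kinetics. The alternative is
parameterized as the logistic y = 1 + (y0 − 1)/(1 + e^((x − x50)/s))
(no specific sigmoid family is canonical here), and the models are
compared by small-sample AIC (AICc) on per-mouse points — they are not
nested, so an F test does not apply. One numerical subtlety: the logistic
family reaches exponential decay only as a boundary limit
(y0 → ∞, x50 → −∞), so on exponential-truth data the optimizer stops on
its iteration cap with converged SS; any finite-SS solution is therefore
accepted. At the study design (ages {0.5, 1, 3, 6} months, n = 6 mice,
per-mouse SD 1 nucleus) the exponential truth is recognized in ~96% of
replicates, and noiseless data of either shape are classified correctly.

## ERG dose-response

Amplitudes are fit in log10-intensity space, unweighted, with eye
averaging assumed upstream. The biphasic fit enforces the identifiability
convention logKA < logKB by post-fit reordering (with f → 1 − f).
Because the model is linear in the two site amplitudes A = Rmax·f and
B = Rmax·(1 − f) once (logKA, logKB) are fixed, the fit is seeded by a
coarse grid over the half-max pair with a non-negative linear solve for
the amplitudes, then polished by bounded least squares — this makes the
4-parameter fit near-global. The standard-model solution (f = 1) is
always included as a start, so the nested SS inequality holds.

Model selection uses the extra sum-of-squares F test with df_num = 2
(logKB and f) at α = 0.05. **This test is intrinsically conservative**:
under the single-site truth the constrained biphasic optimum coincides
with the standard fit in roughly 30% of noise realizations (the
improvement direction would need a negative site amplitude), putting a
point mass at F = 0 — the classic boundary-testing phenomenon. Referred
to F(2, n − 4), the observed null selection rate is ~1–4% across
replicate blocks at nominal 5%, i.e. the test under-selects the biphasic
model rather than over-selecting it. Consumers should read a biphasic
selection as strong evidence, and a non-selection as the default, not as
proof of a single site.

## Particle counting

The interactive threshold adjustment of particle-counting practice is
replaced by a deterministic default: Otsu's between-class-variance
maximization, gated by a bimodality requirement η = σ²_B/σ²_T ≥ 0.75 at
the split (a unimodal Gaussian split at its mean only reaches ~0.64, so
a pure-noise field is declared empty instead of being shredded into
spurious objects). Any finite numeric threshold overrides the automatic
one. Components are labelled with 8-connectivity by default
(4-connectivity available) and filtered by a physical minimum area,
default 10 µm² — small enough to keep any nucleus-scale object at
typical confocal sampling, large enough to reject single-pixel noise.
Touching-object separation is not implemented; counts are exact only for
resolvable, disjoint objects, which the synthetic fields guarantee. The
count is monotone non-increasing in the minimum area, and in the
threshold as long as the threshold stays below the object intensities
(past that, noise fragments objects and the count is undefined rather
than monotone).

## Expression quantification

Densitometry: the summed rhodopsin band intensities of a lane (monomer,
dimer, higher species — band identity is input metadata) divided by the
GAPDH band, then divided by the control-group mean. qPCR: comparative-CT
with amplification efficiency fixed at 2 (no per-gene efficiencies are
available to calibrate), replicates averaged on the CT scale before
differencing, fold = 2^(−ΔΔCT). Both are exact closed forms; the only
statistical content is in the cohort summaries.

## Synthetic-data generators

Each generator is the exact right-inverse of its analysis at zero noise,
draws from one explicit seeded NumPy Generator (no global state, bit
reproducible), and records its parameters in a JSON-serializable
manifest. Defaults encode the study conditions: FRET over the A:D ladder
{0.25…8} with Gaussian efficiency noise; ONL counts at ages
{0.5, 1, 3, 6} months, 6 mice per age, per-mouse SD 1 nucleus, truncated
at zero; ERG ladders log-spaced over 0.001–20 cd·s/m²; 317 × 317 µm
fields with disjoint bright disks (rejection-sampled with ≥ 2 px
clearance) on Gaussian background; correlated Gaussian pixel fields;
CT tables constructed so that the noiseless ΔΔCT returns the true fold.

What they deliberately do not emulate: spectral bleed-through, detector
shot noise or photobleaching in FRET; spatial autocorrelation, uneven
illumination or structured organelles in images; touching or variable-
brightness particles; eccentricity structure within the averaging window;
per-gene qPCR efficiencies. Passing tests therefore demonstrate that the
estimators recover truth under the assumed noise model at the study's
sample sizes — not robustness to the systematic artifacts of real
microscopy and physiology data.

Spectra are single Gaussian emission bands peaked at 476 nm; only the
476 nm read is consumed, so richer spectral shape would be inert.

## Problem sizes

The simulation-based checks use 100 seeds for FRET parameter recovery,
1000 replicates for the FRET specificity error rate, 200 seeds for joint
rate-constant recovery and model discrimination, 400 replicates for ERG
model-selection error, 50 fields for count recovery, and cohorts of 6–14
for the correlation and expression summaries — sizes at which the
binomial/Monte-Carlo error of each reported rate is comfortably below the
tolerance being checked.

## Known limitations

- The non-specific FRET ceilings are assay constants that must be
  supplied; no default is scientifically meaningful.
- The ERG model-selection F test is conservative (see above); a
  simulation-calibrated reference would be needed for exact size.
- The particle counter has no watershed step, so overlapping objects are
  undercounted.
- The one-hit/cumulative-damage discrimination assumes the logistic form
  for the alternative; other sigmoids would give similar but not
  identical AICc margins.
- Joint decay fitting shares y0 but not the noise model across series;
  heteroscedasticity between genotypes is not modelled.
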