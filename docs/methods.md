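# Methods

This note documents the models and procedures `wormmem` implements, the
parameters that matter, what the synthetic data do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Experimental design being modelled

Animals are trained to associate butanone (BUT, the conditioned stimulus)
with food (appetitive US) or starvation (aversive US), in short- or
long-term paradigms (STAP, STAV, LTAP, LTAV), each with mock-trained
controls (identical treatment without the CS) and naive animals.  Neural
recordings follow the butanone/diacetyl exchange protocol: 60 s of
diacetyl, then six 30-s BUT/DA alternations; each exchange is a *trial*,
giving six switch times at 60, 90, …, 210 s.  Behavior is a two-choice
assay: worms start 3.5 cm from a BUT endpoint and a diacetyl alternative
and are scored by where they arrive.

## Trace processing

**Ground state.**  Normalization is F/F_G, with F_G the neuron's baseline
fluorescence.  For long exchange recordings F_G is the mean of smoothed
intensities strictly below the 10% quantile of the smoothed trace
(smoothing: centered 20-frame moving average with edge truncation; the
quantile is the linear-interpolation type).  If no smoothed value lies
strictly below the quantile (constant trace) the quantile value itself is
used.  For short recordings whose neuron returns to baseline, F_G is the
mean of the last 10 frames; the tail detector doubles as the manual
override for interneurons whose baseline must be picked by eye.
ΔF/F_max is realized as (F − F_G)/(F_max − F_G), so baseline maps to 0 and
the peak to 1.

**Resampling and features.**  Mixed frame rates (2–5 Hz across datasets)
are unified by linear interpolation to the highest rate present, never
extrapolating beyond a trace's recorded span.  Post-switch response
strength is the sum of normalized samples in [switch, switch + w); w
defaults to 10 s with a per-neuron override table, since response kinetics
differ strongly between neuron classes.  Classifier features bin activity
into non-overlapping 20-frame means (trailing partial bin dropped) and
z-score with the population (n) divisor; a zero-variance vector maps to
zeros.

A deliberate feature choice: when several neurons are concatenated, the
z-normalization is applied to the *concatenated* binned vector, not per
neuron.  Z-scoring a single neuron's window cancels any purely
multiplicative amplitude effect (z of b + A·k(t) is independent of A);
normalizing after concatenation removes only the common fluorescence scale
and keeps the between-neuron amplitude ratios that carry the group signal.

## Group statistics

The comparison design is a fixed 18-row table of group contrasts (8 for the
short-term exchange dataset), each labelled with the experience component
it isolates: CS (trained vs mock), US+/US− (mock vs naive), VAL (appetitive
vs aversive), TR (trained vs naive), SL (short vs long term).  Per
neuron × switch, summed activities pass a 95% CI filter (keep values within
mean ± 1.959964·SD of their group; sample SD, n−1), then a
distribution-aware test: Shapiro–Wilk for n < 50 else Kolmogorov–Smirnov
against a normal with the sample's mean/SD; both groups normal → t-test
(paired honored), otherwise Wilcoxon rank-sum (unpaired) or signed-rank
(paired).  Families are adjusted with Storey's pFDR at λ = 0.5:
π̂₀ = #{p > λ}/((1−λ)m), floored at 1/m (the raw estimator hits 0 for tiny
families of uniformly strong effects, which would assign q = 0
everywhere), q_(i) = min_{j≥i} π̂₀·m·p_(j)/j.  Benjamini–Hochberg (π₀ = 1)
is available as the conservative cross-check.

A property worth knowing: the CI outlier filter makes the raw tests
anti-conservative under the null (trimming > 1.96 SD points and testing
with unadjusted n roughly doubles the nominal 5% rate in our null studies,
0.096 vs 0.056 without trimming).  The q-value stage still controls the
family-wise false discovery rate: on fully null synthetic studies the
q < 0.05 rate stays well below 0.05 (the acceptance suite measures it).

Behavioral indices: CI = (n_cs − n_alt)/(n_cs + n_alt) ∈ [−1, 1];
LI_stimulus = CI_trained − CI_mock, LI_training = CI_trained − CI_naive,
LI_treatment = CI_mock − CI_naive; LIs are tested against zero by one-sample
t-tests.  Responder classification counts upward (below→above) threshold
crossings: one crossing makes a trial "responding", two crossings across
the six trials make an animal "responding"; thresholds are per-neuron
config inputs.

## Population decoding

Rows are (animal, trial) feature vectors; labels are the five short-term
groups.  Classifiers: k-nearest-neighbors with k = 2 and distance-weighted
votes, a 500-tree random forest, and an MLP with hidden layers (50, 100)
(max 2000 iterations).  Performance is macro F1 (unweighted mean of
per-class F1, zero-division → 0) averaged over 10 rounds of stratified
60/40 train/test splits; confusion matrices are pooled over rounds and
row-normalized.  Split schemes: `trial` (rows split freely),
`within_individual` (each animal's trials split in half, each half averaged
to one vector), `between_individual` (trial-averaged animals split by
animal identity, so no animal contributes to both sides).  The
scrambled-label control permutes labels before splitting and should sit at
1/K.  The scaling curve evaluates nested neuron sets in a caller-supplied
order.

## Linear-combination model of interneuron activity

Per condition, each neuron's activity is averaged across animals for each
trial within the 15-s post-switch window; the six averaged vectors are
concatenated into one observation vector per neuron.  The interneuron
response is fit by OLS (intercept included — activities are normalized but
not centered) on the sensory regressors; rank-deficient designs are
rejected naming the collinear columns.  Reported: coefficients, 95% CIs,
p-values, R², adjusted R².  Incremental fits over regressor prefixes show
the nested-model R² growth; a 50/50 random observation split
cross-validates (test R² uses the held-out mean in SS_tot and may be
negative).  Generalized least squares is deliberately not used.  The
coefficients are statistical communication-route weights, not synaptic
weights.

## Experience-component maps (PCA filtering)

The delta matrix has 36 rows — six components × six trials — where each row
concatenates all neurons' time points of a group-mean activity difference:
CS(AP) = STAP-T − STAP-M, CS(AV) = STAV-T − STAV-M, US+ = STAP-M − naive,
US− = STAV-M − naive, VAL(T) = STAP-T − STAV-T, VAL(M) = STAP-M − STAV-M.
One naive dataset anchors both US rows.  Because each trial's six component
rows are differences among five condition vectors, the matrix rank is at
most 24 in this design (and at most 35 for any 36 mean-centered rows).

PCA is run over the rows (column-mean-centered, SVD); the reconstruction
uses the scores and loadings of a caller-chosen 1-based component set
(default {1, 2, 3, 5}) and adds the column means back, preserving the delta
scale.  Which components carry experience structure is the analyst's
judgment, made by inspecting the returned loadings — it is not automated.
Retained/filtered variance fractions are eigenvalue ratios and sum to 1
exactly; the Frobenius reconstruction error equals the sum of discarded
eigenvalues.

Per neuron, component, and trial the reconstructed deltas are summed over
the neuron's time points and divided by the neuron's mean response
amplitude (a `weighting="multiply"` switch weights high-amplitude neurons
more instead); the mean over the six trials gives the signed change, the SD
the trial variability.  Significance: exact 1-D 2-means on the absolute
changes (optimal two-cluster split of sorted values by a full
within-cluster-SS sweep); the higher-centroid cluster is significant, and
the boundary (centroid midpoint) is reported.  All-equal magnitudes →
nothing significant.

## Locomotion metrics

Only the first 10 min of each track are analyzed by default.  Tracks are
cut into non-overlapping 24-frame segments: deviation angle = unsigned
angle between the segment's net displacement and the direction from the
segment start to the target (0° toward, 180° away); speed = polyline path
length / duration (cm/min); distance = segment midpoint to target.
Zero-displacement segments have no angle and are skipped (counted).
Reversals: an episode starts when a frame's displacement projects onto the
recent heading (mean displacement over the preceding 24 frames) below
−0.1 mm, and ends when forward motion resumes; rates are events per cm of
path, binned by distance to target (0.25 cm bins).  Profiles report per-bin
mean ± SEM across animals plus the 1.2–3.5 cm proximal-region summary (one
mean per animal, the unit for group comparisons by rank-sum + pFDR).

Two detector properties matter for interpretation.  First, a reversal is
only countable if the per-frame displacement exceeds the perceptibility
threshold: at 0.1 mm and 1 Hz tracking this needs speeds above
~0.6 cm/min.  Second, *tortuosity and reversals are confounded at segment
scale*: a path whose direction swings by ~140° between segments projects
briefly backward and is counted, so groups with wide deviation-angle
distributions show inflated detected reversal rates even when the planted
event rate is identical.  This is a property of projection-based detection
on center-of-mass tracks generally, not of the synthetic data alone; the
chemotaxis analysis script flags it where it shows up.

## Chemotaxis simulation

Agents replay a group's empirical locomotion distributions.  Parameters are
estimated per distance-to-target bin (0.5 cm; bins with < 5 segments borrow
the nearest populated bin; the bin range derives from the arena's farthest
corner so groups on one arena share a binning).  Each step — one 24-frame
segment duration — an agent draws a deviation angle (sign randomized, since
the measured angle is unsigned) and speed from its current bin's pools, and
a Poisson reversal count with mean (rate per cm) × (path per step); it
advances speed × step along the direction-to-target rotated by the angle,
minus one step backward per reversal event.  Both endpoints absorb (worms
are immobilized at the endpoints in the assay); walls reflect.  The output
is the arrival fraction per endpoint over time, which is non-decreasing by
construction.  Expected radial drift is E[v]·E[cos θ] per unit time, which
the acceptance suite verifies against the simulator on an effectively
unbounded arena.

Hybrid cohorts take two parameters from one group and the third from
another; the *gap fraction* of a parameter is (hybrid − naive)/(trained −
naive) in end-time CS arrival, averaged over replicate cohorts with a
normal-approximation CI.  A near-zero naive–trained gap makes fractions
undefined (returned as NaN, flagged).  Readout times matter: once both
cohorts saturate near 1 the end-time gap is uninformative, so the analysis
uses a 15-min readout where the groups are well separated.

## Synthetic data: what is emulated, what is not

**Traces.**  Per animal × neuron, raw F = baseline (100 a.u.) + transients
+ drift + noise, clipped at 0.  Transients use a difference-of-exponentials
kernel (rise 1 s, decay 8 s, GCaMP3-like; peak normalized to 1) at each
BUT onset (ON neurons) or BUT removal (OFF neurons).  Amplitude = base
amplitude × baseline × group multiplier, where the multipliers derive from
the planted neuron × component effect matrix:

    naive  = 1                STAP-M = 1 + US+
    STAV-M = 1 + US−          STAP-T = 1 + US+ + CS(AP) + VAL
    STAV-T = 1 + US− + CS(AV) − VAL

The ground truth stores both the multipliers and the implied expected
contrast of every delta-matrix component, so recovery tests compare
against derived expectations rather than raw matrix entries.  Responder
status is drawn per animal (or per trial) with per-neuron-per-group
probabilities (the canonical study gives ASER a 50% responder probability
in naive and aversively trained animals).  Noise is additive Gaussian (SD =
10% of the response amplitude by default); drift is a sinusoid of random
phase, amplitude 5% of baseline, 200-s period.  One seed drives the whole
dataset; fixed seed ⇒ bit-identical output.

Not emulated: biophysics, absolute fluorescence scales, photobleaching,
motion artifacts, neuron-to-neuron correlation beyond the planted effects,
trial-order (habituation) effects.  Passing recovery tests therefore shows
the *pipeline* extracts planted structure at realistic noise; it does not
certify performance numbers on real recordings.

**Tracks.**  Motion is segment-wise: per 24-frame segment the agent draws
an angle (truncated normal on [0, 180]), a speed (positive truncated
normal), and Poisson reversal events realized as 3-frame backward
excursions with constant per-frame step length, so per-segment path length
equals speed × duration exactly and measured per-segment statistics
recover the planted distributions.  Tracking is 1 Hz by default so
ordinary crawl speeds stay above the reversal-perceptibility threshold.
Headings jump discontinuously at segment boundaries — real worms turn
smoothly — which is exactly what produces the tortuosity/reversal confound
described above.  The canonical locomotion study plants directionality
differences only (appetitive 40° ± 20, naive 70° ± 25, aversive 100° ± 25;
speed 1.2 ± 0.15 cm/min and 0.5 reversals/cm shared), the synthetic analog
of training modulating directionality but not speed or reversals.

## Problem sizes and numerical defaults

The canonical trace study is 5 groups × 15 animals × 6 neurons at 2 Hz
(450 records); the null-FDR study uses 100 replicates of 34 neurons × 6
switches × 2 groups × 10 animals; simulations use 1000 agents.  These sizes
make every planted effect detectable while the full suite runs in a few
minutes.  Key defaults: smoothing/binning kernel 20 frames, ground-state
quantile 0.10, integration window 10 s (15 s for the regression and
component analyses), CI filter level 0.95, Storey λ = 0.5, normality-test
switch at n = 50, k-means k = 2, segment length 24 frames, reversal
threshold 0.1 mm/frame, proximal band 1.2–3.5 cm, simulator step = one
segment duration.  Ties in the 2-means sweep resolve to the first minimal
split of the sorted values; `pairwise_test` treats zero-variance groups as
non-normal and routes them to rank tests.

## Known limitations

- The CI filter's anti-conservatism (above) is inherited from the
  procedure it reproduces; interpret raw p-values accordingly and rely on
  the q-values.
- Amplitude-only group effects are invisible to single-neuron z-normalized
  features by construction; single-neuron decoding rests on shape and
  responder-probability differences and is correspondingly weak.
- The reversal detector cannot distinguish sustained retreat from a new
  heading once the rolling heading flips (~half a heading window), and
  over-counts on highly tortuous paths; reversal-rate comparisons between
  groups with very different angle distributions partially reflect
  directionality.
- Gap attribution is a one-factor-at-a-time decomposition; with
  interacting parameters the three fractions need not sum to 1.
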