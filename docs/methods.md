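# Methods

This note documents the models, the synthetic world, the numerical choices,
and the limits of what a green test establishes. Every number quoted here
is either a package default (inspectable in code) or is computed by the
test suite or the acceptance script at run time.

## 1. Stimulus space

Stimuli are abstract descriptors: up to four face parts (left eye, right
eye, a generic roving eye, nose, mouth) placed on a 3×3 grid of positions
inside a face outline. Canonical frontal-face cells are row-major 0 (left
eye), 2 (right eye), 4 (nose), 7 (mouth); an image is *typical* when every
present part sits at a canonical cell (a generic eye at either eye cell
counts), *atypical* otherwise. The candidate space assigns
{empty, eye, nose, mouth} to each of 9 cells (4⁹ = 262,144).

The 82-image screening set applies five enumeration rules in order with
deduplication against previously emitted images, where the duplicate key
collapses all eye identities to one generic eye class: the original
whole-face photograph and the noise-filled outline; the synthesized whole
face; all 27 single-part images; an anchored canonical part plus a roving
eye (4×8 − 1 = 31 after the two-eye coincidence); the canonical
contralateral eye plus a roving nose or mouth (2×8 − 2 = 14 after removing
the canonically placed nose/mouth images already emitted). The
"one or two parts missing" subset is supplied as an explicit seven-image
manifest (four 3-part faces, three 2-part faces) because no single
mechanical dedup convention yields three novel 2-part canonical faces; its
2-part entries use side-specific eye identities and are therefore distinct
grid assignments from the roving generic-eye images. Pixel rendering is
out of scope; images are descriptors only.

## 2. Synthetic recordings

Each site's firing-rate template is

    r(t) = b0 + A·g_i·α(t) + E·ψ_e(t)·f_early(i) + (L·ψ_l(t) + R·ψ_r(t))·f_late(i)

sampled as Poisson counts per 1 ms bin after multiplication by a slow
per-presentation gain (normal, s.d. 0.35, clipped at 0.05). Defaults are
multi-unit-scale rates: baseline b0 = 40 spikes/s, peak evoked rates
320/300/280 spikes/s (pIT/cIT/aIT) with log-normal site spread (s.d. 0.25
in log units), onsets 57/60/63 ms (half-rise ~60/63/66 ms, under 10 ms
apart) and a +13 ms shift for the second simulated animal. The common
kernel α rises sigmoidally (s.d. 3 ms), adapts to a 0.8 plateau
(τ = 120 ms), and is gated off ~105 ms after onset (the 100 ms
presentation). ψ_e carries early selectivity until ~35 ms after onset;
ψ_l carries the late phase, a 43 ms transient in pIT/cIT and sustained in
aIT; ψ_r is a post-error rebound in the transient regions (see §2.3).

**Why these rates and the gain noise.** At 30 ms windows, Poisson counting
noise alone would shrink by √(window) and make long-window (60–200 ms)
decoding trivially easy at any d′ compatible with the windowed medians. A
slow per-presentation excitability gain contributes variance proportional
to the rate squared that does not average out over the window, which is
what lets the same site population show median windowed d′ of ±0.1 yet
support only modestly-above-chance decoding — the regime the analysis
lives in. At multi-unit rates the gain term is comparable to the Poisson
term in 30 ms windows and dominates in long windows.

### 2.1 Calibration

Per-class site targets (d′ early, d′ late) are drawn per region:
pIT 43 decreasing / 8 increasing / 64 stable sites, cIT 18/4/48, aIT 40
stable, with class means chosen so the population medians, preference
fractions, change counts and rate changes land at the configured targets
(the `calibration_targets` block of the default config). Kernel amplitudes
E, L (and R) are then solved per site from a linear system over the
early/late window means, with the trial s.d. computed analytically from
the noise model (Poisson + gain + between-image variance, iterated to a
fixed point) and a correction absorbing the realized typical-minus-atypical
drive difference of the matched image bands. Scaling the site counts
(e.g. for fast tests) scales the class counts proportionally.

### 2.2 Image factors

Per-image drives g_i place 8 typical + 13 atypical images (including the
synthesized whole face as reference) in a band 1.02–1.10 of the reference,
and the rest at 0.45–0.70 (photograph 0.5, outline 0.1), so the
population-level 90% matching step recovers exactly those 21 at the
default scale. Selectivity factors are the class indicator (typical = 1,
atypical = 0) plus image-level jitters; the late factors share a "face
evidence" component across regions (s.d. 0.5) with region-specific
dilution, which is what makes early cIT/aIT responses negative predictors
of late pIT responses across images (the error-coding signature, target
Spearman ρ ≈ −0.5 for cIT). All jitters are centred within the matched
classes so the realized class contrast is exact.

### 2.3 The rebound and the decoding profile

In pIT/cIT the late reversal is a transient; the rebound kernel ψ_r after
it is scaled so that 75% of the class signal integrated over the 60–200 ms
decode window cancels. This is a modelling commitment of the synthetic
world: the reversal carries windowed selectivity but almost no net
long-window class information, keeping linear decoding near chance in pIT
while aIT (whose preference persists) decodes above chance. Without it,
the big per-site reversals that the change classification requires would
make pIT the *most* decodable region — the two findings jointly constrain
the temporal structure.

### 2.4 What the generator does not emulate

Trials are exchangeable (no serial dependence, no adaptation across
presentations); noise is independent across sites (pseudo-population
assumption, as in serially recorded data); there are no correlated noise
modes within a region beyond the shared image factors; the per-site
early-vs-late image correlation within pIT is more negative than zero
because early and late selectivity share the class component (the
corresponding empirical quantity is near zero); and no eye movements,
spike waveforms or LFP exist. A green calibration test therefore
establishes that the analysis chain recovers the statistics the generator
was told to produce — not that the generator is a model of cortex.

## 3. Processing and statistics

All windows are half-open `[start, end)` in ms. Baseline is each image's
across-repetition mean in 25–50 ms; the latency correction shifts the slow
animal's traces 13 ms earlier (once; a second application raises). The
visual-drive screen pools a category's trials and asks for a mean 60–160 ms
response above twice its SEM; under the gain-noise world this ratio
statistic has a non-trivial false-positive rate for silent sites, which is
irrelevant at the default configuration (no silent sites) but documented by
a test. d′ pools *all* trials of all images in a class, so between-image
variance is part of the denominator. The change classification bootstraps
trials within each image (jointly for the two windows), takes the two-sided
tail of Δd′ = d′_late − d′_early at zero (resolution 1/n_boot, floor
reported as 0), and classifies by the observed sign at p < 0.01. The sign
test is the exact binomial tail at p = 1/2. Cross-area correlations are
Spearman over per-image population rates with a joint bootstrap over images
and sites.

## 4. Dynamical models

Two-stage networks: inputs u (2) → hidden x (2) → output y (1), with
A = aI and B = b[1,1]. Three-stage: u (4) → w (4) → x (2) → y (1), with
pairwise convergence B = b[[1,1,0,0],[0,0,1,1]] and C = c[1,1]. All units
are leaky integrators (shared time constant τ); the input is a
Gaussian-smoothed step with latency t₀ (half height) and rise σ, amplitudes
h per input and condition. Architectures: pure feedforward; lateral
inhibition (mutual inhibition k_l within hidden stages only); subtractive
normalization (pooled-activity suppression k_s at every stage); shunting
normalization, whose leak scales as 1/(τ(1 − k_s·Σstage)) and is simulated
with the fourth-order Taylor expansion of the shunt factor around zero;
and feedback networks descending a quadratic between-stage reconstruction
cost (optionally through a tanh nonlinearity with threshold and bias, or a
discriminative construction cost), with k_td weighting the top-down term.
Feedback weights are the transposes of the feedforward weights, as descent
on the quadratic cost requires.

Numerical and interpretive choices:

* Fixed-step explicit RK4, default dt = 0.5 ms, zero initial state;
  halving dt changes windowed readouts by < 0.1% (tested), and the linear
  architectures agree with the closed-form matrix-exponential solution to
  better than 10⁻⁶ relative (tested against an independent oracle).
* The Taylor-4 shunt is only accepted for k_s·Σstage < 1. The exact
  shunting leak diverges there — an impenetrable barrier of the true
  dynamics — so parameter points whose trajectories cross it are reported
  as unstable rather than letting the polynomial wander into a regime the
  model does not define.
* **Readout: square each unit, then sum** (signal = sc·Σᵢ unitᵢ²).
  Squaring stands in for rectification, which acts on each neuron's rate,
  not on a population sum. The order matters mathematically: summing the
  hidden errors first collapses them to (common filter)·Σh per condition,
  which forces the error population's differential to a single sign for
  all time and would make the selectivity reversal — the phenomenon the
  error model exists to capture — inexpressible. Squaring per unit keeps
  the between-channel imbalance visible: feedback cancels the predictable
  sum mode late while the imbalance mode persists, so balanced (typical)
  inputs lose their error response and imbalanced (atypical) inputs keep
  it.
* Errors: e₀ = u − Aᵀx, e₁ = x − Bᵀy (and e₂ = x − Cᵀy for three stages);
  the top-stage error uses an auxiliary downstream predictor z with
  unit-DC tracking dynamics ż = (y − z)/τ and a gain (c for two-stage,
  d for three-stage) scaling the error's magnitude: e_top = gain·(y − z).
  The tracking form makes e_top a transient that decays to zero once the
  prediction catches up; an integrator with DC gain τ would overshoot the
  state it is supposed to predict. For the construction cost the stage
  errors are the construction residuals (Au − w, Bw − x, …) with the gain
  on the top residual and no auxiliary variable.
* Error readout mapping: pIT ← e₁, cIT ← e₂, aIT ← e_top (three-stage);
  pIT ← e₁, aIT ← e_top (two-stage). The middle-stage mapping is the
  natural extension that keeps three-region losses comparable across the
  model family.
* Parameter enumeration: 10 base parameters for two-stage models
  (t₀, σ, τ, a, b, four h values, sc) and 15 for three-stage (plus c and
  four more h values); families append k_l, k_s, or k_td (+ th, bi for the
  tanh reconstruction; + the top-error gain for state-and-error readouts).
  Bounds: t₀∈[50,70], σ∈[0.5,25], τ∈[0.5,1000] ms, coupling constants
  k∈[0,1], gains a,b,c,d∈[0,2], h∈[0,20], sc∈[0,100], th∈[−20,20],
  bi∈[−1,1].

## 5. Fitting

Targets are per-region differential (typical − atypical) and common
(class-average) population profiles on a 1 ms grid over 50–200 ms, each
normalized by the region's mean whole-face response (60–200 ms) and lightly
smoothed (Gaussian, 5 ms). Losses are sums of squared residuals normalized
by each target mode's own sum of squares (a perfect fit is 0; predicting
zero gives ≈ 1 per region and mode), regions weighted equally — the
normalization makes losses comparable across models and regions and keeps
the optimizer's landscape bounded.

The two-step procedure fits the differential mode from many random
in-bounds starts, then re-optimizes the best fits on the equally weighted
differential + common objective. Implementation: starts are a
deterministic prefix of one seeded stream (so the best loss is monotone in
their number — a tested invariant); each start's output gain sc is first
rescaled in closed form onto the target's scale; local optimization is
bounded trust-region nonlinear least squares on the residual vector, in
unit-cube coordinates with σ, τ, sc and the connection gains on a log axis
(loop time constants scale as 1/gain², so the slow-feedback regimes that
produce error transients at tens of milliseconds live at small gains); and
a fixed-budget, seeded differential-evolution probe of the differential
objective supplements the start pool with structured optima (e.g.
condition-specific input patterns) that isolated descents miss. The probe
budget does not depend on the number of starts.

`compare_models` fits each architecture with the same seed and budget and
ranks by the combined loss; when bootstrap-replicate targets are supplied,
their mean discrepancy from the original target is reported as the noise
floor. The family comparison in the acceptance suite uses the three-stage
family: with all three regions constrained jointly, state-coding models
cannot trade off unequal condition drives against the within-stage
suppression to mimic the reversal, and the error-coding model wins with a
clear margin.

## 6. Known limitations

* The fitted error model reproduces the sign structure of the reversal but
  underfits its depth at the reduced multistart budgets used in tests; the
  ranking (the tested claim) is stable across seeds, the residual
  magnitudes are not.
* The model input is a sustained smoothed step, so no model can follow the
  off-response collapse of the data after ~160 ms; this penalty is shared
  by every architecture and does not affect ranking.
* The two-stage model comparison is more fragile than the three-stage one
  (normalization architectures can partially mimic a reversal by giving
  the two conditions unequal total drive at matched sum-of-squares), which
  is why the headline comparison is three-stage.
* Bootstrap p-values have resolution 1/n_boot and are reported with a
  floor of 0 at the default 1000 resamples.
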