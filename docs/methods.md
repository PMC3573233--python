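# Methods

`bgdcm` models resting-state electrophysiology of the motor
cortico–basal-ganglia–thalamocortical loop in the treated (ON) and
untreated (OFF) Parkinsonian state, and infers which connections change
between states from paired cross-spectral densities.  This note records
the model, the estimation machinery, the synthetic-data world used to
validate it, and the numerical choices that matter.

## The generative circuit

Six sources: motor cortex, striatum, external pallidum (GPe),
subthalamic nucleus (STN), internal pallidum (GPi) and thalamus.  Cortex
is a three-population layered ensemble (spiny-stellate input cells,
pyramidal projection cells, inhibitory interneurons); each subcortical
nucleus is a single excitatory (STN, thalamus) or inhibitory (striatum,
GPe, GPi) mass.  Every population carries an excitatory and an
inhibitory second-order synaptic channel with alpha-kernel dynamics

    v' = z,   z' = kappa H (drive) - 2 kappa z - kappa^2 v,

where the drive collects gain-weighted presynaptic firing plus any
exogenous input.  Firing is a centred sigmoid of depolarisation
(`S(v) = expit(rho1 (v - rho2)) - expit(-rho1 rho2)`), so the origin is
always an equilibrium at zero input and connection signs are carried by
the kernels, not the activation.  Nine extrinsic connections wire the
standard architecture (direct, indirect and hyperdirect pathways plus
the pallido-thalamo-cortical return); three variants add a GPe→GPi or
GPe→striatum projection, or re-assign the pallidal electrode to GPe.

Defaults (all in `default_priors.yaml`; there is no authoritative public
table of constants for this circuit family, so these are reconstructed
values documented as package defaults):

| parameter | value | why |
|---|---|---|
| He / Hi | 4 / 32 mV | conventional neural-mass amplitudes |
| kappa_e / kappa_i | 250 / 100 s^-1 | kernel peaks at 4 / 10 ms |
| rho1, rho2 | 2 /mV, 1 mV | slope 0.21 /mV at baseline |
| extrinsic delay | 2 ms | places the STN–GPe resonance near 19 Hz |
| intrinsic delay | 1 ms | short intracortical conduction |
| GPe→STN, STN→GPe gains | 110, 70 | loop gain sets beta sharpness |
| cortex→STN gain | 200 | a strong hyperdirect input: its condition effect is then expressed (and identifiable) in the cortex–STN cross-spectrum |
| STN→GPi, GPi→thal, thal→cortex | 120, 120, 200 | relays subthalamic beta into pallidal and cortical channels |
| other extrinsic gains | 24 | ordinary coupling scale |

With these values the linearized OFF circuit (gain increases of ×1.5 on
cortex→STN, GPe→STN and STN→GPi) expresses a ~19 Hz resonance in every
auto- and cross-spectrum, attenuated ON — the phenotype the inference
must recover.

Innovations (neuronal noise, white + 1/f) enter the cortical input
layer, striatum and STN; site weights (0.25, 1, 1) keep the EEG channel
from being dominated by local broadband input.  Measurement noise is
white + 1/f per channel.  Conduction delays are handled exactly in the
frequency domain as phase factors `exp(-i w d)`; no Padé or Taylor
approximation is involved.  Synaptic channels that receive neither
coupling nor innovation are pruned from the linearized system (their
response is identically zero), which roughly halves the spectral
algebra.

## Data features

Each 50 s segment (1 kHz; one bipolar EEG channel, three bipolar
contacts per deep site) is reduced to three series: the EEG channel and
the first principal component (leading SVD eigenvariate, mean-centred
only) of each deep site's contacts.  The series are decimated to 200 Hz
with a zero-phase Chebyshev anti-alias filter before a vector
autoregression of order 8 is fitted.  The decimation is a deliberate
choice: a fixed-order autoregression resolves spectral structure on the
timescale of its lag window, and eight lags at 1 kHz span only 8 ms —
too short for a beta-band peak — whereas at 200 Hz they span 40 ms.
The VAR is estimated per equation by ridge-regularized least squares on
per-channel-standardized series (a zero-mean Gaussian shrinkage prior
whose precision is scale-free); the analytic transform
`S(w) = H E H*` with `H = (I - sum_k A_k e^{-iwk/fs})^{-1}` gives the
cross-spectral features, restricted to 13–35 Hz at 1 Hz steps.  The
normalization convention is fixed by the white-noise identity `S = E`.

Two bootstrap quantities accompany each segment's features, both from
surrogate series simulated from the segment's own fitted VAR:
the sampling **variance** of each feature at the full segment length,
and the finite-sample estimation **bias** (mean surrogate feature minus
the fitted value), which is subtracted from the data features.

## Inversion

One inversion fits a circuit jointly to a paired OFF/ON feature set.
All parameters are shared across conditions except per-connection
modulators, the log OFF/ON gain ratios (prior: ratio 1, SD 0.25
log-units).  All positive parameters are estimated as log-deviations
from their prior means: extrinsic gains (SD 0.25), global synaptic
amplitude/rate/delay scales (SD 0.1), per-channel observation gains
(SD 0.5), innovation and measurement noise amplitudes (SD 0.5, white
measurement noise per channel).

Because the data features live behind the VAR's parametric lens, the
model's predictions are pushed through the same lens before comparison:
the predicted spectrum (including the decimation filter's squared-twice
magnitude response) is projected onto the VAR(8) family by solving the
multivariate Yule–Walker equations on its autocovariances, and the
projected spectrum supplies the predicted features.  Model and data then
share the autoregression's representation bias instead of the inversion
mistaking that bias for connectivity.

The likelihood treats the real features (auto spectra; real and
imaginary off-diagonal parts) as Gaussian with one precision per
channel-pair group.  Precisions are anchored at the bootstrap noise
estimate and adjusted by restricted maximum likelihood within a bounded
band (they may fall freely where residuals reveal unmodelled structure,
but may rise at most 2.5 log-units above the anchor, so apparent
precision cannot explode when the model interpolates the data).  The
data pair is rescaled once so its mean in-band auto power matches the
prior-mean prediction: absolute recording scale is unidentifiable from
field potentials and this pins it without informing any relative
quantity.

Optimization is Gauss–Newton ascent on the variational (Laplace) free
energy F = accuracy − KL(posterior‖prior), with Levenberg–Marquardt
damping, step rejection whenever a candidate fails to improve F, a
trust-region cap of 0.25 log-units per step, and a finite-difference
Jacobian refreshed on alternate accepted steps.  After convergence
(ΔF < 0.05 nats twice in a row; iteration cap 96) a polish phase
line-searches along the flattest posterior eigendirections — exactly
where curved parameter trade-offs can strand a first-order ascent — and
resumes the ascent once if it improves F.  The looser tolerance and
lower cap relative to a fully converged reference run (ΔF < 0.01, cap
128) change modulator estimates by far less than their posterior spread
and keep a full cohort inversion within a practical compute envelope.
Everything is deterministic given the data: the initialisation is the
prior mean.

Because the data pair is rescaled by a (prior-dependent) normalization
factor, the reported free energy is shifted back by ``n log(norm)`` so
the bound refers to the unscaled data; without that shift, evidence
values would not be comparable across models or segment pairs.  When the
converged residuals exceed ten times the anchored noise level the ascent
is retried once with a conservative deterministic schedule (initial
damping 1, step cap 0.1) and the better bound is kept.

F differences between architectures fitted to the same segments are log
Bayes factors; fixed-effects group comparison sums F over segment
pairs.  The architecture-recovery experiment is run at the spectral-
feature level: paired spectra are generated from the standard circuit at
its prior mean (with the untreated gain increases) plus seeded Gaussian
feature noise of known scale, and every candidate is fitted with
precisions anchored on that true noise.  Fitting the candidates through
the full recording pipeline instead rewards the richer variants for
absorbing the VAR feature family's residual representation bias — a
statement about the feature pipeline, not the architectures — so the
feature-level design is the discriminating experiment; the full-pipeline
comparison remains available for inspection.

## Group inference

Per-connection group summaries follow the averaging convention of
pooling conditional means and their confidence intervals directly
(mean of bounds; a precision-weighted alternative is reported
alongside).  A connection is flagged as changed only if (i) more than
95% of the group-pooled posterior mass lies on one side of ratio 1 and
(ii) the same one-sided 95% posterior-mass criterion holds in at least
half of the individual segment pairs.  The one-sided posterior-mass
reading (threshold 1.645 posterior SDs) follows the criterion's verbal
definition; a two-sided CI-exclusion variant is not equivalent and is
not used.  Before pooling, segment pairs whose free energy falls more
than 3 median-absolute-deviations below the cohort median, or whose
inversion did not converge, are excluded — the analogue of dropping
inconsistently fitted segment pairs.

The Wilcoxon signed-rank test (used by the perturbation contrasts)
drops zero differences, mid-ranks ties (a Pratt variant is available),
computes the exact two-sided p by dynamic programming over sign
assignments for n ≤ 25 and a tie-corrected normal approximation above.

## Contribution and lesion analyses

Network beta is the 13–35 Hz integral of every source's potential
spectrum (hidden sources included through the same transfer machinery),
summed over sources.  The contribution of a connection is the central
finite difference of the per-frequency source-averaged spectrum with
respect to its gain (relative step 1e-3, shrunk once by 10x if the
stencil leaves the stable region); the scalar summary is the band
average.  STN lesioning either zeroes all gains to and from STN or
removes the source from the model; the two are equivalent over the
surviving sources because a linear source without incoming or outgoing
coupling cannot influence anything.  Partial lesions reset chosen
connections' modulators to ratio 1 (their treated strength) inside an
otherwise untreated parameter set.

## The synthetic cohort

The generator emulates the study layout: 5 subjects, 3 OFF/ON segment
pairs each, 50 s at 1 kHz.  Subject-level gains are log-normal jitters
(SD 0.1) of the prior means; segments add a smaller shared jitter
(SD 0.05).  A draw is admissible when both conditions are stable with a
decay margin of at least 4 s^-1 and the predicted STN beta contrast
OFF/ON lies in [2.5, 50] — the cohort emulates patients in whom the
untreated beta exaggeration is clearly but finitely expressed, the
phenotype that motivated the original recordings.  Inadmissible draws
are redrawn (up to 30 times).

Recordings are synthesized in the frequency domain (complex Gaussian
Fourier coefficients with per-bin covariance equal to the predicted
source cross-spectrum, so the expected periodogram equals the prediction
exactly); deep sources are mixed into three contacts with loadings
(1.0, 0.7, 0.4); every channel receives white sensor noise at 10% of
its signal variance, referenced to the quieter (ON) condition so the
same hardware floor applies to both members of a pair.  An independent
time-domain backend (Heun integration of the linearized delay system at
8x oversampling) exists purely as a cross-check of the spectral
machinery.

What the generator does **not** emulate: volume conduction and
electrode geometry, artifacts, non-stationarity, non-Gaussian or
nonlinear (large-amplitude) dynamics, and any between-subject
variability beyond gain jitter.  Passing recovery tests therefore shows
that the estimation machinery is coherent under the model's own
assumptions at realistic noise levels — not that real recordings would
be equally well behaved.

## Problem sizes and determinism

The validation experiments run at the study's native sizes (5 subjects
× 3 pairs × 50 s) for connectivity recovery; model comparison uses six
segment pairs, and the forward-model simulation oracle uses 200 s of
synthetic data.  All stochastic steps take explicit integer seeds;
inversions are deterministic given their inputs.

## Known limitations

* The reciprocal STN–GPe gains are strongly anti-correlated in the
  posterior (the loop product dominates the likelihood), so individual
  estimates of that pair lean on weaker broadband-routing information;
  conditional correlations are reported so this is visible.  In the
  cohort recovery experiment this shows up directly: the true GPe→STN
  increase splits across the reciprocal pair and its per-segment
  significance sits on a knife edge, so a minority of replicate cohorts
  flag only a subset of the three truly-changed connections (never a
  false positive).
* Feature noise is estimated by a within-family parametric bootstrap,
  which understates the variability of peak-region features for very
  sharp resonances; the bounded-ML precision band mitigates but does
  not remove this.
* The free-energy bound treats feature noise as independent across
  frequencies; VAR-derived features are smooth, so evidence differences
  between architectures are sharper than a fully honest account would
  give.  Rankings, not magnitudes, should be interpreted.
* Subjects whose drug effect is barely expressed (contrast near 1) are
  genuinely ambiguous — alternative gain configurations fit their data
  as well as the truth; the phenotype inclusion band excludes such
  draws from the emulated cohort by design.
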