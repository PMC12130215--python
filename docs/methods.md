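# Methods

## Task model

A session is a sequence of 4-s trials at 30 frames/s (120 frames): 1 s
pre-stimulus baseline, 0.25 s stimulus, 0.25 s delay, 1.5 s response window,
1 s post-phase, with inter-trial intervals drawn uniformly from 0.5–2.5 s.
Stimulus onset is frame 31 (1-based). Imaging sessions mix trial types in
exact stratified proportions — 36 % go (600 Hz), 36 % no-go (200 Hz), 25 %
probe (240–560 Hz in 40-Hz steps), 1 % reward omission (RO), 2 % unexpected
reward (UR) — shuffled by the session RNG; "additional" sessions use
48/48/4 % with no RO/UR. Stratified counts (rather than i.i.d. draws) make
the proportions exactly testable and match fixed 200-trial sessions; trial
counts must therefore be divisible by the mix. Probe frequencies are spread
uniformly over the probe set by default (weights configurable): a uniform
sub-distribution keeps every probe frequency estimable from a session of
realistic length.

## Behaving agent

Lick probability follows a lapse-adjusted probit,
p(f) = λ + (1 − 2λ) Φ(β (f − θ)), which equals ½ at the threshold θ for any
lapse rate λ ∈ [0, ½]. Naive agents use β = 0.002 Hz⁻¹, λ = 0.25; expert
agents β = 0.014 Hz⁻¹, λ = 0.005 (θ = 300 Hz throughout); learning stages
interpolate (β geometrically, λ linearly). The expert slope keeps the whole
240–320 Hz band inside the behaviorally ambiguous range (lick probabilities
≈ 0.2–0.6) so those probes act as toss-up frequencies, while go/no-go
performance stays ≈ 95–97 % correct.
Response times are Gaussian (expert mean 0.35 s, sd 0.05 s), floored at
0.273 s — the trained animals' minimum response time — which also guarantees
lick-locked calcium transients start after the decoder's 9-frame window. UR
trials are always licked (the reward valve is audible).

## Calcium populations

Traces are additive: Gaussian noise (sd 1.0, the amplitude unit) plus
planted transients convolved with a peak-normalised difference of
exponentials (rise 0.05 s, decay 0.4 s — GCaMP6f-like package defaults,
configurable).

*Go neurons* respond after stimulus onset with amplitude
A · Φ((f − c)/w) · g, where A = 3 (SNR 3 per frame at peak), and the tuning
midpoint c = 300 Hz deliberately coincides with the agents' psychometric
threshold (width w = 80 Hz): the population signal is then most ambiguous
exactly where behavior is, which is what gives the uncertainty analyses a
recoverable frequency effect. The per-trial gain g has mean 1 and standard
deviation `gain_variability` (default 0.25), inflated 4× at frequencies
configured as ambiguous (240–320 Hz) — a gain-variability account of
stimulus uncertainty — and is additionally shifted by
`choice_coupling` · (lick − p(f)) (default 1.2 — full coupling), so the same latent evidence
drives both the choice and the population response. Trials where choice
contradicts stimulus (miss, FA) therefore carry atypical, midrange signals;
this is the planted mechanism behind "incorrect trials are more uncertain".

*Lick neurons* respond after the lick frame on every licked trial,
including FA and UR. Baseline frames contain noise only.

`simulate_study` builds an 8-day learning curve: agent stage rises 0→1,
go/lick neuron fractions grow 3.6 %→12.2 % and 1.1 %→15.9 %, premovement
probability falls 0.15→0.02, and gain dispersion falls 0.5→0.2. On the
interruption day (default day 6, a weekend pause) gain dispersion and trace
noise are inflated 2.2× with *no* change to the agent, so decoding
uncertainty rises transiently while behavior does not decline. Gain
dispersion alone proved too weak a knob — the decoder keys on amplitude
ordering, which a shared multiplicative gain barely perturbs — hence the
accompanying noise inflation.

Paw trajectories are generated at 160 samples/s; premovement trials receive
a smooth > 60 px excursion inside the 0.5–1.0 s pre-stimulus window, others
white jitter within ±4 px (1 px ≈ 0.05 mm).

## Preprocessing

Frame indexing is 1-based inclusive everywhere in the API: the decoding
window 29–37 contains nine frames of which seven are at or after onset
(0.233 s post-stimulus). Two scalings feed different consumers:

- *z-scores* (neuron classification): per neuron per trial against the 30
  baseline frames, population (ddof 0) denominator; zero baseline sd raises
  by default or, under the `zero` policy, emits zeros and a flag.
- *min–max* (decoder): per neuron over all frames and trials of the session
  by default (scopes `per_segment` and `global` are available). The
  per-neuron-per-session scope preserves trial-to-trial amplitude
  differences, which carry the choice information.

Premovement is flagged when displacement from the window-start position
strictly exceeds 60 px ("exceeding" ⇒ strict) inside the 0.5–1.0 s window;
missing coordinates flag conservatively. Labeling: `stimulus` keeps only
200/600 Hz (0/1); `response` labels lick = 1 over all frequencies and drops
UR (licks there are cued, not chosen); `response_pair` keeps two named
outcomes. Premovement trials are excluded whenever flags exist. Minority
upsampling duplicates samples cyclically and is restricted to the training
partition — duplicating into validation or test would leak.

Folds: stratified k-fold test partition (k = 20 by default), remainder split
80/20 into train/validation, giving 76/19/5 %. Splits are a pure function of
(labels, k, seed).

## Neuron classification

A go neuron must satisfy all three: (1) a z > 2 event within the 6 frames
(+200 ms) after onset in **more than 60 %** of go trials; (2) ROC AUC
(per-trial summary: peak z in that window; go vs all other trials) in the
top 5 % of a 1000-permutation null, percentile computed with midrank ties;
(3) no such activity on FA and UR trials. Criterion 3 is operationalised as
an FA∪UR event rate ≤ 40 %: the z>2-within-6-frames event fires on ~15 % of
pure-noise trials (baseline sd is estimated from 30 frames), so a bound
much below that floor — e.g. 20 % — would reject a large share of genuine go
neurons whenever FA/UR trials are few; 40 % sits between the noise floor
and the 60 % activity criterion. With no FA/UR trials present the criterion
is vacuously true and flagged.

Lick neurons satisfy the analogous criteria (1) and (2) with activity
realigned to the lick frame. Lick events are measured as the post-lick peak
*minus* the mean of the six pre-lick frames: a stimulus transient with a
0.4-s decay is still above 2 z at lick time, so a raw post-lick threshold
would classify every go neuron as lick-locked; requiring an *increase*
captures "activated by licking". Non-lick trials are summarised at the
median lick frame so the ROC contrast uses comparable windows.

## Decoder

Tokens are neurons; token features are the 9 window frames. Pipeline:
affine encoder + GeLU to a latent width D (default 24; 9–30 supported) →
two pre-norm transformer blocks (LayerNorm → multi-head self-attention,
default one head → dropout → residual → LayerNorm → feed-forward, 4D hidden,
GeLU → dropout → residual) → element-wise max over the neuron axis → a
feed-forward head → softmax over two classes. No positional encoding of any
kind. Dropout sites: embedding (after the encoder), attention (on attention
probabilities), residual (after the attention output and the FFN output),
0.1 each by default; active only in `train` and `mc_dropout` modes.

Evaluation mode processes each sample unpadded and uses order-canonical
reductions (elementwise-reduced affine maps; attention softmax and context
sums over value-sorted addends), so permuting neurons reproduces the output
bit for bit and padding can never change a prediction. Batched training and
MC dropout use ordinary BLAS reductions; padded tokens are masked out of
attention (−∞ score) and of the max-pool (−∞ sentinel).

Training: Adam (lr 1e-4) on cross-entropy for 20,000 iterations by default,
batches 64/16/16 (train/val/test), validation evaluated at initialisation,
every `eval_every` = 100 iterations and at the end; the checkpoint is the
earliest minimal-validation-CE snapshot. Gradients come from the package's
reverse-mode autodiff (`neurouq._autograd`), verified against central finite
differences in the test suite. Initialisation is seeded fan-in-scaled
Gaussian. Scaled-down runs in the tests and the acceptance script use
latent 16, 900–1500 iterations at lr 1e-3 with training batch 32; at these
sizes the higher learning rate reaches the same plateau the long default
regimen approaches slowly.

`holdout_protocol` trains on all-but-one day (or mouse) and tests on the
held-out unit over repeated seeds; the shuffled-neuron control re-evaluates
the held-out set with neuron rows permuted — by construction the accuracy
difference is identically zero in eval mode, and the reported two-sample
t-test is degenerate (nan p) in that case.

## Uncertainty protocol

`mcd_infer` runs T forward passes in `mc_dropout` mode (all three dropout
sites active, per Gal's method) and returns the mean and the variance
(ddof 0) of the class-1 probability; T = 1000 by default, T ≥ 2 enforced.
Variance of the probability (not of logits or argmax counts) is the primary
metric; predictive entropy of the mean is exposed as a secondary one. The
full protocol builds stratified folds per seed (defaults k = 20, 10 seeds ⇒
200 models), trains one model per fold, and MCD-infers each fold's test
trials, so every non-excluded trial receives exactly one record per seed.
Per-trial uncertainties are averaged across seeds before any group summary
(mean, sem, n) by day, frequency, outcome, previous/current outcome pair, or
learning stage (days 1–3 naive, 6–8 expert). All randomness derives from a
single protocol seed through `SeedSequence` substreams.

## Statistics

Performance metric: (Hit#+CR#)/(Hit#+Miss#+CR#+FA#); probe/RO/UR never
enter. Psychometric fits: binomial GLM with probit link of lick on
frequency (statsmodels), threshold −intercept/slope; probe trials included,
complete separation flagged rather than raised. d′: per 50-trial block
within (mouse, day), Z(hit rate) − Z(FA rate) with the 0.5 correction
(zero count → 0.5, full count N → N − 0.5, applied before forming rates);
trailing partial blocks dropped so block statistics stay identically
distributed; probe trials are excluded from the counts (signal detection
needs go/no-go only). Group comparisons: one-way ANOVA gating all-pairs
Tukey HSD at α = 0.05, or Bonferroni-corrected one-vs-rest two-sample
t-tests. The d′–uncertainty association is Pearson's r over blocks.

## Problem sizes used in tests and the acceptance script

The scaled uncertainty protocol runs 5 folds × 2 seeds × T = 200 over one
simulated mouse, 8 days × 200 trials, ~45 neurons/session (≈ 1400 usable
trials; 10 trained models). Chance calibration trains on 1000 label-shuffled
trials of 50 neurons for 1500 iterations (latent 16). Classifier recovery
uses a 500-neuron high-SNR session with 300-permutation ROCs. These sizes
were chosen so each stochastic check retains a comfortable margin over its
qualitative assertion.

## What the simulator does and does not show

The generator reproduces the statistical structure the analyses assume —
variable population size, stratified schedules, psychometric behavior,
kernel-shaped transients, choice-coupled gain, learning curves with an
interruption — but not biological realism: no correlated noise across
neurons, no neuropil or motion artefacts, no within-session drift, no
reward-history effects beyond the outcome labels, and lick/go classes are
mutually exclusive by construction. Passing the planted-effect tests shows
the pipeline *recovers* such effects when present at the planted magnitude;
it does not certify effect sizes in real recordings. Real-data headline
accuracies are not reproducible here because the original recordings are
not publicly deposited.

## Numerical notes and edge cases

Cross-entropy is computed in nats with probabilities clipped at 1e-12;
LayerNorm uses ε = 1e-5; softmax subtracts a finite row max so fully masked
rows cannot produce NaN. Max-pool gradients route to the first argmax.
Constant traces min–max-scale to 0. Degenerate baselines (zero sd) follow
the configured policy. Checkpoint ties keep the earlier iteration. The
permutation-AUC percentile uses midranks, making the null percentile
uniform under exchangeability (verified by a KS test).
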