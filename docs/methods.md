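# Methods

`rsvpauth` implements single-account EEG identity authentication from
face-evoked potentials, together with a synthetic data generator that stands
in for unavailable recordings. This note documents the models, the defaults
and why, the numerical choices, and what the synthetic studies do and do not
demonstrate.

## The authentication problem

A registered user watches a rapid serial visual presentation (RSVP) stream:
10 face images per trial, 300 ms each, exactly one being the account
owner's face, organised as 20 blocks × 10 trials (200 target presentations
per session). Seeing one's own face evokes larger and earlier P300-family
potentials (and a slightly larger N250) than seeing someone else's face, so
a classifier on target-locked EEG epochs can decide whether the viewer *is*
the account owner. Two attack models are distinguished: a *blind* imposter
who does not know which image is the target, and a *non-blind* imposter who
does and attends to it deliberately.

## Synthetic recordings

The simulator (`rsvpauth.simulate`) renders each ERP component as a
Gaussian time course (peak latency, SD width, signed peak amplitude in µV)
multiplied by a fixed per-channel topography gain, summed over components
and added at every target onset. Background noise is 1/f ("pink") noise,
independent per channel, plus a shared common-mode term. Defaults:

| parameter | default | rationale |
|---|---|---|
| montage | 16 ch, Fz…Cp6 | the emulated amplifier's 10–20 subset |
| sampling rate | 2400 Hz | acquisition-side rate; decimated to 600 Hz |
| session | 20 blocks × 10 trials | 200 target events |
| N170 | 170 ms, −4 µV both classes | face-generic occipito-temporal component |
| N250 | 250 ms, −3.5 / −3.0 µV | slightly larger for self faces |
| P3a | 320 ms, 6 / 2.5 µV, +30 ms non-self | main self/non-self contrast, centro-parietal |
| P3b | 450 ms, 7 / 3 µV, +50 ms non-self | main contrast, parietal (P3/Pz/P4/Po8) |
| noise | 10 µV pink + 3 µV common-mode | scalp-EEG-scale; single-trial SNR low, 2-trial averages classifiable |
| familiarity | 0.3 for the non-blind imposter | linear interpolation non-self → self; no published effect size exists, so this knob is a modelling choice, not a claim |

Component amplitudes/latencies are qualitative-literature-scale choices;
the self/non-self gap is deliberately concentrated on P3a/P3b over parietal
channels. The `familiarity` factor doubles as a *drift* knob: a session-2
user response generated with familiarity < 1 models day-scale attenuation
of the self-face response.

What the simulator does **not** model: eye-blink/EMG artifacts, volume
conduction from a head model, non-Gaussian component shapes, latency
jitter across trials, responses to the nine non-target images (they are
common to both classes and would largely cancel in the discriminant), and
electrode impedance drift. Consequently, passing results here demonstrate
algorithmic correctness and qualitative behaviour, **not** expected
accuracy on real EEG.

## Preprocessing

Fixed order (asserted by the pipeline runner): common average reference
(hook for any precomputed linear operator, e.g. a REST matrix — building a
REST operator needs a lead field and is out of scope) → zero-phase
Chebyshev-I low-pass → 4-sample block averaging (2400→600 Hz, events
mapped by floor division) → epochs −200..1000 ms around target onsets →
baseline subtraction (−200..0 ms mean) → averaging of adjacent same-class
trial pairs (200 → 100 trials, odd trailing trial dropped). Classification
uses the 0..1000 ms crop: 600 samples at 600 Hz.

The filter is designed by `cheb1ord` for ≤ 1 dB passband ripple to 40 Hz
and ≥ 40 dB attenuation from 49 Hz, with the order rounded up to odd so the
equiripple passband *peaks* at DC (even orders dip −1 dB there, breaking
unity DC gain); applied with `sosfiltfilt`, doubling the stopband
attenuation and zeroing phase. No artifact rejection is applied by default
(no published criterion to follow).

## HDCA

For windows of 100 ms tiling 0..1000 ms (N = 10 windows, 60 samples each),
level one computes the per-window, per-channel mean x̄ᵢ,ₙ and a Fisher
discriminant weight vector per window:

    wₙ ∝ (S_w + λ·(tr S_w / C)·I)⁻¹ (μ₁ − μ₀),   yₙ = Σᵢ wₙ,ᵢ x̄ᵢ,ₙ

with Ledoit–Wolf shrinkage intensity λ (duplicate/silent channels stay
solvable; at C = 16 channels and ~120 training trials shrinkage is cheap
insurance). Weights are unit-norm with the sign fixed so the self class
projects higher. Whether the discriminant should see raw within-window
time points or window means is ambiguous in the HDCA literature; this
implementation uses window means, which makes level one yield one score
per window directly. Level two is an L2-regularised logistic regression
(C = 1, lbfgs) of the labels on the N window scores:

    Y_S = σ(Σₖ vₖ yₖ + b) ∈ [0, 1]

A trial is accepted when Y_S ≥ 0.5 (the calibrated-probability threshold;
an equal-error-rate threshold could be substituted but is not the default).
A login attempt is 2 consecutive trials (6 s of EEG) decided by the mean
score — also the tie rule when the two per-trial decisions disagree.

Degenerate inputs: single-class or < 2-trials-per-class data are rejected;
all-zero data raises (no within-class variance); equal class means return
an arbitrary unit vector (downstream AUC is chance, as it should be).

## GA channel selection

Chromosomes are length-16 binary masks (≥ 1 bit after repair). Fitness is
pooled 5-fold stratified CV accuracy of HDCA on the masked channels, with
the fold assignment frozen per run — otherwise CV resampling noise swamps
the selection pressure — making fitness a deterministic, cacheable function
of the mask. Unstated GA details were fixed as: tournament selection (size
2, with replacement), single-point crossover (p = 0.85), per-individual
single-bit mutation (p = 0.1), one elite copied unchanged, stop at a
generation cap (default 50) or 10 stalled generations. Fitness ties break
toward fewer channels (sparser montages are the point of selection).
"Parallel" evaluation means concurrent fitness evaluation of one panmictic
population; results are identical for any worker count.

## Evaluation

ACC, FAR and FRR are computed from pooled confusion counts in percent
(FAR over imposter tests, FRR over user tests). In-session performance is
stratified 5-fold CV with decisions pooled over folds — every trial tested
exactly once (per-fold averaging of rates would weight folds unequally
after pooling; pooling was chosen). Permanence applies the session-1 model
to session-2 epochs without refitting. The emulated study design is 15
users × (1 self + 2 imposter) datasets = 45 subject-level datasets; one
account's classification problem is 100 pair-averaged user trials vs 200
imposter trials.

The null-calibration study uses a *balanced* user-vs-one-imposter design
(100 + 100): under the protocol's 1:2 imbalance a majority-class rule sits
at ~66%, so "accuracy within the binomial band around 50%" is only a
meaningful chance test when classes are balanced.

## Problem sizes of the bundled studies

The `experiments` module fixes the simulation scales: design arithmetic,
null calibration, the channel-recovery study and the HDCA/GA-HDCA
comparison run the full 20-block protocol; the GA-vs-exhaustive oracle
(6-channel montage, 63 masks) runs 10-block sessions. GA runs use a
20-generation cap — the stall rule typically terminates runs around
generation 15 anyway.

The recovery study's effect design deserves a note, because a recovery
test is only meaningful when its ground truth is actually the optimum of
the fitness being searched. Each of P3/Pz/P4 carries its *own* pair of
Gaussian components at the centres of the 300–400 and 400–500 ms windows
(SD 30 ms; 12, 13, 12 µV — upper-range but plausible P300 amplitudes).
Two design traps were identified and avoided. First, a single
shared-topography component makes the channels mutually redundant: two of
them capture most of the attainable signal-to-noise, excluding the third
is *genuinely* fitter under cross-validated accuracy, and the sparsity
tie-break then correctly prunes it — per-channel independent components
are required. Second, the operating point matters: accuracy is a
plateauing function of sensitivity d′ (channel contributions add in d′²),
so a mid-range operating point (~88% with all three channels) leaves the
third channel a ~3% marginal, comparable to fold-assignment noise, while
near-ceiling saturation creates exact fitness ties that the sparsity
tie-break resolves against informative channels. The chosen amplitudes
place the all-three mask at ≈95–99% CV accuracy with two-channel masks
several points below, maximising each channel's marginal contribution
relative to fitness noise without saturating.

Even at this operating point, full three-channel retention is not
guaranteed: measured across seeded replications, the GA keeps all three
injected channels in roughly 6–8 of 10 runs. In the remainder it selects a
sparser mask that is *strictly fitter on the run's frozen folds* —
verified by direct fitness comparison, so this is faithful behaviour of
wrapper selection under a finite-sample accuracy criterion, not a search
failure. The temporal side of the recovery study is robust: the fitted
fusion weights |v_k| peak in the injected 300–500 ms windows in ≥ 9 of 10
runs.

## Known limitations

- Accuracies measured on the synthetic default conditions (~70–80% CV) are
  not predictions for real EEG in either direction; they depend directly on
  the chosen noise level and effect sizes.
- The GA is stochastic; the exhaustive-equality and recovery checks are
  therefore stated as ≥ 9/10 seeded runs, not certainties.
- REST re-referencing proper, artifact rejection, and EDF *writing* are not
  implemented (the array container + events TSV is the interchange format;
  EDF reading is available via the optional `mne` extra).
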