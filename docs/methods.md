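# Methods

## The measurement model

All analysis operates on 10 s epochs of four-channel EEG (Fp1, Fp2, O1,
O2; µV), acquired at 1000 Hz and analysed at 250 Hz. Per epoch and
channel a Welch PSD is estimated from Hamming-windowed 2 s segments with
50% overlap (0.5 Hz resolution, so the narrowest band — delta,
0.5–4 Hz — contains 7 bins). Bands are half-open `[low, high)` so they
tile 0.5–44 Hz without double counting. Band power is the sum of
density × bin width over a band; relative power divides by the total
over 0.5–44 Hz, so relative powers sum to exactly 1 per channel and are
invariant to amplitude scaling. PSD bins are treated as uniform mass on
`[f, f + 0.5)`: median and 90% spectral-edge frequencies interpolate the
cumulative power linearly inside a bin, the mean frequency is the
power-weighted mean of bin centres, and the peak frequency is the argmax
bin. A "mean frequency" defined as the frequency where the density
equals its average would be multi-valued; the power-weighted mean is the
single-valued reading used here.

Channel aggregates (frontal = Fp1+Fp2, occipital = O1+O2, global = all
four) are unweighted means of per-channel *feature values* — i.e.
relative powers are averaged, not recomputed from averaged spectra. The
alternative (ratio of summed powers) differs only at second order in
the channel spread; averaging per-channel values matches the
per-channel feature inventory of the table the pipeline emits.

Biomarkers: DAR = e_δ/e_α and DTR = e_δ/e_θ are computed per epoch and
channel and then averaged — mean-of-ratios, not ratio-of-means. The
distinction matters: resting DAR distributions are heavy-tailed, so the
cohort mean of per-epoch ratios (≈11) is several times the ratio of
cohort-mean powers (≈2.8). Baseline-relative change is
Δe = (e − r̄)/r̄ against the subject's own resting mean r̄ of the same
feature (stored as a fraction; ×100 for display). Frontal asymmetry is
(e_Fp2 − e_Fp1)/(e_Fp2 + e_Fp1) per band.

The canonical feature table has 149 columns: 4 channels × 5 bands × 5
features (mean power, median/mean/edge/peak frequency) = 100; global
band mean power (5); frontal+occipital band mean power (10) and their
baseline changes (10); per-channel DAR/DTR (8) and changes (8);
per-channel total mean power (4) and changes (4).

## The synthetic-data generator

No public recordings exist for this protocol, so the generator is the
package's ground truth. It emulates the *spectral composition* of each
state, not waveform morphology.

**Composition model.** Per epoch and channel the five relative band
powers form a composition drawn from a logistic-normal distribution
(softmax of a correlated 5-vector latent Gaussian) — the standard
Aitchison model for compositional data. Under it, band ratios such as
DAR = exp(z_δ − z_α) are exactly log-normal, reproducing the heavy
ratio tails seen in resting EEG. An independent-logit-normal model
(sigmoid per band, renormalized) was tried first and rejected: with
moments matched to the same targets its resting DAR cannot exceed ≈4
and its ratio ordering across states is unstable.

**Dependence structure.** Latent variance decomposes into a per-subject
random effect (SD = half the total latent SD, shared across that
subject's states so state contrasts are genuinely within-subject), an
epoch effect shared by all four channels, and a channel-specific
remainder (epoch-level inter-channel correlation 0.5). The latent band
correlations that drive the biomarkers are state-specific: for the two
driving states the delta–theta and delta–alpha correlations are fitted
so the cohort-mean DAR/DTR match their reference values (they land
within ~10%); for the resting state they are pinned at (+0.95, −0.95)
from the reported strong negative delta–alpha/delta–theta band
regressions, because the resting profile's printed moments are mutually
inconsistent (see *Known limitations*).

**Calibration.** `calibrate_latent` fits (μ, σ) per band by a
deterministic stochastic-approximation loop (fixed internal seeds, 60
iterations plus a μ-only polish) so that the *global-channel* relative
powers match the target means/SDs per state. σ is capped at 2.0: beyond
that the fit to the resting delta SD saturates (realized 0.245 against
a target of 0.284) while ratio tails keep inflating. Calibrated
parameters for the three default states ship frozen in the source
(`_LATENT_TABLE`; regenerate with `python -m drivewave.synth`) so that
generation is fast and bit-reproducible; custom specs are calibrated on
the fly and cached. Post-calibration mean errors are ≤0.002 per band.

**Waveforms.** Each band's component is white Gaussian noise filtered by
a 4th-order Butterworth band-pass over an *interior* sub-band (e.g.
delta synthesized on 1.1–3.4 Hz) and scaled so its realized Welch
in-band power equals the target share of the epoch's total power
(default 400 µV², a 20 µV RMS signal). Two deliberate choices here:

* *Interior margins* (≥0.6 Hz from every band edge) keep the content
  clear of the Hamming main lobe at band boundaries and of the
  0.5–44 Hz analysis band-pass roll-off, so neither estimator smearing
  nor preprocessing moves power across band boundaries.
* *Welch-based scaling* (rather than time-domain variance scaling)
  makes the generator contract hold per epoch: realized Welch relative
  powers match their drawn targets to within 0.01 on raw output and
  0.04 after the full preprocessing chain. Variance scaling leaves
  errors up to 0.15 because the Welch estimate of a finite noise epoch
  fluctuates around its variance. The flip side: epoch *variance*
  matches the nominal total power only on average (±2%), with ±15%
  per-epoch scatter.

**Cohort layout.** Default: 17 subjects; per subject one resting
segment of 60 s, one city-roadway segment of 300 s and one expressway
segment of 210 s, each beginning with a 30 s settle period that
preprocessing drops. This yields exactly 3 + 27 + 18 feature epochs per
subject, 51/459/306 per state. The expressway *recorded* duration is
stated elsewhere as 4 min, which contradicts the per-state epoch counts
(⌊(240−30)/10⌋ = 21 ≠ 18); the epoch counts are authoritative here, so
the generator records 3.5 min.

**Artifacts.** `inject_artifacts` adds (i) smooth ~0.4 s frontal
transients (<4 Hz, ~120 µV) with an amplified copy on a parallel EOG
reference, (ii) >20 Hz noise bursts with an EMG reference, and (iii) a
60 Hz sinusoid on every EEG channel, at Poisson event rates, returning
the untouched recording as ground truth plus the event log.

## Preprocessing choices

Order: notch → downsample → (ICA) → band-pass, with the settle-period
trim at segmentation. Filter families are not dictated by the protocol,
so standard EEG practice applies: second-order IIR notch at 60 Hz
(Q=30), an 8th-order Butterworth low-pass at 100 Hz before decimation
(integer factors only), and a 4th-order Butterworth band-pass 0.5–44 Hz
— everything forward-backward (`filtfilt`) for zero phase, since phase
distortion would bias the asymmetry index. ICA uses FastICA with as many
components as EEG channels (four — a rank limit worth remembering);
components are rejected when their absolute Pearson correlation with
the EOG or EMG reference exceeds 0.7 (configurable). With a threshold
of 1.0 (nothing removable) or no crossing component the input passes
through unchanged. Reference channels run through the same filter chain
to stay time-aligned; the 0.5–44 Hz band retains enough of the 20–44 Hz
EMG signature for the correlation test.

The band-pass edges bite: content at 0.5–1 Hz and above ~38 Hz is
attenuated (Butterworth passband droop is squared by filtfilt), which
depresses recovered gamma relative power by ~0.01 absolute and is the
dominant term in the pipeline's ±0.03 recovery error.

## Statistics

Paired comparisons are subject-level: epochs are unbalanced across
states (3 vs 27 per subject), so epoch-level pairing is undefined;
each subject contributes one mean per state and the paired t-test runs
on those. Two-sided tests at α = 0.05, no multiple-testing correction
(the report records the number of tests performed instead). Regressions
are plain OLS; the module reports slope and Pearson r as separate
quantities and never labels a slope as a correlation coefficient. 95%
CIs use the t quantile, mean ± t₀.₉₇₅,ₙ₋₁·SD/√n.

## Selection and classification

ANOVA-F importance is 1 − p per feature, selection at > 0.95, with
constant/all-missing features screened out first; selection is fitted
on the training partition only (no leakage into the held-out subjects).
Splits are subject-wise (default first 12 train / last 5 test). Class
weights are inverse-frequency, w_c = N/(K·n_c) (resting ≈ 5.3, city
≈ 0.59, expressway ≈ 0.89 at the default epoch counts), applied as SVM
class weights, equal LDA priors, tree sample weights, and weighted KNN
votes (ties broken by the nearest neighbour). Distance- and
kernel-based models (KNN, LDA, SVM) are z-scored on the training
partition; trees see raw values. The two legacy tree algorithms are
re-implemented by their defining traits rather than bug-for-bug:
gain-ratio splits with pessimistic (confidence-bound) pruning, and
ANOVA-driven unbiased split-variable selection with univariate binary
splits. Cross-validation is stratified k=10 (reduced with a warning if
a class is smaller), shuffle seeded. Binary tasks get ROC (decision
scores or positive-class probabilities), trapezoidal AUC and
Gini = 2·AUC − 1; predictor importances are permutation importances for
every model family alike.

## What the synthetic cohorts do and do not show

Passing tests on synthetic cohorts demonstrate that the pipeline
*recovers what the generator put in*: state-mean global band relative
powers within ±0.05, exact epoch bookkeeping (51/459/306 × 149
columns), resting-dominant DAR/DTR across seeded replicates, and the
near-perfect rest-vs-driving versus moderate driving-vs-driving
classification contrast. They do not validate the pipeline against real
scalp EEG: the generator has no 1/f background continuum between bands,
no non-stationarity inside an epoch, no volume-conduction mixing beyond
a fixed channel correlation, and artifact templates far cleaner than
real ocular/myogenic contamination. Classification accuracies on
synthetic cohorts depend on the injected between-state separation and
are not comparable to accuracies on recorded data.

## Known limitations

* The resting-state profile is over-determined: its printed delta SD
  (0.284), DAR mean (11.33) and DTR mean (5.20) cannot be reproduced
  simultaneously by any smooth compositional model, because the tiny
  theta SD (0.034) forbids the delta–theta coupling that would keep DTR
  finite while delta spreads. The generator prioritizes the band
  moments and the regression-derived correlations; realized resting
  delta SD is ≈0.25 and the emergent resting DAR/DTR means are ≈15/15 —
  the right regime (resting ≫ driving) but not the printed pair.
* Whether the reported per-state spreads are across epochs or across
  subjects is unspecified; they are treated as across-epoch, with the
  subject effect folded inside (half the SD), and the tests target
  means, not variance decompositions.
* Frontal asymmetry offsets default to zero — no numeric asymmetry
  values are available to calibrate against — so asymmetry is a free
  knob exercised qualitatively (sign and magnitude respond to the
  offset) rather than a calibrated one.
* EDF output uses a minimal built-in EDF+ writer (16-bit, 1 s records,
  annotations as TALs) validated by round-trip against MNE's reader;
  exotic EDF features (discontinuous records, per-channel rates) are
  out of scope.
* Problem sizes in the test suite are chosen for desk-scale runtimes:
  most tests use 4–8 subject cohorts synthesized natively at 250 Hz;
  the acceptance-level checks use the full 17-subject cohort (1000 Hz
  for recovery and bookkeeping, 250 Hz for the 20-replicate direction
  properties).
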