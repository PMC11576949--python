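# Methods

This note documents the models, conventions and numerical choices behind
`lithic-eeg`, in the spirit of a package methods appendix: what each
stage assumes, which knobs matter, and what the synthetic-data studies
do and do not demonstrate.

## Analysis chain and its conventions

### Montage and geometry

The built-in montage is the standard 32-electrode 10–20/10–10 cap
(Fp1 … Fp2) with FCz as the online reference. Electrode positions are
the *ideal* spherical 10–20 angles — inclination measured from the
vertex, azimuth from the nasion meridian — i.e. the classic BESA/EasyCap
angle table re-expressed in one convention (`montage._ANGLES_DEG`;
outer ring at 92°, the FT9/TP9 ring below the equator at 113°). Real
caps deviate from these ideals by electrode-placement error of a few
degrees; nothing downstream is sensitive to that at the precision we
claim. The 2-D plane used for topographic maps and tie-breaks is the
azimuthal-equidistant projection about Cz. The canonical channel
*ordering* is the circular left-front → left-back → right-back →
right-front sweep; deterministic tie-breaks (equal |Z| in channel
selection) refer to this order.

### Preprocessing

* Decimation (2500 → 250 Hz by default) uses `scipy.signal.decimate`
  with its zero-phase IIR anti-aliasing filter; marker and cue indices
  are rescaled by floor division, output length is `floor(n/factor)`.
* Filters are zero-phase (forward–backward) IIR designs: Butterworth
  order 4 band-pass with 1 and 40 Hz corners, and a 50 Hz notch with
  quality factor Q = 35. Only the corner frequencies are protocol
  constraints; order and Q are package defaults chosen for < 5% passband
  ripple on a 20 Hz probe and ≥ 30 dB notch attenuation. Forward–backward
  application preserves beta-phase timing across epochs (no group
  delay).
* Stage order is enforced — downsample → filter → bad-channel handling →
  reference — and violating it raises `PipelineStateError`. The enforced
  constraints are only the genuinely order-sensitive ones (no decimation
  or filtering after re-referencing), so individual stages remain usable
  in isolation.
* Bad-channel screening is deterministic: (a) near-constant channels,
  (b) robust z > 5 of log-variance (median/MAD), (c) a channel whose best
  absolute correlation with any other channel is a robust *low* outlier
  (Fisher-z, robust z > 5) relative to the rest. Criterion (c) is
  relative rather than absolute because perfectly healthy data can have
  genuinely low inter-channel correlations (the synthetic generator's
  sources are channel-independent by design); an absolute threshold
  would be montage- and paradigm-specific.
* Interpolation of bad channels uses spherical inverse-distance weights
  (1/angle², normalised), which reproduces constant fields exactly and
  linear-in-position fields to within ~10% of range on this montage.

### REST re-referencing

The Reference Electrode Standardization Technique maps average-referenced
scalp data toward an infinity reference through a forward head model:
`V_REST = G · pinv(G_avg) · V_avg`, where `G` is the infinity-referenced
gain matrix of an equivalent-source grid and `G_avg` its average-
referenced version. Our `G` comes from an analytic three-shell concentric
sphere (brain/skull/scalp, relative radii 0.87/0.92/1.0, conductivities
1/0.0125/1): for each spherical-harmonic degree the layer coefficients
are solved from the interface continuity conditions, and dipole
potentials are summed over 60 degrees with Legendre recurrences.

Two numerical choices matter:

* **Source grid.** Sources form a Fibonacci-spiral shell at 65% of scalp
  radius restricted to the cranial vault (z > −0.15; ~2600 dipoles × 3
  orientations). The vault restriction is not cosmetic: with sources
  covering the whole sphere, a 32-channel upper-head cap poorly
  constrains the common-mode (reference-offset) component and the
  infinity-reference reconstruction error grows to ~12%; with the vault
  shell the forward-model round trip (average-reference a known `G·s`,
  then REST it) recovers the infinity-referenced potentials to ~2–4%
  relative error. The residual is purely common-mode.
* **Regularisation.** The pseudoinverse truncates singular values below
  10⁻⁴ of the largest. A data-driven Tikhonov parameter was considered
  and rejected: the REST operator is built once per montage, independent
  of any particular data segment, so a fixed spectral cutoff keeps the
  transform deterministic and cacheable.

Equivalence with any specific commercial REST implementation is *not*
claimed; the contract is the round-trip property above.

### ICA cleaning

Infomax with the logistic nonlinearity (natural gradient, annealing;
the weight update is `mne.preprocessing.infomax`) on PCA-whitened,
≥ 1 Hz high-passed continuous data. Extended (sub-Gaussian) switching is
deliberately omitted: the targeted artifact classes — blinks, focal
muscle — are super-Gaussian; this is a documented limitation for
sub-Gaussian artifacts (e.g. line noise, which the notch handles
instead).

Component identification replaces visual marking with two declared
scores in [0, 1]:

* `eye = |corr(topography, frontal template)| × (activation power
  fraction < 4 Hz)`, where the template is a Gaussian in great-circle
  distance from the Fp1/Fp2 midpoint;
* `muscle = (power fraction > 20 Hz) × sqrt(topographic focality)`,
  focality being max²/Σ² of the mixing column.

Defaults remove components with either score ≥ 0.6. These scores are an
operationalisation, not a reconstruction of expert judgment; on real
data they should be audited (the CLI persists the decomposition).
Removal subtracts the back-projection of flagged components, so removing
nothing is exactly lossless.

### Epoching

Manual markers are snapped to the nearest detected auditory-cue onset
within 250 ms; markers without a cue in tolerance are flagged and their
steps excluded — mirroring the experimental practice of deleting markers
of mis-executed trials. Trials are segmented from −200 ms before the
first-step onset to the end of the last step (15,200 ms for three-step
tasks; the rest period is excluded), baseline-corrected on [−200, 0) ms,
then cut into [0, 1000) ms step epochs labelled `task.step`. Step onsets
come from each trial's own aligned markers, tolerating cue jitter. The
1000-ms epochs are *not* re-baselined individually: the segment-level
baseline is the only correction, because a per-step baseline would fall
inside the preceding step's activity.

The hammerstone Execute condition is excluded by default (its impact
transient contaminates the step); the exclusion is configuration, not
hard-coded. Rejection flags epochs with |x| > 100 µV or successive-sample
steps > 50 µV (amplitude checked first; both thresholds config-exposed —
they stand in for visual inspection criteria that are inherently
unpublishable).

### Spectra

Each 1000-ms epoch (250 samples at 250 Hz → 1 Hz resolution) is tapered
with a Tukey window whose cosine ramps jointly cover 10% of the epoch —
the common reading of a "10% Hanning window" in EEG analysis software;
`taper_fraction=1` gives the full Hann for sensitivity checks. The
one-sided FFT amplitude spectrum is calibrated so a unit sinusoid at a
bin frequency (rectangular window) reads 1.0 µV; no window-gain
renormalisation is applied (all conditions share the window, so ratios
and paired differences are unaffected). Amplitudes — not powers — are
averaged across trials, matching the µV reporting unit; `amp_to_power`
converts for readers who want µV². The beta band mean takes bins with
12.5 ≤ f ≤ 30 Hz inclusive; on the 1-Hz grid that is the 18 bins
13 … 30 (no bin exists at 12.5 Hz).

### Statistical core

* **Wilcoxon signed-rank** (per channel, paired across subjects): zero
  differences dropped (Wilcoxon's original treatment), average ranks for
  tied |d|, W = rank sum of positive a−b, Z = (W − n(n+1)/4)/σ with
  tie-corrected σ² = n(n+1)(2n+1)/24 − Σ(t³−t)/48, **no** continuity
  correction, two-sided p = 2(1 − Φ(|Z|)). This convention reproduces
  the printed (Z, p) pairs of the source analyses (e.g. |Z| = 2.14 →
  p = 0.032 → printed 0.03). Z is negative when the first-listed
  condition tends smaller. For n ≤ 12 an exact enumeration p is attached
  (`p_exact`) and the result carries a small-n flag; the normal
  approximation remains the reported value for comparability across n.
* **Channel screening** excludes Fp1, Fp2, TP9, TP10, FT9, FT10 (the
  conventionally noise-prone periphery), leaving 26 of 32 channels. No
  multiplicity correction is applied across the 26 tests — matching the
  protocol being reimplemented — but a Benjamini–Hochberg column
  (`p_bh_supplementary`) is emitted for readers who want it; it is not
  part of the replicated procedure.
* **Selection**: with ≥ 5 channels at p < 0.05, the five largest |Z|
  among the significant; otherwise the overall top five |Z|. Output
  order is |Z|-descending (the source's "ascending magnitude" phrasing
  conflicts with its "highest absolute Z" rule; we standardise on
  descending and record the rule used). Ties break by montage order.
* **Paired centering**: x′(s,c,k) = x(s,c,k) − mean over the two
  conditions, per subject and channel; exact antisymmetry
  x′(s,A,k) = −x′(s,B,k) follows algebraically and is enforced by
  construction.
* **Correlation-matrix PCA** on the 2n × 5 centered observations:
  columns standardised (ddof = 1), eigen-decomposition of the correlation
  matrix, loadings sign-fixed so each PC's largest |loading| is
  positive, scores = standardised data × loadings, variance explained in
  percent (sums to 100 by trace conservation). The mirror structure of
  centered data makes score(s,A) = −score(s,B) exactly on every axis.
* **Scree rule**: number of PCs before the largest successive eigenvalue
  drop, floored at 2 (PC1/PC2 are always plotted and tested).
* **PC-score tests**: the same Wilcoxon on paired scores per plotted
  axis. Because scores mirror, the test effectively operates on doubled
  condition-A scores; its Z sign follows the A-score mean.
* **Outlier re-run**: subjects with any score outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (linear-interpolation quartiles) on a
  *significant* plotted axis are removed and the whole chain — channel
  tests included — re-runs exactly once. Only plotted axes are screened.

**A caveat the package computes rather than hides:** the pipeline-level
type-I error is far above nominal. Under a pure null (no effect, 23
subjects, 200 replicates) the per-channel tests are well calibrated
(false-positive rate ≈ 0.05), but the probability that *some* plotted PC
axis reaches p < 0.05 is ≈ 0.7. The reason is circularity: channels are
selected for consistent paired differences and PC1 then aggregates them
coherently, so the PC1 test inherits and amplifies the selection
optimism. The acceptance script reports this rate
(`null_pipeline_any_axis_rate`) as a standing warning: significant PC
axes in this design are descriptive of the selected pattern, not
confirmatory evidence against a global null.

## The synthetic generator

`SimulationConfig` defaults are the study-scale recording conditions: 23
subjects, ≥ 50 trials per task, 2500 Hz acquisition, 5-s steps, 5-s
rest, 30-ms cues, markers jittered by N(0, 40 ms) around true onsets
(clipped at ±3 SD). A 1-s lead-in (borrowed from the final rest) keeps
the first trial's baseline inside the recording while the total length
stays exactly trials × trial-duration.

Signal model, per channel (µV):

| component | model | default |
|---|---|---|
| background | 1/f^α noise via exact spectral shaping, flat below 1 Hz | α = 1.5, 4 µV rms |
| alpha | 8–12 Hz band-passed white noise | 2 µV rms |
| beta | 12.5–30 Hz band-passed white noise, amplitude = base × subject factor × effect multiplier during each step | 3 µV rms base |
| line noise | common-phase 50 Hz sinusoid, per-channel gain 0.8–1.2 | 2 µV |
| blinks | 300-ms raised cosine through a fixed frontal vector (Gaussian in distance from the Fp midpoint) — rank-1 by construction so ICA can find it | 15/min, 250 µV |
| impact | 80-ms broadband noise burst 400 ms into the hammerstone Execute step, spatially broad | 400 µV |
| subject factor | lognormal baseline multiplying the neural components | SD 0.4 |

Choices worth defending:

* **Beta as band-passed noise, not dipolar oscillators.** The analysis
  only sees channel-space band amplitudes; a biophysical forward model
  would add realism the pipeline cannot distinguish. Channels are
  independent by default (a common-source option exists through custom
  effect maps at the analysis level); the main consequence is that
  inter-channel correlation structure in the PCA comes from the paired
  condition contrast, not from volume conduction.
* **Spectral balance.** Amplitudes are set so the 12.5–30 Hz band mean
  is dominated by the beta process (the 1/f floor contributes roughly a
  fifth of in-band power). This makes injected amplitude multipliers
  approximately recoverable as band-mean ratios — the generator's
  central design goal: a ×1.5 injection is measured as ≈ ×1.44 at 120
  trials (the residual shrinkage is the floor's doing). Real EEG can
  have far worse in-band SNR; recovery rates measured here are an upper
  bound on real-data behaviour.
* **Blink amplitude 250 µV** at the frontal pole is upper-range
  realistic; after the 1 Hz high-pass (which removes about half the
  raised-cosine energy) blink low-frequency variance still dominates F3
  and Fz, which is what makes the ICA selectivity check meaningful.
* **Lognormal subject factors** (SD 0.4 → factors mostly within
  0.45–2.2) reproduce the strong inter-individual baseline variability
  that motivates paired centering: raw PCA scores cluster by subject,
  centered scores by condition.
* **Effects are multiplicative** on beta amplitude, so the subject
  factor cancels in within-subject ratios and the paired design is the
  natural estimator.
* `simulate_beta_table` is a *statistical surrogate* sampled from the
  generator's subject-level model (base × lognormal factor × multiplier
  × exp N(0, 0.05) residual trial-averaging noise). It exists for
  replication studies that need hundreds of cohorts (type-I
  calibration), where the continuous signal chain would add hours of
  compute but no information: under the null the paired tests see
  exchangeable pairs whatever the noise law. Studies that exercise the
  signal chain itself (effect recovery, ICA, rejection) always use the
  full generator.

What the synthetic studies do **not** show: performance under real
volume conduction and channel correlation, non-stationary artifacts
(sweat, electrode drift), imperfect cue audio, or EMG contamination of
beta — the generator's beta band is clean by construction. Passing
recovery tests here validates the pipeline's bookkeeping and statistics,
not its robustness to every property of real recordings.

## Study sizes used in tests and the acceptance script

Replication studies are scaled to run on a single CPU as part of the
package's own design: effect-recovery cohorts use 23 subjects × 2 tasks
at 125 Hz with 12 trials per task (50 seeds); the type-I study uses 200
surrogate-table cohorts; ICA and rejection checks use single subjects at
250 Hz with 6–20 trials. The generator's *defaults* remain the full
study conditions (2500 Hz, 50 trials); the reduced sizes are explicit
arguments at the call sites. At these sizes the ×1.4 three-channel
effect is recovered (≥ 2 injected channels selected and PC1 significant)
in ≈ 100% of seeds — the power margin over the 80% requirement is large
because trial averaging makes subject-level band means precise.

## File formats

The portable dialect is a JSON header + little-endian float32
channel-major binary + TSV marker sheet; round trips are bit-exact at
float32. BrainVision support targets the common variant only
(IEEE float32, multiplexed, µV); reading goes through MNE, writing is
native. The audio-cue channel travels as an extra `AUX_CUE` channel in
BrainVision files. Epoch sets and result tables are JSON + binary + TSV
in the same spirit.

## Known limitations

* Infomax is logistic-only (no extended mode); sub-Gaussian components
  are invisible to it.
* The spherical head model is generic: REST output approximates an
  infinity reference for an idealised head, and the ~2–4% round-trip
  error is a model-internal figure, not a claim about real heads.
* The scree elbow rule (largest successive drop, floor 2) is one of many
  conventions; with slowly decaying spectra it is unstable, which is why
  the floor guarantees PC1/PC2 are always examined.
* The selection → PCA → PC-test chain is circular by design (see the
  type-I caveat above); the package reproduces the procedure and
  quantifies the optimism rather than correcting it.
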