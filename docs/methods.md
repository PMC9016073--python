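# Methods

This note documents the models, defaults and numerical choices behind
`spafnirs`, and what the synthetic-data validation does and does not
establish about real recordings.

## Recording model

A session is a 21-minute dyadic protocol: a 1-minute prebaseline
(discarded from analysis), 10 minutes with eyes closed, and 10 minutes of
eye contact. Each subject contributes:

* fNIRS raw intensities at 7.81 Hz on a prefrontal montage of 16 long
  (30 mm) and 8 short (8 mm) source–detector channels at 760 and 850 nm.
  Long channels sense cortical plus superficial tissue; short channels
  sense superficial tissue only.
* Systemic physiology: HR, MAP, PP, SBP, DBP, SpO2 and bilateral EDA and
  skin temperature at 4 Hz; PETCO2 at 1 Hz.

All series share the session clock; signal types keep their native rates
throughout the coherence stage (wavelet scales are computed per rate), and
are only interpolated to a common 4 Hz grid for the correlated-coherence
matrices.

## Preprocessing chain

Intensity → OD uses the natural logarithm with the temporal mean as
reference: OD(t) = −ln(I(t)/⟨I⟩). Channel quality is the coefficient of
variation of raw intensity (sample standard deviation, n−1), computed per
wavelength; a channel is excluded if *either* wavelength is strictly above
7.5 % — the conservative reading, since both wavelengths are needed for
the chromophore inversion. CV is evaluated on intensity, not OD; the
processing chain this mirrors applies quality control before conversion,
and CV of a near-zero-mean OD series is ill-defined.

Short-separation regression operates on OD per wavelength, before the
Beer–Lambert step (matching the listed order intensity → OD → SSR →
concentration): corrected = long − α·short with α = ⟨long, short⟩/⟨short,
short⟩ on mean-centred series. Each long channel regresses against its
nearest short channel, declared in the montage pairing table (two long
channels per short channel in the default montage). A zero-variance short
channel leaves the long channel unchanged with a warning. α is exactly
the least-squares coefficient, so the corrected series is orthogonal to
the short channel; when the superficial weight in the generator is
positive, the corrected series correlates more strongly with the deep
(cerebral) component than the uncorrected series does — this is tested.

The modified Beer–Lambert inversion solves (E·d·DPF)·Δc = OD per sample
with E the 2×2 extinction matrix in 1/(mM·cm) (Kollias–Gratzer
compilation values at 760/850 nm, shipped as a config table), d the
source–detector distance in cm and DPF fixed at 6. Δ[tHb] is defined as
the sum Δ[O2Hb] + Δ[HHb] and holds exactly. ROI averages are unweighted
means over included channels for the left, right and combined prefrontal
regions, emitted in corrected and uncorrected variants: 18 fNIRS signal
types. An ROI whose channels are all excluded is reported missing and
skipped downstream. Motion correction is not performed.

## Wavelet coherence

The continuous wavelet transform uses the analytic Morlet wavelet with
ω₀ = 6, implemented in the Fourier domain with zero-padding to the next
power of two. Scales are dyadic, s_j = s₀·2^(j·dj) with s₀ = 2·dt and
dj = 1/12, extended to the largest Fourier period needed (the lowest band
edge, 0.002 Hz, capped by the series duration). The Fourier period is
λ = 4π·s/(ω₀+√(2+ω₀²)) ≈ 1.033·s, and the cone of influence excludes
points whose period exceeds λ(d)/√2 at distance d from the nearest edge
(the e-folding time of the wavelet envelope is √2·s).

Squared coherence smooths the scale-normalised auto- and cross-spectra
with one common kernel — a Gaussian in time of std s/√2 per scale,
followed by a boxcar across 0.6/dj ≈ 7 scale indices (edge windows
renormalised by their actual overlap). Using the identical positive
kernel in numerator and denominator makes R² a Cauchy–Schwarz ratio:
0 ≤ R² ≤ 1 always, R²(x,x) = 1 exactly, R² symmetric in its arguments.
Time smoothing is applied by FFT with generous zero-padding (≥ 1.5 n,
fast composite length), so circular wrap-around is negligible.

Coherence is computed over the full 1200 s analysis span and segmented
afterwards; a 600 s window alone could not support VLF scales, and the
COI accounts for the edges. Band medians take, per time point, the median
of R² over in-band scales inside the COI; fully masked columns are
missing. A band whose lower edge is at or above the Nyquist frequency is
skipped entirely — this is why PETCO2 (1 Hz) has no cardiac-band series
and the per-dyad count is (29×4)−1 = 115. For the 4 Hz systemic signals
the cardiac band's upper edge coincides with Nyquist; the median simply
uses the scales that exist (≈ 1–1.93 Hz).

Coherence levels are positively biased at finite smoothing spans (a
handful of independent cross-spectral averages per time–scale point), so
absolute WTC values are not interpreted; all inference is comparative —
between conditions, between groups, or against shuffled-pair surrogates,
which share the identical bias.

No pointwise Monte-Carlo significance test of the WTC field is provided;
the shuffled-pair control plays that role at the level where inference
actually happens.

## Condition statistics

Per dyad, signal type and band, the coherence series is averaged over the
unmasked samples of each condition segment. Across dyads these values
enter an aligned-rank-transform (ART) two-way ANOVA: for each effect
(condition, group, condition×group) the responses are aligned by
removing the estimated cell-mean contributions of the other effects,
ranked across the whole dataset (average ranks for ties), and submitted
to a parametric factorial ANOVA; only the aligned-for effect's F is
retained. The ANOVA is a fixed-effects fit with dyad as the observational
unit (two rows per dyad), chosen for determinism and simplicity; a
random-dyad mixed variant was deliberately not added, since the
within-dyad condition contrast is already captured by the alignment and
the calibration below shows nominal behaviour. Note a subtlety: because
alignment subtracts cell means *before* ranking, ART is exactly invariant
under positive affine transforms of the response but not under arbitrary
monotone transforms — unlike a pure rank test.

Calibration (recomputed by `scripts/acceptance.py`): under a 24-dyad
null the condition test rejects at ≈ 5 % at α = 0.05, and a 0.3
coherence shift with noise sd 0.05 is detected at p < 0.001 in ≈ 100 %
of replicates. FDR is Benjamini–Hochberg, applied across the
signal-type × band family separately per effect (one results table per
effect); the family boundary is configurable.

The surrogate control draws random pairs with replacement across draws,
always combining two subjects from different dyads (true and same-subject
pairings are impossible by construction), and runs the byte-identical
condition-average chain — the surrogate is just a `PreprocessedDyad`
with reassigned subjects. True versus surrogate distributions are
compared per signal, band and condition with a two-sided Wilcoxon
rank-sum test (exact enumeration when both samples ≤ 10, tie-corrected
normal approximation otherwise). The reference ensemble size is 2400
pairs; validation runs use 200 for runtime, which only widens the
Monte-Carlo error of the surrogate median.

## Correlated coherence

Per dyad, band and condition, all band-coherence series are linearly
interpolated to a common 4 Hz grid restricted to the segment (grid
points farther than two native sample periods from an unmasked sample
stay missing, so COI gaps are not bridged), and correlated pairwise with
Spearman's rank correlation over pairwise-complete samples (≥ 10
required). Matrices are 29×29 in VLF/LF1/LF2 and 28×28 in the cardiac
band; the diagonal never enters any summary. Group medians keep only
coefficients individually significant at p < 0.05, recording per-cell
support counts. Condition and familiarity contrasts use two-sample
two-sided Kolmogorov–Smirnov tests per cell (asymptotic p), FDR within
band; the familiarity contrast operates on per-dyad difference matrices
Δ = r(eye contact) − r(eyes closed), without significance filtering
(differences of coefficients carry no per-cell p).

Spearman p-values use the large-sample t approximation. Band-coherence
series are strongly autocorrelated, so these nominal p-values are
optimistic; the output records this caveat and a decimation option
(keep every k-th grid sample) is available, with no decimation as the
default.

## Synthetic-data generator

The generator is the test bed: it produces sessions whose coupling
structure is known exactly.

* **Coupled pairs.** Each primitive signal type carries x = s+n₁,
  y = s+n₂ with s, n₁, n₂ independent band-limited Gaussian processes
  (white noise through a zero-phase 4th-order Butterworth band-pass —
  8 effective poles, ≥ 40 dB one octave into the stop band — then
  standardised to exact sample variance). In-band magnitude-squared
  coherence is σ_s²/(σ_s²+σ_n²) squared; the Welch-oracle calibration
  over a shared-variance grid is part of the acceptance suite.
* **Effects.** Condition and familiarity effects are variance gains on
  the shared component only (eye-contact segment / familiar dyads), so
  they map one-to-one onto the coherence formula. An optional
  co-modulation spec multiplies the shared components of two signal
  types by one common slow envelope (band-limited 0.005–0.02 Hz,
  clipped positive) within a segment and group — the construct the
  correlated-coherence contrast detects. A static gain alone cannot
  produce a correlated-coherence effect, since it shifts the level of a
  coherence series without making two series co-vary.
* **fNIRS forward model.** Deep (cerebral) chromophore components per
  hemisphere carry the cross-subject coupling (a `tHb` spec routes one
  common latent into both chromophores, half each, so the sum carries
  the specified variance); one superficial scalp component per subject
  and chromophore (band-limited 0.04–0.12 Hz, sd 0.3 µM) is added to
  long channels with weight 0.5 and measured by short channels with
  0.02 µM noise; channel noise is 0.05 µM. Channel intensities follow
  the exact Beer–Lambert forward model, making the preprocessing chain
  an analytic round trip.
* **Units.** fNIRS latent variances are µM²; systemic signals are
  latent units around instrument-typical baselines (70 bpm, 90 mmHg,
  …) with 0.1-sd broadband measurement noise.
* **Spectra.** Real physiology has 1/f backgrounds, cardiac pulsation,
  respiration harmonics and nonstationarities the generator omits by
  default: tests need controlled spectra first. Consequently, passing
  tests demonstrate that the *pipeline* recovers known coupling
  structure; they do not validate distributional assumptions against
  real recordings, nor the human-subject group results themselves.

Determinism: every stage derives its streams from one seed via spawned
`SeedSequence`s; identical config + seed reproduces sessions bit for bit.

## Problem sizes used in validation

Where the full protocol adds only runtime, validation uses reduced
designs: ART-recovery corpora use 24 dyads with a shortened 330 s
protocol (30 s prebaseline + two 150 s segments); the co-modulation
contrast uses 24 dyads at full length (the envelope needs several cycles
per segment, and group medians need ~12 dyads per familiarity group to
stabilise); surrogate ensembles use 200 draws. Single-
dyad condition-effect checks use full-length segments, since a small
coherence shift needs many coherence degrees of freedom per segment.
Recovery criteria are majority-of-replicates statements (≥ 80 % of 10
seeded corpora), not per-run certainties.

## Known limitations

* Fixed DPF (6) at both wavelengths; no wavelength-dependent pathlength.
* No motion-artifact correction, filtering or detrending beyond the
  stated chain.
* Asymptotic p-values for Spearman and KS; autocorrelation inflates the
  Spearman significance used for median filtering (caveat recorded in
  outputs).
* The eyes-closed segment precedes eye contact in every session (as in
  the protocol), so condition is confounded with time within a session;
  only the shuffled-pair control, which preserves the protocol
  structure, addresses session-level drift.
* Intra-subject (within-person) coupling is out of scope; only
  between-subject pairs are analysed.
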