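# Methods

## Scope and data model

The package covers the computational layer of a biocybernetically adaptive
VR shooting-range: synthetic trainee physiology, HRV and EEG feature
extraction, a nonparametric repeated-measures battery, SSQ scoring, and a
closed-loop difficulty controller. Raw cardiovascular input is the
beat-to-beat R-to-R interval stream of a chest-strap monitor, in device
units of 1/1024 s; raw EEG is a four-channel (TP9, Fp1, Fp2, TP10) series
from a consumer headband, taken here at 500 Hz. Real cohort recordings of
this kind are rarely shareable (consent constraints), so the synthetic
module is a first-class, tested component rather than a fixture.

## Synthetic RRI: integral pulse frequency modulation

Beats are emitted when the integral of an instantaneous rate

    m(t) = (hr_mean/60) · (1 + a_LF sin(2π·0.1t + φ₁) + a_HF sin(2π·0.25t + φ₂)) + ε(t)

crosses successive integer thresholds (ε white, φ seeded). IPFM was chosen
over Gaussian jitter because it makes frequency-domain HRV targets
constructible: a pure 0.25-Hz rate modulation produces a tachogram whose
power sits in the HF band, which the spectral pipeline must recover. The
integral is accumulated on a 1/128-s grid with left-rectangle summation —
exact for a constant rate, so 60 s at 60 BPM yields exactly 60 intervals
of 1024 device units. The rate-noise depth defaults to 0.02 (≈2% of the
beat rate per grid sample), enough to make block-level mean-HR estimates
vary realistically without burying the modulation structure.

## Synthetic EEG: frequency-domain band synthesis

Each channel is a sum of independent Gaussian components, one per band
(δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–100 Hz), plus broadband noise. Each
component is synthesised by drawing complex Gaussian rFFT coefficients on
the band's bins only and inverse-transforming, then scaling to the
requested standard deviation in µV. Synthesis in the frequency domain
confines injected power exactly to its band (no filter transition
leakage), which makes amplitude-to-bandpower checks sharp: doubling a band
amplitude raises its log bandpower by log₁₀4 Bels. Band-edge membership is
half-open [lo, hi) throughout, so the shared 4, 8, 12 and 30 Hz edges are
never double-counted.

Default band amplitudes (δ 6, θ 8, α 7, β 5, γ 2 µV, broadband 2 µV) give
frontal log bandpowers in the 1–2 Bel range typical of consumer-headband
absolute bandpower displays.

## Cohort generator

The default condition profiles encode the characterization trends: mean HR
75 → 95 → 105 → 115 BPM and frontal theta amplitude 9.0 → 8.5 → 7.5 → 6.5 µV
across baseline/easy/medium/hard, with HF modulation receding (0.08 → 0.04)
and LF growing under load. Between-subject variability is a per-participant
Gaussian offset on hr_mean (sd 5 BPM) and a multiplicative theta-amplitude
factor (sd 10%), shared across that participant's four conditions so the
repeated-measures pairing is preserved. Blocks default to 180 s (the
session protocol's 3-min blocks); n defaults to 10.

What the generator does **not** emulate: respiration and
respiratory sinus arrhythmia proper (HF power is injected, not breathed),
ectopic beats, EEG artifacts (blinks, EMG, motion), electrode drift, or
any correlation between HR and EEG beyond their shared condition labels.
Passing tests therefore demonstrate that the pipeline recovers structure
it is pointed at, not that it is robust to real-world contamination.

## HRV pipeline

Time domain: mean HR = 60/mean(RR); SDNN uses the sample (n−1) denominator
(small-n estimator convention); RMSSD is the root mean square of
successive differences, both in ms. Intervals converting outside
[0.3, 2.0] s warn but are never dropped — the source study applied no
ectopic filtering, and silent data editing is worse than a warning.

Frequency domain: the tachogram is cubic-interpolated onto a uniform 4-Hz
grid (standard HRV practice; the upstream toolbox does not state its
rate), mean-removed, and Welch-estimated with 256-sample (64-s) Hann
windows at 50% overlap; band powers are trapezoidal areas under the
one-sided PSD in ms². VLF is computed even on 3-min blocks for fidelity
with the protocol, with the caveat that VLF estimates on windows this
short carry very few spectral degrees of freedom and should not be
interpreted physiologically. A 120-s minimum span is enforced.

## EEG pipeline

PSD: Welch average of Hamming-windowed 256-sample segments. 90% of 256 is
230.4 samples; the hop is fixed at 26 samples (overlap 230) because the
rounding choice is a reproducibility hazard worth pinning. One-sided
density, grid truncated to 110 Hz. Segment means are removed so a sensor
DC offset cannot smear through the window's main lobe into the delta band.
Note that at 500 Hz a 256-sample window has ≈2-Hz bins and a ≈8-Hz main
lobe: adjacent-band smearing at this resolution is a property of the
instrument configuration, not of the generator (generator leakage is
checked with a full-length periodogram).

Absolute bandpower is log₁₀ of the summed PSD bins in each band (Bels,
matching the headband's "absolute bandpower" convention). Engagement and
θ/β are computed on frontal-averaged **linear** band sums — ratios of log
powers depend on the arbitrary power scale — with a `use_log_ratios`
switch for comparison; asymmetry is the log-power difference α(Fp2) −
α(Fp1) per the asymmetry literature. Zero denominators yield NaN, never an
exception. TP9/TP10 are parsed and carried but excluded from the indexes,
mirroring the frontal-only analysis.

## Statistical battery

* Normality: one-sample KS against a normal with the sample's own mean and
  sd; zero-variance samples return a degenerate flag.
* Omnibus: Friedman over within-participant mid-ranks,
  χ² = 12/(nk(k+1))·ΣRⱼ² − 3n(k+1), df = 3. The design is
  repeated-measures, which is why Friedman (and not Kruskal–Wallis) is the
  omnibus here; tests cross-check against `scipy.stats.friedmanchisquare`.
* Post-hoc: Wilcoxon signed-rank with zero differences dropped, mid-ranks
  on |d|, T = min(W⁺, W⁻), Z = (T − n(n+1)/4)/√(n(n+1)(2n+1)/24), two-sided
  normal p **without** continuity correction — the only variant that gives
  Z = −2.80, p = 0.005 at n = 10 with all same-sign differences. At n = 6
  the normal p deviates from the exact 2⁶-enumeration two-sided p by at
  most 0.10 (verified in tests). Under the min-convention Z ≤ 0 always;
  |Z| is invariant under swapping the pair.
* Family: the four planned contrasts (baseline vs easy/medium/hard, easy
  vs hard) at the Bonferroni level 0.05/4 = 0.0125.

The null false-positive rate of the omnibus at n = 10, k = 4 runs slightly
below nominal (≈0.04 in simulation) — the usual mild conservatism of the
χ² approximation at small n.

## SSQ

The 16 items load the three clusters through the standard binary 16×3
matrix (7 unit loadings per cluster), vendored as a data asset with the
instrument's item names. Scores: N = raw_N·9.54, O = raw_O·7.58,
D = raw_D·13.92, TS = (raw_N+raw_O+raw_D)·3.74. Flags use **strict**
inequality against the cut-offs 9.5/15.2/0/15 — the disorientation cut-off
of 0 is only meaningful as "any symptom at all".

## Difficulty, plant and the adaptation rule

Six simulation variables with hard ranges: targets 3–20, size 0.3–3,
speed 0–5 m/s, hardness 1–20, daylight 0–10, rain 0–1. The scalar
difficulty index is the mean of min-max-normalized variables, with size
entering through its reciprocal (smaller = harder) and daylight inverted.
No aggregation rule exists upstream, so the unweighted mean is the
package's choice. Presets: easy = 10 static targets, medium = 10 at
0.5 m/s, hard = 20 at 1 m/s; size 1.5, hardness 10, daylight 8 and rain
0.1 held constant across presets.

The trainee plant is first-order: hr ← hr + (dt/τ)(setpoint − hr) + noise
with τ = 20 s (physiological HR responses settle over tens of seconds),
setpoint linear in the index from 70 BPM (rest) to 125 BPM (maximal
stress) — so the 100–115 zone is reachable but not trivially so — and
frontal theta relaxing toward the opposite-signed map (2.0 Bels at rest
down 0.6 Bels at maximal difficulty). Noise: 0.5 BPM/√s and 0.02 Bels/√s.

The rule samples the plant at 1 Hz, averages 30-sample buffers, and
evaluates every 5 s (neither period is specified upstream; 30 s of
averaging suppresses beat-scale noise while keeping the loop responsive
within a 3-min block). Decision table: below 100 BPM **and** theta above
the 1.5-Bel gate → increase; below zone but theta depleted → hold (the
concentration gate also caps runaway difficulty, since plant theta falls
below 1.5 Bels near the top of the difficulty range); inside the zone →
hold; above 115 BPM → decrease. Only the increase branch is strictly
dictated by the under-challenge scenario; the hold and decrease branches
complete a zone controller, without which the loop is unbounded. An
alternative rule variant gates on frontal alpha at −0.01 Bels (−0.1 dB)
instead of theta.

An increase step raises speed by 0.25 m/s, target count by 1, rain by
0.05, lowers daylight by 0.5 and scales target size by 0.9 (decrease
inverts every component); steps are sized so the controller can traverse
the reachable difficulty range within one 3-min block at the 5-s update
period, and every emitted configuration is clamped to the hard ranges
(clamping is idempotent; hold is a fixed point). Driving rain and daylight
alongside speed/size/count follows the design intent of modulating both
task and environment stressors; with the environment variables frozen the
reachable setpoint range barely clears the zone's lower bound, which makes
for a fragile controller.

Biofeedback: calmness = 1 − |hr − 107.5|/22.5 clamped to [0, 1] (1 at the
zone center, 0 at three zone half-widths out); focus maps theta affinely
from 0.5 Bels below the gate threshold (0) to the threshold (1), clamped.
Shooting performance is destroyed/shots, NaN when no shots were fired.

## End-to-end study runner

`run_full_study` generates a cohort, extracts all eleven features (frontal
θ, θ/β, engagement, asymmetry, mean HR, SDNN, RMSSD, VLF, LF, HF,
performance), runs the battery, and scores synthetic SSQ responses.
Synthetic shooting performance draws shots ≈ 50 and hits binomially with
per-condition probabilities 0.85/0.64/0.46/0.24; the baseline value
represents an unchallenged calibration round so the feature matrix has no
missing cells. Every output table embeds seed, package version and a
config hash in comment headers; identical config + seed reproduces
byte-identical numeric tables.

## Problem sizes and numerical choices

Tests and the acceptance script use 60–180-s blocks, 10 participants,
600-s closed-loop sessions and 200-seed null batteries — sizes at which
every targeted effect is already analytically forced or comfortably
resolved. Band AUC additivity over disjoint sub-bands is exact when the
split frequency lies on the PSD grid; off-grid splits lose one trapezoid
segment. Device-unit rounding (1/1024 s) shifts hand-computed time-domain
values by up to ≈0.5%; test tolerances account for it.

## Known limitations

* The plant is a single first-order lag — no habituation, fatigue,
  circadian drift, or HR/EEG cross-coupling; closed-loop results
  demonstrate controller correctness, not human outcomes.
* VLF on 3-min windows is retained for protocol fidelity but is not
  physiologically interpretable.
* The PSD amplitude convention of the proprietary headband software is
  unknown; one-sided density with summed-bin log powers is this package's
  documented convention, and cross-package absolute levels may differ by a
  constant offset (which cancels in within-subject contrasts and in the
  linear-power ratio indexes).
* The normal-approximation Wilcoxon is inaccurate in the tails below
  n ≈ 10; the exact-enumeration bound in the tests quantifies this at n = 6.
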