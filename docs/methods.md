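# Methods

## Signal model

The coil channel of a magnetometer arena converts head acceleration into
voltage. A head twitch registers as a 50–90 ms wavelet with two spectral
components (40–50 Hz and 80–100 Hz); grooming and locomotor bouts sit
below 40 Hz; jumps produce irregular broadband wavelets that coincide with
pressure spikes on a floor-mounted piezo disc. All thresholds operate on
amplified volts as recorded — no gain correction is applied, because every
constant in the detector is defined on that scale. Samples are assumed
uniform (the CSV reader enforces ≤ 1 ppm time-step jitter) with timestamps
at sample centers, seconds from recording start.

## Detection pipeline

`detect_htr` = band-pass → rectify → envelope → threshold → conditional
peak acceptance.

**Band-pass.** Butterworth order 3, 70–110 Hz, applied forward–backward
(`sosfiltfilt`), i.e. effective order 6 with zero phase. Zero-phase
filtering was chosen so that a symmetric burst's envelope apex does not
shift (verified < 2 ms on synthetic wavelets); the order is a free choice
— the detection criteria, not the roll-off, carry the discrimination.

**Envelope ("double local maxima").** One pass replaces the trace by
linear interpolation through its strict local maxima (plateaus contribute
their midpoint, endpoints are always anchors so no extrapolation occurs);
the construction is applied twice. Pass 1 rides the half-cycle crests of
the rectified oscillation; pass 2 removes the residual scalloping, so a
multi-cycle wavelet becomes one unimodal peak. Linear interpolation was
preferred over splines as the simplest operator consistent with the idea
of maxima smoothing; a property test pins pass 1 to an independent
brute-force implementation, and a third pass changes the envelope maximum
by < 5 % (near-idempotence). One subtlety: pass 1 passes through every
source local maximum exactly, but the pass-2 chord between adjacent
pass-1 peaks may cut below a source maximum that is not itself a pass-1
peak; only the pass-1 version of the pointwise bound is asserted.

**Threshold.** min(15 × SD, 0.075 V), where SD is the standard deviation
of the *signed* band-passed signal over the whole analyzed epoch. The cap
reconciles the two published phrasings of the rule (an SD multiple with a
top limit, versus a flat 0.075 V): the flat value is the capped case. The
SD multiple and the cap meet exactly at noise SD 0.005 V; the boundary is
classified uncapped. A zero-variance signal raises an error rather than
detecting with a zero threshold. An optional robust mode (1.4826 × MAD)
resists SD inflation by dense event trains but is off by default to match
the published detector. Whether the original computes SD over the session
or a baseline epoch is unstated; the analyzed epoch is used (the CLI
`--t-start/--t-end` window selects the epoch).

**Acceptance criteria.** Topographic prominence ≥ threshold; width
< 90 ms, measured at evaluation height peak − prominence/2 with linearly
interpolated crossings; pairwise separation ≥ 200 ms, enforced greedily in
descending prominence (ties to the earlier event) so detection is
deterministic and favors the strongest events. The width bound is strict
(a 90.0 ms peak is rejected). Events within 250 ms of either end of the
trace are discarded as filter-transient guards. Raising the threshold can
never add events (monotonicity), and accepted events always satisfy the
separation bound — both asserted as property tests.

## Jump exclusion

The piezo trace is baseline-corrected by a centered 1 s rolling median
(robust to the very spikes being kept), rectified, and scanned for local
maxima ≥ 0.3 V separated by ≥ 100 ms, so one takeoff/landing ring yields
one annotation. 0.3 V corresponds to ~8 × the piezo noise SD on the
reference hardware; a SD-multiple mode exists for other hardware, absolute
0.3 V is the default. A detection within ±0.1 s of any piezo maximum is
flagged `jump_match`. Matching is interval membership, not one-to-one — a
single jump may shield several spurious detections — and enlarging the
tolerance never un-excludes an event. Excluded events stay in the output.

## Validation metrics

Detections are matched one-to-one to reference annotations of a chosen
class by considering all pairs with |Δt| ≤ tolerance in ascending |Δt| and
accepting a pair iff neither member is taken. At realistic event densities
this equals the minimum-total-|Δt| assignment (checked against exhaustive
enumeration on ≤ 10-event instances) while staying deterministic and
O(k log k). Defaults: 0.5 s tolerance against human video annotation,
0.1 s for sensor-to-sensor comparisons. PPV/FDR/FNR follow the usual
event-level definitions; zero denominators yield flagged NaNs, not
exceptions. A second statistic, `event_class_fp_rate`, reports the
fraction of reference events of an artifact class (e.g. jumps) that
attracted ≥ 1 accepted detection — its denominator is the reference class
size, which is a different quantity from the detection-based FDR, and the
two are deliberately kept as separately named functions.

## Time-course analysis

Accepted events are counted in contiguous half-open bins (default 15 min;
boundary events belong to the later bin; a trailing partial bin is
dropped; total counts are conserved across bin widths that divide the
window). The decay fit is ordinary least squares on (t, ln y) over the
strictly positive bins: λ = −slope (1/min), half-life ln 2/λ (minutes),
with r² of the log-linear fit. Zero bins are excluded by default rather
than offset — an optional +0.5 continuity offset exists but any offset
choice is arbitrary, and exclusion keeps the exact-halving fixture exact.
Flat or growing series yield λ ≤ 0 with the half-life flagged undefined.
The fit window starts at the supplied window's first bin, which for a
post-injection recording is the peak bin; a start index is configurable.
Effect–concentration correlation is a plain Pearson r with a two-sided
t-distribution p on n − 2 degrees of freedom; constant series are flagged.

## Synthetic sessions

The generator renders Gaussian coil noise (default SD 0.002 V), plus
scheduled events:

* **HTR wavelet** — Hann-windowed sum of a dominant 80–100 Hz and a half-
  amplitude 40–50 Hz sinusoid, normalized to a prescribed peak voltage
  (defaults 0.1–0.5 V, 60 ms).
* **Grooming / locomotor** — Hann-windowed sub-40 Hz tone (locomotor
  25–30 Hz); after the 70–110 Hz band-pass its residual RMS is < 5 %.
* **Jump** — Hann-windowed 30–150 Hz colored noise on the coil, paired
  with a 20 ms half-sine piezo spike (default 0.5 V) within ±50 ms of the
  wavelet center. The coil waveform is stochastic by design: its in-band
  energy varies draw to draw, so only a fraction of jumps (well above 0.3
  under the defaults 0.12 s / 0.2 V) triggers the detector, reproducing
  the probabilistic false-positive regime seen in vivo.

Defaults were chosen so the detector's two regimes are both reachable:
with coil noise SD 0.002 V the threshold is 15 × SD ≈ 0.03 V (uncapped,
well below event prominences); raising the noise exercises the 0.075 V
cap. Piezo noise SD 0.0375 V makes 8 × SD equal the 0.3 V jump threshold,
matching the published threshold-to-noise ratio. True in-vivo amplitude
distributions are unpublished; these values are synthetic calibrations,
not measurements, so passing tests demonstrate the detector's logic and
statistical behavior, not field performance on any particular hardware.
Real recordings also contain non-Gaussian, non-stationary noise, sensor
drift and overlapping behaviors that the generator does not emulate.

Schedules are explicit lists, jittered grids with a minimum gap, or an
inhomogeneous Poisson process with intensity r₀·e^(−λt) (thinning).
Coil noise, piezo noise and schedule randomness come from separate seeded
substreams: changing the piezo seed leaves the coil channel bit-identical.
Events scheduled closer than 50 ms trigger a ground-truth-ambiguity
warning but are still rendered.

## Problem sizes in the test and acceptance suites

Statistical suites run at sizes that make their assertions sharp while the
whole suite stays lightweight: noise-only false-positive Monte-Carlo over
20 × 60 s sessions; the sensitivity suite over 10 seeds × 20 events in
40 s sessions (amplitude ≥ 20 × noise SD, gaps ≥ 1 s); λ recovery over
20 Poisson event trains of 8 × 15 min bins at r₀ = 8/min and a 30 min
half-life, fitted from binned counts; one full signal-level Poisson
session of 30 min closes the generate → detect → bin → fit loop. The
acceptance sessions use 27 + 110 events in 420 s and 162 events in 400 s.

## Known limitations

* One recording per file; multi-coil session multiplexing is out of scope.
* Fixed per-epoch threshold — no rolling/adaptive variant; recordings with
  very dense events inflate the plain SD (use the robust mode knowingly).
* The jump filter needs the piezo channel; without it, broadband artifacts
  are only rejected by the width criterion, which is probabilistic.
* Weak-amplitude cohorts (e.g. aged animals) shift the amplitude-to-
  threshold ratio; no preset is provided because no amplitude data exist.
* The 40–200 Hz wide-band view and spectrogram are inspection aids, not a
  detection path.
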