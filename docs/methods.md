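# Methods

This note documents the models, rules and numerical choices behind
`uihkit`, and what the synthetic verification studies do and do not show.

## The experimental workflow being modelled

Transcranial ultrasound stimulation of the hypothalamic preoptic area
(POA) can push a mouse into a torpor-like state: core temperature (T_core)
and metabolic rate (VO₂) fall, the respiratory quotient (RQ = VCO₂/VO₂)
drops toward ~0.7 (fat oxidation), interscapular brown-adipose-tissue
surface temperature (T_BAT) falls while tail temperature rises, and the
animal spontaneously rewarms after roughly an hour.  A bang-bang feedback
controller that fires an ultrasound train whenever telemetry T_core
exceeds a 34 °C setpoint can hold the state for 24 h.  `uihkit`
implements the quantitative analysis for each readout of such an
experiment, plus seeded synthetic generators so that every stage can be
verified against known ground truth without any recorded data.

## Thermoregulatory plant

The simulated animal is a first-order thermal model,

    dT/dt = −k_loss (T − T_amb) + k_therm · H(t)
    dH/dt = (H0 − H) / tau_recovery

where `H ∈ [h_floor, H0]` is thermogenic drive.  Each ultrasound train
decrements `H` by `suppression_per_train` (scaled by acoustic pressure,
see below) and `H` relaxes back with time constant `tau_recovery`.  The
drive is floored at `h_floor`, the basal (obligatory) component of heat
production that POA stimulation does not remove; only the facultative
(BAT) component above the floor is suppressible.  The basal/facultative
split is what makes the closed loop self-limiting: even if trains fire
back to back, the equilibrium temperature cannot fall below
`T_amb + k_therm·h_floor/k_loss` ≈ 30 °C.

Observables are derived from the state: `T_BAT = T_core +
bat_gain·(H − H0)` (the BAT surface leads the core downward when drive is
suppressed), `VO₂ = vo2_gain·H`, and RQ interpolates linearly from
`rq_normal` (0.85) to `rq_torpid` (0.72) as the facultative drive empties.
Gaussian measurement noise is added to each observable; the state itself
is deterministic given the schedule.

Defaults (`T_amb` 22 °C, `k_loss` 0.05 min⁻¹, `k_therm` 0.725 °C·min⁻¹,
`tau_recovery` 60 min, `suppression_per_train` 0.39, `h_floor` 0.55) were
derived once in closed form so that the plant sits at a 36.5 °C
equilibrium, a single default 6-stimulus train produces a ≈3.3 °C core
dip, and the bout (2-s.d. onset to return above 34 °C) lasts about an
hour — the phenomenology of a single torpor bout.  Because the model is
linear, the single-train dip depth is proportional to the suppression:

    depth = k_therm · s · (e^{−λt*} − e^{−k t*}) / (k − λ),
    t* = ln(k/λ)/(k−λ),  λ = 1/tau_recovery,  k = k_loss

`suppression_for_dip` inverts this to program an exact dip depth, which is
the ground truth for the endpoint parameter-recovery studies.

Integration is explicit Euler at `dt ≤ 0.1` min (default 0.05); the
integration error is bounded in tests by comparison with an adaptive
high-accuracy integrator on the same piecewise-linear system.

The plant is an emulation target, not a biophysical claim: it has no
circadian rhythm, no behavioural thermoregulation, no ambient-temperature
dependence of the dose–response, and rewarming kinetics are free
parameters (the literature the package mirrors reports none).

### Pressure dose scaling

Acoustic parameters (pressure, duty cycle, PRF) are carried as train
metadata; only pressure reaches the plant, through a dose factor that is
zero at or below 0.8 MPa (the observed response threshold), linear up to
the 1.6 MPa reference pressure, and saturating at 1 above it.  The
saturation is this package's choice: the mid-session escalation protocol
(+10 % pressure after 12 h, compensating coupling-gel degradation) is a
compensation, not an intended 20 % increase in physiological effect, and
an unsaturated linear extrapolation would make the escalated half of a
session overshoot the control band.

## Thermography

`T_BAT` extraction follows the automated tracking rule: threshold the
frame at ambient + 4 °C (ambient estimated as the mode of border pixels,
0.25 °C bins), keep the largest connected component, estimate the
centroid and principal axis from second-order moments, and place a
3-mm-radius disk ROI 25 % of the body length anterior to the centroid.
The mean over pixels whose centre lies within the disk (strict geometric
rule, checked against a brute-force loop) is the per-frame temperature;
a zero-phase 4th-order Butterworth low-pass (default cutoff 0.1 Hz)
removes camera flicker.  Tail temperature is a 2-mm-diameter disk 10 mm
along the tail from a supplied tail base.

Design choices where the procedure is under-specified:

* **Anterior disambiguation.** The principal axis is orientation-ambiguous.
  The first frame resolves it with an explicit head hint or the
  warmer-end heuristic; subsequent frames keep temporal continuity with
  the previous frame.  Continuity matters because the BAT patch turns
  *cooler* than the trunk mid-bout, which would flip a per-frame
  warm-end rule.
* **Tail suppression.** A morphological opening (default structuring
  radius 1.5 mm) removes the tail from the body mask before pose
  estimation, so body length excludes the tail.
* **Degenerate masks** (< 10 px) are an error, not a guess.
* Body length is the mask extent projected on the axis plus one pixel
  (pixel-centre extent underestimates object extent).

In the rendered synthetic scenes the painted BAT patch has a 5-mm radius
— the interscapular depot is ~10 mm across — so the 3-mm measurement ROI
sits inside it and sub-millimetre tracking error does not mix trunk
pixels into the ROI, exactly as in the physical measurement.

## Physiological endpoints

All endpoints compare an extremum in a fixed post-stimulus search window
against a pre-stimulus baseline mean, with half-open `[start, end)`
windows in seconds relative to ultrasound onset:

| signal | baseline | search |
|--------|----------|--------|
| T_BAT  | [−15 min, 0) | [7 min, 12 min) |
| T_core | [−6 min, −1 min) | [0, 30 min) |
| VO₂    | [−6 min, −1 min) | [0, 30 min) |
| RQ     | [−30 min, −2 min) | [45 min, 55 min) |

Bout onset is the first post-stimulus sample below baseline mean − 2 s.d.
(sample s.d., n−1; the convention is configurable but fixed here), bout
end the first return of T_core to 34 °C, and duration their difference.
Extrema are computed sample-wise with no interpolation; only the RQ ratio
aligns VCO₂ to VO₂ by nearest neighbour within 30 s.

## Closed-loop controller

Pure bang-bang: sample telemetry T_core every minute; if the sample
strictly exceeds `T_set` (34 °C) and no train is in progress, fire a
train (6 × 10-s stimuli, 20-s inter-stimulus gaps → 30-s onset-to-onset
period, 1.6 MPa); at or below `T_set`, hold.  After 12 h, pressure is
multiplied by 1.1 and the stimulus count raised to 8 for subsequent
trains.  A NaN sample holds and logs a warning.  Re-triggering during a
train is suppressed rather than queued (the telemetry interval, 60 s, is
shorter than a train, 160 s; the protocol source is silent on this and
suppression is the conservative choice).

The controller battery (100 seeded 24-h sessions) asserts a hard safety
invariant — no train onset at a sample ≤ `T_set` — and an efficacy band:
after the first sample at or below the setpoint, ≥ 90 % of samples lie in
[T_set − 2, T_set + 0.5] °C.  With the default plant the sessions sit at
≈ 32.9 °C mean with ~23.5 h below 34 °C.

## Photometry

Processing chain for stimulus-locked GCaMP traces: zero-phase 2nd-order
Butterworth high-pass at 0.01 Hz (de-bleach), z-score over the full
recording (sample s.d.; normalisation span configurable), peak detection
by topographic prominence (default 2 z-units; checked against an
exhaustive prominence oracle), and per-train window statistics — peak
amplitude, mean z, peak frequency — in three windows: 5 s before onset,
10 s during, 15 s after offset.  Evoked-activity onset is the first
post-onset sample with z above the 5-s pre-window mean + 3 s.d.  In vitro
ΔF/F = (F − F₀)/F₀ uses the same onset rule.

For detecting individual transients in noisy traces, `transient_peaks`
low-passes at 0.5 Hz before detection (matched to the ~1-s transient
kernel, so white sensor noise cannot reach a 2-z prominence) and then
refines each candidate's time to the transient's leading edge on the
unsmoothed z-trace: the first sample exceeding the local pre-event
mean + 3 s.d. that *sustains* the level for 3 samples (a lone noise spike
cannot; a transient decaying over seconds does).  The leading edge is the
identifiable landmark of a sharp-rise/slow-decay transient: the smoothed
maximum lags it by the filter width, and the raw maximum wanders along
the flat decay with noise.  At the 5:1 amplitude-to-noise boundary the
refined peak time is within 2 samples of truth in ≈ 98/100 seeds, and
the 3-s.d. onset statistic in ≥ 99/100.

## Histology quantification

A cell is positive for a marker when its mean intensity strictly exceeds
the whole-brain background mean + 3 s.d. (sample s.d.; pixels under cell
masks excluded from the background).  Region fractions are positives over
cells in the region; the coexpression fraction defaults to B-positives
among A-positives (the denominator is exposed because the prose
convention is ambiguous).  Cell segmentation is out of scope — the module
consumes per-cell intensity tables.

## snRNA-seq rules

* **QC:** remove cells with mitochondrial fraction > 5 %, detected genes
  > 7,500, or < 200 — strict inequalities, so boundary cells are kept.
  Mitochondrial counts are `mt-`-prefixed genes.
* **Normalisation:** ln(1 + count/total × 10,000) (natural log), zeros
  preserved.
* **Variable features:** top 4,000 genes by dispersion (variance/mean of
  normalised values, n−1 variance) after removing a 139-gene IEG list.
  The packaged list is a synthetic stand-in (well-known activity-regulated
  gene symbols padded with clearly synthetic placeholders) and is
  caller-replaceable; the curated list it stands in for is not printed in
  the literature this package mirrors.
* **Torpor clusters:** k-means (k = 2 by default, seeded, 10 restarts)
  on per-cluster mean normalised expression of *Adcyap1*, *Qrfp*, *Esr1*;
  the component with the higher centroid mean is torpor-associated.  The
  number of torpor clusters is an outcome, not a parameter, so k is
  exposed.
* **Activated cluster:** torpor clusters ranked by the mean of per-gene
  z-scored IEG expression (*Fos*, *Fosb*, *Nr4a1*, *Egr1*, *Dusp1*),
  z-scored across the torpor set; exact ties are broken by cluster id and
  flagged.
* **Excitatory/inhibitory:** mean normalised *Slc17a6* vs *Gad1* above a
  0.5 threshold; both → hybrid, neither → unassigned.

Graph-based community detection is deliberately not reimplemented:
cluster labels are an input (ground-truth labels in the synthetic
studies).  The rules above — not the clustering — are the bespoke content.

## Synthetic generators: what they emulate and what they do not

Every generator is a pure function of its parameters and a seed and
returns its ground truth.  The thermal renderer paints an elliptical body
(34 °C), a BAT disk following the programmed T_BAT trace, a 2-mm tail and
ambient background, with optional per-pixel Gaussian noise and body
drift.  The photometry generator is an exponential bleach plus
instant-rise/exponential-decay transients plus white noise.  Cell tables
draw intensities from Gaussian positive/negative distributions with
Bernoulli region fractions.  Count matrices are Poisson draws around
per-cluster marker means with heavy-tailed filler-gene rates, per-cell
depth factors and a targeted mitochondrial fraction.

None of these reproduce the hard parts of real data: fur occlusion and
radiometric drift in thermography, isosbestic artefacts and motion in
photometry, segmentation error in histology, ambient RNA, doublets and
batch structure in snRNA-seq.  Passing the recovery studies therefore
shows that the *rules are implemented correctly and are recoverable under
their stated noise model* — not that the rules are robust to every
real-world artefact.

## Verification battery and problem sizes

`scripts/acceptance.py --seed N --out results.json` recomputes, from
scratch: oracle equivalence on 8 × 1,000 random instances; dip recovery
(99 rendered videos, depths 1/2/3 °C, pixel noise 0.1 °C, ±0.15 °C
tolerance); photometry recovery (100 seeds at the 5:1 amplitude bound);
histology fraction recovery (fractions 0.02/0.10/0.30, 500 cells/region,
3 binomial-s.e. tolerance); the 100-session controller battery;
snRNA-seq recovery (100 seeds, 2,000 genes × 3,000 cells, 8-fold
markers); stage-rerun determinism; and the default-plant endpoint demo.
These sizes keep the full battery in a few minutes on one CPU while
leaving every statistical threshold comfortably resolvable.

## Known limitations

* The plant's dose–response saturation above 1.6 MPa is an assumption;
  dose studies in the emulated literature only bracket 0.4–1.6 MPa.
* Heart-rate endpoints are not modelled (ECG analysis is out of scope).
* The thermography tracker assumes a single animal and a temperature-
  calibrated camera.
* `lognormalize` densifies per-column in a Python loop; fine at 10⁴
  cells, not tuned for 10⁶.
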