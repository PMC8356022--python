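# Methods

## Coordinate and sampling conventions

Depth `z` is measured in micrometres basal to the apical tissue margin:
apically directed motion therefore has negative velocity, and all printed
thresholds can be used verbatim (rapid apical: ≤ −10 μm / 30 min; basal:
≥ +15 μm / ≥ 2 h). Trajectories must be uniformly sampled (default
δt = 10 min, the standard acquisition interval for nuclear-motility
recordings); tracks with missing frames are rejected rather than
interpolated, because every downstream formula (velocity, MSD lags, sliding
windows) assumes a constant δt. Units are fixed to μm and minutes — no unit
autodetection. Duplicate `(track_id, t)` rows are an error, and a
configurable minimum track length is exposed (default 2 frames; how short
tracks were censored in typical acquisitions is not knowable from the data
contract, so no stronger default is imposed).

## Kinematics

Velocity is the first difference of *raw* positions divided by δt;
acceleration is the first difference of velocity, again δt-normalized for
unit consistency (μm/min²). Differencing raw positions and smoothing the
derivatives (rather than smoothing positions before differencing) keeps the
telescoping identity Σ v·δt = z_N − z_1 exact; the alternative order is a
deliberate non-feature. Smoothing is a centred moving average, default
window 5 frames (50 min), chosen to suppress frame-to-frame tracking jitter
while leaving ~1 h translocations intact. At series edges the window is
truncated to the frames that exist (e.g. `[0, 3, 0]` with window 3 →
`[1.5, 1.0, 1.5]`), so smoothed series keep full length and event detection
near track ends remains defined.

## Event detection

Two apical criteria operate at different granularity and are kept as
distinct classes rather than unified: *directional* segments are maximal
runs of same-signed smoothed velocity lasting ≥ 60 min (zero velocity breaks
runs; a `max_interruption` parameter, default 0, can tolerate brief
opposite-signed frames), while *rapid apical* events are sliding 30-min
windows with net displacement ≤ −10 μm. All thresholds are inclusive,
exactly as printed, and configurable.

Qualifying rapid windows that overlap or abut are merged into one event —
without merging, a single 60-min run would be counted once per qualifying
window. Within each merged event, phase landmarks are located on the
smoothed series: the translocation peak at the velocity minimum (earliest
frame on ties), the onset at the nearest preceding local minimum of
acceleration, and the cessation at the nearest following local maximum.
Local extrema use a plateau-aware three-point neighbour rule (a plateau
strictly below/above its neighbours counts once, at its first frame); when
no interior extremum exists the extreme value within one window-length of
the event boundary is used. Velocity index *i* maps to frame *i* (the
interval start) and acceleration index *j* to frame *j + 1* (its centre).

*Basal persistent* movements scan all spans of ≥ 120 min freely (not
anchored to directional segments); a span qualifies when its whole-span net
displacement is ≥ +15 μm, and overlapping qualifying spans merge into
maximal events. *Oscillations* are rapid → basal → rapid subsequences
counted greedily left-to-right with chaining (the closing rapid event can
open the next cycle), so K rapid events interleaved with basal movements
yield K − 1 cycles.

Event rates are normalized as count / cumulative recording minutes × 1000,
where cumulative recording time is the sum of trajectory durations
(n_frames − 1)·δt; this makes recordings with different track counts and
durations comparable. Start-depth histograms use left-closed, right-open
bins anchored at 0 μm and report per-bin rates, which by construction sum
to the class rate.

## MSD analysis

The estimator is the overlapping-pairs time average with denominator N − n
(not the independent-pairs variant). Population profiles average
per-trajectory MSDs lag-by-lag, unweighted across tracks — each cell
contributes equally regardless of track length — with the across-track
SEM as dispersion. Both fits are constrained through the origin because
both models (2RDΔt with R = 1, and aΔt²) have no intercept; a negative
fitted coefficient is clipped to zero with a warning. Long-lag MSD values
average few displacement pairs and are high-variance, so the default fit
range is lags ≤ one third of the maximum available lag; the range is a
parameter and is echoed in all outputs.

## Permutation inference

The exact permutation scheme behind "two-way ANOVA with post hoc Monte
Carlo permutation" is underdetermined, so the package declares one:
Freedman–Lane residual permutation. For each tested term (two main effects
and the interaction, sum-to-zero coding), the reduced model without that
term is fitted; its residuals are permuted, added back to the reduced-model
fit, and the term's F statistic is recomputed, giving an asymptotically
exact null that respects the other terms. Post hoc pairwise contrasts
permute labels between the two contrasted levels. All p-values use the
add-one estimator, so p ∈ [1/(B+1), 1] and p = 0 is impossible; default
B = 9999. Degenerate responses (zero residual variance) are resolved
deterministically: F = 0 when the term explains nothing, F = ∞ when the
full model fits exactly but the reduced one does not, so constant data
yield p = 1 on every term. The experimental unit is the retina /
experimental repeat — callers aggregate to one scalar per unit before
testing; the API takes per-unit values only and cannot silently permute
frame-level observations. No multiple-testing correction is applied beyond
the permutation scheme itself. The routine pairwise tests (unpaired t,
Mann-Whitney, with D'Agostino–Pearson routing in `auto` mode) delegate to
scipy.

## Synthetic data

The trajectory generator is a regime-switching 1-D random walk at δt = 10
min over 73 frames (12 h). Every interval carries Gaussian diffusive noise
of variance 2·D·δt; basal regimes add +drift·δt and rapid regimes subtract
speed·δt (block profile) or follow a half-sine-squared speed bump (smooth
profile) whose increments are exact integrals of the continuous profile.
Regimes are exclusive — drift and rapid motion never superimpose — and the
ground-truth log tiles each track without gaps. Depth reflects at the
apical margin (nuclei remain anchored apically); there is no basal boundary
by default. For smooth events the log also records the analytic landmarks:
the acceleration minimum at one quarter of the event (onset), the velocity
minimum at its centre (peak) and the acceleration maximum at three quarters
(cessation), in fractional frames.

Default parameters are the measured study conditions where such values are
printed: rapid speeds uniform on 0.3–1.2 μm/min (only the range is known,
so the least-informative distribution on it is used), duration 60 min,
arrival rate 0.3 events/1000 min as a Poisson process, and an oscillation
preset of 3% of tracks carrying one scripted (not emergent) rapid → basal →
rapid cycle — scripted so the cycle count is exact ground truth. Where no
value is printed the defaults are declared modeling choices: resting
diffusivity D = 0.05 μm²/min (between the stationary late-stage coefficient
of movement ~0.03 and the early-stage total ~0.25, which includes event
contributions); basal drift 0.125 μm/min with 180-min episodes (net ~22 μm,
comfortably over the 15 μm/2 h criterion it must emulate) at 1.7
episodes/1000 min (≈ 493 basal movements across 394 twelve-hour tracks, the
frequency scale of an early-postnatal cohort); starting depths uniform on
20–80 μm. `scripted_rapid_tracks` / `scripted_basal_tracks` assign exactly
one event to that many tracks for detector validation, where per-event
ground truth must be unambiguous; scripted tracks get enough initial depth
headroom that a scripted run is not folded by the reflecting boundary.

Detector-validation cohorts use background D = 0.02 μm²/min, scripted rapid
speeds 0.5–0.8 μm/min and basal episodes of 0.15 μm/min × 180 min. These
sizes were chosen by power analysis up front: a 30-min displacement at
D = 0.02 has σ ≈ 1.1 μm against a ≥ 5 μm margin to the −10 μm threshold,
and a 180-min basal episode nets 27 μm against the 15 μm threshold with
σ ≈ 2.6 μm, so misses and false alarms are ≥ 4σ events and recall/precision
are expected to be exact at cohort sizes of tens of events.

The histology generator places correctly localized nuclei uniformly within
the local ONL (the real depth distribution is bottom-heavy, but uniform is
the simplest declared choice and displacement scoring only depends on the
margin side), and displaced nuclei 0.5–10 μm basal to the basal margin.
The synapse generator spaces ribeye foci ≥ 5 μm apart and places mGluR6
puncta at 0.1–0.45 μm (apposed) or ≥ 1 μm / absent (unapposed), so the
0.51 μm criterion classifies every focus unambiguously and cross-apposition
to a neighbouring focus is geometrically impossible.

What the generators do *not* emulate: tracking noise and track loss,
spatially varying ONL thickness, nuclear crowding interactions between
neighbours, emergent (rather than scripted) oscillation timing, and any
image-level artefact. Passing tests therefore demonstrate that the
estimators and detectors are correct under the declared kinematic model at
realistic parameter values — not that the model captures every feature of
live recordings.

## Histology scoring

Relative ONL position is 100·(z − apical)/(basal − apical), computed
against the margins at the nucleus's own tangential position; it may be
negative or exceed 100%. "Basally displaced" is strict (z > basal margin);
the margins themselves count as correctly localized; nuclei apical to the
apical margin are flagged `apically_ectopic` separately and never folded
into "displaced", since the displacement rule only speaks about the basal
side. Densities are per en-face area with two reporting units (per
1000 μm² and per mm², differing by exactly 1000). Apposition distance is
centroid-to-centroid in 3-D and inclusive at the threshold. Shape and
location are input labels — classifying them from morphology is an imaging
task outside this package. Per-cell fractions are averaged across cells
(cells with zero foci contribute to the focus-count mean but are excluded
from shape/apposition denominators), matching per-cell reporting practice.

## Numerical choices and problem sizes

Simulation-backed tests use cohorts of 25–300 tracks × 73 frames, 1000
null datasets × 999 permutations for calibration, and 97–200 objects for
histology/synapse recovery — sizes at which every Monte Carlo tolerance in
the suite corresponds to ≥ 95% coverage while the full suite and the
acceptance script each complete in seconds. Spacing uniformity uses a
relative tolerance of 1e-9; threshold comparisons are exact (inclusive)
with a 1e-12 guard only where a fit-range boundary is compared to a float
lag. Time-reversing a trajectory changes only the summation order of the
MSD estimator, so equality holds to ~1e-15 relative rather than bitwise.
All randomness flows through `numpy.random.default_rng` seeds carried in
configs and results; identical seeds give bit-identical outputs.

## Known limitations

- Event classes may overlap across (not within) classes by design: a rapid
  apical run is typically also part of a directional apical segment.
- The rapid-apical detector reports merged window spans; net displacement
  is measured over the merged span, which can slightly exceed the
  translocation proper before landmark refinement.
- Freedman–Lane permutation is asymptotically, not exactly, level-α for
  small unbalanced designs; calibration is verified at n = 20.
- The generators emit 1-D depth trajectories only; tangential (xy) motion,
  when needed for lateral-displacement checks, must be added by the caller.
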