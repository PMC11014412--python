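# Methods

## Problem and signal model

A karate forefist punch recorded by a wrist-worn 3-axis accelerometer ends
in a sharp deceleration when the arm reaches full extension: the deepest
negative excursion of the X axis (the axis along the forearm) marks the
*striking sample* μ. A *pre-action* — a fist pull, an arm drop, a sideways
shake of the fist — is a small movement immediately preceding the punch
that telegraphs its timing. It is hard to detect with whole-gesture
classifiers because its energy is dwarfed by the punch itself.

The detector exploits one asymmetry: the waveform *just before* the strike
is nearly the same for every competent punch, while anything further back
in time is punch-irrelevant. All comparisons are therefore anchored at μ
and run backwards.

## Detection procedure

Given an input trace `D` and a reference set of `J` pre-action-free
templates `W_j` (each with its own striking sample ν_j):

1. **Anchor and reverse.** The template's pre-strike segment
   (ν_j + 1 samples, strike first) is fixed. The input's pre-strike window
   of length ℓ, also reversed, grows one sample at a time:
   ℓ = ℓ_min … μ + 1.
2. **Cost profile.** For every ℓ, the dependent multivariate DTW distance
   (one shared warping path, per-step cost summed over X, Y, Z; squared
   difference by default) between the growing window and the fixed
   template is recorded — `CostList_j(ℓ)`. An incremental engine extends
   the DP matrix by one row per sample, so the whole profile costs the
   same as one full DTW, and each entry is exactly equal to a from-scratch
   recomputation (the full-matrix routine is itself implemented as
   repeated row extensions, making the equality structural rather than
   numerical).
3. **Extrema and gap.** While the window covers only the punch, cost
   falls; once it reaches back into movement the templates do not contain,
   cost rises. Scanning in increasing ℓ, ψ is the first local minimum and
   φ the first subsequent local maximum (plateaus collapse to their first
   index). The *gap* `C_max − C_min` measures the foreign — pre-action —
   energy.
4. **Template choice and verdict.** The template with the smallest `C_min`
   is the best-matching punch style; its gap is compared with the
   threshold `T`. `gap > T` ⇒ pre-action present, localized to the
   forward-time sample interval `[μ − ℓ_φ + 1, μ − ℓ_ψ + 1)`.

Templates are built per expert by rigid alignment of repeated clean
punches at their striking samples, truncation to the common window, and a
pointwise mean (`reference.build_template`). Averaging, rather than
selecting a single punch, damps whatever residual micro-movements even a
skilled punch carries. DTW-barycenter averaging was deliberately not used:
rigid strike-anchored averaging is the simplest scheme consistent with
per-sample means, and the strike anchor is the one fiducial the data
guarantee.

## Numerical and design choices

**Profile start (ℓ_min).** When the query window is much shorter than the
fixed template, DTW must compress the template many-to-one; the resulting
costs are huge and non-monotone in ℓ and reflect window-length mismatch,
not similarity. These degenerate lengths would otherwise supply a spurious
first min/max pair on *every* input. The profile therefore starts at
ℓ_min = ⌈(ν_j + 1)/3⌉ per template — a 3:1 compression bound in the spirit
of classic DTW slope constraints — leaving the informative descending limb
and cost floor intact. `ell_min` is an explicit parameter everywhere for
callers who want the full profile.

**Smoothing.** Under sensor noise the cost floor chatters at one-sample
scale (wiggles of order 10³ against gaps of order 10⁸); a literal
first-extremum scan latches onto the first wiggle. The high-level
estimator therefore applies a centred width-3 moving average before
scanning (`smoothing=3`; pass `None` for raw profiles). Extremum values
are read off the scanned curve, which also guarantees `gap ≥ 0`
(the curve is non-decreasing between a local minimum and the next local
maximum).

**Boundary maximum.** A profile that is still rising at ℓ = μ + 1 (the
cost keeps creeping upward after the pre-action ends, so no interior
maximum forms) has the maximum of its final ascent at the boundary; the
first index of the final run is then accepted as φ. Interior maxima, when
they exist, are always found first.

**Threshold T and units.** With squared local costs, profile values and
gaps scale with the *square* of signal amplitude. The shipped default
`T = 0.90e8` is expressed in squared raw sensor counts and is only
meaningful at that scale; any new sensor or unit requires
`calibrate_threshold`, which computes gaps once and sweeps candidate
thresholds, picking the accuracy maximizer (ties to the smaller
threshold, favouring recall). Traces carry their unit as a string and no
conversion is ever attempted.

**Identity behaviour.** An input bit-identical to a template has a
strictly decreasing profile ending at 0, hence no interior minimum and a
zero gap — exactly, when the template's own quiet segments are exactly
zero (e.g. templates built from noise-free signals). Templates averaged
from noisy recordings retain a noise floor, and a self-match then shows a
residual wiggle gap of order 10³–10⁴: negligible against any practical
threshold, but not floating-point zero.

**Degenerate inputs.** Constant X channel → strike undetectable, explicit
error. Profiles with fewer than 3 points, or without a local minimum,
make that template ineligible; if every template is ineligible the verdict
is "no pre-action". Strike ties break to the earliest sample. Samples
after μ never influence the profile, the gap, or the verdict.

## Baseline classifier

The comparison method makes none of the above moves: it sums three
*independent* single-axis DTW distances over whole traces, averages the
distance to each bank participant's punches, and returns the group label
(with/without pre-action) of the nearest participant, ties to the earliest.
The query's own participant must be excluded (`LabeledPunchBank.excluding`).
Per-participant averaging, not pooling, is essential: a participant holding
the single globally nearest punch can still lose to one whose punches are
uniformly close.

## Velocity indicator

Peak hand speed is the maximum Euclidean norm of the per-axis cumulative
trapezoidal integral of acceleration up to μ. Gravity and sensor bias are
proxied by the per-axis mean over the integration window and subtracted
first (`detrend="mean"`); optional moving-average smoothing suppresses
noise. Output is km/h when the trace unit is m/s²; for any other unit the
conversion is refused and the value is returned in native unit·s with a
flag. Peak (not at-strike) speed is reported: the punch decelerates through
the strike, so the peak is the natural "how fast was the punch" number.
Single integration over a sub-second window keeps bias drift second-order;
no gyroscope-based gravity rotation is attempted (the pipeline has no
gyroscope).

## Synthetic data: what it does and does not emulate

All tests run on simulated punches (`synth`): raised-cosine segments on a
`lead-in | pre-action slot | approach | strike | follow-through` timeline,
with per-punch tempo jitter (±15% on all durations), white Gaussian noise,
and three injectable pre-action archetypes — `fist_pull` (negative-then-
positive X excursion), `arm_lower` (Y-dominant drop with a small Z
component), `side_shake` (3-cycle Z oscillation). The slot is always on
the timeline (silent when no pre-action is injected) so labels differ by
waveform content, not trace length. All randomness flows from the config
seed; identical configs are bit-reproducible.

Default scale: strike 8000, approach 3000, pre-action 5000, noise SD 80
(arbitrary sensor counts, `unit="raw"`); durations 0.15 / 0.25 / 0.25 /
0.08 / 0.12 s at 100 Hz. The sample rate is a free configuration — the
algorithm is rate-agnostic — and 100 Hz is a typical wearable rate. The
amplitudes were chosen once so that injected pre-actions produce squared-
cost gaps in the 10⁷–10⁸ band where the shipped default threshold scale is
meaningful, with pre-action energy well above noise.

What the simulator does **not** capture: biomechanical coupling between
axes, orientation change of gravity during the punch, sensor saturation,
multi-punch streams, and the idiosyncratic, poorly-repeatable shapes of
real human pre-actions. Passing tests therefore demonstrate that the
algorithm behaves as designed under its stated assumptions — not that the
shipped default threshold or the measured accuracies transfer to real
recordings, which would require calibration on labeled sensor data.

## Problem sizes

The shipped experiments use a reference set of 5 simulated experts × 30
clean punches, 100 punches per class for calibration/evaluation (50/50
split), 200 baseline queries against a 4-participant bank, 300–1000 random
window pairs for the DTW enumeration cross-check, and ~60–110-sample
traces throughout; one full acceptance run takes a few seconds on one CPU.
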