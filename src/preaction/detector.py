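"""Pre-action estimation from a single punch trace.

The method anchors every comparison at the striking sample — the global
negative peak of X-axis acceleration, where the arm reaches full extension
and decelerates hard — then walks *backwards* in time.  The pre-strike
segment of the input is reversed and compared, at every window length
ℓ = ℓ_min … μ+1, against the fixed reversed pre-strike segment of each
expert template.  The DTW distance as a function of ℓ (the *cost profile*)
first falls while the windows cover only the punch itself, then rises once
the growing window reaches back into a movement the templates do not
contain.  The rise — the gap between the first local minimum and the first
subsequent local maximum of the profile — is the pre-action score; a gap
above the threshold T yields a "pre-action present" verdict, and the ℓ-range
between the two extrema maps back to a forward-time interval locating the
pre-action.

Units and scale: with the default squared-difference local cost, profile
values and gaps scale with the *square* of the signal amplitude.  The
shipped default threshold ``DEFAULT_THRESHOLD`` (0.90e8) is meaningful only
at the original sensor's native scale; any other pipeline should calibrate
T on labeled data via :func:`calibrate_threshold`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dtw import DtwConfig, GrowingDtw
from .io import AccelTrace, ReferenceSet, Template

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_WINDOW",
    "DEFAULT_SMOOTHING",
    "StrikeDetectionError",
    "CostProfile",
    "ExtremaResult",
    "EstimationResult",
    "detect_striking_index",
    "cut_and_reverse",
    "compute_cost_profile",
    "find_extrema",
    "default_ell_min",
    "estimate_preaction",
    "calibrate_threshold",
]

#: Decision threshold on the extremum gap, in squared sensor-native units.
DEFAULT_THRESHOLD = 0.90e8

#: Absolute floor on the smallest reversed-window length in a cost profile.
DEFAULT_MIN_WINDOW = 2

#: Default moving-average width applied to profiles before extrema scanning.
DEFAULT_SMOOTHING = 3


def default_ell_min(template_prestrike_len: int) -> int:
    """Default smallest window length for a template whose reversed
    pre-strike segment has ``template_prestrike_len`` samples.

    Very short windows force the fixed template to compress many-to-one
    onto the query; those degenerate alignments measure window-length
    mismatch rather than waveform similarity, and their cost is large and
    non-monotone in ℓ, which would masquerade as the profile's first
    extrema.  Bounding the compression at 3:1 (a slope constraint in the
    spirit of classic DTW step-pattern limits) starts the profile on the
    informative descending limb while leaving room for the cost floor
    before any pre-action-driven rise.
    """
    return max(DEFAULT_MIN_WINDOW, -(-(template_prestrike_len) // 3))


class StrikeDetectionError(ValueError):
    """Raised when no striking sample can be located in a trace."""


def detect_striking_index(trace: AccelTrace) -> int:
    """Index μ of the striking sample: the global minimum of the X channel.

    The punch decelerates sharply at full arm extension, so the strike shows
    as the deepest negative X-axis excursion.  Ties break to the earliest
    sample.  A constant X channel has no meaningful minimum and is rejected.
    """
    x = trace.x
    if np.all(x == x[0]):
        raise StrikeDetectionError(
            f"{trace.source_id or 'trace'}: X channel is constant; "
            "no striking sample detectable"
        )
    return int(np.argmin(x))


def cut_and_reverse(trace: AccelTrace, mu: int, length: int) -> np.ndarray:
    """Reversed pre-strike window: samples at forward indices
    ``[mu - length + 1, mu]``, with the strike sample first.

    ``length`` must satisfy ``1 <= length <= mu + 1``.  Applying the cut
    twice with the same arguments and reversing restores forward order.
    """
    if not (1 <= length <= mu + 1):
        raise ValueError(
            f"window length {length} out of range [1, {mu + 1}] for strike index {mu}"
        )
    return trace.samples[mu - length + 1: mu + 1][::-1]


@dataclass(frozen=True)
class CostProfile:
    """DTW distance versus reversed-window length for one template.

    ``distances[k]`` is the DTW distance at window length
    ``ell = ell_min + k``; the final entry corresponds to the full
    pre-strike prefix ``ell = mu + 1``.
    """

    distances: np.ndarray
    template_id: str
    ell_min: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.distances, dtype=np.float64)
        if np.any(arr < 0):
            raise ValueError("cost profile distances must be non-negative")
        object.__setattr__(self, "distances", arr)

    def __len__(self) -> int:
        return int(self.distances.shape[0])

    def ell(self, k: int) -> int:
        """Window length corresponding to profile position ``k``."""
        return self.ell_min + k


_ABSENT = -1


@dataclass(frozen=True)
class ExtremaResult:
    """First local minimum / subsequent first local maximum of a profile.

    ``psi`` and ``phi`` are 0-based positions *into the profile* (window
    length = ``ell_min + position``); ``-1`` marks an absent extremum, in
    which case ``gap`` is 0.
    """

    psi: int
    phi: int
    c_min: float
    c_max: float
    gap: float

    @property
    def has_pair(self) -> bool:
        return self.psi != _ABSENT and self.phi != _ABSENT

    @property
    def has_min(self) -> bool:
        return self.psi != _ABSENT


@dataclass(frozen=True)
class EstimationResult:
    """Verdict for one input punch.

    ``interval`` is the estimated pre-action location as a half-open
    forward-time sample interval ``[start, end)``, non-empty only when
    ``has_preaction`` is true.
    """

    has_preaction: bool
    gap: float
    threshold: float
    best_template_id: str | None
    interval: tuple[int, int] | None
    striking_index: int
    profile: CostProfile | None = None
    extrema: ExtremaResult | None = None

    def to_dict(self) -> dict:
        """JSON-ready summary (used by the CLI)."""
        return {
            "has_preaction": bool(self.has_preaction),
            "gap": float(self.gap),
            "threshold": float(self.threshold),
            "best_template_id": self.best_template_id,
            "interval_samples": list(self.interval) if self.interval else None,
            "striking_index": int(self.striking_index),
            "profile": None if self.profile is None else
                       [float(v) for v in self.profile.distances],
            "profile_ell_min": None if self.profile is None else self.profile.ell_min,
        }


def compute_cost_profile(
    trace: AccelTrace,
    mu: int,
    template: Template,
    cfg: DtwConfig = DtwConfig(),
    ell_min: int | None = None,
) -> CostProfile:
    """Growing-window cost profile of ``trace`` against one template.

    The template side is fixed: its full reversed pre-strike segment
    (length ν+1, strike first).  The query side is the reversed pre-strike
    window of the input, grown one sample at a time from ℓ=1 back towards
    the start of the trace; distances are recorded for ℓ in
    ``[ell_min, mu + 1]`` (``ell_min=None`` applies the 2:1 slope rule of
    :func:`default_ell_min`).  Computed with the O(m)-per-step incremental
    DTW engine, which is exactly equivalent to recomputing full DTW at
    each ℓ.
    """
    nu = template.striking_index
    if ell_min is None:
        ell_min = default_ell_min(nu + 1)
    if ell_min < 1:
        raise ValueError("ell_min must be >= 1")
    w_rev = cut_and_reverse(template.trace, nu, nu + 1)
    engine = GrowingDtw(w_rev, cfg)
    distances = []
    for ell in range(1, mu + 2):
        d = engine.extend(trace.samples[mu - ell + 1])
        if ell >= ell_min:
            distances.append(d)
    return CostProfile(
        distances=np.asarray(distances, dtype=np.float64),
        template_id=template.label,
        ell_min=ell_min,
    )


def _plateau_runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse equal-valued runs: return (run start indices, run values)."""
    keep = np.ones(len(values), dtype=bool)
    keep[1:] = values[1:] != values[:-1]
    starts = np.nonzero(keep)[0]
    return starts, values[starts]


def find_extrema(profile: CostProfile, smoothing: int | None = None) -> ExtremaResult:
    """Locate the first local minimum ψ and the first local maximum φ > ψ.

    Scanning the profile in increasing window length: ψ is the first
    interior position whose value is below both neighbours, φ the first
    interior position after ψ whose value is above both neighbours.
    Plateaus (runs of equal values) collapse to their first position.  When
    no qualifying pair exists the gap is 0 and the missing extrema are
    marked absent (-1).

    ``smoothing`` optionally applies a centred moving average of the given
    odd width before scanning (edges use the shrunken window); off by
    default.
    """
    values = profile.distances
    if len(values) < 3:
        raise ValueError("profile too short for extrema (need >= 3 points)")
    if smoothing is not None and smoothing > 1:
        kernel = np.ones(int(smoothing))
        values = np.convolve(values, kernel, mode="same") / np.convolve(
            np.ones_like(values), kernel, mode="same"
        )

    starts, runvals = _plateau_runs(values)
    psi = phi = _ABSENT
    c_min = c_max = np.nan
    for k in range(1, len(runvals) - 1):
        prev_v, v, next_v = runvals[k - 1], runvals[k], runvals[k + 1]
        if psi == _ABSENT:
            if v < prev_v and v < next_v:
                psi = int(starts[k])
                c_min = float(values[psi])
        else:
            if v > prev_v and v > next_v:
                phi = int(starts[k])
                c_max = float(values[phi])
                break
    # a profile that still rises at the end of the scan has the maximum of
    # its final ascent at the boundary: accept the last run as φ
    if psi != _ABSENT and phi == _ABSENT and runvals[-1] > runvals[-2]:
        phi = int(starts[-1])
        c_max = float(values[phi])
    if psi == _ABSENT or phi == _ABSENT:
        return ExtremaResult(psi=psi, phi=phi,
                             c_min=c_min if psi != _ABSENT else np.nan,
                             c_max=np.nan, gap=0.0)
    return ExtremaResult(psi=psi, phi=phi, c_min=c_min, c_max=c_max,
                         gap=c_max - c_min)


def estimate_preaction(
    trace: AccelTrace,
    refset: ReferenceSet,
    threshold: float = DEFAULT_THRESHOLD,
    cfg: DtwConfig = DtwConfig(),
    *,
    ell_min: int | None = None,
    smoothing: int | None = DEFAULT_SMOOTHING,
) -> EstimationResult:
    """Full verdict for one punch against a reference set.

    One cost profile is computed per template; the winning template j* is
    the one with the smallest first-local-minimum value C_min (templates
    whose profile has no local minimum, or is too short for extrema, are
    ineligible — if all are ineligible the verdict is "no pre-action").
    The verdict compares j*'s gap C_max − C_min against ``threshold``; on a
    positive verdict the pre-action interval is the forward-time sample
    range spanned by the two extrema,
    ``[mu − ell(phi) + 1, mu − ell(psi) + 1)``.
    """
    if len(refset) < 1:
        raise ValueError("reference set is empty")
    mu = detect_striking_index(trace)

    best: tuple[float, CostProfile, ExtremaResult] | None = None
    last_profile: CostProfile | None = None
    for template in refset:
        prof = compute_cost_profile(trace, mu, template, cfg, ell_min)
        last_profile = prof
        if len(prof) < 3:
            continue
        ext = find_extrema(prof, smoothing)
        if not ext.has_min:
            continue
        if best is None or ext.c_min < best[0]:
            best = (ext.c_min, prof, ext)

    if best is None:
        return EstimationResult(
            has_preaction=False, gap=0.0, threshold=threshold,
            best_template_id=None, interval=None, striking_index=mu,
            profile=last_profile, extrema=None,
        )

    _, prof, ext = best
    gap = ext.gap
    has_pre = gap > threshold
    interval = None
    if has_pre and ext.has_pair:
        start = mu - prof.ell(ext.phi) + 1
        end = mu - prof.ell(ext.psi) + 1
        interval = (int(start), int(end))
    return EstimationResult(
        has_preaction=has_pre, gap=float(gap), threshold=float(threshold),
        best_template_id=prof.template_id, interval=interval,
        striking_index=mu, profile=prof, extrema=ext,
    )


def calibrate_threshold(
    labeled: Sequence[tuple[AccelTrace, bool]],
    refset: ReferenceSet,
    candidate_thresholds: Sequence[float],
    cfg: DtwConfig = DtwConfig(),
    *,
    ell_min: int | None = None,
    smoothing: int | None = DEFAULT_SMOOTHING,
) -> tuple[float, pd.DataFrame]:
    """Pick the gap threshold maximizing accuracy on labeled punches.

    Gaps are computed once per trace; every candidate threshold is then a
    cheap comparison.  Returns ``(best_threshold, table)`` where the table
    has one metrics row per candidate (see :func:`preaction.evaluation.sweep`);
    ties in accuracy break to the smaller threshold.
    """
    from .evaluation import sweep  # local import to avoid a cycle

    if not labeled:
        raise ValueError("need at least one labeled trace")
    if not candidate_thresholds:
        raise ValueError("need at least one candidate threshold")
    gaps = np.array([
        estimate_preaction(t, refset, threshold=np.inf, cfg=cfg,
                           ell_min=ell_min, smoothing=smoothing).gap
        for t, _ in labeled
    ])
    labels = np.array([bool(lab) for _, lab in labeled])
    table = sweep(gaps, labels, candidate_thresholds)
    best_idx = int(table.sort_values(
        ["accuracy", "threshold"], ascending=[False, True], kind="stable"
    ).index[0])
    return float(table.loc[best_idx, "threshold"]), table
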