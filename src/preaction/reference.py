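"""Building pre-action-free reference templates.

Each expert contributes many repetitions of a clean forefist punch; a
single template per expert is produced by rigid alignment at the striking
sample and pointwise averaging.  Averaging suppresses the small residual
preliminary movements that even a skilled punch may carry.

Alignment scheme: every punch is anchored at its detected striking index;
the common window keeps ``min_pre`` samples before the strike (the minimum
pre-strike length over the expert's punches) and ``min_post`` samples from
the strike onward (the minimum post-strike length), so the template's
striking index is ``min_pre``.  Punches are not resampled or warped before
averaging.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .detector import detect_striking_index
from .io import AccelTrace, ReferenceSet, Template

__all__ = ["build_template", "build_reference_set"]


def build_template(punches: Sequence[AccelTrace], label: str = "") -> Template:
    """Average repeated punches into one template.

    Punches are aligned at their striking indices and truncated to the
    common window ``[strike - min_pre, strike + min_post)``; the template is
    the per-sample, per-axis arithmetic mean and its striking index is
    ``min_pre``.  The result is independent of punch order, and averaging a
    single punch (or identical punches) reproduces the punch on the common
    window.
    """
    if len(punches) == 0:
        raise ValueError("need at least one punch to build a template")
    units = {p.unit for p in punches}
    if len(units) > 1:
        raise ValueError(f"punches mix units: {sorted(units)}")
    rates = {p.sample_rate_hz for p in punches}
    if len(rates) > 1:
        raise ValueError(f"punches mix sample rates: {sorted(rates)}")

    strikes = [detect_striking_index(p) for p in punches]
    min_pre = min(strikes)
    min_post = min(len(p) - mu for p, mu in zip(punches, strikes))
    length = min_pre + min_post
    if length < 2:
        raise ValueError("common aligned window shorter than 2 samples")

    stack = np.stack([
        p.samples[mu - min_pre: mu + min_post]
        for p, mu in zip(punches, strikes)
    ])
    mean = stack.mean(axis=0)
    trace = AccelTrace(
        samples=mean,
        sample_rate_hz=punches[0].sample_rate_hz,
        source_id=label or "template",
        unit=punches[0].unit,
    )
    return Template(trace=trace, striking_index=min_pre, label=label)


def build_reference_set(
    per_expert_punches: Mapping[str, Sequence[AccelTrace]],
) -> ReferenceSet:
    """One averaged template per expert; J equals the number of experts."""
    if not per_expert_punches:
        raise ValueError("need at least one expert")
    templates = [
        build_template(punches, label=str(expert))
        for expert, punches in per_expert_punches.items()
    ]
    units = {t.trace.unit for t in templates}
    if len(units) > 1:
        raise ValueError(f"experts mix units: {sorted(units)}")
    return ReferenceSet(tuple(templates), unit=templates[0].trace.unit)
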