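"""Seeded synthetic punch generator with ground truth.

The human recordings behind this problem are not publicly available, so
every test and experiment in this package runs on simulated wrist
acceleration.  A simulated forefist punch is assembled from raised-cosine
(Hann-windowed) segments on a common timeline:

``lead-in | pre-action slot | approach | strike | follow-through``

* **approach** — smooth positive X-axis lobe (the arm accelerating towards
  the target), with small sympathetic Y/Z components;
* **strike** — a short, deep negative X-axis lobe (the abrupt deceleration
  at full arm extension); its minimum is the ground-truth striking sample;
* **pre-action slot** — always present on the timeline so that traces with
  and without pre-actions have comparable layouts; for ``none`` (or zero
  amplitude) it stays silent.  Three archetypes can be injected:
  ``fist_pull`` (negative-then-positive X excursion), ``arm_lower``
  (Y-dominant downward excursion) and ``side_shake`` (Z oscillation).

Raised cosines keep the signal continuous and differentiable, avoiding DTW
artifacts from step discontinuities.  Tempo jitter rescales all segment
durations per punch so generated punches differ in length, and white
Gaussian noise is added throughout.  All randomness flows from the config
seed; identical configs produce bit-identical traces.

The default amplitude scale mimics raw sensor counts of a wearable
accelerometer, placing squared-cost profile gaps in the 10⁷–10⁸ range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

from .baseline import LabeledPunchBank, Participant
from .io import AccelTrace, save_trace

__all__ = [
    "PreactionType",
    "SynthConfig",
    "PunchTruth",
    "generate_punch",
    "generate_dataset",
    "generate_expert_punches",
]

PreactionType = Literal["none", "fist_pull", "arm_lower", "side_shake"]

_PREACTION_TYPES = ("none", "fist_pull", "arm_lower", "side_shake")


@dataclass(frozen=True)
class SynthConfig:
    """Simulator settings for one punch.

    Durations are seconds, amplitudes are in the trace unit (raw sensor
    counts by default).  ``tempo_jitter`` is the half-width of the uniform
    factor applied to all durations (0.15 → durations scaled by
    U[0.85, 1.15]); ``seed`` fixes all randomness.
    """

    sample_rate_hz: float = 100.0
    lead_in_s: float = 0.15
    preaction_duration_s: float = 0.25
    approach_duration_s: float = 0.25
    strike_duration_s: float = 0.08
    tail_s: float = 0.12
    strike_amplitude: float = 8000.0
    approach_amplitude: float = 3000.0
    preaction_type: PreactionType = "none"
    preaction_amplitude: float = 5000.0
    tempo_jitter: float = 0.15
    noise_sd: float = 80.0
    unit: str = "raw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preaction_type not in _PREACTION_TYPES:
            raise ValueError(
                f"preaction_type must be one of {_PREACTION_TYPES}, "
                f"got {self.preaction_type!r}"
            )
        for name in ("lead_in_s", "preaction_duration_s", "approach_duration_s",
                     "strike_duration_s", "tail_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.tempo_jitter < 1):
            raise ValueError("tempo_jitter must be in [0, 1)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")


@dataclass(frozen=True)
class PunchTruth:
    """Ground truth attached to a generated punch.

    ``preaction_interval`` is the half-open sample interval of the injected
    movement (``None`` when absent); ``peak_speed`` is the noise-free peak
    hand speed implied by the approach lobe, in unit·s.
    """

    label: bool
    strike_index: int
    preaction_interval: tuple[int, int] | None
    peak_speed: float


def _hann(n: int) -> np.ndarray:
    if n < 1:
        return np.zeros(0)
    if n == 1:
        return np.ones(1)
    return np.hanning(n)


def _n_samples(duration_s: float, rate: float, factor: float) -> int:
    return max(2, int(round(duration_s * factor * rate)))


def generate_punch(cfg: SynthConfig) -> tuple[AccelTrace, PunchTruth]:
    """Simulate one punch; returns the trace and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    factor = 1.0 + rng.uniform(-cfg.tempo_jitter, cfg.tempo_jitter)
    rate = cfg.sample_rate_hz

    n_lead = _n_samples(cfg.lead_in_s, rate, factor)
    n_pre = _n_samples(cfg.preaction_duration_s, rate, factor)
    n_appr = _n_samples(cfg.approach_duration_s, rate, factor)
    n_strk = _n_samples(cfg.strike_duration_s, rate, factor)
    n_tail = _n_samples(cfg.tail_s, rate, factor)
    n = n_lead + n_pre + n_appr + n_strk + n_tail

    sig = np.zeros((n, 3))

    # pre-action slot (always on the timeline; silent when none / amplitude 0)
    pre_start = n_lead
    pre_end = n_lead + n_pre
    amp = cfg.preaction_amplitude
    if cfg.preaction_type == "fist_pull" and amp != 0:
        half = n_pre // 2
        sig[pre_start: pre_start + half, 0] -= amp * _hann(half)
        sig[pre_start + half: pre_end, 0] += amp * _hann(n_pre - half)
    elif cfg.preaction_type == "arm_lower" and amp != 0:
        w = _hann(n_pre)
        sig[pre_start:pre_end, 1] -= amp * w
        sig[pre_start:pre_end, 2] += 0.2 * amp * w
    elif cfg.preaction_type == "side_shake" and amp != 0:
        tau = np.linspace(0.0, 1.0, n_pre)
        sig[pre_start:pre_end, 2] += amp * np.sin(2 * np.pi * 3 * tau) * _hann(n_pre)

    # approach: positive X lobe with small sympathetic Y/Z motion
    a0 = pre_end
    w_appr = _hann(n_appr)
    sig[a0: a0 + n_appr, 0] += cfg.approach_amplitude * w_appr
    sig[a0: a0 + n_appr, 1] += 0.10 * cfg.approach_amplitude * w_appr
    sig[a0: a0 + n_appr, 2] -= 0.08 * cfg.approach_amplitude * w_appr

    # strike: deep negative X lobe; its centre is the striking sample
    s0 = a0 + n_appr
    w_strk = _hann(n_strk)
    sig[s0: s0 + n_strk, 0] -= cfg.strike_amplitude * w_strk
    strike_index = s0 + int(np.argmax(w_strk))

    if cfg.noise_sd > 0:
        sig = sig + rng.normal(0.0, cfg.noise_sd, size=sig.shape)

    label = cfg.preaction_type != "none" and amp != 0
    truth = PunchTruth(
        label=label,
        strike_index=strike_index,
        preaction_interval=(pre_start, pre_end) if label else None,
        peak_speed=0.5 * cfg.approach_amplitude * (n_appr / rate),
    )
    trace = AccelTrace(
        samples=sig,
        sample_rate_hz=rate,
        source_id=f"synth-{cfg.preaction_type}-{cfg.seed}",
        unit=cfg.unit,
    )
    return trace, truth


def _participant_style(base: SynthConfig, rng: np.random.Generator) -> SynthConfig:
    """Per-participant habits: durations and amplitudes scaled a little."""
    return replace(
        base,
        approach_duration_s=base.approach_duration_s * rng.uniform(0.9, 1.1),
        strike_amplitude=base.strike_amplitude * rng.uniform(0.9, 1.1),
        approach_amplitude=base.approach_amplitude * rng.uniform(0.9, 1.1),
        preaction_amplitude=base.preaction_amplitude * rng.uniform(0.9, 1.1),
    )


def generate_dataset(
    n_per_class: int,
    seed: int,
    base_cfg: SynthConfig | None = None,
    *,
    n_participants_per_class: int = 5,
    outdir: str | Path | None = None,
) -> tuple[LabeledPunchBank, dict[str, list[PunchTruth]]]:
    """Balanced labeled punch bank with per-trace ground truth.

    ``n_per_class`` punches per label are split across
    ``n_participants_per_class`` simulated participants per class, each
    with its own movement style; positive-class punches cycle through the
    three pre-action archetypes.  Tempo jitter guarantees unequal trace
    lengths.  When ``outdir`` is given, traces are written as CSV plus a
    YAML truth manifest, and regenerating with the same seed reproduces
    the files bit-exactly.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if base_cfg is None:
        base_cfg = SynthConfig()
    ss = np.random.SeedSequence(seed)
    style_rng = np.random.default_rng(ss.spawn(1)[0])
    seed_iter = iter(ss.generate_state(2 * n_per_class + 64).tolist())

    pre_types = ("fist_pull", "arm_lower", "side_shake")
    participants: list[Participant] = []
    truths: dict[str, list[PunchTruth]] = {}
    for label in (False, True):
        counts = np.full(n_participants_per_class, n_per_class // n_participants_per_class)
        counts[: n_per_class % n_participants_per_class] += 1
        k_global = 0
        for p_idx, count in enumerate(counts):
            if count == 0:
                continue
            pid = f"{'with' if label else 'without'}-{p_idx}"
            style = _participant_style(base_cfg, style_rng)
            punches, ptruths = [], []
            for _ in range(count):
                ptype = pre_types[k_global % 3] if label else "none"
                k_global += 1
                cfg = replace(style, preaction_type=ptype,
                              seed=int(next(seed_iter)) % (2 ** 31))
                trace, truth = generate_punch(cfg)
                punches.append(trace)
                ptruths.append(truth)
            participants.append(Participant(pid, tuple(punches), label))
            truths[pid] = ptruths

    bank = LabeledPunchBank(tuple(participants))
    if outdir is not None:
        _write_dataset(bank, truths, Path(outdir), seed)
    return bank, truths


def _write_dataset(bank: LabeledPunchBank, truths: dict[str, list[PunchTruth]],
                   outdir: Path, seed: int) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for participant in bank:
        for k, (trace, truth) in enumerate(
            zip(participant.punches, truths[participant.participant_id])
        ):
            fname = f"{participant.participant_id}-{k:03d}.csv"
            save_trace(trace, outdir / fname)
            entries.append({
                "file": fname,
                "participant": participant.participant_id,
                "label": bool(truth.label),
                "strike_index": int(truth.strike_index),
                "preaction_interval": (
                    list(truth.preaction_interval)
                    if truth.preaction_interval else None
                ),
            })
    manifest = {
        "seed": int(seed),
        "sample_rate_hz": float(bank.participants[0].punches[0].sample_rate_hz),
        "unit": bank.participants[0].punches[0].unit,
        "traces": entries,
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def generate_expert_punches(
    n_experts: int,
    punches_per_expert: int,
    seed: int,
    base_cfg: SynthConfig | None = None,
) -> dict[str, list[AccelTrace]]:
    """Clean (pre-action-free) punches from simulated experts with distinct
    tempos, ready for :func:`preaction.reference.build_reference_set`."""
    if n_experts < 1 or punches_per_expert < 1:
        raise ValueError("need >= 1 expert and >= 1 punch per expert")
    if base_cfg is None:
        base_cfg = SynthConfig()
    ss = np.random.SeedSequence(seed)
    style_rng = np.random.default_rng(ss.spawn(1)[0])
    seed_iter = iter(ss.generate_state(n_experts * punches_per_expert).tolist())
    out: dict[str, list[AccelTrace]] = {}
    for e in range(n_experts):
        style = _participant_style(
            replace(base_cfg, preaction_type="none"), style_rng
        )
        punches = []
        for _ in range(punches_per_expert):
            cfg = replace(style, seed=int(next(seed_iter)) % (2 ** 31))
            trace, _ = generate_punch(cfg)
            punches.append(trace)
        out[f"expert{e}"] = punches
    return out
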